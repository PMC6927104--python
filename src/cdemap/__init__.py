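"""cdemap: semi-automated mapping of ISO 11179 CDEs to BRIDG classes.

Fit a :class:`CDEMapper` to a corpus of data elements with known BRIDG
class mappings; the fitted :class:`MapperResults` recommends candidate
classes for new data elements and evaluates top-n match rates.
"""

from .corpus import (
    ATTRIBUTE_FIELDS,
    CDECorpus,
    CDERecord,
    SplitConfig,
    cap_class_members,
    filter_by_class_size,
    read_corpus,
    split_train_verify,
    write_corpus,
)
from .evaluate import (
    EvaluationReport,
    Recommendation,
    SweepPoint,
    class_similarity,
    dec_concept_overlap,
    evaluation_table,
    make_grid,
    match_rate,
    recommend,
    restrict_to_sufficient,
    sweep_parameters,
)
from .exceptions import (
    CdemapError,
    ConfigurationError,
    DegenerateInputError,
    DuplicateIdError,
    SchemaError,
    ValidationError,
)
from .model import (
    CDEMapper,
    MapperResults,
    TrainingConfig,
    TrainingState,
    other_class_avg,
    train,
    training_error,
    update_weights,
    within_class_avg,
)
from .similarity import (
    SimilarityCache,
    SimilarityWeights,
    attribute_similarity,
    attribute_vector,
    edit_distance,
    greedy_reduce,
    greedy_similarity_list,
    overall_similarity,
    tokenize,
    word_similarity,
    word_similarity_matrix,
)
from .synthetic import SyntheticConfig, generate_corpus, perturb_word

__version__ = "0.1.0"

__all__ = [
    "ATTRIBUTE_FIELDS",
    "CDECorpus",
    "CDEMapper",
    "CDERecord",
    "CdemapError",
    "ConfigurationError",
    "DegenerateInputError",
    "DuplicateIdError",
    "EvaluationReport",
    "MapperResults",
    "Recommendation",
    "SchemaError",
    "SimilarityCache",
    "SimilarityWeights",
    "SplitConfig",
    "SweepPoint",
    "SyntheticConfig",
    "TrainingConfig",
    "TrainingState",
    "ValidationError",
    "attribute_similarity",
    "attribute_vector",
    "cap_class_members",
    "class_similarity",
    "dec_concept_overlap",
    "edit_distance",
    "evaluation_table",
    "filter_by_class_size",
    "generate_corpus",
    "greedy_reduce",
    "greedy_similarity_list",
    "make_grid",
    "match_rate",
    "other_class_avg",
    "overall_similarity",
    "perturb_word",
    "read_corpus",
    "recommend",
    "restrict_to_sufficient",
    "split_train_verify",
    "sweep_parameters",
    "tokenize",
    "train",
    "training_error",
    "update_weights",
    "within_class_avg",
    "word_similarity",
    "word_similarity_matrix",
    "write_corpus",
]
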
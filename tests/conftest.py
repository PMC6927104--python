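import pytest
from hypothesis import settings

from cdemap import CDECorpus, CDERecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_record(
    pid: str,
    long_name: str = "",
    object_class: str = "",
    property_name: str = "",
    value_domain_long_name: str = "",
    representation_term: str = "",
    question_text: str = "",
    dec_concepts=None,
    mapped_class=None,
) -> CDERecord:
    return CDERecord(
        public_id=pid,
        long_name=long_name,
        object_class=object_class,
        property_name=property_name,
        value_domain_long_name=value_domain_long_name,
        representation_term=representation_term,
        question_text=question_text,
        dec_concepts=dec_concepts,
        mapped_class=mapped_class,
    )


@pytest.fixture
def worked_pair():
    """The two leukemia-classification CDEs used as the running example."""
    acute = CDERecord(
        public_id="2178693",
        long_name="Acute Myeloid Leukemia Classification Type",
        object_class="Acute Myeloid Leukemia",
        property_name="Classification",
        value_domain_long_name="Acute Myeloid Leukemia Classification Type",
        representation_term="Acute Myeloid Leukemia Type",
        question_text="What was the classification of the acute myelogenous leukemia?",
        mapped_class="PerformedDiagnosis",
    )
    chronic = CDERecord(
        public_id="2178694",
        long_name="Chronic Myelogenous Leukemia Classification Type",
        object_class="Chronic Myelogenous Leukemia",
        property_name="Classification",
        value_domain_long_name="Chronic Myelogenous Leukemia Classification Type",
        representation_term="Chronic Myelogenous Leukemia Type",
        question_text="What was the classification of the chronic myelogenous leukemia?",
        mapped_class="PerformedDiagnosis",
    )
    return acute, chronic


@pytest.fixture
def tiny_labeled_corpus():
    """Three well-separated classes of three records each.

    Class vocabularies are disjoint, so every within-class similarity
    exceeds every between-class similarity under any simplex weights.
    """
    records = []
    vocab = {
        "Alpha": ("bola rota", "nive", "tudo", "What was the nive of the bola rota"),
        "Beta": ("kema lupo", "gira", "sefa", "What was the gira of the kema lupo"),
        "Gamma": ("dopu vemi", "hato", "rilo", "What was the hato of the dopu vemi"),
    }
    for cls, (oc, prop, rep, qt) in vocab.items():
        for i in range(3):
            records.append(
                CDERecord(
                    public_id=f"{cls}-{i}",
                    long_name=f"{oc} {prop} {rep}",
                    object_class=oc,
                    property_name=prop,
                    value_domain_long_name=f"{rep} type",
                    representation_term=rep,
                    question_text=qt,
                    dec_concepts=frozenset(oc.split() + [prop, rep]),
                    mapped_class=cls,
                )
            )
    return CDECorpus(records)
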
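"""Shared fixtures: published count tables and small synthetic inputs.

Everything is generated programmatically — the published top-five count
rows and the multimorbidity gene rows are tiny and typed in directly; all
larger inputs come from :mod:`comine.simulate`.
"""

import io

import pytest

from comine.genesets import GeneSetCollection
from comine.lexicon import MeshDescriptor, build_lexicon

# Published top-five co-occurrence counts: co-disease -> (p_each_pair, p_all,
# 4-dp sort ratio).
TABLE1 = {
    "Dementia": (142, 843, 0.1684),
    "Type 2 diabetes": (95, 843, 0.1127),
    "Hypertension": (60, 843, 0.0712),
    "Parkinson's disease": (51, 843, 0.0605),
    "Down Syndrome": (43, 843, 0.0510),
}

# Published four-count rows: co-disease -> (n_both, n_cd_only, n_idx_only,
# n_total, published FET p).
TABLE2 = {
    "Dementia": (142, 220, 1066, 125_924, 1.30e-238),
    "Type 2 diabetes": (95, 11_209, 1113, 125_924, 0.68),
    "Hypertension": (60, 6726, 1148, 125_924, 0.59),
    "Parkinson's disease": (51, 683, 1157, 125_924, 6.28e-30),
    "Down syndrome": (43, 346, 1165, 125_924, 1.88e-34),
}

SIGNIFICANT_TABLE2 = {"Dementia", "Parkinson's disease", "Down syndrome"}

# Published multimorbidity rows: exact disease signature -> gene set.
TABLE3_ROWS = {
    frozenset({"AD", "dementia", "Parkinson's disease", "Down syndrome"}): {
        "MAPT", "PSEN1", "APP", "APOE",
    },
    frozenset({"AD", "dementia", "Parkinson's disease"}): {
        "A2M", "ABCA7", "PLAU", "PSEN2", "MPO",
    },
    frozenset({"AD", "dementia", "Down syndrome"}): {"COL18A1", "SYNJ1"},
    frozenset({"AD", "dementia", "hypertension", "Parkinson's disease"}): {"HFE", "NOS3"},
    frozenset({"AD", "Parkinson's disease", "Down syndrome"}): {"SORL1"},
    frozenset({"AD", "type 2 diabetes", "hypertension"}): {"NOTCH2"},
    frozenset({"AD", "dementia", "hypertension"}): {"TGFB2"},
    frozenset({"AD", "dementia", "type 2 diabetes"}): {"LAMA1"},
}

TABLE3_DISEASES = (
    "AD",
    "dementia",
    "type 2 diabetes",
    "hypertension",
    "Parkinson's disease",
    "Down syndrome",
)


def table3_collection(extra_private: bool = True) -> GeneSetCollection:
    """Gene-set collection whose exact-membership rows are the published ones.

    ``extra_private`` adds a private index-only gene and one pairwise-only
    gene, which must not create or alter multimorbidity rows.
    """
    sets: dict[str, set[str]] = {d: set() for d in TABLE3_DISEASES}
    for diseases, genes in TABLE3_ROWS.items():
        for d in diseases:
            sets[d].update(genes)
    if extra_private:
        sets["AD"].add("PRNP")  # index-only
        sets["AD"].add("BIN1")  # AD + dementia only: pairwise, not multimorbid
        sets["dementia"].add("BIN1")
    return GeneSetCollection(sets=sets, index_disease="AD")


@pytest.fixture
def table3() -> GeneSetCollection:
    return table3_collection()


@pytest.fixture
def toy_lexicon():
    """Six-disease lexicon plus one animal-only descriptor (excluded)."""
    descriptors = [
        MeshDescriptor("Alzheimer Disease", frozenset({"Nervous System Diseases"})),
        MeshDescriptor("Dementia", frozenset({"Nervous System Diseases"})),
        MeshDescriptor("Diabetes Mellitus, Type 2", frozenset({"Nutritional and Metabolic Diseases"})),
        MeshDescriptor("Hypertension", frozenset({"Cardiovascular Diseases"})),
        MeshDescriptor("Parkinson Disease", frozenset({"Nervous System Diseases"})),
        MeshDescriptor("Down Syndrome", frozenset({"Congenital Abnormalities"})),
        MeshDescriptor("Foot Rot", frozenset({"Animal Diseases"})),
    ]
    return build_lexicon(descriptors, excluded_categories={"Animal Diseases"})


MEDLINE_TWO_RECORDS = """\
PMID- 10000001
TI  - Comorbid dementia in a neurodegeneration cohort.
MH  - *Alzheimer Disease/genetics
MH  - Dementia
MH  - Comorbidity

PMID- 10000002
MH  - Hypertension
MH  - Diabetes Mellitus,
      Type 2/epidemiology
MH  - Comorbidity
"""


@pytest.fixture
def medline_stream():
    return io.StringIO(MEDLINE_TWO_RECORDS)
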
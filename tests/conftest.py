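import pytest

from rarephenome.codes import CodeHierarchy, CodeNode, System


@pytest.fixture
def icd10_hierarchy() -> CodeHierarchy:
    """A small ICD-10 extract: categories with subcode children."""
    nodes = [
        CodeNode(System.ICD10, "C96", "other neoplasms of lymphoid tissue"),
        CodeNode(System.ICD10, "C96.0", "multisystemic Langerhans-cell histiocytosis", ["C96"]),
        CodeNode(System.ICD10, "C96.5", "unisystemic Langerhans-cell histiocytosis", ["C96"]),
        CodeNode(System.ICD10, "C96.6", "unifocal Langerhans-cell histiocytosis", ["C96"]),
        CodeNode(System.ICD10, "L21", "seborrhoeic dermatitis"),
        CodeNode(System.ICD10, "L21.1", "seborrheic infantile dermatitis", ["L21"]),
        CodeNode(System.ICD10, "E27", "other disorders of adrenal gland"),
        CodeNode(System.ICD10, "E27.1", "primary adrenocortical insufficiency", ["E27"]),
        CodeNode(System.ICD10, "A07", "other protozoal intestinal diseases"),
        CodeNode(System.ICD10, "A07.3", "isosporiasis", ["A07"]),
    ]
    return CodeHierarchy(System.ICD10, nodes)


@pytest.fixture
def orpha_hierarchy() -> CodeHierarchy:
    nodes = [
        CodeNode(System.ORPHA, "ORPHA:389", "Langerhans cell histiocytosis"),
        CodeNode(System.ORPHA, "ORPHA:300", "infantile erythroderma"),
        CodeNode(System.ORPHA, "ORPHA:314", "Leiner disease", ["ORPHA:300"]),
        CodeNode(System.ORPHA, "ORPHA:85138", "primary adrenocortical insufficiency"),
        CodeNode(System.ORPHA, "ORPHA:472", "isosporiasis"),
        CodeNode(System.ORPHA, "ORPHA:210", "cyclosporosis"),
    ]
    return CodeHierarchy(System.ORPHA, nodes)
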
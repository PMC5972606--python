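import pytest

from helpers import make_terminology


@pytest.fixture
def onco_terminology():
    return make_terminology(
        [
            ("C1", "breast cancer", ["cancer of the breast"], ["T047"], ["C3"]),
            ("C2", "metastasis", [], ["T191"], []),
            ("C3", "neoplasm", [], ["T191"], []),
            ("C4", "cancer", [], ["T047"], ["C3"]),
            ("C5", "aspirin", [], ["T121"], []),
            ("C6", "chest pain", [], ["T184"], []),
            ("C7", "dyspnea", [], ["T184"], []),
            ("C8", "poliovirus", [], ["T005"], []),
        ]
    )


@pytest.fixture
def semgroup_table(tmp_path):
    path = tmp_path / "groups.txt"
    path.write_text(
        "DISO|Disorders|T047|Disease or Syndrome\n"
        "DISO|Disorders|T191|Neoplastic Process\n"
        "DISO|Disorders|T184|Sign or Symptom\n"
        "CHEM|Chemicals & Drugs|T121|Pharmacologic Substance\n"
        "LIVB|Living Beings|T005|Virus\n",
        encoding="utf-8",
    )
    return path
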
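"""Shared test construction helpers."""

from clinannotate.terminology import load_terminology_string

TSV_HEADER = "id\tpref_label\tsynonyms\tsemantic_types\tparents\tsource\n"


def make_terminology(rows):
    """rows: list of (id, pref, synonyms, types, parents) tuples."""
    lines = [TSV_HEADER.rstrip("\n")]
    for cid, pref, syns, types, parents in rows:
        lines.append(
            "\t".join([cid, pref, "|".join(syns), "|".join(types), "|".join(parents), "test"])
        )
    return load_terminology_string("\n".join(lines) + "\n")
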
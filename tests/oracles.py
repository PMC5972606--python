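"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected results from first principles and never call
the code paths they check.
"""

import math
import random

from clinannotate._tokenize import token_tuple, tokenize


def brute_force_matches(doc, term):
    """Every (start, end, concept_id, match_type) found by testing every
    token window against every label; PREF wins over SYN on ties."""
    toks = tokenize(doc)
    labels = []
    for cid, c in term.concepts.items():
        labels.append((token_tuple(c.pref_label), cid, "PREF"))
        for s in c.synonyms:
            labels.append((token_tuple(s), cid, "SYN"))
    max_len = max((len(lt) for lt, _, _ in labels), default=0)
    best = {}
    for i in range(len(toks)):
        # windows longer than the longest label can never match
        for j in range(i, min(i + max_len, len(toks))):
            window = tuple(t.text for t in toks[i : j + 1])
            for label_toks, cid, mt in labels:
                if label_toks == window:
                    key = (toks[i].start, toks[j].end, cid)
                    if best.get(key) != "PREF":
                        best[key] = mt if best.get(key) is None or mt == "PREF" else best[key]
    return {(s, e, cid, mt) for (s, e, cid), mt in best.items()}


def cvalue_oracle(freqs):
    """C-Value from a {term: frequency} map, straight from the definition."""
    out = {}
    for a, fa in freqs.items():
        a_toks = a.split()
        parents = [b for b in freqs if b != a and _nests(a_toks, b.split())]
        length_factor = math.log2(len(a_toks) + 1)
        if parents:
            cv = length_factor * (fa - sum(freqs[b] for b in parents) / len(parents))
        else:
            cv = length_factor * fa
        out[a] = max(cv, 0.0)
    return out


def _nests(inner, outer):
    if len(inner) >= len(outer):
        return False
    return any(outer[i : i + len(inner)] == inner for i in range(len(outer) - len(inner) + 1))


def random_recognizer_instance(rng: random.Random, max_labels=30, max_doc_tokens=200):
    """A random small dictionary and document over a tiny shared vocabulary."""
    from helpers import make_terminology

    vocab = [f"w{i}" for i in range(rng.randint(3, 8))]
    rows = []
    n_concepts = rng.randint(1, max(1, max_labels // 2))
    for k in range(n_concepts):
        pref = " ".join(rng.choice(vocab) for _ in range(rng.randint(1, 3)))
        syns = [
            " ".join(rng.choice(vocab) for _ in range(rng.randint(1, 3)))
            for _ in range(rng.randint(0, 2))
        ]
        rows.append((f"C{k}", pref, syns, [], []))
    term = make_terminology(rows)
    seps = [" ", "  ", ", ", ". ", "-", "; "]
    parts = []
    for _ in range(rng.randint(0, max_doc_tokens)):
        word = rng.choice(vocab)
        if rng.random() < 0.3:
            word = word.upper() if rng.random() < 0.5 else word.capitalize()
        parts.append(word)
        parts.append(rng.choice(seps))
    doc = "".join(parts)
    return term, doc


def exhaustive_span_match(preds, golds):
    """tp via exhaustive multiset matching of exact tuples (each gold once)."""
    golds = list(golds)
    tp = 0
    for p in preds:
        if p in golds:
            golds.remove(p)
            tp += 1
    return tp
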
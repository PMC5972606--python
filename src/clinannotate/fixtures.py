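"""Synthetic terminologies and clinical-note-like corpora with gold annotations.

Labels are built from a closed pool of invented pseudo-medical tokens,
so they can never collide with filler text or with trigger phrases, and
each concept draws from its own exclusive slice of the pool, so no label
nests inside another concept's label.  Mentions are planted in template
sentences; with the configured probabilities a mention is wrapped in a
negation / experiencer / historical template whose cue phrase comes from
the shipped trigger lexicon, and the gold record stores the expected
context values.  Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GenerationError
from .recognizer import (
    Annotation,
    EXPERIENCER_DEFAULT,
    NEGATION_DEFAULT,
    TEMPORALITY_DEFAULT,
)
from .serialization import ScoredDocument, read_brat, write_brat
from .terminology import Concept, Terminology

_SYLLABLES = (
    "zor", "vex", "plo", "quam", "brel", "dax", "fyn", "gruv", "hilp", "jurn",
    "klyv", "morx", "nebb", "ossk", "prut", "quez", "ruv", "slan", "trok", "urv",
    "wix", "yam", "zeph", "crul", "dov", "ebru", "flim", "gosp", "hyx", "ivar",
)

# filler vocabulary is ordinary English chosen to avoid every phrase in the
# shipped trigger lexicon and, being real words, it cannot collide with the
# invented label tokens
_DISTRACTOR_SENTENCES = (
    "Vital signs were stable overnight.",
    "The care team reviewed the chart together.",
    "Routine labs were drawn this morning.",
    "The nurse documented the medication schedule.",
    "Breakfast was tolerated well today.",
    "The bed linens were changed at noon.",
)

# (prefix, suffix, negation, experiencer, temporality)
_PLAIN_TEMPLATES = (
    ("The patient has ", ".",),
    ("Examination reveals ", "."),
    ("Assessment shows ", " today."),
)
_NEGATION_TEMPLATES = (
    ("No sign of ", "."),
    ("The patient denies ", "."),
    ("There is no evidence of ", "."),
)
_EXPERIENCER_TEMPLATES = (
    ("The mother had ", "."),
    ("Family history of ", "."),
    ("Her father developed ", "."),
)
_HISTORICAL_TEMPLATES = (
    ("History of ", "."),
    ("Reported history of ", " last year."),
)


@dataclass(frozen=True)
class GoldRecord:
    doc_id: str
    start: int
    end: int
    concept_id: str
    negation: str = NEGATION_DEFAULT
    experiencer: str = EXPERIENCER_DEFAULT
    temporality: str = TEMPORALITY_DEFAULT


@dataclass
class GoldCorpus:
    documents: list[tuple[str, str]]
    gold: list[GoldRecord]
    params: dict = field(default_factory=dict)

    def text_of(self, doc_id: str) -> str:
        for did, text in self.documents:
            if did == doc_id:
                return text
        raise KeyError(doc_id)


@dataclass
class CorpusParams:
    n_concepts: int = 5
    n_notes: int = 10
    mentions_per_note: int = 2
    p_negation: float = 0.0
    p_experiencer: float = 0.0
    p_historical: float = 0.0
    distractor_rate: float = 0.0
    min_label_tokens: int = 1
    max_label_tokens: int = 3
    pool_size: int = 200
    semantic_type: str = "T047"

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise GenerationError("vocabulary size must be >= 1")
        for name in ("p_negation", "p_experiencer", "p_historical", "distractor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise GenerationError(f"{name} must lie in [0, 1]")
        if not (1 <= self.min_label_tokens <= self.max_label_tokens):
            raise GenerationError("label token bounds must satisfy 1 <= min <= max")


def _token_pool(rng: random.Random, size: int) -> list[str]:
    pool: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(pool) < size and attempts < size * 50:
        word = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
        attempts += 1
        if word not in seen:
            seen.add(word)
            pool.append(word)
    if len(pool) < size:
        raise GenerationError(f"could not build a pool of {size} distinct tokens")
    return pool


def generate_corpus(params: CorpusParams, seed: int) -> tuple[Terminology, GoldCorpus]:
    """Build a synthetic terminology and a note corpus with gold annotations."""
    rng = random.Random(seed)
    pool = _token_pool(rng, params.pool_size)

    lengths = [
        rng.randint(params.min_label_tokens, params.max_label_tokens)
        for _ in range(params.n_concepts)
    ]
    if sum(lengths) > len(pool):
        raise GenerationError(
            f"token pool too small: need {sum(lengths)} tokens for "
            f"{params.n_concepts} labels, pool has {len(pool)}"
        )
    concepts: list[Concept] = []
    cursor = 0
    for i, n_tok in enumerate(lengths):
        label = " ".join(pool[cursor : cursor + n_tok])
        cursor += n_tok
        concepts.append(
            Concept(
                id=f"C{i + 1:04d}",
                pref_label=label,
                semantic_types=[params.semantic_type],
                source="synthetic",
            )
        )
    term = Terminology(concepts)

    documents: list[tuple[str, str]] = []
    gold: list[GoldRecord] = []
    for note_idx in range(params.n_notes):
        doc_id = f"note{note_idx + 1:03d}"
        parts: list[str] = []
        pos = 0
        for _ in range(params.mentions_per_note):
            if rng.random() < params.distractor_rate:
                filler = rng.choice(_DISTRACTOR_SENTENCES)
                parts.append(filler)
                pos += len(filler) + 1
            concept = rng.choice(concepts)
            roll = rng.random()
            negation, experiencer, temporality = (
                NEGATION_DEFAULT,
                EXPERIENCER_DEFAULT,
                TEMPORALITY_DEFAULT,
            )
            if roll < params.p_negation:
                prefix, suffix = rng.choice(_NEGATION_TEMPLATES)
                negation = "negated"
            elif roll < params.p_negation + params.p_experiencer:
                prefix, suffix = rng.choice(_EXPERIENCER_TEMPLATES)
                experiencer = "other"
            elif roll < params.p_negation + params.p_experiencer + params.p_historical:
                prefix, suffix = rng.choice(_HISTORICAL_TEMPLATES)
                temporality = "historical"
            else:
                prefix, suffix = rng.choice(_PLAIN_TEMPLATES)
            start = pos + len(prefix)
            end = start + len(concept.pref_label)
            sentence = prefix + concept.pref_label + suffix
            parts.append(sentence)
            pos += len(sentence) + 1
            gold.append(
                GoldRecord(doc_id, start, end, concept.id, negation, experiencer, temporality)
            )
        text = " ".join(parts)
        documents.append((doc_id, text))

    corpus = GoldCorpus(documents, gold, params=vars(params) | {"seed": seed})
    for rec in corpus.gold:  # span fidelity is guaranteed by construction; verify anyway
        assert corpus.text_of(rec.doc_id)[rec.start : rec.end] == term[rec.concept_id].pref_label
    return term, corpus


def gold_to_scored_documents(corpus: GoldCorpus) -> list[ScoredDocument]:
    """View the gold records as ScoredDocuments (for writers and tests)."""
    docs = []
    for doc_id, text in corpus.documents:
        anns = [
            Annotation(
                concept_id=r.concept_id,
                start=r.start,
                end=r.end,
                surface=text[r.start : r.end],
                negation=r.negation,
                experiencer=r.experiencer,
                temporality=r.temporality,
            )
            for r in corpus.gold
            if r.doc_id == doc_id
        ]
        docs.append(ScoredDocument(doc_id, text, anns))
    return docs


def write_gold_brat(corpus: GoldCorpus, out_dir: str | Path) -> list[Path]:
    """Emit the gold corpus as BRAT .txt/.ann pairs; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sd in gold_to_scored_documents(corpus):
        txt, ann = write_brat(sd)
        txt_path = out_dir / f"{sd.doc_id}.txt"
        ann_path = out_dir / f"{sd.doc_id}.ann"
        txt_path.write_text(txt, encoding="utf-8")
        ann_path.write_text(ann, encoding="utf-8")
        written += [txt_path, ann_path]
    return written


def read_gold_brat(corpus_dir: str | Path) -> list[ScoredDocument]:
    """Read a directory of BRAT pairs back (exercises the standoff reader)."""
    corpus_dir = Path(corpus_dir)
    docs = []
    for txt_path in sorted(corpus_dir.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        docs.append(
            read_brat(
                txt_path.read_text(encoding="utf-8"),
                ann_path.read_text(encoding="utf-8") if ann_path.exists() else "",
                doc_id=txt_path.stem,
            )
        )
    return docs
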
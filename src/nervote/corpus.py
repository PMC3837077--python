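"""BIO-format corpus containers, I/O, and cross-corpus harmonization.

Corpora are token-per-line column files in the CoNLL style used by the
JNLPBA/GENIA shared tasks: whitespace-separated columns, one token per
line, a blank line between sentences.  Each token carries a surface form,
optional part-of-speech and chunk columns, and a BIO label (``O``,
``B-<type>`` or ``I-<type>``).

Harmonization operations cover the protocols used when mixing corpora
annotated by different groups: renaming entity types (e.g. the GENETAG
``NEWGENE`` type to ``protein``), dropping annotations for types one
corpus lacks, concatenating corpora, and removing sentences that contain
no entity at all (a common rebalancing step for gene/protein corpora).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Token",
    "Sentence",
    "Corpus",
    "ValidationIssue",
    "ValidationReport",
    "CorpusFormatError",
    "read_bio_corpus",
    "write_bio_corpus",
    "validate_bio",
    "convert_genetag",
    "remap_labels",
    "rename_types",
    "merge_corpora",
    "remove_noninformative_sentences",
    "label_alphabet",
]

_BIO_RE = re.compile(r"^(?:O|[BI]-\S+)$")


class CorpusFormatError(ValueError):
    """Raised for malformed column files (with the offending line number)."""


@dataclass(frozen=True, slots=True)
class Token:
    surface: str
    label: str = "O"
    pos: str | None = None
    chunk: str | None = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if not _BIO_RE.match(self.label):
            raise ValueError(f"label {self.label!r} is not a BIO tag")


@dataclass(frozen=True, slots=True)
class Sentence:
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.tokens]

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


def label_alphabet(entity_types: Iterable[str]) -> list[str]:
    """Canonical label order: B-/I- labels sorted by type, ``O`` last.

    Placing ``O`` last means a deterministic first-maximum tie-break in the
    voter can never invent an entity out of a zero-information tie.
    """
    labs: list[str] = []
    for t in sorted(set(entity_types)):
        labs.extend((f"B-{t}", f"I-{t}"))
    labs.append("O")
    return labs


@dataclass(frozen=True, slots=True)
class Corpus:
    sentences: tuple[Sentence, ...]

    @property
    def entity_types(self) -> frozenset[str]:
        return frozenset(
            lab[2:] for s in self.sentences for lab in s.labels if lab != "O"
        )

    @property
    def label_alphabet(self) -> list[str]:
        return label_alphabet(self.entity_types)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    sentence: int
    position: int
    label: str
    message: str


@dataclass(slots=True)
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_bio(corpus: Corpus) -> ValidationReport:
    """Flag orphan ``I-X`` labels (no preceding ``B-X``/``I-X`` of type X).

    Orphans are reported, never rewritten: the evaluator's chunker treats
    them as chunk starts, matching conlleval behaviour.
    """
    report = ValidationReport()
    for si, sent in enumerate(corpus.sentences):
        prev = "O"
        for ti, tok in enumerate(sent):
            lab = tok.label
            if lab.startswith("I-"):
                typ = lab[2:]
                if prev not in (f"B-{typ}", f"I-{typ}"):
                    report.issues.append(
                        ValidationIssue(si, ti, lab, "orphan I- label")
                    )
            prev = lab
    return report


def read_bio_corpus(
    path: str | Path,
    columns: Sequence[str] = ("word", "label"),
) -> Corpus:
    """Read a token-per-line column file into a :class:`Corpus`.

    ``columns`` names the role of each whitespace-separated column in
    order; ``word`` and ``label`` are mandatory roles, ``pos`` and
    ``chunk`` optional.  Blank lines separate sentences.
    """
    cols = list(columns)
    if "word" not in cols or "label" not in cols:
        raise ValueError("column spec must include 'word' and 'label'")
    path = Path(path)
    sentences: list[Sentence] = []
    current: list[Token] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if current:
                    sentences.append(Sentence(tuple(current)))
                    current = []
                continue
            fields_ = line.split()
            if len(fields_) < len(cols):
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected {len(cols)} columns, "
                    f"got {len(fields_)}"
                )
            rec = dict(zip(cols, fields_))
            lab = rec["label"]
            if not _BIO_RE.match(lab):
                raise CorpusFormatError(
                    f"{path}:{lineno}: label {lab!r} is not O/B-/I-"
                )
            current.append(
                Token(
                    surface=rec["word"],
                    label=lab,
                    pos=rec.get("pos"),
                    chunk=rec.get("chunk"),
                )
            )
    if current:
        sentences.append(Sentence(tuple(current)))
    return Corpus(tuple(sentences))


def write_bio_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to column format.

    Emits only the columns actually present (pos/chunk are included when
    any token carries them), so ``read ∘ write`` round-trips.
    """
    has_pos = any(t.pos is not None for s in corpus for t in s)
    has_chunk = any(t.chunk is not None for s in corpus for t in s)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus:
            for tok in sent:
                fields_ = [tok.surface]
                if has_pos:
                    fields_.append(tok.pos if tok.pos is not None else "-")
                if has_chunk:
                    fields_.append(tok.chunk if tok.chunk is not None else "-")
                fields_.append(tok.label)
                fh.write(" ".join(fields_) + "\n")
            fh.write("\n")


def columns_of(corpus: Corpus) -> list[str]:
    """Column spec matching :func:`write_bio_corpus` output for *corpus*."""
    cols = ["word"]
    if any(t.pos is not None for s in corpus for t in s):
        cols.append("pos")
    if any(t.chunk is not None for s in corpus for t in s):
        cols.append("chunk")
    cols.append("label")
    return cols


def convert_genetag(path: str | Path) -> Corpus:
    """Convert a GENETAG-style file (word + NEWGENE/NEWGENE1/PoS tag) to BIO.

    ``NEWGENE1`` (overlapping mention) tags are first replaced by
    ``NEWGENE``; maximal runs of gene tokens become ``B-NEWGENE``,
    ``I-NEWGENE``, ...; every gene token is assigned the proper-noun PoS
    ``NNP``; non-gene tokens keep their PoS and are labeled ``O``.
    """
    path = Path(path)
    sentences: list[Sentence] = []
    current: list[tuple[str, str]] = []  # (word, tag)

    def flush() -> None:
        if not current:
            return
        toks: list[Token] = []
        prev_gene = False
        for word, tag in current:
            if tag in ("NEWGENE", "NEWGENE1"):
                lab = "I-NEWGENE" if prev_gene else "B-NEWGENE"
                toks.append(Token(word, lab, pos="NNP"))
                prev_gene = True
            else:
                toks.append(Token(word, "O", pos=tag))
                prev_gene = False
        sentences.append(Sentence(tuple(toks)))
        current.clear()

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            fields_ = line.split()
            if len(fields_) < 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected word and tag columns"
                )
            current.append((fields_[0], fields_[1]))
    flush()
    return Corpus(tuple(sentences))


def remap_labels(corpus: Corpus, keep_types: Iterable[str]) -> Corpus:
    """Keep annotations for *keep_types* only; all other labels become O.

    This is the cross-corpus harmonization step applied before merging
    corpora with narrower annotation schemes (e.g. keep only ``protein``
    when mixing a five-type corpus into a protein-only one).
    """
    keep = set(keep_types)
    unknown = keep - set(corpus.entity_types)
    if unknown:
        raise ValueError(f"unknown entity types: {sorted(unknown)}")
    new_sents = []
    for sent in corpus:
        toks = tuple(
            tok if tok.label == "O" or tok.label[2:] in keep
            else replace(tok, label="O")
            for tok in sent
        )
        new_sents.append(Sentence(toks))
    return Corpus(tuple(new_sents))


def rename_types(corpus: Corpus, mapping: Mapping[str, str]) -> Corpus:
    """Rename entity types (e.g. ``{"NEWGENE": "protein"}``)."""
    new_sents = []
    for sent in corpus:
        toks = []
        for tok in sent:
            if tok.label != "O" and tok.label[2:] in mapping:
                toks.append(
                    replace(tok, label=tok.label[:2] + mapping[tok.label[2:]])
                )
            else:
                toks.append(tok)
        new_sents.append(Sentence(tuple(toks)))
    return Corpus(tuple(new_sents))


def merge_corpora(
    corpora: Sequence[Corpus],
    rename: Mapping[str, str] | None = None,
) -> Corpus:
    """Concatenate corpora, optionally renaming entity types first.

    The rename map is applied to every input; type harmonization is an
    explicit caller decision so merges stay auditable.
    """
    if not corpora:
        raise ValueError("need at least one corpus to merge")
    if rename:
        corpora = [rename_types(c, rename) for c in corpora]
    sents: list[Sentence] = []
    for c in corpora:
        sents.extend(c.sentences)
    return Corpus(tuple(sents))


def remove_noninformative_sentences(corpus: Corpus) -> Corpus:
    """Drop sentences with no entity mention at all (all-O sentences)."""
    kept = tuple(
        s for s in corpus.sentences if any(lab != "O" for lab in s.labels)
    )
    return Corpus(kept)
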
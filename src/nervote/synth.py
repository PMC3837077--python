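"""Synthetic corpora and simulated classifier banks.

Real biomedical NER corpora are large, licensed downloads; this module
generates corpora that reproduce the structural properties the method
depends on — multi-token entity mentions of several classes,
orthographically marked entity tokens (capital/digit/hyphen patterns),
trigger words preceding mentions, PoS-like and chunk-like auxiliary
columns — and simulates base-classifier outputs with controllable
per-class reliability, so the voting ensemble and its optimizer can be
exercised end-to-end without any external data.

Simulated errors are injected per token (not per span), which breaks
BIO validity in exactly the way real taggers do and stresses the
decode/evaluate path under the strict-boundary criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, Sentence, Token, label_alphabet
from .evaluation import strict_match_scores
from .models import PredictionMatrix, make_folds

__all__ = [
    "CorpusGenConfig",
    "ReliabilityProfile",
    "generate_corpus",
    "simulate_classifier_outputs",
]


@dataclass(frozen=True)
class CorpusGenConfig:
    """Knobs for corpus generation.

    ``entity_density`` is the expected number of entity mentions per
    sentence (Poisson-thinned by available space);
    ``orthographic_signal`` the probability that an entity token is
    drawn with a capital/digit/hyphen surface pattern rather than a
    plain lowercase form; ``trigger_signal`` the probability that a
    dedicated trigger verb immediately precedes a mention.
    """

    n_sentences: int = 200
    sentence_len_range: tuple[int, int] = (8, 25)
    entity_types: tuple[str, ...] = ("protein", "DNA")
    entity_density: float = 1.0
    entity_len_range: tuple[int, int] = (1, 4)
    orthographic_signal: float = 0.8
    trigger_signal: float = 0.3
    filler_vocab_size: int = 400
    entity_vocab_size: int = 60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.orthographic_signal <= 1:
            raise ValueError("orthographic_signal must be in [0, 1]")
        if not 0 <= self.trigger_signal <= 1:
            raise ValueError("trigger_signal must be in [0, 1]")
        if self.entity_density < 0:
            raise ValueError("entity_density must be non-negative")
        if self.entity_len_range[0] < 1:
            raise ValueError("entity length must be >= 1")
        if self.sentence_len_range[0] < 1:
            raise ValueError("sentence length must be >= 1")


_TRIGGERS = ("binds", "activates", "inhibits", "phosphorylates",
             "encodes", "regulates")

_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"


def _plain_word(rng: np.random.Generator, syllables: int = 2) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(syllables)
    )


def _marked_surface(rng: np.random.Generator, type_idx: int) -> str:
    """Entity-token surface with an orthographic pattern.

    Patterns rotate over capital-digit hybrids ('IL-2'-like), all-caps
    acronyms, mixed-case forms and alpha-digit forms, biased per entity
    type so types stay partly distinguishable by shape.
    """
    kind = int(rng.integers(4))
    stem = _plain_word(rng, 1).upper() + _plain_word(rng, 1).upper()[:1]
    if kind == 0:
        return f"{stem}-{int(rng.integers(1, 99))}"
    if kind == 1:
        return stem + _plain_word(rng, 1).upper()
    if kind == 2:
        return f"{_plain_word(rng, 1)}{stem}{type_idx + 1}"
    return f"{stem}{int(rng.integers(1, 99))}"


def generate_corpus(config: CorpusGenConfig) -> Corpus:
    """Generate a BIO-labeled corpus with the configured structure."""
    rng = np.random.default_rng(config.rng_seed)
    fillers = sorted({
        _plain_word(rng, int(rng.integers(2, 4)))
        for _ in range(config.filler_vocab_size)
    })
    # per-type entity dictionaries: sequences of 1..max_len token tuples
    ent_dicts: list[list[tuple[str, ...]]] = []
    lo_len, hi_len = config.entity_len_range
    for ti, _ in enumerate(config.entity_types):
        entries = []
        for _ in range(config.entity_vocab_size):
            n = int(rng.integers(lo_len, hi_len + 1))
            toks = tuple(
                _marked_surface(rng, ti)
                if rng.random() < config.orthographic_signal
                else _plain_word(rng, 2)
                for _ in range(n)
            )
            entries.append(toks)
        ent_dicts.append(entries)

    def filler_token() -> Token:
        return Token(fillers[int(rng.integers(len(fillers)))],
                     "O", pos="NN", chunk="O")

    sentences: list[Sentence] = []
    for _ in range(config.n_sentences):
        slen = int(rng.integers(*config.sentence_len_range))
        n_ent = int(rng.poisson(config.entity_density))
        mentions: list[tuple[int, tuple[str, ...]]] = []
        for _ in range(n_ent):
            ti = int(rng.integers(len(config.entity_types)))
            mentions.append(
                (ti, ent_dicts[ti][int(rng.integers(len(ent_dicts[ti])))])
            )
        # every mention needs one filler slot before it; drop overflow
        # mentions only when the sentence genuinely cannot hold them
        while mentions and (
            sum(len(m) for _, m in mentions) + len(mentions) > slen
        ):
            mentions.pop()
        n_fill = slen - sum(len(m) for _, m in mentions)
        # distribute filler over the len(mentions)+1 gaps, >=1 before
        # each mention
        n_gaps = len(mentions) + 1
        gap_sizes = [1] * len(mentions) + [0]
        extra = n_fill - len(mentions)
        if extra > 0 and n_gaps > 0:
            alloc = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))
            gap_sizes = [g + int(a) for g, a in zip(gap_sizes, alloc)]
        toks: list[Token] = []
        for gi, (ti, mention) in enumerate(mentions):
            fill = [filler_token() for _ in range(gap_sizes[gi])]
            if fill and rng.random() < config.trigger_signal:
                trig = _TRIGGERS[int(rng.integers(len(_TRIGGERS)))]
                fill[-1] = Token(trig, "O", pos="VBZ", chunk="B-VP")
            toks.extend(fill)
            typ = config.entity_types[ti]
            for j, w in enumerate(mention):
                toks.append(Token(
                    w,
                    ("B-" if j == 0 else "I-") + typ,
                    pos="NNP",
                    chunk="B-NP" if j == 0 else "I-NP",
                ))
        toks.extend(filler_token() for _ in range(gap_sizes[-1]))
        sentences.append(Sentence(tuple(toks)))
    return Corpus(tuple(sentences))


@dataclass(frozen=True)
class ReliabilityProfile:
    """Per-class accuracy of one simulated classifier.

    ``accuracy`` maps each label to the probability of emitting the
    gold label; errors follow ``confusion``: ``"uniform"`` draws
    uniformly over the other labels, ``"to_o"`` always outputs O, and
    ``"boundary_jitter"`` turns B- into I- of the same type (and vice
    versa), exercising the strict-boundary penalty.
    """

    name: str
    accuracy: Mapping[str, float] = field(default_factory=dict)
    default_accuracy: float = 0.9
    confusion: str = "uniform"

    def __post_init__(self) -> None:
        for lab, a in self.accuracy.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"accuracy for {lab!r} outside [0, 1]")
        if self.confusion not in ("uniform", "to_o", "boundary_jitter"):
            raise ValueError(f"unknown confusion rule {self.confusion!r}")

    def a(self, label: str) -> float:
        return float(self.accuracy.get(label, self.default_accuracy))


def simulate_classifier_outputs(
    corpus: Corpus,
    profiles: Sequence[ReliabilityProfile],
    folds: Sequence[np.ndarray] | None = None,
    k: int = 5,
    rng_seed: int = 0,
    labels: Sequence[str] | None = None,
) -> PredictionMatrix:
    """Build a prediction bank from reliability profiles instead of
    trained models.

    For each held-out token with gold label j, classifier m emits j
    with probability a(m, j) and otherwise a label from its confusion
    rule.  Each classifier's F_m is computed by the strict-match scorer
    on its own simulated outputs, exactly as for trained classifiers.
    """
    if not profiles:
        raise ValueError("at least one reliability profile required")
    if labels is None:
        labels = tuple(label_alphabet(corpus.entity_types))
    else:
        labels = tuple(labels)
        used = {lab for s in corpus for lab in s.labels}
        if not used <= set(labels):
            raise ValueError("explicit label list misses corpus labels")
        if labels[-1] != "O":
            raise ValueError("label alphabet must end with O")
    index = {lab: j for j, lab in enumerate(labels)}
    if folds is None:
        folds = make_folds(corpus, k, rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))

    fold_sent_lengths = [
        [len(corpus.sentences[int(i)]) for i in fold] for fold in folds
    ]
    fold_gold = [
        np.array([index[lab] for i in fold
                  for lab in corpus.sentences[int(i)].labels], dtype=np.intp)
        for fold in folds
    ]
    n_lab = len(labels)
    fold_outputs = []
    for gold in fold_gold:
        t = len(gold)
        out = np.empty((t, len(profiles)), dtype=np.intp)
        for m, prof in enumerate(profiles):
            acc = np.array([prof.a(lab) for lab in labels])
            correct = rng.random(t) < acc[gold]
            emitted = gold.copy()
            wrong = ~correct
            if wrong.any():
                if prof.confusion == "to_o":
                    emitted[wrong] = index["O"]
                elif prof.confusion == "boundary_jitter":
                    emitted[wrong] = np.array([
                        index[_jitter(labels[g])] for g in gold[wrong]
                    ])
                else:
                    shift = rng.integers(1, n_lab, size=int(wrong.sum()))
                    emitted[wrong] = (gold[wrong] + shift) % n_lab
            out[:, m] = emitted
        fold_outputs.append(out)

    f_values = np.empty(len(profiles))
    bank = PredictionMatrix(
        labels=labels,
        classifier_names=tuple(p.name for p in profiles),
        fold_sentence_indices=[np.asarray(f).copy() for f in folds],
        fold_sent_lengths=fold_sent_lengths,
        fold_gold=fold_gold,
        fold_outputs=fold_outputs,
        classifier_F=f_values,
    )
    for m in range(len(profiles)):
        gold_seqs: list[list[str]] = []
        pred_seqs: list[list[str]] = []
        for f in range(bank.n_folds):
            gold_seqs.extend(bank.fold_gold_sequences(f))
            pred_seqs.extend(bank.fold_label_sequences(f, m))
        f_values[m] = strict_match_scores(gold_seqs, pred_seqs).overall.f_measure
    bank.validate()
    return bank


def _jitter(label: str) -> str:
    if label.startswith("B-"):
        return "I-" + label[2:]
    if label.startswith("I-"):
        return "B-" + label[2:]
    return "O"
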
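"""Strict-boundary chunk-level scoring of BIO label sequences.

An entity chunk counts as correct only when its left boundary, right
boundary and type all equal a gold chunk's — the strict matching
criterion of the JNLPBA shared-task evaluation.  Recall is correct/gold
chunks, precision correct/predicted, F their harmonic mean, all on the
percent scale.

Orphan ``I-X`` labels (no preceding ``B-X``/``I-X`` of the same type)
start a new chunk, matching conlleval; set ``orphan_starts_chunk=False``
in :func:`extract_chunks` to drop them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

__all__ = ["Chunk", "ClassScores", "EvalReport", "extract_chunks",
           "strict_match_scores"]


class Chunk(NamedTuple):
    start: int  # 0-based token index
    end: int    # inclusive
    entity_type: str


def extract_chunks(
    labels: Sequence[str], orphan_starts_chunk: bool = True
) -> list[Chunk]:
    """Extract maximal entity spans from one sentence's BIO labels."""
    chunks: list[Chunk] = []
    start = -1
    ctype = ""
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            if start >= 0:
                chunks.append(Chunk(start, i - 1, ctype))
            start, ctype = i, lab[2:]
        elif lab.startswith("I-"):
            typ = lab[2:]
            if start >= 0 and typ == ctype:
                continue  # extends the open chunk
            if start >= 0:
                chunks.append(Chunk(start, i - 1, ctype))
            if orphan_starts_chunk:
                start, ctype = i, typ
            else:
                start = -1
        else:  # O
            if start >= 0:
                chunks.append(Chunk(start, i - 1, ctype))
            start = -1
    if start >= 0:
        chunks.append(Chunk(start, len(labels) - 1, ctype))
    return chunks


def _prf(correct: int, gold: int, predicted: int) -> tuple[float, float, float]:
    r = 100.0 * correct / gold if gold else 0.0
    p = 100.0 * correct / predicted if predicted else 0.0
    f = 2 * r * p / (r + p) if (r + p) > 0 else 0.0
    return r, p, f


@dataclass(slots=True)
class ClassScores:
    gold: int = 0
    predicted: int = 0
    correct: int = 0

    @property
    def recall(self) -> float:
        return _prf(self.correct, self.gold, self.predicted)[0]

    @property
    def precision(self) -> float:
        return _prf(self.correct, self.gold, self.predicted)[1]

    @property
    def f_measure(self) -> float:
        return _prf(self.correct, self.gold, self.predicted)[2]


@dataclass(slots=True)
class EvalReport:
    overall: ClassScores = field(default_factory=ClassScores)
    per_class: dict[str, ClassScores] = field(default_factory=dict)

    def as_dict(self) -> dict:
        def row(s: ClassScores) -> dict:
            return {
                "gold": s.gold, "predicted": s.predicted,
                "correct": s.correct,
                "recall": round(s.recall, 2),
                "precision": round(s.precision, 2),
                "f_measure": round(s.f_measure, 2),
            }
        return {
            "overall": row(self.overall),
            "per_class": {k: row(v) for k, v in sorted(self.per_class.items())},
        }

    def format_table(self) -> str:
        lines = [f"{'class':<14}{'R':>8}{'P':>8}{'F':>8}"
                 f"{'gold':>7}{'pred':>7}{'corr':>7}"]
        rows = [("overall", self.overall)] + sorted(self.per_class.items())
        for name, s in rows:
            lines.append(
                f"{name:<14}{s.recall:>8.2f}{s.precision:>8.2f}"
                f"{s.f_measure:>8.2f}{s.gold:>7}{s.predicted:>7}{s.correct:>7}"
            )
        return "\n".join(lines)


def strict_match_scores(
    gold: Sequence[Sequence[str]],
    predicted: Sequence[Sequence[str]],
    orphan_starts_chunk: bool = True,
) -> EvalReport:
    """Score predicted label sequences against gold, sentence-aligned.

    Both arguments are sequences of per-sentence BIO label sequences of
    identical shape.  Chunks are compared as (sentence, start, end, type)
    tuples; full credit only on exact boundary and type agreement.
    """
    if len(gold) != len(predicted):
        raise ValueError(
            f"sentence count mismatch: {len(gold)} gold vs "
            f"{len(predicted)} predicted"
        )
    report = EvalReport()

    def cls(name: str) -> ClassScores:
        if name not in report.per_class:
            report.per_class[name] = ClassScores()
        return report.per_class[name]

    for si, (g_labs, p_labs) in enumerate(zip(gold, predicted)):
        if len(g_labs) != len(p_labs):
            raise ValueError(f"sentence {si}: token count mismatch")
        g_chunks = set(extract_chunks(g_labs, orphan_starts_chunk))
        p_chunks = set(extract_chunks(p_labs, orphan_starts_chunk))
        matched = g_chunks & p_chunks
        for ch in g_chunks:
            report.overall.gold += 1
            cls(ch.entity_type).gold += 1
        for ch in p_chunks:
            report.overall.predicted += 1
            cls(ch.entity_type).predicted += 1
        for ch in matched:
            report.overall.correct += 1
            cls(ch.entity_type).correct += 1
    return report
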
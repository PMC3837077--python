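"""Per-token weighted voting over the outputs of N base classifiers.

Classifier m's vote for class c carries weight ``V(m, c) * F_m``, where
``V`` is the learned N x O weight matrix and ``F_m`` the classifier's
cross-validated F-measure.  Each token is assigned the class with the
maximum combined score; boundary disagreements between classifiers are
resolved implicitly by this per-token argmax.

Column order is the corpus label alphabet with ``O`` last, and ties are
broken toward the earliest column, so a zero-information tie can never
invent an entity.  The decision is invariant to scaling all weights
and/or all F_m by a common positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["WeightMatrix", "combined_scores", "weighted_vote_decode",
           "decode_ids"]


@dataclass(frozen=True)
class WeightMatrix:
    """N x O vote-weight matrix with named rows (classifiers) and columns
    (labels).

    When ``include_o`` is False the ``O`` column is not a learned weight:
    O votes carry weight ``1.0 * F_m`` and only entity-label columns are
    searched by the optimizer.
    """

    values: np.ndarray  # shape (n_classifiers, n_labels)
    classifier_names: tuple[str, ...]
    labels: tuple[str, ...]
    include_o: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.classifier_names), len(self.labels)):
            raise ValueError(
                f"weight matrix shape {v.shape} does not match "
                f"{len(self.classifier_names)} classifiers x "
                f"{len(self.labels)} labels"
            )
        if (v < 0).any():
            raise ValueError("vote weights must be non-negative")
        object.__setattr__(self, "values", v)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("# weighted-vote matrix: rows=classifiers cols=labels\n")
            fh.write(f"# include_o {self.include_o}\n")
            fh.write("labels " + " ".join(self.labels) + "\n")
            for name, row in zip(self.classifier_names, self.values):
                fh.write(name + " " + " ".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WeightMatrix":
        path = Path(path)
        include_o = True
        labels: tuple[str, ...] = ()
        names: list[str] = []
        rows: list[list[float]] = []
        for line in path.read_text(encoding="utf-8").splitlines():
            if line.startswith("# include_o"):
                include_o = line.split()[-1] == "True"
                continue
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if parts[0] == "labels":
                labels = tuple(parts[1:])
            else:
                names.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(np.array(rows), tuple(names), labels, include_o)


def combined_scores(
    token_outputs: Sequence[str],
    weights: WeightMatrix,
    classifier_F: Sequence[float],
) -> dict[str, float]:
    """Combined score of every class for one token.

    ``score(c) = sum over classifiers m voting c of V(m, c) * F_m``;
    classes nobody voted for score zero.
    """
    if len(token_outputs) != len(weights.classifier_names):
        raise ValueError("one output per classifier required")
    index: Mapping[str, int] = {lab: j for j, lab in enumerate(weights.labels)}
    scores = {lab: 0.0 for lab in weights.labels}
    for m, lab in enumerate(token_outputs):
        if lab not in index:
            raise ValueError(f"label {lab!r} outside alphabet")
        w = weights.values[m, index[lab]]
        if not weights.include_o and lab == "O":
            w = 1.0
        scores[lab] += w * classifier_F[m]
    return scores


def decode_ids(
    pred_ids: np.ndarray,
    v_full: np.ndarray,
    classifier_F: np.ndarray,
) -> np.ndarray:
    """Vectorized per-token argmax decode on integer-coded labels.

    ``pred_ids`` is (n_tokens, n_classifiers); ``v_full`` the effective
    (n_classifiers, n_labels) weight matrix (already including any fixed
    O-column weight).  Ties resolve to the smallest label id, which is an
    entity label under the O-last alphabet order.
    """
    n_tok, n_clf = pred_ids.shape
    scores = np.zeros((n_tok, v_full.shape[1]))
    rows = np.arange(n_tok)
    for m in range(n_clf):
        lab = pred_ids[:, m]
        np.add.at(scores, (rows, lab), v_full[m, lab] * classifier_F[m])
    return scores.argmax(axis=1)


def weighted_vote_decode(
    predictions: Sequence[Sequence[Sequence[str]]],
    weights: WeightMatrix,
    classifier_F: Sequence[float],
) -> list[list[str]]:
    """Decode per-sentence label sequences from N classifiers' outputs.

    ``predictions[m][s]`` is classifier m's label sequence for sentence
    s; the result is one joint label sequence per sentence of identical
    length.
    """
    n_clf = len(predictions)
    if n_clf != len(weights.classifier_names):
        raise ValueError("prediction set / weight matrix shape mismatch")
    index = {lab: j for j, lab in enumerate(weights.labels)}
    v_full = effective_weights(weights)
    f_arr = np.asarray(classifier_F, dtype=float)
    out: list[list[str]] = []
    for s in range(len(predictions[0])):
        seqs = [predictions[m][s] for m in range(n_clf)]
        if len({len(q) for q in seqs}) != 1:
            raise ValueError(f"sentence {s}: classifier output lengths differ")
        try:
            ids = np.array(
                [[index[lab] for lab in q] for q in seqs], dtype=np.intp
            ).T
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} outside alphabet") from exc
        joint = decode_ids(ids, v_full, f_arr)
        out.append([weights.labels[j] for j in joint])
    return out


def effective_weights(weights: WeightMatrix) -> np.ndarray:
    """Weight matrix with the fixed O-column weight substituted if needed."""
    v = weights.values.copy()
    if not weights.include_o and "O" in weights.labels:
        v[:, weights.labels.index("O")] = 1.0
    return v
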
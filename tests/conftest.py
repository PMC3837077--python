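"""Shared fixtures and independent oracle implementations.

The oracle functions here deliberately re-derive chunking, scoring and
voting from their definitions with different code paths than the
package, so agreement tests are meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest

from nervote.corpus import Corpus, Sentence, Token


def corpus_from_labels(rows, surfaces=None, pos=None, chunk=None) -> Corpus:
    """Corpus from per-sentence label lists; surfaces default to w<i>."""
    sents = []
    for si, labels in enumerate(rows):
        toks = []
        for ti, lab in enumerate(labels):
            toks.append(Token(
                surface=surfaces[si][ti] if surfaces else f"w{si}_{ti}",
                label=lab,
                pos=pos[si][ti] if pos else None,
                chunk=chunk[si][ti] if chunk else None,
            ))
        sents.append(Sentence(tuple(toks)))
    return Corpus(tuple(sents))


def random_bio_sequence(rng: np.random.Generator, length: int,
                        types: tuple[str, ...]) -> list[str]:
    """Random label sequence over the full alphabet, BIO-valid or not.

    Drawing labels independently produces orphan I- labels at a
    realistic rate, which is exactly what stresses strict scoring.
    """
    alphabet = ["O"] + [f"{p}-{t}" for t in types for p in ("B", "I")]
    return [alphabet[rng.integers(len(alphabet))] for _ in range(length)]


# ------------------------------------------------------- oracle scoring

def oracle_chunks(labels) -> set[tuple[int, int, str]]:
    """Brute-force chunk extraction: find each start position, then
    extend; orphan I- starts a chunk."""
    out = set()
    n = len(labels)
    for i, lab in enumerate(labels):
        if lab == "O":
            continue
        typ = lab[2:]
        starts = lab.startswith("B-") or (
            i == 0 or labels[i - 1] not in (f"B-{typ}", f"I-{typ}")
        )
        if not starts:
            continue
        j = i
        while j + 1 < n and labels[j + 1] == f"I-{typ}":
            j += 1
        out.add((i, j, typ))
    return out


def oracle_strict_scores(gold_rows, pred_rows):
    """Set-intersection strict scorer returning the same count structure
    as the package's report, computed independently."""
    gold_set, pred_set = set(), set()
    for s, labs in enumerate(gold_rows):
        gold_set |= {(s, a, b, t) for (a, b, t) in oracle_chunks(labs)}
    for s, labs in enumerate(pred_rows):
        pred_set |= {(s, a, b, t) for (a, b, t) in oracle_chunks(labs)}
    correct = gold_set & pred_set

    def stats(g, p, c):
        r = 100.0 * c / g if g else 0.0
        pr = 100.0 * c / p if p else 0.0
        f = 2 * r * pr / (r + pr) if r + pr else 0.0
        return {"gold": g, "predicted": p, "correct": c,
                "recall": r, "precision": pr, "f": f}

    types = {t for (_, _, _, t) in gold_set | pred_set}
    per_class = {
        t: stats(
            sum(1 for ch in gold_set if ch[3] == t),
            sum(1 for ch in pred_set if ch[3] == t),
            sum(1 for ch in correct if ch[3] == t),
        )
        for t in types
    }
    return stats(len(gold_set), len(pred_set), len(correct)), per_class


def oracle_vote(token_labels, v, f_values, alphabet):
    """Exhaustive per-token argmax with first-maximum tie-breaking."""
    scores = [0.0] * len(alphabet)
    for m, lab in enumerate(token_labels):
        j = alphabet.index(lab)
        scores[j] += v[m][j] * f_values[m]
    best = 0
    for j in range(1, len(alphabet)):
        if scores[j] > scores[best]:
            best = j
    return alphabet[best]


# ------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_synthetic_corpus():
    from nervote.synth import CorpusGenConfig, generate_corpus

    return generate_corpus(CorpusGenConfig(n_sentences=80, rng_seed=11))
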
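"""Base sequence labelers, cross-validation folds, and the prediction bank.

The ensemble never sees the learners themselves — only a
:class:`PredictionMatrix`: for every cross-validation fold, every
held-out token's predicted label from each of the N base classifiers,
plus each classifier's overall strict-match F-measure F_m.  Any learner
exposing the small :class:`SequenceBackend` contract can register; the
built-in backends are a word-memorizing baseline (tests), a
logistic-regression greedy sequence labeler and a polynomial-kernel SVM
token classifier (both via scikit-learn).
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus import Corpus, Sentence, label_alphabet
from .evaluation import strict_match_scores
from .features import (FeatureResources, FeatureTemplate, build_resources,
                       extract_features)

__all__ = [
    "LabelerSpec",
    "PredictionMatrix",
    "SequenceBackend",
    "register_backend",
    "make_backend",
    "make_folds",
    "train_and_predict",
    "build_model_bank",
]


@dataclass(frozen=True)
class LabelerSpec:
    """Identity of one base classifier: backend + feature template."""

    name: str
    learner_kind: str
    template: FeatureTemplate = field(default_factory=FeatureTemplate)
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def hyper_dict(self) -> dict:
        return dict(self.hyperparameters)


@dataclass
class PredictionMatrix:
    """Per-fold, per-token outputs of all base classifiers.

    ``fold_outputs[f]`` has shape (held-out tokens in fold f, N) of
    integer label ids into ``labels``; ``fold_gold[f]`` the gold ids;
    ``fold_sent_lengths[f]`` splits the token axis back into sentences.
    ``classifier_F`` holds each classifier's overall strict-match
    F-measure on the percent scale.
    """

    labels: tuple[str, ...]
    classifier_names: tuple[str, ...]
    fold_sentence_indices: list[np.ndarray]
    fold_sent_lengths: list[list[int]]
    fold_gold: list[np.ndarray]
    fold_outputs: list[np.ndarray]
    classifier_F: np.ndarray

    @property
    def n_classifiers(self) -> int:
        return len(self.classifier_names)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_folds(self) -> int:
        return len(self.fold_outputs)

    def validate(self) -> None:
        for f in range(self.n_folds):
            out = self.fold_outputs[f]
            if out.shape != (len(self.fold_gold[f]), self.n_classifiers):
                raise ValueError(f"fold {f}: incomplete prediction matrix")
            if out.min(initial=0) < 0 or out.max(initial=0) >= self.n_labels:
                raise ValueError(f"fold {f}: label id outside alphabet")

    def fold_label_sequences(
        self, fold: int, classifier: int
    ) -> list[list[str]]:
        """Classifier's held-out predictions for one fold, per sentence."""
        ids = self.fold_outputs[fold][:, classifier]
        return self._split(ids, fold)

    def fold_gold_sequences(self, fold: int) -> list[list[str]]:
        return self._split(self.fold_gold[fold], fold)

    def _split(self, ids: np.ndarray, fold: int) -> list[list[str]]:
        out, i = [], 0
        for ln in self.fold_sent_lengths[fold]:
            out.append([self.labels[j] for j in ids[i: i + ln]])
            i += ln
        return out

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.labels).encode())
        h.update(json.dumps(self.classifier_names).encode())
        for f in range(self.n_folds):
            h.update(self.fold_gold[f].tobytes())
            h.update(self.fold_outputs[f].tobytes())
        h.update(np.asarray(self.classifier_F).tobytes())
        return h.hexdigest()


# ----------------------------------------------------------- backends

class SequenceBackend:
    """Contract for pluggable sequence labelers."""

    def fit(self, sentences: Sequence[Sentence], template: FeatureTemplate,
            resources: FeatureResources) -> None:
        raise NotImplementedError

    def predict(self, sentences: Sequence[Sentence]) -> list[list[str]]:
        raise NotImplementedError


_BACKENDS: dict[str, Callable[..., SequenceBackend]] = {}


def register_backend(name: str):
    def deco(cls):
        _BACKENDS[name] = cls
        return cls
    return deco


def make_backend(spec: LabelerSpec) -> SequenceBackend:
    if spec.learner_kind not in _BACKENDS:
        raise KeyError(
            f"unknown backend {spec.learner_kind!r}; "
            f"registered: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[spec.learner_kind](**spec.hyper_dict())


@register_backend("memorize")
class MemorizerBackend(SequenceBackend):
    """Dependency-free baseline: each word maps to its most frequent
    training label (ties lexicographic); unseen words get ``O``."""

    def __init__(self) -> None:
        self.table: dict[str, str] = {}

    def fit(self, sentences, template, resources) -> None:
        counts: dict[str, dict[str, int]] = {}
        for sent in sentences:
            for tok in sent:
                counts.setdefault(tok.surface, {}).setdefault(tok.label, 0)
                counts[tok.surface][tok.label] += 1
        self.table = {
            w: min(labs, key=lambda l: (-labs[l], l))
            for w, labs in counts.items()
        }

    def predict(self, sentences) -> list[list[str]]:
        return [
            [self.table.get(t.surface, "O") for t in sent]
            for sent in sentences
        ]


class _SklearnTokenBackend(SequenceBackend):
    """Token classifier over extracted feature dicts.

    Dynamic (previous-tag) features use gold tags at training time and
    the model's own left-to-right predictions at decode time (greedy).
    """

    def __init__(self, **hyper) -> None:
        self.hyper = hyper
        self.template: FeatureTemplate | None = None
        self.resources: FeatureResources | None = None
        self._vec = None
        self._clf = None

    def _estimator(self):
        raise NotImplementedError

    def fit(self, sentences, template, resources) -> None:
        from sklearn.feature_extraction import DictVectorizer

        self.template, self.resources = template, resources
        X, y = [], []
        for sent in sentences:
            gold = sent.labels
            for i in range(len(sent)):
                X.append(_stringify(extract_features(
                    sent, i, template, resources,
                    previous_tags=gold[:i], training=True,
                )))
                y.append(gold[i])
        self._vec = DictVectorizer(sparse=True)
        Xv = self._vec.fit_transform(X)
        self._clf = self._estimator()
        self._clf.fit(Xv, y)

    def predict(self, sentences) -> list[list[str]]:
        assert self.template is not None
        out = []
        if self.template.dynamic_depth == 0:
            flat, lens = [], []
            for sent in sentences:
                lens.append(len(sent))
                for i in range(len(sent)):
                    flat.append(_stringify(extract_features(
                        sent, i, self.template, self.resources,
                    )))
            pred = self._clf.predict(self._vec.transform(flat))
            i = 0
            for ln in lens:
                out.append(list(pred[i: i + ln]))
                i += ln
            return out
        for sent in sentences:
            tags: list[str] = []
            for i in range(len(sent)):
                feats = _stringify(extract_features(
                    sent, i, self.template, self.resources,
                    previous_tags=tags,
                ))
                tags.append(self._clf.predict(self._vec.transform([feats]))[0])
            out.append(tags)
        return out


def _stringify(feats: Mapping[str, object]) -> dict[str, object]:
    # DictVectorizer one-hot-encodes string values and passes numbers
    # through; binary indicators stay numeric.
    return {k: (v if isinstance(v, (int, float)) else str(v))
            for k, v in feats.items()}


@register_backend("maxent")
class MaxEntBackend(_SklearnTokenBackend):
    """L2-regularized multinomial logistic regression token labeler."""

    def _estimator(self):
        from sklearn.linear_model import LogisticRegression

        hyper = {"max_iter": 300, "C": 1.0} | self.hyper
        return LogisticRegression(**hyper)


@register_backend("svm-poly")
class PolySVMBackend(_SklearnTokenBackend):
    """Polynomial-kernel SVM token labeler (one-vs-one multi-class)."""

    def _estimator(self):
        from sklearn.svm import SVC

        hyper = {"kernel": "poly", "degree": 2, "coef0": 1.0,
                 "C": 1.0} | self.hyper
        return SVC(**hyper)


# --------------------------------------------------------------- folds

def make_folds(
    corpus: Corpus, k: int, rng_seed: int
) -> list[np.ndarray]:
    """Partition sentence indices into k near-equal shuffled folds.

    Sentence-level partitioning keeps sequences intact; sizes differ by
    at most one; deterministic for a fixed seed.
    """
    n = len(corpus)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} sentences")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def train_and_predict(
    spec: LabelerSpec,
    corpus: Corpus,
    folds: Sequence[np.ndarray],
    unknown_seed: int = 0,
) -> tuple[list[list[list[str]]], float]:
    """K-fold predictions for one labeler plus its overall F-measure.

    For each fold the backend is trained on the complement (resources
    rebuilt on that training portion only) and predicts the held-out
    sentences; F_m is the strict-match overall F over all held-out
    predictions concatenated, on the percent scale.
    """
    all_gold: list[list[str]] = []
    all_pred: list[list[str]] = []
    per_fold: list[list[list[str]]] = []
    for fold in folds:
        held = set(int(i) for i in fold)
        train_sents = [s for i, s in enumerate(corpus) if i not in held]
        test_sents = [corpus.sentences[int(i)] for i in fold]
        resources = build_resources(
            Corpus(tuple(train_sents)), unknown_seed=unknown_seed
        )
        try:
            backend = make_backend(spec)
            backend.fit(train_sents, spec.template, resources)
            preds = backend.predict(test_sents)
        except Exception as exc:
            raise RuntimeError(
                f"backend failure for labeler {spec.name!r} "
                f"({spec.learner_kind})"
            ) from exc
        per_fold.append(preds)
        all_gold.extend(s.labels for s in test_sents)
        all_pred.extend(preds)
    f_m = strict_match_scores(all_gold, all_pred).overall.f_measure
    return per_fold, f_m


def build_model_bank(
    corpus: Corpus,
    specs: Sequence[LabelerSpec],
    k: int = 5,
    rng_seed: int = 0,
    cache_dir: str | Path | None = None,
) -> PredictionMatrix:
    """Train every labeler on shared folds and assemble the prediction
    bank.

    All classifiers are evaluated on identical folds (the ensemble
    fitness is ill-defined otherwise).  With ``cache_dir`` set, the bank
    is cached on disk keyed by (corpus, specs, k, seed).
    """
    if not specs:
        raise ValueError("at least one labeler spec required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate labeler names in spec set")

    cache_path = None
    if cache_dir is not None:
        key = hashlib.sha256(json.dumps(
            [_corpus_key(corpus),
             [(s.name, s.learner_kind, s.template.to_dict(),
               list(s.hyperparameters)) for s in specs],
             k, rng_seed],
            sort_keys=True).encode()).hexdigest()
        cache_path = Path(cache_dir) / f"bank-{key[:24]}.pkl"
        if cache_path.exists():
            with cache_path.open("rb") as fh:
                return pickle.load(fh)

    labels = tuple(label_alphabet(corpus.entity_types))
    index = {lab: j for j, lab in enumerate(labels)}
    folds = make_folds(corpus, k, rng_seed)
    fold_sent_lengths = [
        [len(corpus.sentences[int(i)]) for i in fold] for fold in folds
    ]
    fold_gold = [
        np.array([index[lab] for i in fold
                  for lab in corpus.sentences[int(i)].labels], dtype=np.intp)
        for fold in folds
    ]
    fold_outputs = [
        np.empty((len(g), len(specs)), dtype=np.intp) for g in fold_gold
    ]
    f_values = np.empty(len(specs))
    for m, spec in enumerate(specs):
        per_fold, f_m = train_and_predict(
            spec, corpus, folds, unknown_seed=rng_seed
        )
        f_values[m] = f_m
        for f, preds in enumerate(per_fold):
            flat = [index[lab] for sent in preds for lab in sent]
            fold_outputs[f][:, m] = flat
    bank = PredictionMatrix(
        labels=labels,
        classifier_names=tuple(names),
        fold_sentence_indices=[f.copy() for f in folds],
        fold_sent_lengths=fold_sent_lengths,
        fold_gold=fold_gold,
        fold_outputs=fold_outputs,
        classifier_F=f_values,
    )
    bank.validate()
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        with cache_path.open("wb") as fh:
            pickle.dump(bank, fh)
    return bank


def _corpus_key(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for sent in corpus:
        for tok in sent:
            h.update(
                f"{tok.surface}\x00{tok.pos}\x00{tok.chunk}\x00{tok.label}\n"
                .encode()
            )
        h.update(b"\x01")
    return h.hexdigest()
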
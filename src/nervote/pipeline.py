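"""End-to-end orchestration: bank -> GA -> decode -> score.

The ensemble's vote weights V and classifier F-measures F_m come from
the cross-validation phase on the training corpus; test-time
predictions come from the same classifiers retrained on 100% of the
training data.  Every artifact written carries the run seed and a
config hash so runs are replayable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus
from .evaluation import EvalReport, strict_match_scores
from .features import build_resources
from .ga import Chromosome, EnsembleSolution, GAConfig, run_ga
from .models import LabelerSpec, build_model_bank, make_backend
from .voting import weighted_vote_decode

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    train_corpus: Corpus
    test_corpus: Corpus
    specs: tuple[LabelerSpec, ...]
    ga: GAConfig = field(default_factory=GAConfig)
    folds: int = 5
    seed: int = 0
    out_dir: Path | None = None
    inject_best_individual: bool = False


@dataclass
class PipelineResult:
    solution: EnsembleSolution
    ensemble_report: EvalReport
    individual_reports: dict[str, EvalReport]
    ensemble_cv_fitness: float
    classifier_F: np.ndarray

    def summary(self) -> dict:
        return {
            "ensemble_cv_fitness": round(self.ensemble_cv_fitness, 2),
            "classifier_F": {
                name: round(float(f), 2)
                for name, f in zip(
                    self.solution.weight_matrix.classifier_names,
                    self.classifier_F,
                )
            },
            "ensemble_test": self.ensemble_report.as_dict()["overall"],
            "individual_test": {
                name: rep.as_dict()["overall"]
                for name, rep in sorted(self.individual_reports.items())
            },
        }


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "specs": [
                (s.name, s.learner_kind, s.template.to_dict(),
                 list(s.hyperparameters))
                for s in config.specs
            ],
            "ga": {
                k: getattr(config.ga, k)
                for k in ("population_size", "generations", "k1", "k2",
                          "k3", "k4", "delta", "folds", "rng_seed",
                          "include_o")
            },
            "folds": config.folds,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    injected: Sequence[Chromosome] | None = None,
) -> PipelineResult:
    """Train the bank, optimize weights, decode and score the test set.

    With ``inject_best_individual`` the degenerate identity chromosome
    of the best base classifier (its row all ones, others zero) is
    appended to the initial GA population, guaranteeing through elitism
    that the ensemble's CV fitness is at least that classifier's
    per-fold mean F.
    """
    bank = build_model_bank(
        config.train_corpus, list(config.specs), k=config.folds,
        rng_seed=config.seed,
    )
    ga_cfg = config.ga
    if ga_cfg.rng_seed != config.seed or ga_cfg.folds != config.folds:
        ga_cfg = GAConfig(**{
            **{k: getattr(ga_cfg, k)
               for k in ("population_size", "generations", "k1", "k2", "k3",
                         "k4", "delta", "include_o")},
            "folds": config.folds, "rng_seed": config.seed,
        })
    inject = list(injected) if injected else []
    n_weighted = len(bank.labels) - (0 if ga_cfg.include_o else 1)
    if config.inject_best_individual:
        best_m = int(np.argmax(bank.classifier_F))
        genes = np.zeros(bank.n_classifiers * n_weighted)
        genes[best_m * n_weighted:(best_m + 1) * n_weighted] = 1.0
        inject.append(Chromosome(genes))
    solution = run_ga(ga_cfg, bank, injected=inject or None)

    # test-time predictions: retrain every classifier on the full
    # training corpus
    resources = build_resources(config.train_corpus, unknown_seed=config.seed)
    test_sents = list(config.test_corpus.sentences)
    gold = [s.labels for s in test_sents]
    per_clf_preds = []
    individual_reports: dict[str, EvalReport] = {}
    for spec in config.specs:
        backend = make_backend(spec)
        backend.fit(
            list(config.train_corpus.sentences), spec.template, resources
        )
        preds = backend.predict(test_sents)
        per_clf_preds.append(preds)
        individual_reports[spec.name] = strict_match_scores(gold, preds)
    joint = weighted_vote_decode(
        per_clf_preds, solution.weight_matrix, solution.classifier_F
    )
    ensemble_report = strict_match_scores(gold, joint)

    result = PipelineResult(
        solution=solution,
        ensemble_report=ensemble_report,
        individual_reports=individual_reports,
        ensemble_cv_fitness=float(solution.best.fitness),
        classifier_F=solution.classifier_F,
    )
    if config.out_dir is not None:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: RunConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    result.solution.weight_matrix.save(out / "weights.txt")
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "folds": config.folds,
        "fitness_trace": [round(f, 6) for f in result.solution.fitness_trace],
        "summary": result.summary(),
    }
    (out / "report.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (out / "report.txt").write_text(
        f"run {chash} seed={config.seed}\n\n"
        "== ensemble (test) ==\n"
        + result.ensemble_report.format_table() + "\n\n"
        + "\n\n".join(
            f"== {name} (test) ==\n" + rep.format_table()
            for name, rep in sorted(result.individual_reports.items())
        )
        + "\n",
        encoding="utf-8",
    )
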
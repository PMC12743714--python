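"""End-to-end orchestration: generate, filter, undersample, fit, evaluate.

``run_experiment`` composes the whole study pipeline on synthetic data and
persists every artifact (case table, out-of-fold predictions, metric and
validity reports, CDF curves) together with a manifest recording the
configuration hash, seeds, library versions, and a checksum per output
file, so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .adasampling import AdaConfig, ada_fit, ada_predict
from .datagen import GeneratorConfig, PUDataset, generate_pu_dataset
from .evaluation import evaluate_all, make_cv_folds, metrics_table, prediction_cdf
from .io import write_case_table, write_json
from .preprocess import apply_cohort_filters, compute_class_label_mean, undersample
from .spy import SpyConfig, spy_fit, spy_predict
from .validity import PopulationFrame, build_validity_report, format_validity_report

__all__ = ["ExperimentConfig", "run_cv", "run_experiment", "population_frame_from_generator"]


@dataclass
class ExperimentConfig:
    """Configuration of a full experiment run.

    The master seed drives every stochastic stage through deterministic
    child seeds; model sections set to None skip that learner.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_unlabeled: Optional[int] = None  # undersample target; None keeps all unlabeled
    spy: Optional[SpyConfig] = field(default_factory=SpyConfig)
    ada: Optional[AdaConfig] = field(default_factory=AdaConfig)
    n_folds: int = 5
    ks: Sequence[float] = (10, 20, 30)
    scenarios: Sequence[str] = ("A", "B", "C", "D", "E")
    validity_from_generator: bool = True
    population: Optional[PopulationFrame] = None
    out_dir: str | Path = "pucase_run"
    seed: int = 0


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


def run_cv(
    dataset: PUDataset,
    fit_fn: Callable[[PUDataset, int], object],
    predict_fn: Callable[[object, PUDataset], pd.Series],
    threshold_fn: Callable[[object, PUDataset], float],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[dict[int, pd.Series], dict[int, float]]:
    """Generic cross-validated PU fit: out-of-fold predictions per fold.

    For each fold, the learner is fitted on the remaining folds (``fit_fn``
    receives the training subset and a fold seed) and scores the held-out
    fold; ``threshold_fn`` extracts that fold's classification threshold
    from the fitted model and its training set.
    """
    folds = make_cv_folds(dataset, n_folds=n_folds, seed=seed)
    fold_of = folds.reindex(dataset.frame["case_id"].to_numpy()).to_numpy()
    seeds = _child_seeds(seed, n_folds)
    predictions: dict[int, pd.Series] = {}
    thresholds: dict[int, float] = {}
    for fold in range(n_folds):
        train_frame = dataset.frame.loc[fold_of != fold].reset_index(drop=True)
        test_frame = dataset.frame.loc[fold_of == fold].reset_index(drop=True)
        train = PUDataset(
            frame=train_frame,
            feature_columns=list(dataset.feature_columns),
            truth=dataset.truth,
            flags=list(dataset.flags),
        )
        test = PUDataset(
            frame=test_frame, feature_columns=list(dataset.feature_columns), truth=dataset.truth
        )
        fit = fit_fn(train, seeds[fold])
        predictions[fold] = predict_fn(fit, test)
        thresholds[fold] = threshold_fn(fit, train)
    return predictions, thresholds


def population_frame_from_generator(
    full: PUDataset, learning: PUDataset
) -> PopulationFrame:
    """Population counts taken from generator truth: full pool vs learning sample."""
    l_i = int((full.frame["s"] == 1).sum())
    u_i = int((full.frame["s"] == 0).sum())
    u_t = int((learning.frame["s"] == 0).sum())
    return PopulationFrame(l_i=l_i, u_i=u_i, u_t=u_t)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: ExperimentConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(o) if isinstance(o, (frozenset, set)) else list(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the pipeline end-to-end and persist all artifacts.

    Stages: generate -> cohort filters -> undersample -> five-fold CV fits
    of the configured learners -> scenario evaluation -> external validity.
    Returns a bundle with the in-memory results and the manifest. Any stage
    error is re-raised annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    bundle: dict = {}

    stage = "generate"
    try:
        full = generate_pu_dataset(config.generator)
        stage = "filter"
        filtered, filter_report = apply_cohort_filters(full)
        stage = "undersample"
        if config.n_unlabeled is not None:
            learning = undersample(filtered, config.n_unlabeled, seed=config.seed)
        else:
            learning = filtered
        bundle["label_mean"] = compute_class_label_mean(learning)
        artifacts.append(write_case_table(learning, out_dir / "dataset.csv"))
        (out_dir / "filter_report.json").write_text(filter_report.to_json())
        artifacts.append(out_dir / "filter_report.json")

        population = config.population
        if population is None and config.validity_from_generator:
            population = population_frame_from_generator(filtered, learning)

        model_runs: dict[str, tuple[dict[int, pd.Series], dict[int, float]]] = {}
        if config.spy is not None:
            stage = "fit-spy"

            def fit_spy(train: PUDataset, fold_seed: int):
                cfg = dataclasses.replace(config.spy, seed=fold_seed)
                return spy_fit(train, cfg)

            model_runs["spy"] = run_cv(
                learning,
                fit_spy,
                spy_predict,
                lambda fit, train: fit.step2_train_label_mean,
                n_folds=config.n_folds,
                seed=config.seed,
            )
        if config.ada is not None:
            stage = "fit-ada"

            def fit_ada(train: PUDataset, fold_seed: int):
                cfg = dataclasses.replace(config.ada, seed=fold_seed)
                return ada_fit(train, cfg)

            model_runs["ada"] = run_cv(
                learning,
                fit_ada,
                ada_predict,
                lambda fit, train: fit.train_label_mean,
                n_folds=config.n_folds,
                seed=config.seed,
            )

        stage = "evaluate"
        bundle["metrics"] = {}
        bundle["validity"] = {}
        s_series = pd.Series(
            learning.frame["s"].to_numpy(), index=learning.frame["case_id"].to_numpy()
        )
        groups = s_series.map({1: "labeled_positive", 0: "unlabeled"})
        for model, (preds, thresholds) in model_runs.items():
            pooled = pd.concat([preds[k] for k in sorted(preds)])
            pooled.rename("probability").to_csv(out_dir / f"predictions_{model}.csv")
            artifacts.append(out_dir / f"predictions_{model}.csv")

            reports = evaluate_all(
                preds, thresholds, learning, scenarios=config.scenarios, ks=config.ks
            )
            bundle["metrics"][model] = reports
            for which in ("pooled", "fold_mean"):
                table = metrics_table(reports, which=which)
                table.round(3).to_csv(out_dir / f"metrics_{model}_{which}.csv")
                artifacts.append(out_dir / f"metrics_{model}_{which}.csv")

            cdf = prediction_cdf(pooled, groups)
            for group, curve in cdf.items():
                p = out_dir / f"cdf_{model}_{group}.csv"
                curve.to_csv(p, index=False)
                artifacts.append(p)

            if population is not None:
                stage = "validity"
                report = build_validity_report(preds, thresholds, learning.frame, population)
                bundle["validity"][model] = report
                format_validity_report(report).to_csv(
                    out_dir / f"validity_{model}.csv", index=False
                )
                artifacts.append(out_dir / f"validity_{model}.csv")

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(config),
            "master_seed": config.seed,
            "versions": _versions(),
            "label_mean": bundle["label_mean"],
            "files": {p.name: _sha256(p) for p in artifacts},
        }
        write_json(manifest, out_dir / "manifest.json")
        bundle["manifest"] = manifest
        bundle["population"] = population
        bundle["learning_sample"] = learning
        return bundle
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"experiment failed during stage '{stage}': {exc}") from exc


def _versions() -> dict[str, str]:
    import sklearn

    versions = {
        "pucase": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
    try:
        import xgboost

        versions["xgboost"] = xgboost.__version__
    except ImportError:
        pass
    return versions
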
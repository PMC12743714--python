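"""Synthetic PU case-table generator.

Emulates the statistical structure of hospital administrative case-cost data
for a positive-unlabeled (PU) learning study: a latent binary disease class
``y`` drawn with class prior ``alpha``, an observed label ``s`` assigned to
latent positives with propensity ``e(x)`` (constant label frequency ``c``
under SCAR, attribute-dependent under SAR), right-skewed zero-inflated cost
features with class-conditional location shifts, procedure-chapter counts,
overlapping explicit/implicit coding flags, and the cohort fields the
inclusion filters operate on.

Ground truth (``y``, alpha, c) is recorded so parameter recovery and the
SCAR-estimability of recall can be tested — something impossible on the real
data the generator emulates, where only ``(x, s)`` are observed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CostFeature",
    "CountFeature",
    "GeneratorConfig",
    "GeneratorTruth",
    "CaseRecord",
    "PUDataset",
    "COHORT_COLUMNS",
    "generate_pu_dataset",
    "inject_cohort_noise",
    "NOISE_KINDS",
]

#: Non-feature columns every case table carries, in canonical order.
COHORT_COLUMNS = [
    "case_id",
    "s",
    "y",
    "explicit_flag",
    "implicit_flag",
    "age_band",
    "length_of_stay_days",
    "total_costs",
    "has_main_diagnosis",
    "has_drg",
]


@dataclass(frozen=True)
class CostFeature:
    """Zero-inflated log-normal cost attribute.

    ``zero_prob`` and ``log_mean`` are (negative-class, positive-class)
    pairs; ``log_sd`` is shared. Costs are in currency units (CHF-like) and
    always non-negative; the point mass at zero mirrors the many exact-zero
    cost cells of real case-cost tables (a case without an ICU stay has ICU
    cost exactly 0).
    """

    name: str
    zero_prob: tuple[float, float]
    log_mean: tuple[float, float]
    log_sd: float = 1.0


@dataclass(frozen=True)
class CountFeature:
    """Poisson procedure-chapter count with class-conditional mean."""

    name: str
    mean: tuple[float, float]


def default_cost_features() -> list[CostFeature]:
    # Locations/zero-shares chosen so positives show the qualitative pattern
    # of coded sepsis cases: heavy ICU/laboratory/pharmaceutical involvement
    # and roughly three-fold higher total costs, with strong right skew.
    return [
        CostFeature("cost_icu", zero_prob=(0.90, 0.45), log_mean=(7.5, 9.1), log_sd=1.2),
        CostFeature("cost_laboratory", zero_prob=(0.30, 0.05), log_mean=(4.6, 6.6), log_sd=1.0),
        CostFeature("cost_pharmaceuticals", zero_prob=(0.20, 0.05), log_mean=(4.4, 5.9), log_sd=1.2),
        CostFeature("cost_nursing", zero_prob=(0.02, 0.01), log_mean=(7.2, 8.3), log_sd=1.0),
        CostFeature("cost_emergency", zero_prob=(0.55, 0.25), log_mean=(5.5, 5.8), log_sd=0.8),
    ]


def strong_shift_cost_features() -> list[CostFeature]:
    """Strongly separated cost profile: a positive case almost always shows
    elevated ICU, laboratory, pharmaceutical and nursing costs. Used for
    parameter-recovery experiments where the separability assumption is meant
    to hold nearly exactly, rather than only qualitatively."""
    return [
        CostFeature("cost_icu", zero_prob=(0.95, 0.05), log_mean=(7.0, 9.8), log_sd=0.8),
        CostFeature("cost_laboratory", zero_prob=(0.40, 0.01), log_mean=(4.5, 7.5), log_sd=0.7),
        CostFeature("cost_pharmaceuticals", zero_prob=(0.30, 0.01), log_mean=(4.2, 7.0), log_sd=0.8),
        CostFeature("cost_nursing", zero_prob=(0.02, 0.0), log_mean=(7.0, 9.2), log_sd=0.7),
        CostFeature("cost_emergency", zero_prob=(0.60, 0.05), log_mean=(5.3, 6.8), log_sd=0.7),
    ]


def default_count_features() -> list[CountFeature]:
    return [
        CountFeature("chop_respiratory", mean=(0.04, 0.23)),
        CountFeature("chop_cardiovascular", mean=(0.19, 0.68)),
        CountFeature("chop_digestive", mean=(0.18, 0.68)),
        CountFeature("chop_other_procedures", mean=(2.24, 3.21)),
    ]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic PU case generator.

    Parameters
    ----------
    n_cases
        Number of cases to generate.
    class_prior
        alpha = p(y=1), the latent positive-class prior; 0 < alpha < 1.
    label_frequency
        c = p(s=1 | y=1), the label frequency; 0 <= c <= 1.
    propensity_mode
        "SCAR": every latent positive is labeled with constant probability c.
        "SAR": the labeling propensity is logistic in ``propensity_attributes``
        and rescaled so its mean over latent positives equals c.
    propensity_attributes
        Mapping feature name -> logistic weight (SAR mode only).
    implicit_given_positive
        Probability a latent positive also satisfies the implicit (infection
        plus organ dysfunction) coding rule.
    implicit_only_rate
        Probability a latent negative satisfies the implicit rule.
    """

    n_cases: int = 5000
    class_prior: float = 0.2
    label_frequency: float = 0.5
    propensity_mode: Literal["SCAR", "SAR"] = "SCAR"
    propensity_attributes: Optional[dict[str, float]] = None
    cost_features: list[CostFeature] = field(default_factory=default_cost_features)
    count_features: list[CountFeature] = field(default_factory=default_count_features)
    base_cost_log_mean: tuple[float, float] = (8.7, 9.1)
    base_cost_log_sd: float = 0.8
    implicit_given_positive: float = 0.65
    implicit_only_rate: float = 0.045
    age_mean: tuple[float, float] = (53.0, 71.0)
    age_sd: tuple[float, float] = (18.0, 13.0)
    los_mean: tuple[float, float] = (4.0, 11.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be a positive integer")
        if not 0.0 < self.class_prior < 1.0:
            raise ValueError("class_prior must lie strictly between 0 and 1")
        if not 0.0 <= self.label_frequency <= 1.0:
            raise ValueError("label_frequency must lie in [0, 1]")
        if self.propensity_mode not in ("SCAR", "SAR"):
            raise ValueError("propensity_mode must be 'SCAR' or 'SAR'")
        if self.propensity_mode == "SAR" and not self.propensity_attributes:
            raise ValueError("SAR mode requires propensity_attributes")


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth recorded alongside a synthetic dataset."""

    class_prior: float
    label_frequency: float
    propensity_mode: str
    n_latent_positive: int
    n_labeled: int
    propensity_description: str = "constant e(x) = c (SCAR)"


@dataclass(frozen=True)
class CaseRecord:
    """One inpatient case: features x, observed label s, latent class y."""

    case_id: int
    features: dict[str, float]
    label_observed: int
    latent_class: Optional[int]
    explicit_flag: int
    implicit_flag: int
    age_band: str
    length_of_stay_days: int
    total_costs: float
    has_main_diagnosis: bool
    has_drg: bool


@dataclass
class PUDataset:
    """A collection of cases, stored as one row per case in ``frame``.

    ``feature_columns`` lists the learning attributes (cost and count
    features); everything else is cohort/label bookkeeping. ``truth`` is
    present only for synthetic data.
    """

    frame: pd.DataFrame
    feature_columns: list[str]
    truth: Optional[GeneratorTruth] = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.frame)

    @property
    def labeled_fraction(self) -> float:
        return float(self.frame["s"].mean())

    def record(self, case_id: int) -> CaseRecord:
        row = self.frame.loc[self.frame["case_id"] == case_id].iloc[0]
        y = row["y"]
        return CaseRecord(
            case_id=int(row["case_id"]),
            features={c: float(row[c]) for c in self.feature_columns},
            label_observed=int(row["s"]),
            latent_class=None if pd.isna(y) else int(y),
            explicit_flag=int(row["explicit_flag"]),
            implicit_flag=int(row["implicit_flag"]),
            age_band=str(row["age_band"]),
            length_of_stay_days=int(row["length_of_stay_days"]),
            total_costs=float(row["total_costs"]),
            has_main_diagnosis=bool(row["has_main_diagnosis"]),
            has_drg=bool(row["has_drg"]),
        )

    def validate(self) -> None:
        f = self.frame
        if f["case_id"].duplicated().any():
            raise ValueError("case_ids are not unique")
        if not f["s"].isin([0, 1]).all():
            raise ValueError("observed label s must be binary")
        has_y = f["y"].notna()
        if has_y.any():
            labeled_latent = f.loc[f["s"] == 1, "y"]
            if (labeled_latent.dropna() != 1).any():
                raise ValueError("labeled case with latent class 0 (violates p(y=1|s=1)=1)")
        if ((f["s"] == 1) & (f["explicit_flag"] != 1)).any():
            raise ValueError("labeled case without explicit coding flag")

    def copy(self) -> "PUDataset":
        return PUDataset(
            frame=self.frame.copy(),
            feature_columns=list(self.feature_columns),
            truth=self.truth,
            flags=list(self.flags),
        )


def _age_band(age: np.ndarray) -> np.ndarray:
    lo = (np.clip(age, 0, 99) // 5).astype(int) * 5
    return np.array([f"{a}-{a + 4}" for a in lo])


def generate_pu_dataset(config: GeneratorConfig) -> PUDataset:
    """Draw a PU case table from the class-conditional mixture model.

    Latent classes are Bernoulli(alpha); features come from the
    class-conditional zero-inflated log-normal / Poisson distributions; the
    observed label s is drawn for latent positives with propensity e(x)
    (constant c under SCAR, mean-calibrated logistic under SAR). Labels are
    assigned by explicit coding, so ``explicit_flag`` equals s; implicit
    flags are drawn independently per class so the five evaluation
    constellations overlap. Reproducible under a fixed seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_class, rng_feat, rng_label, rng_flags, rng_cohort = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = config.n_cases

    y = (rng_class.random(n) < config.class_prior).astype(int)
    pos = y == 1

    cols: dict[str, np.ndarray] = {}
    for cf in config.cost_features:
        zero = np.where(pos, cf.zero_prob[1], cf.zero_prob[0])
        mu = np.where(pos, cf.log_mean[1], cf.log_mean[0])
        vals = rng_feat.lognormal(mean=mu, sigma=cf.log_sd)
        vals[rng_feat.random(n) < zero] = 0.0
        cols[cf.name] = vals
    for ct in config.count_features:
        lam = np.where(pos, ct.mean[1], ct.mean[0])
        cols[ct.name] = rng_feat.poisson(lam).astype(float)

    base_mu = np.where(pos, config.base_cost_log_mean[1], config.base_cost_log_mean[0])
    base_cost = rng_feat.lognormal(mean=base_mu, sigma=config.base_cost_log_sd)
    cost_names = [cf.name for cf in config.cost_features]
    total_costs = base_cost + sum(cols[c] for c in cost_names)

    # Labeling propensity among latent positives.
    if config.propensity_mode == "SCAR":
        e = np.full(n, config.label_frequency)
        desc = "constant e(x) = c (SCAR)"
    else:
        z = np.zeros(n)
        for name, w in (config.propensity_attributes or {}).items():
            v = cols[name]
            scale = v.std()
            z += w * (v - v.mean()) / (scale if scale > 0 else 1.0)
        raw = 1.0 / (1.0 + np.exp(-z))
        mean_pos = raw[pos].mean() if pos.any() else 1.0
        e = np.clip(raw * (config.label_frequency / mean_pos), 0.0, 1.0)
        desc = "logistic e(x_e), mean-calibrated to c (SAR)"

    s = np.where(pos & (rng_label.random(n) < e), 1, 0)

    explicit = s.copy()  # labels are assigned by explicit coding
    p_impl = np.where(pos, config.implicit_given_positive, config.implicit_only_rate)
    implicit = (rng_flags.random(n) < p_impl).astype(int)

    age = np.where(
        pos,
        rng_cohort.normal(config.age_mean[1], config.age_sd[1], n),
        rng_cohort.normal(config.age_mean[0], config.age_sd[0], n),
    )
    age = np.clip(age, 20, 94)
    los = 1 + rng_cohort.poisson(np.where(pos, config.los_mean[1], config.los_mean[0]))

    frame = pd.DataFrame(
        {
            "case_id": np.arange(1, n + 1),
            "s": s,
            "y": y.astype(float),
            "explicit_flag": explicit,
            "implicit_flag": implicit,
            "age_band": _age_band(age),
            "length_of_stay_days": los.astype(int),
            "total_costs": total_costs,
            "has_main_diagnosis": np.ones(n, dtype=bool),
            "has_drg": np.ones(n, dtype=bool),
            **cols,
        }
    )
    feature_columns = cost_names + [ct.name for ct in config.count_features]
    truth = GeneratorTruth(
        class_prior=config.class_prior,
        label_frequency=config.label_frequency,
        propensity_mode=config.propensity_mode,
        n_latent_positive=int(pos.sum()),
        n_labeled=int(s.sum()),
        propensity_description=desc,
    )
    flags = [] if s.sum() > 0 else ["no labeled positives"]
    ds = PUDataset(frame=frame, feature_columns=feature_columns, truth=truth, flags=flags)
    ds.validate()
    return ds


#: Supported cohort-violation kinds for :func:`inject_cohort_noise`.
NOISE_KINDS = (
    "underage",
    "missing_main_diagnosis",
    "missing_drg",
    "missing_cost",
    "zero_total_costs",
    "zero_length_of_stay",
)


def inject_cohort_noise(
    dataset: PUDataset, fractions: dict[str, float], seed: int = 0
) -> tuple[PUDataset, pd.DataFrame]:
    """Mutate disjoint random case subsets to each violate one cohort rule.

    ``fractions`` maps a violation kind (see :data:`NOISE_KINDS`) to the
    fraction of cases to mutate; counts are ``round(fraction * n)``. Returns
    the mutated dataset and a mutation log (case_id, violation). Fractions
    must each lie in [0, 1] and sum to at most 1 so subsets stay disjoint.
    """
    for kind, frac in fractions.items():
        if kind not in NOISE_KINDS:
            raise ValueError(f"unknown violation kind: {kind!r}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for {kind!r} must lie in [0, 1]")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("violation fractions sum above 1; subsets must be disjoint")

    out = dataset.copy()
    f = out.frame
    n = len(f)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    log_rows: list[tuple[int, str]] = []
    start = 0
    cost_col = next(
        (c for c in dataset.feature_columns if c.startswith("cost_")),
        dataset.feature_columns[0] if dataset.feature_columns else None,
    )
    for kind, frac in fractions.items():
        k = int(round(frac * n))
        idx = f.index[order[start : start + k]]
        start += k
        if kind == "underage":
            f.loc[idx, "age_band"] = "15-19"
        elif kind == "missing_main_diagnosis":
            f.loc[idx, "has_main_diagnosis"] = False
        elif kind == "missing_drg":
            f.loc[idx, "has_drg"] = False
        elif kind == "missing_cost":
            if cost_col is None:
                raise ValueError("dataset has no cost feature to blank")
            f.loc[idx, cost_col] = np.nan
        elif kind == "zero_total_costs":
            f.loc[idx, "total_costs"] = 0.0
        elif kind == "zero_length_of_stay":
            f.loc[idx, "length_of_stay_days"] = 0
        log_rows.extend((int(cid), kind) for cid in f.loc[idx, "case_id"])
    log = pd.DataFrame(log_rows, columns=["case_id", "violation"])
    return out, log
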
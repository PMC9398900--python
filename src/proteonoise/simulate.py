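"""Synthetic antibody-array cohorts with planted level shifts and noise structure.

The generator emulates the study design the downstream analyses expect:
cross-sectional serum cohorts (young, middle-aged, old, and an age-matched
cognitively impaired "disease" group) plus a longitudinal series of
therapeutic plasma exchange (TPE) rounds on the same subjects.  Protein
levels are log-normal; a configurable subset of analytes carries an
old-vs-young mean shift, and a disjoint (or overlapping) "noise-reporter"
subset carries variance inflation that grows with age, is strongest in the
disease group, and contracts across TPE rounds.  Every dataset is emitted
together with a :class:`GroundTruth` describing exactly which analytes were
planted and what the implied noise-age relation is, so each downstream
stage has an oracle to test against.

Model summary (natural log scale throughout):

* analyte baseline log-level ``m_a ~ Normal(log_level_mean, log_level_spread)``
  drawn once per seed and shared by every cohort;
* subject level ``v = exp(m_a + shift_a + sigma_a * z)`` with
  ``sigma_a = baseline_sigma * inflation``;
* noise inflation rises linearly with age from 1 at the young-cohort
  mid-age to ``sd_inflation_old`` at the old-cohort mid-age, is the flat
  ``sd_inflation_disease`` in the disease group, and decays geometrically
  over TPE rounds by a total factor ``tpe_sd_contraction``;
* replicate spots are log-normal around the subject level with coefficient
  of variation ``baseline_cv``, optionally scaled by the same inflation so
  that within-slide replicate scatter tracks the biological dispersion;
* each slide gets a log-normal scanner gain and an additive background,
  and carries positive/negative control spots from which normalization can
  recover the signal scale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import ArraySample, write_spot_tables
from .errors import ConfigurationError

_DEFAULT_COHORT_SIZES = {"young": 5, "middle": 5, "old": 5, "disease": 5, "tpe": 8}
_DEFAULT_AGES = {
    "young": (20.0, 30.0),
    "middle": (46.0, 52.0),
    "old": (60.0, 79.0),
    "disease": (64.0, 90.0),
    "tpe": (46.0, 79.0),
}
_DEFAULT_CONTROLS = {"n_pos": 6, "n_neg": 6, "pos_level": 20000.0, "neg_level": 150.0}
# Fraction of the old/young log level shift expressed per cohort.
_LEVEL_SHIFT_FRACTION = {"young": 0.0, "middle": 0.5, "old": 1.0, "disease": 1.0}


def _c4(n: int) -> float:
    """Unbiasing constant: E[sample SD of n normals] = c4(n) * sigma."""
    if n < 2:
        return 0.0
    return math.sqrt(2.0 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    The defaults mirror the emulated study: 507 analytes, small serum
    cohorts, a 72-analyte two-fold level-shift set, a 9-analyte
    noise-reporter set with threefold old-age SD inflation and fivefold
    disease inflation, four TPE timepoints (R0..R3) over which the planted
    dispersion contracts by at least fivefold, and duplicate spot printing
    with 5% technical CV.
    """

    n_analytes: int = 507
    n_per_cohort: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_COHORT_SIZES)
    )
    ages: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_AGES)
    )
    n_rounds: int = 4
    replicates_per_spot: int = 2
    level_shift_set: tuple[str, ...] | None = None
    level_shift_ratio: float = 2.0
    level_shift_fraction_up: float = 0.5
    noise_set: tuple[str, ...] | None = None
    sd_inflation_old: float = 3.0
    sd_inflation_disease: float = 5.0
    tpe_recovery_fraction: float = 1.0
    tpe_sd_contraction: float | None = 5.0
    baseline_cv: float = 0.05
    baseline_sigma: float = 0.2
    log_level_mean: float = math.log(500.0)
    log_level_spread: float = 0.5
    replicate_noise_tracks_dispersion: bool = True
    control_spots: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_CONTROLS)
    )
    gain_sd: float = 0.2
    analyte_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_analytes < 1:
            raise ConfigurationError("n_analytes must be >= 1")
        if self.analyte_ids is None:
            width = max(3, len(str(self.n_analytes)))
            ids = tuple(f"P{i + 1:0{width}d}" for i in range(self.n_analytes))
        else:
            ids = tuple(self.analyte_ids)
            if len(ids) != self.n_analytes:
                raise ConfigurationError(
                    f"{len(ids)} analyte ids given for n_analytes={self.n_analytes}"
                )
            if len(set(ids)) != len(ids):
                raise ConfigurationError("analyte ids must be unique")
        object.__setattr__(self, "analyte_ids", ids)
        if self.noise_set is None:
            object.__setattr__(self, "noise_set", ids[: min(9, len(ids))])
        else:
            object.__setattr__(self, "noise_set", tuple(self.noise_set))
        if self.level_shift_set is None:
            hi = min(len(ids), 9 + 72)
            object.__setattr__(self, "level_shift_set", ids[min(9, len(ids)) : hi])
        else:
            object.__setattr__(self, "level_shift_set", tuple(self.level_shift_set))
        id_set = set(ids)
        for name, subset in (
            ("noise_set", self.noise_set),
            ("level_shift_set", self.level_shift_set),
        ):
            for a in subset:
                if a not in id_set:
                    raise ConfigurationError(
                        f"{name} references unknown analyte id {a!r}"
                    )
        for cohort, n in self.n_per_cohort.items():
            if cohort not in _DEFAULT_COHORT_SIZES:
                raise ConfigurationError(f"unknown cohort {cohort!r}")
            if n < 1:
                raise ConfigurationError(f"cohort {cohort!r} has count {n} (< 1)")
            if cohort not in self.ages:
                raise ConfigurationError(f"cohort {cohort!r} has no age range")
        for cohort, (lo, hi) in self.ages.items():
            if not (0 < lo <= hi):
                raise ConfigurationError(f"invalid age range for {cohort!r}: {(lo, hi)}")
        # Fold parameters of 1.0 are permitted: they plant a null effect,
        # which the calibration checks rely on.
        for name in ("level_shift_ratio", "sd_inflation_old", "sd_inflation_disease"):
            if getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.tpe_sd_contraction is not None and self.tpe_sd_contraction < 1.0:
            raise ConfigurationError("tpe_sd_contraction must be >= 1 or None")
        if not 0.0 <= self.tpe_recovery_fraction <= 1.0:
            raise ConfigurationError("tpe_recovery_fraction must be in [0, 1]")
        if not 0.0 <= self.level_shift_fraction_up <= 1.0:
            raise ConfigurationError("level_shift_fraction_up must be in [0, 1]")
        if self.baseline_cv < 0:
            raise ConfigurationError("baseline_cv must be >= 0")
        if self.baseline_sigma <= 0:
            raise ConfigurationError("baseline_sigma must be > 0")
        if self.replicates_per_spot < 1:
            raise ConfigurationError("replicates_per_spot must be >= 1")
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")
        for key in ("n_pos", "n_neg", "pos_level", "neg_level"):
            if key not in self.control_spots:
                raise ConfigurationError(f"control_spots missing {key!r}")
        if min(self.control_spots["n_pos"], self.control_spots["n_neg"]) < 1:
            raise ConfigurationError("control spot counts must be >= 1")
        if self.control_spots["pos_level"] <= self.control_spots["neg_level"]:
            raise ConfigurationError("pos_level must exceed neg_level")


@dataclasses.dataclass
class GroundTruth:
    """Oracle emitted alongside every simulated dataset.

    ``true_scores`` holds, per sample, the replicate-mode noise score the
    generator implies over the planted noise set (mean over planted
    analytes of ``c4(n_rep) * cv_eff * subject_level``); ``clock_truth`` is
    the (slope, intercept) of the population noise-age line implied by the
    configuration over the healthy reference cohorts.
    """

    planted_noise_set: tuple[str, ...]
    planted_level_set: tuple[str, ...]
    analyte_ids: tuple[str, ...]
    cohort_params: pd.DataFrame
    true_scores: pd.Series
    clock_truth: tuple[float, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_noise_set": list(self.planted_noise_set),
            "planted_level_set": list(self.planted_level_set),
            "analyte_ids": list(self.analyte_ids),
            "cohort_params": self.cohort_params.to_dict(orient="list"),
            "true_scores": {k: float(v) for k, v in self.true_scores.items()},
            "clock_truth": list(self.clock_truth),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_noise_set=tuple(payload["planted_noise_set"]),
            planted_level_set=tuple(payload["planted_level_set"]),
            analyte_ids=tuple(payload["analyte_ids"]),
            cohort_params=pd.DataFrame(payload["cohort_params"]),
            true_scores=pd.Series(payload["true_scores"], name="true_score"),
            clock_truth=tuple(payload["clock_truth"]),
        )


# ---------------------------------------------------------------------------
# Internal machinery
# ---------------------------------------------------------------------------

def _streams(config: SimulationConfig):
    """Deterministic child seed sequences: (analytes, cohorts, tpe).

    Cohort and TPE sampling use separate streams so that
    ``simulate_cohorts`` + ``simulate_tpe_series`` reproduce exactly the
    samples of ``simulate_study`` under the same config.
    """
    return np.random.SeedSequence(config.seed).spawn(3)


def _analyte_log_levels(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(_streams(config)[0])
    return rng.normal(config.log_level_mean, config.log_level_spread, config.n_analytes)


def _index_of(config: SimulationConfig, subset: tuple[str, ...]) -> np.ndarray:
    lookup = {a: i for i, a in enumerate(config.analyte_ids)}
    return np.array([lookup[a] for a in subset], dtype=int)


def _level_shift_signs(config: SimulationConfig) -> np.ndarray:
    m = len(config.level_shift_set)
    n_up = math.ceil(config.level_shift_fraction_up * m)
    signs = np.ones(m)
    signs[n_up:] = -1.0
    return signs


def _age_mid(config: SimulationConfig, cohort: str) -> float:
    lo, hi = config.ages[cohort]
    return 0.5 * (lo + hi)


def _inflation_at_age(config: SimulationConfig, age: float) -> float:
    """Healthy noise inflation: 1 at the young mid-age, rising linearly to
    ``sd_inflation_old`` at the old mid-age (floored at 1 below young)."""
    y_mid = _age_mid(config, "young") if "young" in config.ages else 25.0
    o_mid = _age_mid(config, "old") if "old" in config.ages else 69.5
    if o_mid <= y_mid:
        return config.sd_inflation_old
    u = max(age - y_mid, 0.0) / (o_mid - y_mid)
    return 1.0 + (config.sd_inflation_old - 1.0) * u


def _tpe_progress(config: SimulationConfig, round_: int) -> float:
    if config.n_rounds < 2:
        return 0.0
    return config.tpe_recovery_fraction * round_ / (config.n_rounds - 1)


def _subject_params(
    config: SimulationConfig,
    base_log_levels: np.ndarray,
    cohort: str,
    age: float,
    round_: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-analyte (log_mean, log_sd, replicate_cv) for one subject state."""
    log_mu = base_log_levels.copy()
    sigma = np.full(config.n_analytes, config.baseline_sigma)
    cv = np.full(config.n_analytes, config.baseline_cv)

    level_idx = _index_of(config, config.level_shift_set)
    noise_idx = _index_of(config, config.noise_set)

    if cohort == "tpe":
        progress = _tpe_progress(config, int(round_ or 0))
        level_frac = 1.0 - progress
        base_infl = _inflation_at_age(config, age)
        contraction = (
            base_infl
            if config.tpe_sd_contraction is None
            else config.tpe_sd_contraction
        )
        inflation = base_infl * contraction ** (-progress)
    else:
        level_frac = _LEVEL_SHIFT_FRACTION[cohort]
        if cohort == "disease":
            inflation = config.sd_inflation_disease
        else:
            inflation = _inflation_at_age(config, age)

    if level_idx.size:
        log_mu[level_idx] += (
            _level_shift_signs(config) * math.log(config.level_shift_ratio) * level_frac
        )
    if noise_idx.size:
        sigma[noise_idx] = sigma[noise_idx] * inflation
        if config.replicate_noise_tracks_dispersion:
            cv[noise_idx] = cv[noise_idx] * inflation
    return log_mu, sigma, cv


def _draw_sample(
    rng: np.random.Generator,
    config: SimulationConfig,
    log_mu: np.ndarray,
    sigma: np.ndarray,
    cv: np.ndarray,
    *,
    sample_id: str,
    subject_id: str,
    cohort: str,
    age: float,
    sex: str,
    round_: int | None,
) -> tuple[ArraySample, np.ndarray]:
    n, n_rep = config.n_analytes, config.replicates_per_spot
    z = rng.standard_normal(n)
    v = np.exp(log_mu + sigma * z)  # subject-level true abundance
    eps = rng.standard_normal((n, n_rep))
    reps = v[:, None] * np.exp(cv[:, None] * eps - 0.5 * cv[:, None] ** 2)
    gain = math.exp(rng.normal(0.0, config.gain_sd))
    ctrl = config.control_spots
    bg = float(ctrl["neg_level"])
    ctrl_cv = config.baseline_cv
    neg = gain * bg * np.exp(
        ctrl_cv * rng.standard_normal(int(ctrl["n_neg"])) - 0.5 * ctrl_cv**2
    )
    pos = gain * (bg + float(ctrl["pos_level"])) * np.exp(
        ctrl_cv * rng.standard_normal(int(ctrl["n_pos"])) - 0.5 * ctrl_cv**2
    )
    sample = ArraySample(
        sample_id=sample_id,
        subject_id=subject_id,
        cohort=cohort,
        age=age,
        sex=sex,
        round=round_,
        analyte_ids=config.analyte_ids,
        spots=gain * (bg + reps),
        pos_controls=pos,
        neg_controls=neg,
    )
    return sample, v


def _true_score(
    config: SimulationConfig, cv: np.ndarray, v: np.ndarray
) -> float:
    idx = _index_of(config, config.noise_set)
    if idx.size == 0:
        return 0.0
    return float((_c4(config.replicates_per_spot) * cv[idx] * v[idx]).mean())


def _expected_score_at(
    config: SimulationConfig,
    base_log_levels: np.ndarray,
    cohort: str,
    age: float,
) -> float:
    """Population-expected replicate-mode noise score at one (cohort, age)."""
    log_mu, sigma, cv = _subject_params(config, base_log_levels, cohort, age)
    idx = _index_of(config, config.noise_set)
    if idx.size == 0:
        return 0.0
    ev = np.exp(log_mu[idx] + 0.5 * sigma[idx] ** 2)
    return float((_c4(config.replicates_per_spot) * cv[idx] * ev).mean())


def _clock_truth(
    config: SimulationConfig, base_log_levels: np.ndarray
) -> tuple[float, float]:
    """Config-implied (slope, intercept) of expected noise score vs age,
    weighted by the healthy reference design (young + middle + old)."""
    ages, scores, weights = [], [], []
    for cohort in ("young", "middle", "old"):
        n = config.n_per_cohort.get(cohort, 0)
        if n < 1 or cohort not in config.ages:
            continue
        lo, hi = config.ages[cohort]
        grid = np.linspace(lo, hi, 33)
        for a in grid:
            ages.append(a)
            scores.append(_expected_score_at(config, base_log_levels, cohort, a))
            weights.append(n / len(grid))
    if len(set(ages)) < 2:
        return (0.0, float(scores[0]) if scores else 0.0)
    slope, intercept = np.polyfit(ages, scores, 1, w=np.sqrt(weights))
    return float(slope), float(intercept)


def _cohort_param_rows(
    config: SimulationConfig,
    base_log_levels: np.ndarray,
    label: str,
    cohort: str,
    age: float,
    round_: int | None = None,
) -> pd.DataFrame:
    log_mu, sigma, _ = _subject_params(config, base_log_levels, cohort, age, round_)
    mean = np.exp(log_mu + 0.5 * sigma**2)
    sd = mean * np.sqrt(np.expm1(sigma**2))
    return pd.DataFrame(
        {
            "analyte_id": list(config.analyte_ids),
            "cohort": label,
            "mean": mean,
            "sd": sd,
            "log_sd": sigma,
        }
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ArraySample], GroundTruth]:
    """Simulate the cross-sectional cohorts listed in ``n_per_cohort``.

    Returns the raw (un-normalized) array samples plus the ground truth.
    The ``tpe`` cohort is excluded here; see :func:`simulate_tpe_series`.
    """
    base = _analyte_log_levels(config)
    rng = np.random.default_rng(_streams(config)[1])
    samples: list[ArraySample] = []
    true_scores: dict[str, float] = {}
    param_rows = []
    for cohort in ("young", "middle", "old", "disease"):
        n = config.n_per_cohort.get(cohort, 0)
        if n < 1:
            continue
        lo, hi = config.ages[cohort]
        for i in range(n):
            age = float(rng.uniform(lo, hi))
            sex = "F" if rng.random() < 0.5 else "M"
            log_mu, sigma, cv = _subject_params(config, base, cohort, age)
            sid = f"{cohort}_{i + 1:03d}"
            sample, v = _draw_sample(
                rng,
                config,
                log_mu,
                sigma,
                cv,
                sample_id=sid,
                subject_id=sid,
                cohort=cohort,
                age=age,
                sex=sex,
                round_=None,
            )
            samples.append(sample)
            true_scores[sid] = _true_score(config, cv, v)
        param_rows.append(
            _cohort_param_rows(config, base, cohort, cohort, _age_mid(config, cohort))
        )
    truth = GroundTruth(
        planted_noise_set=config.noise_set,
        planted_level_set=config.level_shift_set,
        analyte_ids=config.analyte_ids,
        cohort_params=(
            pd.concat(param_rows, ignore_index=True)
            if param_rows
            else pd.DataFrame(
                columns=["analyte_id", "cohort", "mean", "sd", "log_sd"]
            )
        ),
        true_scores=pd.Series(true_scores, name="true_score", dtype=float),
        clock_truth=_clock_truth(config, base),
    )
    return samples, truth


def simulate_tpe_series(
    config: SimulationConfig,
) -> tuple[list[ArraySample], GroundTruth]:
    """Simulate the longitudinal TPE series (rounds R0..R(n_rounds-1)).

    The same subjects appear at every round; for noise-set analytes the
    biological log-SD declines monotonically across rounds, reaching the
    configured total contraction at the last round when
    ``tpe_recovery_fraction`` is 1; planted level shifts relax toward the
    young means on the same schedule.
    """
    if config.n_rounds < 2:
        raise ConfigurationError("a TPE series requires n_rounds >= 2")
    n_subjects = config.n_per_cohort.get("tpe", 0)
    if n_subjects < 1:
        raise ConfigurationError("n_per_cohort['tpe'] must be >= 1 for a TPE series")
    base = _analyte_log_levels(config)
    rng = np.random.default_rng(_streams(config)[2])
    lo, hi = config.ages["tpe"]
    samples: list[ArraySample] = []
    true_scores: dict[str, float] = {}
    subjects = []
    for i in range(n_subjects):
        age = float(rng.uniform(lo, hi))
        sex = "F" if rng.random() < 0.5 else "M"
        subjects.append((f"tpe_{i + 1:02d}", age, sex))
    for subject_id, age, sex in subjects:
        for r in range(config.n_rounds):
            log_mu, sigma, cv = _subject_params(config, base, "tpe", age, r)
            sid = f"{subject_id}_r{r}"
            sample, v = _draw_sample(
                rng,
                config,
                log_mu,
                sigma,
                cv,
                sample_id=sid,
                subject_id=subject_id,
                cohort="tpe",
                age=age,
                sex=sex,
                round_=r,
            )
            samples.append(sample)
            true_scores[sid] = _true_score(config, cv, v)
    mid_age = 0.5 * (lo + hi)
    param_rows = [
        _cohort_param_rows(config, base, f"tpe_r{r}", "tpe", mid_age, r)
        for r in range(config.n_rounds)
    ]
    truth = GroundTruth(
        planted_noise_set=config.noise_set,
        planted_level_set=config.level_shift_set,
        analyte_ids=config.analyte_ids,
        cohort_params=pd.concat(param_rows, ignore_index=True),
        true_scores=pd.Series(true_scores, name="true_score", dtype=float),
        clock_truth=_clock_truth(config, base),
    )
    return samples, truth


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[ArraySample], GroundTruth]:
    """Simulate cross-sectional cohorts plus the TPE series in one dataset."""
    samples, truth = simulate_cohorts(config)
    if config.n_per_cohort.get("tpe", 0) >= 1 and config.n_rounds >= 2:
        tpe_samples, tpe_truth = simulate_tpe_series(config)
        samples = samples + tpe_samples
        truth = GroundTruth(
            planted_noise_set=truth.planted_noise_set,
            planted_level_set=truth.planted_level_set,
            analyte_ids=truth.analyte_ids,
            cohort_params=pd.concat(
                [truth.cohort_params, tpe_truth.cohort_params], ignore_index=True
            ),
            true_scores=pd.concat([truth.true_scores, tpe_truth.true_scores]),
            clock_truth=truth.clock_truth,
        )
    return samples, truth


def write_dataset(
    samples: list[ArraySample], truth: GroundTruth, outdir: str | Path
) -> None:
    """Write spots.tsv + meta.tsv + ground_truth.json for one dataset."""
    outdir = Path(outdir)
    write_spot_tables(samples, outdir)
    truth.to_json(outdir / "ground_truth.json")
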
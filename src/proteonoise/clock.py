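"""Per-sample noise scores and the linear noise-age clock.

The noise score condenses a noise-reporter panel into one number per
sample.  Two interpretations of "mean of the panel SDs" are provided:

* ``replicate`` (default) - for each panel analyte, the SD of that
  sample's replicate spots; the score is the mean over the panel.  This
  reads within-slide dispersion and requires the replicate tensor.
* ``panel_dispersion`` - each panel analyte is z-scored against a healthy
  reference cohort and the score is the SD of the sample's z-values
  across the panel.  This works on replicate-free matrices.

The clock is an ordinary least-squares trendline of score on
chronological age fitted on a healthy reference population; biological
age is then the inverse map ``(score - intercept) / slope`` (classical
calibration, not inverse regression), so a sample lying exactly on the
trendline is assigned its own chronological age.  Scores, clocks and
reports all carry the scoring mode and panel identifier, and cross-mode
or cross-panel prediction is rejected at run time.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .arrays import AbundanceMatrix, panel_id as _panel_id
from .errors import (
    ConfigurationError,
    DegenerateFitError,
    InsufficientDataError,
    ModeUnavailableError,
    PredictionDisabledError,
    SchemaError,
    ValidationError,
)
from .noise import NoisePanel

MODES = ("replicate", "panel_dispersion")
HEALTHY_REFERENCE = ("young", "middle", "old")


@dataclasses.dataclass
class NoiseScores:
    """Per-sample noise scores with their provenance (mode + panel)."""

    scores: pd.Series  # index = sample_id
    mode: str
    panel: tuple[str, ...]

    @property
    def panel_id(self) -> str:
        return _panel_id(self.panel)


def _panel_ids(panel: NoisePanel | Sequence[str]) -> tuple[str, ...]:
    if isinstance(panel, NoisePanel):
        return tuple(panel.analytes)
    return tuple(dict.fromkeys(panel))


def noise_score(
    matrix: AbundanceMatrix,
    panel: NoisePanel | Sequence[str],
    mode: str = "replicate",
    reference_cohort: str = "young",
) -> NoiseScores:
    """Compute the panel noise score for every sample in the matrix."""
    ids = _panel_ids(panel)
    if not ids:
        raise ValidationError("panel is empty")
    missing = sorted(set(ids) - set(matrix.analyte_ids))
    if missing:
        raise ValidationError(f"panel analytes missing from matrix: {missing}")
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; choose from {MODES}")
    lookup = {a: i for i, a in enumerate(matrix.analyte_ids)}
    idx = np.array([lookup[a] for a in ids])

    if mode == "replicate":
        if matrix.replicates is None or matrix.replicates.shape[2] < 2:
            raise ModeUnavailableError(
                "replicate mode needs >= 2 replicate spots per analyte; "
                "use mode='panel_dispersion' for replicate-free matrices"
            )
        reps = matrix.replicates[idx]  # (panel, samples, reps)
        scores = reps.std(axis=2, ddof=1).mean(axis=0)
    else:
        if len(ids) < 2:
            raise ValidationError("panel_dispersion mode needs >= 2 panel analytes")
        ref_mask = matrix.sample_mask(cohort=reference_cohort)
        if ref_mask.sum() < 2:
            raise InsufficientDataError(
                f"panel_dispersion mode needs >= 2 {reference_cohort!r} "
                "reference samples"
            )
        X = matrix.values.to_numpy(dtype=float)[idx]
        ref = X[:, ref_mask]
        mu = ref.mean(axis=1, keepdims=True)
        sd = ref.std(axis=1, ddof=1, keepdims=True)
        z = np.divide(X - mu, sd, out=np.zeros_like(X), where=sd > 0)
        scores = z.std(axis=0, ddof=1)
    return NoiseScores(
        scores=pd.Series(scores, index=list(matrix.sample_ids), name="noise_score"),
        mode=mode,
        panel=ids,
    )


class NoiseAgeClock(RegressorMixin, BaseEstimator):
    """Linear calibration of the noise score against chronological age.

    ``fit(X, y)`` regresses score (``X``, one column) on age (``y``) by
    OLS; ``predict(X)`` inverts the trendline to report biological age.
    Fitted attributes: ``slope_`` (score units per year), ``intercept_``
    (score units), ``pearson_r_``, ``p_value_``, ``stderr_``,
    ``n_reference_``, plus provenance ``mode_``/``panel_id_`` when fitted
    through :func:`fit_clock`.
    """

    def fit(self, X, y) -> "NoiseAgeClock":
        scores = np.asarray(X, dtype=float).reshape(-1)
        ages = np.asarray(y, dtype=float).reshape(-1)
        if scores.size != ages.size:
            raise ValidationError("scores and ages differ in length")
        if scores.size < 3:
            raise InsufficientDataError("clock fitting needs >= 3 reference samples")
        if np.unique(ages).size < 2:
            raise DegenerateFitError("all reference ages identical; slope undefined")
        res = stats.linregress(ages, scores)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.pearson_r_ = float(res.rvalue)
        self.p_value_ = float(res.pvalue)
        self.stderr_ = float(res.stderr)
        self.n_reference_ = int(scores.size)
        return self

    def predict(self, X) -> np.ndarray:
        if self.slope_ == 0.0:
            raise PredictionDisabledError(
                "clock slope is exactly 0; biological age is undefined"
            )
        scores = np.asarray(X, dtype=float).reshape(-1)
        return (scores - self.intercept_) / self.slope_

    def to_dict(self) -> dict:
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "pearson_r": self.pearson_r_,
            "p_value": self.p_value_,
            "stderr": self.stderr_,
            "n_reference": self.n_reference_,
            "mode": getattr(self, "mode_", None),
            "panel_id": getattr(self, "panel_id_", None),
            "panel": list(getattr(self, "panel_", ())),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseAgeClock":
        payload = json.loads(Path(path).read_text())
        clock = cls()
        clock.slope_ = float(payload["slope"])
        clock.intercept_ = float(payload["intercept"])
        clock.pearson_r_ = float(payload["pearson_r"])
        clock.p_value_ = float(payload["p_value"])
        clock.stderr_ = float(payload["stderr"])
        clock.n_reference_ = int(payload["n_reference"])
        if payload.get("mode"):
            clock.mode_ = payload["mode"]
        if payload.get("panel_id"):
            clock.panel_id_ = payload["panel_id"]
        if payload.get("panel"):
            clock.panel_ = tuple(payload["panel"])
        return clock


def fit_clock(
    scores: NoiseScores,
    ages: pd.Series | Sequence[float],
    reference_ids: Sequence[str] | None = None,
) -> NoiseAgeClock:
    """Fit the noise-age trendline on reference samples.

    ``ages`` is a Series indexed by sample id (or a sequence aligned with
    ``scores.scores``).  ``reference_ids`` restricts the fit (e.g. to the
    healthy young + middle + old cohorts); by default every scored sample
    is used.
    """
    s = scores.scores
    if isinstance(ages, pd.Series):
        ages = ages.reindex(s.index)
        if ages.isna().any():
            raise SchemaError(
                f"missing ages for samples: {sorted(s.index[ages.isna()])}"
            )
    else:
        ages = pd.Series(np.asarray(ages, dtype=float), index=s.index)
    if reference_ids is not None:
        reference_ids = list(reference_ids)
        s = s.loc[reference_ids]
        ages = ages.loc[reference_ids]
    clock = NoiseAgeClock().fit(s.to_numpy(), ages.to_numpy(dtype=float))
    clock.mode_ = scores.mode
    clock.panel_id_ = scores.panel_id
    clock.panel_ = scores.panel
    return clock


def _check_provenance(scores: NoiseScores, clock: NoiseAgeClock) -> None:
    mode = getattr(clock, "mode_", None)
    pid = getattr(clock, "panel_id_", None)
    if mode is not None and mode != scores.mode:
        raise ConfigurationError(
            f"clock was fitted in mode {mode!r} but scores are {scores.mode!r}"
        )
    if pid is not None and pid != scores.panel_id:
        raise ConfigurationError(
            f"clock was fitted on panel {pid} but scores use panel {scores.panel_id}"
        )


def predict_bio_age(
    scores: NoiseScores,
    clock: NoiseAgeClock,
    chronological_ages: pd.Series,
) -> pd.DataFrame:
    """Per-sample biological-age report from scores and a fitted clock.

    Returns a DataFrame indexed by sample id with ``chronological_age``,
    ``biological_age``, ``delta`` (biological - chronological, years),
    ``relative_noise_age`` (biological / chronological) and an
    ``extrapolated`` flag for negative predicted ages.
    """
    _check_provenance(scores, clock)
    bio = clock.predict(scores.scores.to_numpy())
    ages = chronological_ages.reindex(scores.scores.index)
    if ages.isna().any():
        raise SchemaError(
            f"missing chronological ages for: {sorted(scores.scores.index[ages.isna()])}"
        )
    ages = ages.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "chronological_age": ages,
            "biological_age": bio,
            "delta": bio - ages,
            "relative_noise_age": bio / ages,
            "extrapolated": bio < 0,
        },
        index=scores.scores.index,
    )


def tpe_age_shift(
    matrix: AbundanceMatrix,
    panel: NoisePanel | Sequence[str],
    clock: NoiseAgeClock,
    mode: str = "replicate",
    round_pre: int = 0,
    round_post: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject biological-age change between two TPE rounds.

    Scores the pre and post round samples of the TPE cohort, converts them
    to biological ages with the given clock, and returns a per-subject
    table (``bio_age_pre``, ``bio_age_post``, ``shift``) plus a summary
    with the cohort mean shift and a paired two-sided Student's t p-value.
    """
    meta = matrix.meta
    tpe_mask = (meta["cohort"] == "tpe").to_numpy()
    if round_post is None:
        rounds = sorted(meta.loc[tpe_mask, "round"].dropna().unique())
        if len(rounds) < 2:
            raise InsufficientDataError("need >= 2 TPE rounds")
        round_post = int(rounds[-1])
    pre = matrix.subset(matrix.sample_mask(cohort="tpe", round=round_pre))
    post = matrix.subset(matrix.sample_mask(cohort="tpe", round=round_post))
    sub_pre = set(pre.meta["subject_id"])
    sub_post = set(post.meta["subject_id"])
    if sub_pre != sub_post:
        raise SchemaError(
            "unmatched TPE subjects between rounds: "
            f"{sorted(sub_pre.symmetric_difference(sub_post))}"
        )
    rows = []
    for part, label in ((pre, "pre"), (post, "post")):
        s = noise_score(part, panel, mode=mode)
        rep = predict_bio_age(s, clock, part.meta["age"])
        rep = rep.assign(subject_id=part.meta["subject_id"].to_numpy(), when=label)
        rows.append(rep)
    pre_rep = rows[0].set_index("subject_id")
    post_rep = rows[1].set_index("subject_id")
    subjects = sorted(sub_pre)
    table = pd.DataFrame(
        {
            "age": pre_rep.loc[subjects, "chronological_age"],
            "bio_age_pre": pre_rep.loc[subjects, "biological_age"],
            "bio_age_post": post_rep.loc[subjects, "biological_age"],
        }
    )
    table["shift"] = table["bio_age_post"] - table["bio_age_pre"]
    if len(subjects) >= 2 and not np.allclose(table["shift"].var(ddof=1), 0):
        t_stat, p = stats.ttest_rel(table["bio_age_post"], table["bio_age_pre"])
    else:
        t_stat, p = float("nan"), float("nan")
    summary = {
        "n_subjects": len(subjects),
        "round_pre": int(round_pre),
        "round_post": int(round_post),
        "mean_shift": float(table["shift"].mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p),
    }
    return table, summary
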
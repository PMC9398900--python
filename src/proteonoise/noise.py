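"""Differential-variability scan and noise-reporter panel selection.

The central statistic is the mean-based Levene test: a one-way ANOVA on the
absolute deviations of each observation from its group mean.  It is the
small-sample workhorse for detecting variance (noise) shifts between
cohorts; median- and trimmed-mean-centered variants (Brown-Forsythe) are
available behind a flag but are not the default because their power at the
cohort sizes typical of serum panels is poor.

A variance scan applies the two-group test to every analyte across a set of
cohort "transitions" (young to old, pre- to post-exchange, healthy old to
cognitively impaired, young to middle-aged), records SD fold changes and
directions, and controls the per-transition false discovery rate with the
Benjamini-Hochberg step-up procedure.  Noise-reporter analytes are then
selected by intersection rules over those transitions:

* rule A - FDR-significant SD increase with age and an SD decrease with
  plasma exchange;
* rule B - significant SD increase with age and with disease;
* rule C - significant SD increase with age and at least a
  ``sd_fold_min``-fold SD contraction with plasma exchange;
* rule D - the conjunction of B and C (recorded in provenance).

The panel is the union of A, B and C plus any externally nominated
analytes (e.g. a network-node protein chosen on ontology grounds).
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .arrays import AbundanceMatrix, panel_id as _panel_id
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    ValidationError,
)

REQUIRED_TRANSITIONS = ("young_to_old", "pre_to_post_tpe")


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def levene_mean(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Mean-based Levene test of variance homogeneity across k groups.

    With ``Z_ij = |x_ij - mean_i|`` the statistic is

        W = ((N - k) / (k - 1)) * sum_i n_i (Zbar_i - Zbar)^2
                                 / sum_ij (Z_ij - Zbar_i)^2

    referred to the F distribution with (k-1, N-k) degrees of freedom.
    Identical deviations in every group give W = 0, p = 1; zero
    within-group deviation spread with distinct group means of |deviation|
    gives W = inf, p = 0.
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise InsufficientDataError("levene_mean requires at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise InsufficientDataError(
                f"levene_mean group {i} has {g.size} value(s); need >= 2"
            )
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"levene_mean group {i} contains non-finite values")
    k = len(arrs)
    n = np.array([g.size for g in arrs])
    N = int(n.sum())
    z = [np.abs(g - g.mean()) for g in arrs]
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = sum(zi.sum() for zi in z) / N
    ss_between = float((n * (zbar_i - zbar) ** 2).sum())
    ss_within = float(sum(((zi - m) ** 2).sum() for zi, m in zip(z, zbar_i)))
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    w = (N - k) / (k - 1) * ss_between / ss_within
    p = float(stats.f.sf(w, k - 1, N - k))
    return float(w), p


def _levene_mean_two_vectorized(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group mean-based Levene over an analyte family.

    ``a`` and ``b`` are (n_analytes, n_a) and (n_analytes, n_b).
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise InsufficientDataError("each transition side needs >= 2 samples")
    N, k = na + nb, 2
    za = np.abs(a - a.mean(axis=1, keepdims=True))
    zb = np.abs(b - b.mean(axis=1, keepdims=True))
    zbar_a = za.mean(axis=1)
    zbar_b = zb.mean(axis=1)
    zbar = (za.sum(axis=1) + zb.sum(axis=1)) / N
    ss_between = na * (zbar_a - zbar) ** 2 + nb * (zbar_b - zbar) ** 2
    ss_within = ((za - zbar_a[:, None]) ** 2).sum(axis=1) + (
        (zb - zbar_b[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (N - k) / (k - 1) * ss_between / ss_within
    degenerate = ss_within == 0.0
    w = np.where(degenerate & (ss_between == 0.0), 0.0, w)
    w = np.where(degenerate & (ss_between > 0.0), np.inf, w)
    p = np.where(np.isinf(w), 0.0, stats.f.sf(np.where(np.isinf(w), 1.0, w), k - 1, N - k))
    p = np.where(degenerate & (ss_between == 0.0), 1.0, p)
    return w, p


def bh_step_up(p_values: Iterable[float], q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``.

    Sort ascending (stable), find the largest rank k with
    ``p_(k) <= k q / m`` and reject hypotheses of rank 1..k.  Flags are
    returned in the original input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"q must be in [0, 1], got {q}")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ok = ps <= q * np.arange(1, m + 1) / m
    flags_sorted = np.zeros(m, dtype=bool)
    if ok.any():
        kmax = int(np.nonzero(ok)[0][-1])
        flags_sorted[: kmax + 1] = True
    flags = np.zeros(m, dtype=bool)
    flags[order] = flags_sorted
    return flags


# ---------------------------------------------------------------------------
# Transitions and the variance table
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TransitionSpec:
    """A named pair of disjoint sample selectors.

    ``group_a``/``group_b`` map metadata columns (``cohort``, ``round``,
    ``subject_id``) to a required value or collection of values.
    """

    name: str
    group_a: Mapping[str, object]
    group_b: Mapping[str, object]

    @staticmethod
    def _mask(meta: pd.DataFrame, sel: Mapping[str, object]) -> np.ndarray:
        mask = np.ones(len(meta), dtype=bool)
        for col, crit in sel.items():
            if col not in meta.columns:
                raise ValidationError(f"unknown metadata column {col!r}")
            if isinstance(crit, (str, int, np.integer, float)):
                hit = meta[col] == crit
            else:
                hit = meta[col].isin(list(crit))
            mask &= np.asarray(hit.fillna(False), dtype=bool)
        return mask

    def masks(self, meta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        ma = self._mask(meta, self.group_a)
        mb = self._mask(meta, self.group_b)
        if np.any(ma & mb):
            raise ValidationError(f"transition {self.name}: overlapping groups")
        for label, m in (("a", ma), ("b", mb)):
            if m.sum() < 2:
                raise InsufficientDataError(
                    f"transition {self.name}: group_{label} selects "
                    f"{int(m.sum())} sample(s); need >= 2"
                )
        return ma, mb


def default_transitions(meta: pd.DataFrame) -> list[TransitionSpec]:
    """Build the standard transitions available in a metadata table.

    Pre/post plasma exchange compares round 0 against the last round.
    """
    cohorts = set(meta["cohort"])
    out = []
    if {"young", "old"} <= cohorts:
        out.append(
            TransitionSpec("young_to_old", {"cohort": "young"}, {"cohort": "old"})
        )
    if "tpe" in cohorts:
        rounds = sorted(meta.loc[meta["cohort"] == "tpe", "round"].dropna().unique())
        if len(rounds) >= 2:
            out.append(
                TransitionSpec(
                    "pre_to_post_tpe",
                    {"cohort": "tpe", "round": int(rounds[0])},
                    {"cohort": "tpe", "round": int(rounds[-1])},
                )
            )
    if {"old", "disease"} <= cohorts:
        out.append(
            TransitionSpec("old_to_disease", {"cohort": "old"}, {"cohort": "disease"})
        )
    if {"young", "middle"} <= cohorts:
        out.append(
            TransitionSpec("young_to_middle", {"cohort": "young"}, {"cohort": "middle"})
        )
    return out


def variance_scan(
    matrix: AbundanceMatrix,
    transitions: Sequence[TransitionSpec] | None = None,
    q: float = 0.10,
    center: str = "mean",
    proportiontocut: float = 0.1,
) -> pd.DataFrame:
    """Per-analyte SD shifts and Levene tests across cohort transitions.

    Returns a long DataFrame with one row per analyte x transition:
    ``analyte_id, transition, sd_a, sd_b, sd_fold, direction, levene_w,
    p_value, bh_reject``.  SDs use the n-1 denominator; BH flags are
    computed per transition across the whole analyte family.  ``center``
    may be ``"mean"`` (default, vectorized) or ``"median"``/``"trimmed"``
    for the Brown-Forsythe variants.
    """
    if transitions is None:
        transitions = default_transitions(matrix.meta)
    if not transitions:
        raise ConfigurationError("no transitions to scan")
    X = matrix.values.to_numpy(dtype=float)
    analytes = list(matrix.analyte_ids)
    frames = []
    for t in transitions:
        ma, mb = t.masks(matrix.meta)
        a, b = X[:, ma], X[:, mb]
        sd_a = a.std(axis=1, ddof=1)
        sd_b = b.std(axis=1, ddof=1)
        if center == "mean":
            w, p = _levene_mean_two_vectorized(a, b)
        elif center in ("median", "trimmed"):
            w = np.empty(len(analytes))
            p = np.empty(len(analytes))
            for i in range(len(analytes)):
                w[i], p[i] = stats.levene(
                    a[i], b[i], center=center, proportiontocut=proportiontocut
                )
            # scipy emits NaN when every deviation is zero; map to the
            # no-evidence convention used throughout this module.
            bad = ~np.isfinite(p)
            w[bad] = 0.0
            p[bad] = 1.0
        else:
            raise ValidationError(f"unknown center {center!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            sd_fold = np.where(
                sd_a > 0, sd_b / sd_a, np.where(sd_b > 0, np.inf, np.nan)
            )
        direction = np.where(sd_b > sd_a, "up", np.where(sd_b < sd_a, "down", "flat"))
        frames.append(
            pd.DataFrame(
                {
                    "analyte_id": analytes,
                    "transition": t.name,
                    "n_a": int(ma.sum()),
                    "n_b": int(mb.sum()),
                    "sd_a": sd_a,
                    "sd_b": sd_b,
                    "sd_fold": sd_fold,
                    "direction": direction,
                    "levene_w": w,
                    "p_value": p,
                    "bh_reject": bh_step_up(p, q),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NoisePanel:
    """A selected noise-reporter analyte set with per-analyte provenance.

    ``provenance`` maps each member to the subset of rules that admitted
    it ("A", "B", "C", "D") or "external" for injected analytes.
    """

    analytes: tuple[str, ...]
    provenance: dict[str, tuple[str, ...]]
    external_additions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.analytes)) != len(self.analytes):
            raise ValidationError("panel analyte ids must be unique")
        for a in self.analytes:
            if not self.provenance.get(a):
                raise ValidationError(f"panel analyte {a} carries no rule tag")

    @property
    def panel_id(self) -> str:
        return _panel_id(self.analytes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "analytes": list(self.analytes),
                    "provenance": {k: list(v) for k, v in self.provenance.items()},
                    "external_additions": list(self.external_additions),
                    "panel_id": self.panel_id,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NoisePanel":
        payload = json.loads(Path(path).read_text())
        return cls(
            analytes=tuple(payload["analytes"]),
            provenance={k: tuple(v) for k, v in payload["provenance"].items()},
            external_additions=tuple(payload.get("external_additions", ())),
        )


def select_noise_panel(
    table: pd.DataFrame,
    sd_fold_min: float = 5.0,
    external_additions: Sequence[str] = (),
    alpha: float = 0.05,
    rule_a_significance: str = "bh",
    rule_b_significance: str = "raw",
    rule_c_significance: str = "raw",
) -> NoisePanel:
    """Apply the intersection rules to a variance table.

    Rule A uses the FDR flag on the aging transition by default; rules B
    and C use the raw Levene p at ``alpha`` (each rule's significance mode
    is configurable as ``"bh"`` or ``"raw"``).  The fivefold filter of
    rule C is applied to the SD ratio in the direction of change, which
    with plasma exchange is a decrease: ``sd(pre) / sd(post) >= sd_fold_min``.
    """

    def per_transition(name: str) -> pd.DataFrame | None:
        sub = table[table["transition"] == name]
        return None if sub.empty else sub.set_index("analyte_id")

    for required in REQUIRED_TRANSITIONS:
        if per_transition(required) is None:
            raise ConfigurationError(
                f"variance table is missing the required transition {required!r}"
            )
    y2o = per_transition("young_to_old")
    tpe = per_transition("pre_to_post_tpe")
    o2d = per_transition("old_to_disease")
    analyte_order = list(dict.fromkeys(table["analyte_id"]))

    def significant(sub: pd.DataFrame, mode: str) -> pd.Series:
        if mode == "bh":
            return sub["bh_reject"].astype(bool)
        if mode == "raw":
            return sub["p_value"] < alpha
        raise ValidationError(f"unknown significance mode {mode!r}")

    aging_up = y2o["direction"] == "up"
    tpe_down = tpe["direction"] == "down"
    with np.errstate(divide="ignore", invalid="ignore"):
        tpe_contraction = tpe["sd_a"] / tpe["sd_b"]
    tpe_big_drop = tpe_down & (tpe_contraction >= sd_fold_min)

    rule_a = significant(y2o, rule_a_significance) & aging_up & tpe_down
    rule_c = significant(y2o, rule_c_significance) & aging_up & tpe_big_drop
    if o2d is not None:
        rule_b = (
            significant(y2o, rule_b_significance)
            & aging_up
            & significant(o2d, rule_b_significance)
            & (o2d["direction"] == "up")
        )
    else:
        rule_b = pd.Series(False, index=y2o.index)
    rule_d = rule_b & rule_c

    provenance: dict[str, tuple[str, ...]] = {}
    for a in analyte_order:
        tags = [
            tag
            for tag, rule in (("A", rule_a), ("B", rule_b), ("C", rule_c), ("D", rule_d))
            if bool(rule.get(a, False))
        ]
        if tags:
            provenance[a] = tuple(tags)
    members = [a for a in analyte_order if a in provenance]

    known = set(analyte_order)
    externals = tuple(dict.fromkeys(external_additions))
    for e in externals:
        if e not in known:
            raise ConfigurationError(
                f"external addition {e!r} is not an analyte of this matrix"
            )
        if e in provenance:
            provenance[e] = provenance[e] + ("external",)
        else:
            provenance[e] = ("external",)
            members.append(e)
    return NoisePanel(
        analytes=tuple(members),
        provenance=provenance,
        external_additions=externals,
    )


class NoisePanelSelector(TransformerMixin, BaseEstimator):
    """Estimator facade: scan variance shifts and select the noise panel.

    ``fit(X, y)`` takes ``X`` with shape (n_samples, n_analytes) (DataFrame
    columns are the analyte ids) and ``y`` a per-sample metadata DataFrame
    with ``cohort`` and ``round`` columns.  After fitting,
    ``variance_table_`` and ``panel_`` are available and ``transform``
    restricts ``X`` to the panel columns.
    """

    def __init__(
        self,
        q: float = 0.10,
        sd_fold_min: float = 5.0,
        alpha: float = 0.05,
        external_additions: Sequence[str] = (),
        transitions: Sequence[TransitionSpec] | None = None,
        center: str = "mean",
        rule_a_significance: str = "bh",
        rule_b_significance: str = "raw",
        rule_c_significance: str = "raw",
    ):
        self.q = q
        self.sd_fold_min = sd_fold_min
        self.alpha = alpha
        self.external_additions = external_additions
        self.transitions = transitions
        self.center = center
        self.rule_a_significance = rule_a_significance
        self.rule_b_significance = rule_b_significance
        self.rule_c_significance = rule_c_significance

    def fit(self, X, y) -> "NoisePanelSelector":
        X = pd.DataFrame(X)
        meta = pd.DataFrame(y)
        if len(X) != len(meta):
            raise ValidationError("X and metadata lengths differ")
        analytes = [str(c) for c in X.columns]
        matrix = AbundanceMatrix(
            values=pd.DataFrame(
                X.to_numpy(dtype=float).T, index=analytes, columns=meta.index
            ),
            meta=meta,
        )
        self.variance_table_ = variance_scan(
            matrix, transitions=self.transitions, q=self.q, center=self.center
        )
        self.panel_ = select_noise_panel(
            self.variance_table_,
            sd_fold_min=self.sd_fold_min,
            external_additions=tuple(self.external_additions),
            alpha=self.alpha,
            rule_a_significance=self.rule_a_significance,
            rule_b_significance=self.rule_b_significance,
            rule_c_significance=self.rule_c_significance,
        )
        self.feature_names_in_ = np.array(analytes, dtype=object)
        self.n_features_in_ = len(analytes)
        self.support_ = np.array(
            [a in set(self.panel_.analytes) for a in analytes], dtype=bool
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]
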
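"""Differential mean-level screen and principal-component rejuvenation trajectory.

The level screen is the classical per-analyte two-sample Student's t test
combined with a two-sided fold-change threshold on the ratio of cohort
means: an analyte is selected when its old/young ratio strictly exceeds
the threshold in either direction and the t-test p-value is below alpha.
No multiple-testing correction is applied at this stage (the screen is a
candidate filter, not an inferential endpoint); the variance scan in
:mod:`proteonoise.noise` is where FDR control lives.

The trajectory summary projects each sample onto the first two principal
components of the analyte-standardized panel submatrix and expresses every
group centroid as signed progress along the old-to-young centroid axis
(0 = at the old centroid, 1 = at the young centroid), which makes the
longitudinal pull of repeated plasma exchange toward the young proteome a
single scalar per round.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .arrays import AbundanceMatrix
from .errors import InsufficientDataError, ValidationError


class DifferentialLevelSelector(TransformerMixin, BaseEstimator):
    """Select analytes whose mean level differs between two cohorts.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_analytes) and ``y``
    cohort labels; analytes with ``fold > fold_threshold`` or
    ``fold < 1/fold_threshold`` (strict) and ``p < alpha`` are selected.
    The fold change is the ratio of group-b to group-a means with a
    symmetric floor so the label-swap symmetry ``fold -> 1/fold`` is exact.

    Attributes
    ----------
    results_ : DataFrame sorted by ascending p with columns
        ``analyte_id, mean_a, mean_b, fold_change, p_value, selected,
        degenerate``.
    support_ : boolean mask over the input analyte order.
    """

    def __init__(
        self,
        fold_threshold: float = 1.75,
        alpha: float = 0.05,
        group_a: str = "young",
        group_b: str = "old",
        equal_var: bool = True,
        mean_floor: float = 1e-12,
    ):
        self.fold_threshold = fold_threshold
        self.alpha = alpha
        self.group_a = group_a
        self.group_b = group_b
        self.equal_var = equal_var
        self.mean_floor = mean_floor

    def fit(self, X, y) -> "DifferentialLevelSelector":
        if self.fold_threshold < 1:
            raise ValidationError("fold_threshold must be >= 1")
        X = pd.DataFrame(X)
        labels = np.asarray(y, dtype=object)
        if len(labels) != len(X):
            raise ValidationError("X and y lengths differ")
        ma = labels == self.group_a
        mb = labels == self.group_b
        if ma.sum() < 2 or mb.sum() < 2:
            raise InsufficientDataError(
                f"need >= 2 samples in each of {self.group_a!r} "
                f"({int(ma.sum())}) and {self.group_b!r} ({int(mb.sum())})"
            )
        a = X.loc[ma].to_numpy(dtype=float)
        b = X.loc[mb].to_numpy(dtype=float)
        mean_a = a.mean(axis=0)
        mean_b = b.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(b, a, axis=0, equal_var=self.equal_var)
            p = np.asarray(res.pvalue, dtype=float)
        # zero variance in both groups: p := 1 if the means agree, else 0,
        # and the analyte is flagged degenerate.
        var_a = a.var(axis=0)
        var_b = b.var(axis=0)
        degenerate = (var_a == 0) & (var_b == 0)
        p = np.where(degenerate, np.where(mean_a == mean_b, 1.0, 0.0), p)
        floor = self.mean_floor
        fold = np.maximum(mean_b, floor) / np.maximum(mean_a, floor)
        thr = self.fold_threshold
        selected = ((fold > thr) | (fold < 1.0 / thr)) & (p < self.alpha)
        analytes = [str(c) for c in X.columns]
        self.feature_names_in_ = np.array(analytes, dtype=object)
        self.n_features_in_ = len(analytes)
        self.support_ = selected
        self.results_ = (
            pd.DataFrame(
                {
                    "analyte_id": analytes,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "fold_change": fold,
                    "p_value": p,
                    "selected": selected,
                    "degenerate": degenerate,
                }
            )
            .sort_values(["p_value", "analyte_id"], kind="stable")
            .reset_index(drop=True)
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        return pd.DataFrame(X).loc[:, self.support_]


def select_differential(
    matrix: AbundanceMatrix,
    fold_threshold: float = 1.75,
    alpha: float = 0.05,
    group_a: str = "young",
    group_b: str = "old",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-analyte young-vs-old level screen on an abundance matrix.

    Thin wrapper over :class:`DifferentialLevelSelector`; returns its
    ``results_`` table (sorted by ascending p-value).
    """
    sel = DifferentialLevelSelector(
        fold_threshold=fold_threshold,
        alpha=alpha,
        group_a=group_a,
        group_b=group_b,
        equal_var=equal_var,
    )
    sel.fit(matrix.values.T, matrix.meta["cohort"].to_numpy())
    return sel.results_


@dataclasses.dataclass
class TrajectorySummary:
    """Group centroids in PC1/2 and per-group progress along old -> young.

    ``displacements`` maps group labels ("young", "old", "R0", "R1", ...)
    to the scalar projection of (centroid - old centroid) onto the
    old-to-young axis divided by the squared axis length, so that the old
    centroid sits at 0 and the young centroid at 1 by construction.
    """

    centroids: pd.DataFrame
    displacements: pd.Series
    explained_variance_ratio: tuple[float, float]


def pca_trajectory(
    matrix: AbundanceMatrix, panel: Sequence[str]
) -> TrajectorySummary:
    """Summarize longitudinal movement of TPE rounds in PCA space.

    The panel submatrix is z-scored per analyte across all included
    samples, projected onto its first two principal components, and each
    group (young, old, middle/disease if present, and every TPE round) is
    reduced to its centroid and its progress along the old-to-young axis.
    """
    panel = list(dict.fromkeys(panel))
    if not panel:
        raise ValidationError("panel is empty")
    missing = sorted(set(panel) - set(matrix.analyte_ids))
    if missing:
        raise ValidationError(f"panel analytes missing from matrix: {missing}")
    meta = matrix.meta
    for anchor in ("young", "old"):
        if int((meta["cohort"] == anchor).sum()) < 3:
            raise InsufficientDataError(
                f"need >= 3 {anchor} samples to anchor the trajectory"
            )
    sub = matrix.values.loc[panel].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(sub - mu, sd, out=np.zeros_like(sub), where=sd > 0)
    rank = np.linalg.matrix_rank(z - z.mean(axis=1, keepdims=True))
    if rank < 2:
        raise ValidationError(
            f"panel submatrix is degenerate (rank {rank} < 2); PCA trajectory undefined"
        )
    pca = PCA(n_components=2)
    coords = pca.fit_transform(z.T)  # samples x 2

    groups: dict[str, np.ndarray] = {}
    for cohort in ("young", "middle", "old", "disease"):
        mask = (meta["cohort"] == cohort).to_numpy()
        if mask.any():
            groups[cohort] = coords[mask].mean(axis=0)
    tpe_rounds = sorted(meta.loc[meta["cohort"] == "tpe", "round"].dropna().unique())
    for r in tpe_rounds:
        mask = ((meta["cohort"] == "tpe") & (meta["round"] == r)).to_numpy()
        groups[f"R{int(r)}"] = coords[mask].mean(axis=0)

    axis = groups["young"] - groups["old"]
    axis_sq = float(axis @ axis)
    if axis_sq == 0.0:
        raise ValidationError("young and old centroids coincide; axis undefined")
    displacements = {
        name: float((c - groups["old"]) @ axis / axis_sq) for name, c in groups.items()
    }
    return TrajectorySummary(
        centroids=pd.DataFrame(groups, index=["PC1", "PC2"]).T,
        displacements=pd.Series(displacements, name="progress"),
        explained_variance_ratio=tuple(pca.explained_variance_ratio_[:2]),
    )
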
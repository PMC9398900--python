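"""Antibody-array sample containers, control-based normalization, and matrix assembly.

An array sample carries, for every analyte, the replicate spot intensities
plus the built-in positive and negative control spots.  Normalization is the
standard control-spot dialect for this array family: the mean of the
negative controls is treated as slide background and subtracted from every
spot, and the background-corrected intensities are then rescaled so that the
positive-control mean hits a common reference level.  The result is
comparable across slides up to control-spot measurement noise and is
invariant to a global scanner gain.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateArrayError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

COHORTS = ("young", "middle", "old", "disease", "tpe")
_COHORT_RANK = {c: i for i, c in enumerate(COHORTS)}


def panel_id(analytes: Iterable[str]) -> str:
    """Stable short identifier for a set of analytes (order-insensitive)."""
    joined = ",".join(sorted(analytes))
    return hashlib.sha1(joined.encode()).hexdigest()[:12]


@dataclasses.dataclass
class ArraySample:
    """One subject x timepoint worth of spot intensities.

    Parameters
    ----------
    spots
        Array of shape ``(n_analytes, n_replicates)`` with non-negative,
        finite intensities in arbitrary fluorescence units (analyte spots
        remain non-negative after normalization because background-corrected
        values are clamped at zero; control spots are kept unclamped as
        quality-control diagnostics).
    round
        TPE round index (0 = before the first exchange) or ``None`` for
        cross-sectional cohort samples.
    """

    sample_id: str
    subject_id: str
    cohort: str
    age: float
    analyte_ids: tuple[str, ...]
    spots: np.ndarray
    pos_controls: np.ndarray
    neg_controls: np.ndarray
    round: int | None = None
    sex: str | None = None
    normalized: bool = False
    norm_factor: float | None = None
    background: float | None = None

    def __post_init__(self) -> None:
        self.analyte_ids = tuple(self.analyte_ids)
        self.spots = np.atleast_2d(np.asarray(self.spots, dtype=float))
        self.pos_controls = np.asarray(self.pos_controls, dtype=float).ravel()
        self.neg_controls = np.asarray(self.neg_controls, dtype=float).ravel()
        self.validate()

    def validate(self) -> None:
        n, r = self.spots.shape
        if n != len(self.analyte_ids):
            raise ValidationError(
                f"sample {self.sample_id}: {n} spot rows for "
                f"{len(self.analyte_ids)} analyte ids"
            )
        if r < 1:
            raise ValidationError(f"sample {self.sample_id}: no replicate spots")
        if not np.all(np.isfinite(self.spots)):
            raise ValidationError(f"sample {self.sample_id}: non-finite spot intensity")
        if np.any(self.spots < 0):
            raise ValidationError(f"sample {self.sample_id}: negative spot intensity")
        if self.pos_controls.size == 0 or self.neg_controls.size == 0:
            raise ValidationError(f"sample {self.sample_id}: empty control spots")
        if not (
            np.all(np.isfinite(self.pos_controls))
            and np.all(np.isfinite(self.neg_controls))
        ):
            raise ValidationError(f"sample {self.sample_id}: non-finite control spot")
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown cohort {self.cohort!r}"
            )

    @property
    def n_replicates(self) -> int:
        return self.spots.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Per-analyte abundance: mean over replicate spots."""
        return self.spots.mean(axis=1)


def normalize_sample(raw: ArraySample, reference_pos_level: float) -> ArraySample:
    """Background-subtract and positive-control rescale one sample.

    The negative-control mean ``b`` is subtracted from every spot; analyte
    spots are clamped at zero; everything is then scaled by
    ``reference_pos_level / (mean(pos_controls) - b)`` so that the normalized
    positive-control mean equals ``reference_pos_level`` exactly.

    Raises
    ------
    DegenerateArrayError
        If the positive-control mean does not exceed the negative-control
        mean: the slide is uninterpretable and must be excluded rather than
        silently normalized.
    """
    if not reference_pos_level > 0:
        raise ValidationError("reference_pos_level must be > 0")
    b = float(raw.neg_controls.mean())
    pos_net = float(raw.pos_controls.mean()) - b
    if pos_net <= 0:
        raise DegenerateArrayError(
            f"sample {raw.sample_id}: positive-control mean "
            f"({raw.pos_controls.mean():.4g}) does not exceed negative-control "
            f"mean ({b:.4g}); sample excluded"
        )
    f = reference_pos_level / pos_net
    return dataclasses.replace(
        raw,
        spots=np.clip(raw.spots - b, 0.0, None) * f,
        pos_controls=(raw.pos_controls - b) * f,
        neg_controls=(raw.neg_controls - b) * f,
        normalized=True,
        norm_factor=f,
        background=b,
    )


class ControlNormalizer(TransformerMixin, BaseEstimator):
    """Batch normalizer using built-in positive/negative control spots.

    ``fit`` learns the reference positive-control level (by default the
    median across the batch of per-sample background-corrected
    positive-control means); ``transform`` normalizes every sample to that
    reference.  Samples whose positive controls do not rise above background
    are excluded (``on_degenerate="drop"``, recorded in ``excluded_ids_``)
    or raise (``on_degenerate="raise"``).
    """

    def __init__(
        self,
        reference_pos_level: float | None = None,
        on_degenerate: str = "drop",
    ):
        self.reference_pos_level = reference_pos_level
        self.on_degenerate = on_degenerate

    def fit(self, X: Iterable[ArraySample], y=None) -> "ControlNormalizer":
        samples = list(X)
        if not samples:
            raise InsufficientDataError("no samples to fit the normalizer on")
        nets = [
            float(s.pos_controls.mean()) - float(s.neg_controls.mean())
            for s in samples
        ]
        usable = [v for v in nets if v > 0]
        if not usable:
            raise DegenerateArrayError("every sample in the batch is degenerate")
        if self.reference_pos_level is not None:
            ref = float(self.reference_pos_level)
            if not ref > 0:
                raise ValidationError("reference_pos_level must be > 0")
        else:
            ref = float(np.median(usable))
        self.reference_pos_level_ = ref
        self.n_samples_fit_ = len(samples)
        return self

    def transform(self, X: Iterable[ArraySample]) -> list[ArraySample]:
        if self.on_degenerate not in ("drop", "raise"):
            raise ValidationError("on_degenerate must be 'drop' or 'raise'")
        out: list[ArraySample] = []
        excluded: list[str] = []
        for s in X:
            try:
                out.append(normalize_sample(s, self.reference_pos_level_))
            except DegenerateArrayError:
                if self.on_degenerate == "raise":
                    raise
                excluded.append(s.sample_id)
        self.excluded_ids_ = tuple(excluded)
        return out


@dataclasses.dataclass
class AbundanceMatrix:
    """Normalized analyte x sample matrix with per-sample annotations.

    ``values`` is a DataFrame (rows = analytes, columns = sample ids);
    ``meta`` is indexed by sample id with columns ``subject_id``, ``cohort``,
    ``round``, ``age``, ``sex``, ``norm_factor``, ``background``;
    ``replicates`` optionally retains the normalized replicate intensities
    as an ``(n_analytes, n_samples, n_replicates)`` tensor, in which case
    ``values`` equals its mean over the replicate axis.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    replicates: np.ndarray | None = None

    @property
    def analyte_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def sample_mask(
        self,
        cohort: str | Sequence[str] | None = None,
        round: int | Sequence[int] | None = None,
        subject_id: str | Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over samples matching all given criteria."""
        mask = np.ones(len(self.meta), dtype=bool)
        for col, crit in (
            ("cohort", cohort),
            ("round", round),
            ("subject_id", subject_id),
        ):
            if crit is None:
                continue
            if isinstance(crit, (str, int, np.integer)):
                hit = self.meta[col] == crit
            else:
                hit = self.meta[col].isin(list(crit))
            mask &= np.asarray(hit.fillna(False), dtype=bool)
        return mask

    def subset(self, mask: np.ndarray) -> "AbundanceMatrix":
        mask = np.asarray(mask, dtype=bool)
        reps = self.replicates[:, mask, :] if self.replicates is not None else None
        return AbundanceMatrix(
            values=self.values.loc[:, mask],
            meta=self.meta.loc[mask],
            replicates=reps,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.rename_axis("analyte_id").to_csv(outdir / "abundance.tsv", sep="\t")
        self.meta.rename_axis("sample_id").to_csv(outdir / "samples.tsv", sep="\t")
        if self.replicates is not None:
            n_rep = self.replicates.shape[2]
            cols = {}
            for j, sid in enumerate(self.sample_ids):
                for r in range(n_rep):
                    cols[f"{sid}__rep{r + 1}"] = self.replicates[:, j, r]
            pd.DataFrame(cols, index=list(self.analyte_ids)).rename_axis(
                "analyte_id"
            ).to_csv(outdir / "replicates.tsv", sep="\t")

    @classmethod
    def read(cls, indir: str | Path) -> "AbundanceMatrix":
        indir = Path(indir)
        values = pd.read_csv(indir / "abundance.tsv", sep="\t", index_col=0)
        meta = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        values.columns = values.columns.astype(str)
        if "round" in meta:
            meta["round"] = meta["round"].astype("Int64")
        reps = None
        rep_path = indir / "replicates.tsv"
        if rep_path.exists():
            wide = pd.read_csv(rep_path, sep="\t", index_col=0)
            n_rep = len({c.rsplit("__rep", 1)[1] for c in wide.columns})
            reps = np.empty((values.shape[0], values.shape[1], n_rep))
            for j, sid in enumerate(values.columns):
                for r in range(n_rep):
                    reps[:, j, r] = wide[f"{sid}__rep{r + 1}"].to_numpy()
        return cls(values=values, meta=meta, replicates=reps)


def _sample_sort_key(s: ArraySample):
    rnd = -1 if s.round is None else int(s.round)
    return (_COHORT_RANK.get(s.cohort, len(COHORTS)), s.subject_id, rnd, s.sample_id)


def assemble_matrix(samples: Iterable[ArraySample]) -> AbundanceMatrix:
    """Assemble normalized samples into an :class:`AbundanceMatrix`.

    All samples must carry the same analyte id set (any row order); rows are
    emitted in sorted analyte-id order and columns in deterministic
    (cohort, subject, round) order.  The replicate tensor is retained when
    every sample has the same replicate count.
    """
    samples = sorted(samples, key=_sample_sort_key)
    if not samples:
        raise InsufficientDataError("no samples to assemble")
    ref_set = set(samples[0].analyte_ids)
    for s in samples[1:]:
        if set(s.analyte_ids) != ref_set:
            diff = sorted(ref_set.symmetric_difference(s.analyte_ids))
            raise SchemaError(
                f"sample {s.sample_id} analyte list differs from "
                f"{samples[0].sample_id}; symmetric difference: {diff}"
            )
    order = sorted(ref_set)
    rep_counts = {s.n_replicates for s in samples}
    keep_reps = len(rep_counts) == 1
    n_rep = rep_counts.pop() if keep_reps else 0

    spot_stacks = []
    for s in samples:
        idx = [s.analyte_ids.index(a) for a in order] if list(s.analyte_ids) != order else None
        spot_stacks.append(s.spots[idx] if idx is not None else s.spots)

    values = pd.DataFrame(
        np.column_stack([sp.mean(axis=1) for sp in spot_stacks]),
        index=order,
        columns=[s.sample_id for s in samples],
    )
    replicates = None
    if keep_reps and n_rep >= 1:
        replicates = np.stack(spot_stacks, axis=1)  # (analyte, sample, replicate)
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "cohort": [s.cohort for s in samples],
            "round": pd.array([s.round for s in samples], dtype="Int64"),
            "age": [s.age for s in samples],
            "sex": [s.sex for s in samples],
            "norm_factor": [s.norm_factor for s in samples],
            "background": [s.background for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )
    return AbundanceMatrix(values=values, meta=meta, replicates=replicates)


# ---------------------------------------------------------------------------
# Spot-table dialect (shared with the simulator's writers)
# ---------------------------------------------------------------------------

def write_spot_tables(
    samples: Sequence[ArraySample], outdir: str | Path
) -> tuple[Path, Path]:
    """Write samples as ``spots.tsv`` + ``meta.tsv``.

    The spot table has one row per (spot, replicate): columns ``spot_id``,
    ``spot_type`` (analyte | pos_ctrl | neg_ctrl), ``analyte_id``,
    ``replicate``, then one intensity column per sample id.
    """
    samples = list(samples)
    if not samples:
        raise InsufficientDataError("no samples to write")
    first = samples[0]
    for s in samples[1:]:
        if (
            s.analyte_ids != first.analyte_ids
            or s.n_replicates != first.n_replicates
            or s.pos_controls.size != first.pos_controls.size
            or s.neg_controls.size != first.neg_controls.size
        ):
            raise SchemaError(
                f"sample {s.sample_id} layout differs from {first.sample_id}; "
                "spot tables require a homogeneous slide layout"
            )
    rows_id, rows_type, rows_analyte, rows_rep = [], [], [], []
    for a in first.analyte_ids:
        for r in range(first.n_replicates):
            rows_id.append(f"{a}.{r + 1}")
            rows_type.append("analyte")
            rows_analyte.append(a)
            rows_rep.append(r + 1)
    for i in range(first.pos_controls.size):
        rows_id.append(f"POS.{i + 1}")
        rows_type.append("pos_ctrl")
        rows_analyte.append("")
        rows_rep.append(1)
    for i in range(first.neg_controls.size):
        rows_id.append(f"NEG.{i + 1}")
        rows_type.append("neg_ctrl")
        rows_analyte.append("")
        rows_rep.append(1)
    table = pd.DataFrame(
        {
            "spot_id": rows_id,
            "spot_type": rows_type,
            "analyte_id": rows_analyte,
            "replicate": rows_rep,
        }
    )
    for s in samples:
        table[s.sample_id] = np.concatenate(
            [s.spots.ravel(order="C"), s.pos_controls, s.neg_controls]
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spots_path = outdir / "spots.tsv"
    meta_path = outdir / "meta.tsv"
    table.to_csv(spots_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "subject_id": [s.subject_id for s in samples],
            "cohort": [s.cohort for s in samples],
            "round": ["" if s.round is None else s.round for s in samples],
            "age": [s.age for s in samples],
            "sex": ["" if s.sex is None else s.sex for s in samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)
    return spots_path, meta_path


def read_spot_tables(
    spots_path: str | Path, meta_path: str | Path
) -> list[ArraySample]:
    """Read the ``spots.tsv`` + ``meta.tsv`` dialect back into samples."""
    table = pd.read_csv(spots_path, sep="\t")
    meta = pd.read_csv(
        meta_path, sep="\t", dtype={"sample_id": str, "subject_id": str}
    )
    analyte_rows = table[table["spot_type"] == "analyte"]
    analyte_ids = tuple(dict.fromkeys(analyte_rows["analyte_id"]))
    n_rep = int(analyte_rows["replicate"].max())
    pos_rows = table[table["spot_type"] == "pos_ctrl"]
    neg_rows = table[table["spot_type"] == "neg_ctrl"]
    samples = []
    for rec in meta.to_dict("records"):
        sid = str(rec["sample_id"])
        if sid not in table.columns:
            raise SchemaError(f"sample {sid} present in metadata but not in spot table")
        col = analyte_rows[sid].to_numpy()
        spots = col.reshape(len(analyte_ids), n_rep)
        rnd = rec.get("round")
        rnd = None if pd.isna(rnd) or rnd == "" else int(rnd)
        sex = rec.get("sex")
        sex = None if (sex is None or pd.isna(sex) or sex == "") else str(sex)
        samples.append(
            ArraySample(
                sample_id=sid,
                subject_id=str(rec["subject_id"]),
                cohort=str(rec["cohort"]),
                age=float(rec["age"]),
                round=rnd,
                sex=sex,
                analyte_ids=analyte_ids,
                spots=spots,
                pos_controls=pos_rows[sid].to_numpy(),
                neg_controls=neg_rows[sid].to_numpy(),
            )
        )
    return samples


def read_flat_matrix(
    values_path: str | Path, meta_path: str | Path
) -> AbundanceMatrix:
    """Read a pre-normalized 'one row per analyte' TSV plus metadata TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    missing = sorted(set(values.columns).symmetric_difference(meta.index))
    if missing:
        raise SchemaError(f"matrix/metadata sample mismatch: {missing}")
    meta = meta.loc[list(values.columns)]
    if "round" in meta:
        meta["round"] = pd.array(
            [None if pd.isna(v) else int(v) for v in meta["round"]], dtype="Int64"
        )
    return AbundanceMatrix(values=values, meta=meta, replicates=None)
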
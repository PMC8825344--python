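"""Expression-matrix containers, normalization, filtering, smoothing and QC.

The downstream analysis operates on a gene x sample FPKM matrix together
with per-sample metadata carrying a signed day offset from the flowering
day (negative = before bloom, 0 = bloom, positive = after). This module
holds those two containers plus the preprocessing steps applied before
module detection: FPKM normalization of raw fragment counts, the
variance >= 1 gene filter, the sliding-window smoother used for all
profile plots and peak calls, and correlation-based outlier-sample
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "VarianceFilterReport",
    "OutlierReport",
    "compute_fpkm",
    "variance_filter",
    "moving_average_profile",
    "detect_outlier_samples",
]

DAY_OFFSET_RANGE = (-60, 30)


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows, samples in columns, nonnegative reals.
    unit : {"counts", "FPKM"}
        Scale of ``values``. ``gene_lengths`` (bp) is required for counts.
    gene_lengths : pandas.Series, optional
        Transcript length in base pairs, indexed by gene id.
    """

    values: pd.DataFrame
    unit: str = "FPKM"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "FPKM"):
            raise ValueError(f"unit must be 'counts' or 'FPKM', got {self.unit!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be nonnegative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.loc[list(gene_ids)]
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.unit, lengths)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.unit, self.gene_lengths)


@dataclass
class SampleMetadata:
    """Per-sample annotations: tree, site, year, date and day offset.

    ``day_offset`` is the signed number of days from the flowering day
    (day 0), negative before bloom. The collection date is informational;
    day_offset is authoritative.
    """

    table: pd.DataFrame
    day_offset_range: tuple[int, int] = DAY_OFFSET_RANGE

    REQUIRED = ("sample_id", "tree_id", "site", "year", "day_offset")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id in metadata: {dups.tolist()[:5]}")
        lo, hi = self.day_offset_range
        off = self.table["day_offset"]
        bad = self.table.loc[(off < lo) | (off > hi), "sample_id"]
        if len(bad):
            raise ValueError(
                f"day_offset outside [{lo}, {hi}] for samples: {bad.tolist()[:5]}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def day_offsets(self, sample_ids: Sequence[str]) -> np.ndarray:
        s = self.table.set_index("sample_id")["day_offset"]
        missing = [x for x in sample_ids if x not in s.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        return s.loc[list(sample_ids)].to_numpy(dtype=float)

    def replicate_keys(self, sample_ids: Sequence[str]) -> list[tuple]:
        """(tree_id, site, year) replicate series key for each sample."""
        t = self.table.set_index("sample_id")
        return [
            (t.at[s, "tree_id"], t.at[s, "site"], t.at[s, "year"]) for s in sample_ids
        ]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleMetadata(keep.copy(), self.day_offset_range)


@dataclass
class VarianceFilterReport:
    n_input: int
    n_retained: int

    @property
    def fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass
class OutlierReport:
    flagged: list[str]
    unusable: list[str] = field(default_factory=list)
    mean_distance: pd.Series | None = None
    linkage: np.ndarray | None = None


def compute_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM(g, s) = count(g, s) * 1e9 / (length(g) * total_count(s)).
    """
    if matrix.unit != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    if matrix.gene_lengths is None:
        raise ValueError("gene_lengths are required to compute FPKM")
    lengths = matrix.gene_lengths
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths for: {bad[:5]}")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero library size in sample(s): {zero}")
    fpkm = matrix.values.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(fpkm, unit="FPKM", gene_lengths=lengths)


def variance_filter(
    matrix: ExpressionMatrix,
    threshold: float = 1.0,
    log_scale: bool = False,
) -> tuple[ExpressionMatrix, VarianceFilterReport]:
    """Retain genes whose across-sample variance is >= ``threshold``.

    Variance uses the n-1 denominator on the expression scale as stored
    (FPKM by default); ``log_scale`` computes it on log1p values instead.
    """
    if matrix.n_samples < 2:
        raise ValueError("variance_filter requires at least 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    if log_scale:
        vals = np.log1p(vals)
    var = vals.var(axis=1, ddof=1)
    keep = var >= threshold
    kept = matrix.subset_genes(matrix.values.index[keep])
    report = VarianceFilterReport(n_input=matrix.n_genes, n_retained=int(keep.sum()))
    return kept, report


def moving_average_profile(
    values: Sequence[float] | np.ndarray | pd.Series,
    day_offsets: Sequence[float] | np.ndarray,
    window: int = 8,
    step: int = 4,
) -> list[tuple[float, float]]:
    """Sliding-window smoother over samples ordered by day offset.

    Samples are sorted by ``day_offsets`` (stable for ties); windows of
    ``window`` consecutive samples advance by ``step`` samples, each
    emitting (mean day offset, mean value). If fewer than ``window``
    samples exist, a single window covers them all; a trailing partial
    window is emitted when at least window/2 samples remain uncovered
    past the last full window.
    """
    vals = np.asarray(values, dtype=float)
    days = np.asarray(day_offsets, dtype=float)
    if vals.size == 0:
        raise ValueError("moving_average_profile requires nonempty input")
    if vals.shape != days.shape:
        raise ValueError("values and day_offsets must have equal length")
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    order = np.argsort(days, kind="stable")
    vals, days = vals[order], days[order]
    n = vals.size
    spans: list[tuple[int, int]] = []
    if n <= window:
        spans.append((0, n))
    else:
        start = 0
        while start + window <= n:
            spans.append((start, start + window))
            start += step
        covered = spans[-1][1]
        if n - covered >= window / 2:
            spans.append((covered, n))
    return [(float(days[a:b].mean()), float(vals[a:b].mean())) for a, b in spans]


def detect_outlier_samples(
    matrix: ExpressionMatrix,
    z_cut: float = 3.0,
) -> OutlierReport:
    """Flag samples far from the rest in 1 - Pearson correlation space.

    Samples are clustered (average linkage) on 1 - r of log1p expression;
    a sample is flagged when its mean distance to all other samples
    exceeds mean + z_cut * sd of that statistic. Samples with zero
    expression variance (correlation undefined) are reported unusable.
    """
    if matrix.n_samples < 4:
        raise ValueError("detect_outlier_samples requires at least 4 samples")
    logx = np.log1p(matrix.values.to_numpy(dtype=float))
    sds = logx.std(axis=0)
    usable = sds > 1e-12  # tolerate float noise in truly constant samples
    unusable = [s for s, ok in zip(matrix.sample_ids, usable) if not ok]
    ids = [s for s, ok in zip(matrix.sample_ids, usable) if ok]
    sub = logx[:, usable]
    if sub.shape[1] < 4:
        raise ValueError(
            f"fewer than 4 usable samples after excluding zero-variance: {unusable}"
        )
    corr = np.corrcoef(sub, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    m = dist.shape[0]
    mean_dist = dist.sum(axis=1) / (m - 1)
    mu, sd = mean_dist.mean(), mean_dist.std(ddof=1)
    if sd == 0 or not np.isfinite(z_cut):
        flagged_mask = np.zeros(m, dtype=bool)
    else:
        flagged_mask = mean_dist > mu + z_cut * sd
    flagged = [s for s, f in zip(ids, flagged_mask) if f]
    return OutlierReport(
        flagged=flagged,
        unusable=unusable,
        mean_distance=pd.Series(mean_dist, index=ids),
        linkage=link,
    )
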
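"""Co-expression module detection, eigengenes and stage assignment.

Implements a deterministic weighted-correlation-network workflow: an
unsigned adjacency |r|^power on log1p expression, topological overlap
dissimilarity, average-linkage hierarchical clustering with a fixed
height cut refined by small-cluster merging, eigengene-correlation
module merging, and finally assignment of each module to a flowering
stage bin (or to the constitutive / replicate-variable classes) from the
smoothed peak day of its eigengene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, SampleMetadata, moving_average_profile

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModule",
    "ModulePartition",
    "STAGE_BINS",
    "pick_soft_power",
    "detect_modules",
    "module_eigengene",
    "assign_stage",
    "assign_stages",
    "group_eigengenes",
]

#: WGCNA-style color names, assigned to modules by descending size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
]

#: Half-open / closed day-offset windows translating the week-based stage
#: labels into day ranges around bloom (day 0).
STAGE_BINS: list[tuple[float, float, bool, str]] = [
    (-35.0, -28.0, False, "4-5 WBF"),
    (-28.0, -24.5, False, "4 WBF"),
    (-24.5, -17.5, False, "3 WBF"),
    (-17.5, -10.5, False, "2-3 WBF"),
    (-10.5, -3.5, False, "1-2 WBF"),
    (-3.5, 3.5, True, "flowering"),
    (3.5, 14.0, True, "1-2 WAF"),
]


def stage_bin_for_day(day: float) -> str | None:
    for lo, hi, closed, label in STAGE_BINS:
        if label == "flowering":
            if lo <= day <= hi:
                return label
        elif closed:
            if lo < day <= hi:
                return label
        else:
            if lo <= day < hi:
                return label
    return None


@dataclass
class GeneModule:
    label: str
    gene_ids: list[str]
    eigengene: np.ndarray | None = None
    explained_variance: float | None = None
    stage: str | None = None
    peak_day: float | None = None

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModulePartition:
    modules: list[GeneModule]
    unassigned_gene_ids: list[str]
    parameters: dict = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            overlap = seen & set(m.gene_ids)
            if overlap:
                raise ValueError(f"gene(s) in multiple modules: {sorted(overlap)[:5]}")
            seen |= set(m.gene_ids)
        dup = seen & set(self.unassigned_gene_ids)
        if dup:
            raise ValueError(f"gene(s) both assigned and unassigned: {sorted(dup)[:5]}")

    def module_of(self) -> dict[str, str]:
        out = {}
        for m in self.modules:
            for g in m.gene_ids:
                out[g] = m.label
        return out

    def stage_specific(self) -> list[GeneModule]:
        return [
            m
            for m in self.modules
            if m.stage is not None and m.stage not in ("constitutive", "variable")
        ]


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over binned connectivities."""
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = (counts > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    if np.allclose(x, x[0]):
        return 1.0  # degenerate: all connectivities identical
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    r2 = 1.0 - (resid**2).sum() / ss_tot
    # only a decaying degree distribution counts as scale-free-like
    return float(r2) if slope < 0 else 0.0


def _correlation(matrix: ExpressionMatrix) -> np.ndarray:
    x = np.log1p(matrix.values.to_numpy(dtype=float))
    sd = x.std(axis=1)
    corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def pick_soft_power(
    matrix: ExpressionMatrix,
    powers: list[int] | None = None,
    r2_target: float = 0.8,
) -> int:
    """Smallest soft-threshold power reaching the scale-free fit target.

    Falls back (with a warning) to the power maximizing the fit R^2 when
    no candidate reaches ``r2_target``; when the criterion is entirely
    uninformative (no power gives a decaying degree distribution, as on
    small strongly modular data) the conventional unsigned-network
    default of 6 is used instead.
    """
    if powers is None:
        powers = list(range(1, 21))
    if not powers:
        raise ValueError("empty candidate power list")
    if matrix.n_samples < 8:
        raise ValueError("pick_soft_power requires at least 8 samples")
    corr = np.abs(_correlation(matrix))
    np.fill_diagonal(corr, 0.0)
    best_power, best_r2 = powers[0], -np.inf
    for p in sorted(powers):
        k = (corr**p).sum(axis=1)
        r2 = _scale_free_r2(k)
        if r2 >= r2_target:
            return int(p)
        if r2 > best_r2:
            best_power, best_r2 = p, r2
    if best_r2 < 0.3:  # a fit this poor carries no signal about the power
        fallback = 6 if 6 in powers else sorted(powers)[len(powers) // 2]
        logger.warning(
            "scale-free criterion uninformative (best R^2=%.3f); "
            "using the default unsigned-network power %d",
            best_r2,
            fallback,
        )
        return int(fallback)
    logger.warning(
        "no candidate power reached scale-free R^2 >= %.2f; using power %d (R^2=%.3f)",
        r2_target,
        best_power,
        best_r2,
    )
    return int(best_power)


def _tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l_mat = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l_mat + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(1.0 - tom, 0.0, None)


def module_eigengene(
    submatrix: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized submatrix.

    Rows are genes, columns samples, on the log1p scale. Returns a
    unit-norm per-sample vector, sign-oriented to correlate positively
    with the module's mean standardized profile, and the fraction of
    variance it explains. A single-gene module returns that gene's
    z-scored profile (explained variance 1).
    """
    x = np.asarray(submatrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("module submatrix must be 2-D with >= 1 gene")
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if x.shape[0] == 1:
        e = z[0]
        norm = np.linalg.norm(e)
        return (e / norm if norm else e), 1.0
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    total = (s**2).sum()
    ev = float(s[0] ** 2 / total) if total > 0 else 0.0
    return e, ev


def _eigengene_for_genes(
    matrix: ExpressionMatrix, gene_ids: list[str]
) -> tuple[np.ndarray, float]:
    sub = np.log1p(matrix.values.loc[gene_ids].to_numpy(dtype=float))
    return module_eigengene(sub)


def detect_modules(
    matrix: ExpressionMatrix,
    power: int,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float = 0.85,
    small_cluster_corr: float = 0.5,
) -> ModulePartition:
    """Partition genes into co-expression modules.

    Unsigned adjacency |r|^power on log1p values, topological overlap
    dissimilarity, average-linkage clustering cut at the fixed
    TOM-dissimilarity height ``cut_height`` (within-module merges sit
    well below it, between-module merges near 1), clusters below
    ``min_module_size`` merged into the best-correlated module (mean
    profile r >= ``small_cluster_corr``) or left unassigned, then
    modules with eigengene correlation > 1 - merge_height merged.
    Deterministic for fixed inputs.
    """
    genes = matrix.gene_ids
    if len(genes) < 2:
        raise ValueError("detect_modules requires at least 2 genes")
    corr = _correlation(matrix)
    adj = np.abs(corr) ** power
    diss = _tom_dissimilarity(adj)
    link = average(squareform(diss, checks=False))
    labels = fcluster(link, t=cut_height, criterion="distance")

    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    big = {k: v for k, v in clusters.items() if len(v) >= min_module_size}
    small = {k: v for k, v in clusters.items() if len(v) < min_module_size}
    if not big:
        if len(genes) < min_module_size:
            big = {1: list(range(len(genes)))}
            small = {}
        else:
            # no cluster large enough: everything unassigned
            return ModulePartition(
                modules=[],
                unassigned_gene_ids=list(genes),
                parameters={
                    "power": power,
                    "min_module_size": min_module_size,
                    "merge_height": merge_height,
                    "cut_height": cut_height,
                },
                sample_ids=matrix.sample_ids,
            )

    logx = np.log1p(matrix.values.to_numpy(dtype=float))

    def mean_profile(idx: list[int]) -> np.ndarray:
        return logx[idx].mean(axis=0)

    # merge each small cluster into its best-correlated large module
    unassigned: list[int] = []
    big_keys = sorted(big)
    for k in sorted(small):
        idx = small[k]
        prof = mean_profile(idx)
        best_key, best_r = None, -np.inf
        for bk in big_keys:
            bp = mean_profile(big[bk])
            if prof.std() == 0 or bp.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(prof, bp)[0, 1])
            if r > best_r:
                best_key, best_r = bk, r
        if best_key is not None and best_r >= small_cluster_corr:
            big[best_key] = big[best_key] + idx
        else:
            unassigned.extend(idx)

    # iterative eigengene-correlation merging
    groups: list[list[int]] = [sorted(v) for _, v in sorted(big.items())]
    merged = True
    while merged and len(groups) > 1:
        merged = False
        eigs = [module_eigengene(logx[g])[0] for g in groups]
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                r = float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if r > 1.0 - merge_height and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is not None:
            _, i, j = best
            groups[i] = sorted(groups[i] + groups[j])
            del groups[j]
            merged = True

    groups.sort(key=lambda g: (-len(g), g[0]))
    modules = []
    for rank, g in enumerate(groups):
        label = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
        gene_ids = [genes[i] for i in g]
        eig, ev = _eigengene_for_genes(matrix, gene_ids)
        modules.append(
            GeneModule(
                label=label, gene_ids=gene_ids, eigengene=eig, explained_variance=ev
            )
        )
    return ModulePartition(
        modules=modules,
        unassigned_gene_ids=[genes[i] for i in sorted(unassigned)],
        parameters={
            "power": power,
            "min_module_size": min_module_size,
            "merge_height": merge_height,
            "cut_height": cut_height,
        },
        sample_ids=matrix.sample_ids,
    )


def assign_stage(
    module: GeneModule,
    metadata: SampleMetadata,
    sample_ids: list[str],
    specificity_ratio: float = 2.0,
    window: int = 8,
    step: int = 4,
    replicate_window: int = 3,
    min_replicate_agreement: float = 0.5,
    agreement_days: float = 4.0,
) -> GeneModule:
    """Assign a flowering-stage bin (or constitutive/variable) to a module.

    The eigengene is smoothed with the standard sliding window; the peak
    day is the center of the maximal window. The module is stage-specific
    iff (max window mean - overall mean) / sd(window means) >=
    ``specificity_ratio`` and at least ``min_replicate_agreement`` of the
    replicate series (tree/site/year) peak in the same stage bin — where a
    replicate also counts as agreeing when its peak day lies within
    ``agreement_days`` of the pooled peak, so a peak sitting on a bin
    boundary is not spuriously called replicate-inconsistent. Otherwise
    the module is 'constitutive' (flat or insufficiently peaked) or
    'variable' (peaked but replicate-inconsistent or outside the bins).
    """
    if module.eigengene is None:
        raise ValueError("module eigengene must be computed before stage assignment")
    days = metadata.day_offsets(sample_ids)
    prof = moving_average_profile(module.eigengene, days, window=window, step=step)
    centers = np.array([c for c, _ in prof])
    means = np.array([m for _, m in prof])
    sd = means.std(ddof=0)
    if sd == 0:
        module.stage, module.peak_day = "constitutive", None
        return module
    ratio = (means.max() - means.mean()) / sd
    peak_day = float(centers[int(np.argmax(means))])
    if ratio < specificity_ratio:
        module.stage, module.peak_day = "constitutive", None
        return module
    pooled_bin = stage_bin_for_day(peak_day)
    # replicate agreement on the peak bin
    reps = metadata.replicate_keys(sample_ids)
    rep_peaks: list[float] = []
    for key in sorted(set(reps)):
        idx = [i for i, k in enumerate(reps) if k == key]
        if len(idx) < 2:
            continue
        rprof = moving_average_profile(
            np.asarray(module.eigengene)[idx],
            days[idx],
            window=min(replicate_window, len(idx)),
            step=1,
        )
        rc = np.array([c for c, _ in rprof])
        rm = np.array([m for _, m in rprof])
        rep_peaks.append(float(rc[int(np.argmax(rm))]))
    if pooled_bin is None:
        module.stage, module.peak_day = "variable", peak_day
        return module
    agree = sum(
        1
        for p in rep_peaks
        if stage_bin_for_day(p) == pooled_bin or abs(p - peak_day) <= agreement_days
    )
    if rep_peaks and agree / len(rep_peaks) < min_replicate_agreement:
        module.stage, module.peak_day = "variable", peak_day
        return module
    module.stage, module.peak_day = pooled_bin, peak_day
    return module


def assign_stages(
    partition: ModulePartition,
    metadata: SampleMetadata,
    specificity_ratio: float = 2.0,
    **kwargs,
) -> ModulePartition:
    for m in partition.modules:
        assign_stage(
            m,
            metadata,
            partition.sample_ids,
            specificity_ratio=specificity_ratio,
            **kwargs,
        )
    return partition


def group_eigengenes(partition: ModulePartition, n_groups: int = 4) -> dict[str, int]:
    """Cluster module eigengenes into ``n_groups`` correlation groups."""
    mods = [m for m in partition.modules if m.eigengene is not None]
    if len(mods) <= n_groups:
        return {m.label: i + 1 for i, m in enumerate(mods)}
    eig = np.vstack([m.eigengene for m in mods])
    corr = np.corrcoef(eig)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=n_groups, criterion="maxclust")
    return {m.label: int(lab) for m, lab in zip(mods, labels)}
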
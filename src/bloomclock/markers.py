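"""Forecast-marker gene selection.

Scores every gene of a stage-specific module for peak expression level,
stage specificity and replicate stability, then selects the two forecast
markers (from the 3 WBF and 1-2 WBF stage modules by default) and a
monotonically increasing, replicate-stable control gene from the
constitutive class — mirroring a marker screen that wants genes whose
profiles repeat across trees, sites and years rather than genes that
respond to local conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr

from .expression import ExpressionMatrix, SampleMetadata, moving_average_profile
from .modules import ModulePartition

__all__ = ["MarkerScore", "score_markers", "select_forecast_genes", "score_control_candidates"]


@dataclass
class MarkerScore:
    gene_id: str
    module_label: str
    mean_peak_expression: float
    specificity: float
    stability: float
    monotonicity: float
    composite_rank: int = 0


def _smoothed(vals: np.ndarray, days: np.ndarray, window: int, step: int) -> np.ndarray:
    prof = moving_average_profile(vals, days, window=window, step=step)
    return np.array([m for _, m in prof])


def _replicate_profiles(
    vals: np.ndarray,
    days: np.ndarray,
    rep_keys: list[tuple],
    window: int,
    step: int,
) -> list[np.ndarray]:
    profs = []
    for key in sorted(set(rep_keys)):
        idx = [i for i, k in enumerate(rep_keys) if k == key]
        if len(idx) < 2:
            continue
        profs.append(
            _smoothed(vals[idx], days[idx], window=min(window, len(idx)), step=step)
        )
    return profs


def _stability(profiles: list[np.ndarray]) -> float:
    """Mean pairwise Pearson r between per-replicate smoothed profiles."""
    rs = []
    for a, b in combinations(profiles, 2):
        n = min(a.size, b.size)
        a2, b2 = a[:n], b[:n]
        if a2.std() == 0 or b2.std() == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(a2, b2)[0, 1]))
    return float(np.mean(rs)) if rs else float("nan")


def score_markers(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    partition: ModulePartition,
    window: int = 8,
    step: int = 4,
    replicate_window: int = 3,
    allow_single_replicate: bool = False,
) -> list[MarkerScore]:
    """Score genes of stage-specific modules as forecast-marker candidates.

    specificity: (peak window mean - overall mean) / sd of window means,
    on the pooled smoothed profile. stability: mean pairwise Pearson r
    between per-replicate smoothed profiles. mean_peak_expression: mean
    FPKM over the samples of the peak window. Ranked lexicographically by
    descending (stability, specificity, mean_peak_expression), ties by
    gene id.
    """
    sample_ids = partition.sample_ids or matrix.sample_ids
    days = metadata.day_offsets(sample_ids)
    rep_keys = metadata.replicate_keys(sample_ids)
    n_reps = len({k for k in rep_keys if rep_keys.count(k) >= 2})
    if n_reps < 2 and not allow_single_replicate:
        raise ValueError(
            "stability needs >= 2 replicate series; pass allow_single_replicate=True "
            "to waive the stability criterion"
        )
    vals = matrix.values[sample_ids]
    scores: list[MarkerScore] = []
    for module in partition.stage_specific():
        for gid in module.gene_ids:
            x = vals.loc[gid].to_numpy(dtype=float)
            prof = moving_average_profile(x, days, window=window, step=step)
            means = np.array([m for _, m in prof])
            sd = means.std(ddof=0)
            specificity = float((means.max() - means.mean()) / sd) if sd > 0 else 0.0
            # peak window samples -> mean FPKM at the peak
            order = np.argsort(days, kind="stable")
            peak_i = int(np.argmax(means))
            spans = _window_spans(len(x), window, step)
            a, b = spans[peak_i]
            mean_peak = float(x[order][a:b].mean())
            if n_reps >= 2:
                profs = _replicate_profiles(x, days, rep_keys, replicate_window, 1)
                stability = _stability(profs)
            else:
                stability = float("nan")
            rho = spearmanr(days, x).statistic if x.std() > 0 else 0.0
            scores.append(
                MarkerScore(
                    gene_id=gid,
                    module_label=module.label,
                    mean_peak_expression=mean_peak,
                    specificity=specificity,
                    stability=stability,
                    monotonicity=float(rho) if np.isfinite(rho) else 0.0,
                )
            )
    key = lambda s: (
        -(s.stability if np.isfinite(s.stability) else -np.inf),
        -s.specificity,
        -s.mean_peak_expression,
        s.gene_id,
    )
    scores.sort(key=key)
    for i, s in enumerate(scores):
        s.composite_rank = i + 1
    return scores


def _window_spans(n: int, window: int, step: int) -> list[tuple[int, int]]:
    if n <= window:
        return [(0, n)]
    spans = []
    start = 0
    while start + window <= n:
        spans.append((start, start + window))
        start += step
    if n - spans[-1][1] >= window / 2:
        spans.append((spans[-1][1], n))
    return spans


def score_control_candidates(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    gene_ids: list[str],
    replicate_window: int = 3,
) -> list[MarkerScore]:
    """Monotonicity/stability scores for control-gene candidates."""
    sample_ids = matrix.sample_ids
    days = metadata.day_offsets(sample_ids)
    rep_keys = metadata.replicate_keys(sample_ids)
    out = []
    for gid in gene_ids:
        x = matrix.values.loc[gid].to_numpy(dtype=float)
        rho = spearmanr(days, x).statistic if x.std() > 0 else 0.0
        profs = _replicate_profiles(x, days, rep_keys, replicate_window, 1)
        out.append(
            MarkerScore(
                gene_id=gid,
                module_label="constitutive",
                mean_peak_expression=float(x.mean()),
                specificity=0.0,
                stability=_stability(profs),
                monotonicity=float(rho) if np.isfinite(rho) else 0.0,
            )
        )
    return out


def select_forecast_genes(
    scores: list[MarkerScore],
    partition: ModulePartition,
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    target_stages: tuple[str, str] = ("3 WBF", "1-2 WBF"),
    control_stability_min: float = 0.5,
) -> dict[str, str]:
    """Pick the marker pair and the control gene.

    CBFb is the top-ranked gene of the module assigned the earlier
    target stage, CBFg the top-ranked of the later one. The control
    (CBFr) maximizes Spearman monotonicity vs. day among
    constitutive-class genes with replicate stability >=
    ``control_stability_min``. The three genes are distinct.
    """
    early_stage, late_stage = target_stages
    chosen: dict[str, str] = {}
    for role, stage in (("CBFb", early_stage), ("CBFg", late_stage)):
        cand = [s for s in scores if _stage_of(partition, s.module_label) == stage]
        if not cand:
            raise ValueError(f"no scored genes in a module assigned stage {stage!r}")
        cand.sort(key=lambda s: s.composite_rank)
        chosen[role] = cand[0].gene_id

    const_genes = []
    for m in partition.modules:
        if m.stage == "constitutive":
            const_genes.extend(m.gene_ids)
    ctrl_scores = score_control_candidates(matrix, metadata, const_genes)
    eligible = [
        s
        for s in ctrl_scores
        if np.isfinite(s.stability)
        and s.stability >= control_stability_min
        and s.monotonicity > 0
        and s.gene_id not in chosen.values()
    ]
    if not eligible:
        best = max((s.monotonicity for s in ctrl_scores), default=float("nan"))
        raise ValueError(
            "no qualifying control gene (stability >= "
            f"{control_stability_min}, positive monotonicity); best monotonicity "
            f"found: {best}"
        )
    eligible.sort(key=lambda s: (-s.monotonicity, s.gene_id))
    chosen["CBFr"] = eligible[0].gene_id
    return chosen


def _stage_of(partition: ModulePartition, label: str) -> str | None:
    for m in partition.modules:
        if m.label == label:
            return m.stage
    return None
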
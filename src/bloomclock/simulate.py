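"""Synthetic time-course data with planted ground truth.

Generates the inputs the pipeline consumes — a gene x sample FPKM matrix,
sample metadata, a GO annotation and Ct tables — with known structure so
every downstream stage can be validated without sequencing data. The
default configuration emulates the study design of the real experiment:
seven clonal trees at three sites sampled roughly every four days from
five weeks before bloom to eleven days after, with a minority of genes
organized into seven stage-peaked co-expression modules and the rest
either constitutive, monotonically trending, or inconsistent between
replicate trees.

Gene classes
------------
* ``module`` genes: Gaussian bump in log1p expression centered on the
  module's peak day. Two designated forecast-marker genes (one in the
  3 WBF module, one in the 1-2 WBF module) get the largest amplitude and
  reduced noise, emulating the high-expressed, replicate-stable genes a
  marker screen should single out.
* ``trend`` genes: monotone increasing log expression across the window;
  the designated control gene has the steepest, least noisy ramp. A
  linear ramp is deliberately not stage-peaked, so these genes land in
  the constitutive class downstream — like the reference gene's module
  in the real data.
* ``constitutive`` genes: flat low expression (mostly removed by the
  variance filter, as in the real data where only ~31% of genes pass).
* ``variable`` genes: flat plus a per-(tree, site, year) random offset,
  i.e. replicate-inconsistent expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, SampleMetadata

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "default_config",
    "generate_timecourse",
    "generate_ct_series",
    "generate_forecast_training",
    "generate_go_annotation",
]

#: Coefficients of the days-to-flowering forecast used as planted truth:
#: (beta_g, beta_b, beta_gb, beta_0) in days per dCt unit / days.
DEFAULT_FORECAST_COEFFICIENTS = (3.56, -0.59, -0.22, -3.70)

DEFAULT_TREES = [
    ("KDRI", "Chiba", 2019),
    ("SU1", "Shimane", 2019),
    ("SU2", "Shimane", 2019),
    ("SU3", "Shimane", 2019),
    ("KPUA", "Kyoto", 2019),
    ("KPUB", "Kyoto", 2019),
    ("KPUC", "Kyoto", 2019),
]

DEFAULT_SAMPLING_DAYS = [-36, -32, -28, -24, -20, -16, -12, -8, -4, 0, 5, 11]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic time course.

    Defaults reproduce the study conditions: 2,000 genes, seven planted
    modules peaking at -32, -28, -21, -17, -10, 0 and +10 days relative
    to bloom, seven trees x 12 sampling days, replicate noise sd 0.2 on
    the log-expression scale.
    """

    n_genes: int = 2000
    n_stage_modules: int = 7
    module_sizes: list[int] = field(
        default_factory=lambda: [60, 100, 120, 70, 90, 160, 50]
    )
    peak_days: list[float] = field(
        default_factory=lambda: [-32, -28, -21, -17, -10, 0, 10]
    )
    bump_width_days: float = 3.0
    amplitude_range: tuple[float, float] = (2.5, 4.0)
    background_fraction_constitutive: float = 0.5
    trees: list[tuple[str, str, int]] = field(default_factory=lambda: list(DEFAULT_TREES))
    sampling_days: list[float] = field(default_factory=lambda: list(DEFAULT_SAMPLING_DAYS))
    replicate_noise_sd: float = 0.2
    seed: int = 42
    # secondary knobs, fixed defaults
    n_trend_genes: int = 40
    trend_amplitude_range: tuple[float, float] = (1.5, 2.5)
    baseline_log_range: tuple[float, float] = (0.5, 2.0)
    tree_offset_sd: float = 1.0
    marker_amplitude_bonus: float = 0.8
    marker_noise_factor: float = 0.25
    ct_noise_sd: float = 0.5
    forecast_coefficients: tuple[float, float, float, float] = DEFAULT_FORECAST_COEFFICIENTS

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.module_sizes) != self.n_stage_modules or len(
            self.peak_days
        ) != self.n_stage_modules:
            raise ValueError(
                "module_sizes and peak_days must each have n_stage_modules entries"
            )
        if any(m <= 0 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        planted = sum(self.module_sizes) + self.n_trend_genes
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.bump_width_days <= 0:
            raise ValueError("bump_width_days must be positive")
        if not 0 <= self.background_fraction_constitutive <= 1:
            raise ValueError("background_fraction_constitutive must be in [0, 1]")
        if self.replicate_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if list(self.sampling_days) != sorted(self.sampling_days):
            raise ValueError("sampling_days must be sorted ascending")
        if not self.trees:
            raise ValueError("at least one tree is required")


@dataclass
class SimulationTruth:
    """Planted ground truth of one simulated dataset."""

    module_membership: dict[str, str]
    profile_params: dict[str, tuple[float, float, float]]
    forecast_coefficients: tuple[float, float, float, float]
    ct_noise_sd: float
    seed: int
    planted_markers: dict[str, str] = field(default_factory=dict)
    ct_params: dict[str, tuple] = field(default_factory=dict)

    def module_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.module_membership.values():
            if lab.startswith("module"):
                seen.setdefault(lab, None)
        return list(seen)


def default_config(seed: int = 42) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def generate_timecourse(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SimulationTruth]:
    """Simulate one FPKM matrix + metadata with planted module structure.

    One sample is produced per (tree, sampling day). Module genes follow
    a Gaussian bump in log1p expression centered at their module's peak
    day; trend genes ramp up linearly; constitutive genes are flat;
    variable genes carry a per-replicate offset. Gaussian noise with sd
    ``replicate_noise_sd`` is added to every log value. Identical config
    and seed give identical output.
    """
    config.validate()
    config.trees = [tuple(t) for t in config.trees]  # YAML configs give lists
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    days = np.asarray(config.sampling_days, dtype=float)
    samples, day_of, tree_of = [], [], []
    for tree_id, site, year in config.trees:
        for d in days:
            sid = f"{tree_id}_{year}_d{int(d):+03d}"
            samples.append(sid)
            day_of.append(d)
            tree_of.append((tree_id, site, year))
    n_s = len(samples)
    day_arr = np.asarray(day_of)
    tree_index = np.asarray([config.trees.index(t) for t in tree_of])

    membership: dict[str, str] = {}
    profile_params: dict[str, tuple[float, float, float]] = {}
    planted_markers: dict[str, str] = {}
    log_expr = np.zeros((config.n_genes, n_s))

    lo_b, hi_b = config.baseline_log_range
    lo_a, hi_a = config.amplitude_range
    noise_factor = np.ones(config.n_genes)

    # markers sit in the modules peaking nearest -21 (CBFb) and -10 (CBFg),
    # mirroring the 3 WBF / 1-2 WBF module origin of the real marker pair
    peaks = np.asarray(config.peak_days, dtype=float)
    mod_b = int(np.argmin(np.abs(peaks - (-21.0))))
    mod_g = int(np.argmin(np.abs(peaks - (-10.0))))

    g = 0
    for mi, (size, peak) in enumerate(zip(config.module_sizes, config.peak_days)):
        label = f"module{mi + 1}"
        profile_params[label] = (
            float(peak),
            config.bump_width_days,
            float((lo_a + hi_a) / 2.0),
        )
        for j in range(size):
            gid = genes[g]
            membership[gid] = label
            baseline = rng.uniform(lo_b, hi_b)
            amp = rng.uniform(lo_a, hi_a)
            if j == 0 and mi == mod_b:
                amp = hi_a + config.marker_amplitude_bonus
                noise_factor[g] = config.marker_noise_factor
                planted_markers["CBFb"] = gid
            elif j == 0 and mi == mod_g:
                amp = hi_a + config.marker_amplitude_bonus
                noise_factor[g] = config.marker_noise_factor
                planted_markers["CBFg"] = gid
            bump = amp * np.exp(
                -((day_arr - peak) ** 2) / (2.0 * config.bump_width_days**2)
            )
            log_expr[g] = baseline + bump
            g += 1

    # monotone trend group; first gene is the planted control
    span = days.max() - days.min() if days.max() > days.min() else 1.0
    ramp01 = (day_arr - days.min()) / span
    lo_t, hi_t = config.trend_amplitude_range
    for j in range(config.n_trend_genes):
        gid = genes[g]
        membership[gid] = "trend"
        baseline = rng.uniform(lo_b, hi_b)
        amp = rng.uniform(lo_t, hi_t)
        if j == 0:
            amp = hi_t + 0.5
            noise_factor[g] = config.marker_noise_factor
            planted_markers["CBFr"] = gid
        log_expr[g] = baseline + amp * ramp01
        g += 1

    n_back = config.n_genes - g
    n_const = int(round(n_back * config.background_fraction_constitutive))
    for j in range(n_back):
        gid = genes[g]
        baseline = rng.uniform(lo_b, hi_b)
        if j < n_const:
            membership[gid] = "constitutive"
            log_expr[g] = baseline
        else:
            membership[gid] = "variable"
            offsets = rng.normal(0.0, config.tree_offset_sd, size=len(config.trees))
            log_expr[g] = baseline + offsets[tree_index]
        g += 1

    if config.replicate_noise_sd > 0:
        noise = rng.normal(0.0, config.replicate_noise_sd, size=log_expr.shape)
        log_expr = log_expr + noise * noise_factor[:, None]

    values = np.maximum(np.expm1(log_expr), 0.0)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        unit="FPKM",
        gene_lengths=pd.Series(
            rng.integers(500, 5000, size=config.n_genes).astype(float), index=genes
        ),
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "tree_id": [t[0] for t in tree_of],
                "site": [t[1] for t in tree_of],
                "year": [t[2] for t in tree_of],
                "collection_date": [
                    (
                        pd.Timestamp(f"{t[2]}-04-01") + pd.Timedelta(days=int(d))
                    ).date().isoformat()
                    for t, d in zip(tree_of, day_of)
                ],
                "day_offset": day_arr.astype(int),
            }
        )
    )
    truth = SimulationTruth(
        module_membership=membership,
        profile_params=profile_params,
        forecast_coefficients=tuple(config.forecast_coefficients),
        ct_noise_sd=config.ct_noise_sd,
        seed=config.seed,
        planted_markers=planted_markers,
        ct_params={
            # dCt_b: quadratic in days-to-flowering with vertex at 20 DBF
            "CBFb": (0.012, 20.0, 1.5),
            # dCt_g: cubic with interior local minimum at 10 DBF; second
            # stationary point at 50 DBF, outside any sampled window;
            # scaled so Ct stays within [10, 45] over -11..36 DBF
            "CBFg": (-0.0015, 10.0, 50.0, 8.0),
            # control Ct: rises with days-to-flowering (less transcript
            # earlier), i.e. falls as bloom approaches
            "CBFr": (21.0, 0.12),
        },
    )
    return matrix, meta, truth


def _ct_curves(truth: SimulationTruth, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless (dct_b, dct_g, ct_r) at days-to-flowering ``t``."""
    a, vb, c0 = truth.ct_params["CBFb"]
    dct_b = a * (t - vb) ** 2 + c0
    k, r1, r2, d0 = truth.ct_params["CBFg"]
    # antiderivative of k*(t - r1)*(t - r2): stationary points at r1, r2
    dct_g = k * (t**3 / 3.0 - (r1 + r2) / 2.0 * t**2 + r1 * r2 * t) + d0
    r0, slope = truth.ct_params["CBFr"]
    ct_r = r0 + slope * t
    return dct_b, dct_g, ct_r


def generate_ct_series(
    days: list[float] | np.ndarray,
    truth: SimulationTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate qPCR Ct records for the marker trio over ``days``.

    ``days`` are signed day offsets from bloom (negative before). The
    CBFb dCt follows a quadratic and the CBFg dCt a cubic in
    days-to-flowering, with extrema at the planted days; the control Ct
    decreases monotonically along the stage axis when noise is zero.
    Per-record Gaussian noise has sd ``truth.ct_noise_sd``.

    Returns (ct_table, metadata_table); the Ct table has columns
    sample_id, role, ct and the metadata table sample_id, day_offset.
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("generate_ct_series requires a nonempty days list")
    t = -days  # days-to-flowering, positive before bloom
    dct_b, dct_g, ct_r = _ct_curves(truth, t)
    ct_b = dct_b + ct_r
    ct_g = dct_g + ct_r
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    sample_ids = [f"CT{i:03d}" for i in range(1, days.size + 1)]
    for sid, cb, cg, cr in zip(sample_ids, ct_b, ct_g, ct_r):
        for role, ct in (("CBFb", cb), ("CBFg", cg), ("CBFr", cr)):
            noisy = ct + (rng.normal(0.0, truth.ct_noise_sd) if truth.ct_noise_sd else 0.0)
            rows.append({"sample_id": sid, "role": role, "ct": float(np.clip(noisy, 10.0, 45.0))})
    ct_table = pd.DataFrame(rows)
    meta = pd.DataFrame({"sample_id": sample_ids, "day_offset": days})
    return ct_table, meta


def generate_forecast_training(
    truth: SimulationTruth,
    dct_g_grid: np.ndarray | None = None,
    dct_b_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """dCt pairs with days-to-flowering computed from the planted model.

    Used for parameter-recovery checks: the returned frame satisfies
    days = b_g*dct_g + b_b*dct_b + b_gb*dct_g*dct_b + b_0 exactly
    (plus optional Gaussian noise on days).
    """
    if dct_g_grid is None:
        dct_g_grid = np.linspace(0.0, 8.0, 6)
    if dct_b_grid is None:
        dct_b_grid = np.linspace(0.0, 12.0, 6)
    bg, bb, bgb, b0 = truth.forecast_coefficients
    gg, bbv = np.meshgrid(np.asarray(dct_g_grid, float), np.asarray(dct_b_grid, float))
    gg, bbv = gg.ravel(), bbv.ravel()
    days = bg * gg + bb * bbv + bgb * gg * bbv + b0
    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        days = days + rng.normal(0.0, noise_sd, size=days.shape)
    return pd.DataFrame(
        {
            "sample_id": [f"TR{i:03d}" for i in range(1, gg.size + 1)],
            "dct_g": gg,
            "dct_b": bbv,
            "days_to_flowering": days,
        }
    )


def generate_go_annotation(
    genes: list[str],
    truth: SimulationTruth,
    n_terms: int = 20,
    planted_term_module: list[tuple[str, str]] | None = None,
    planted_fraction: float = 0.5,
    background_rate: float = 0.05,
    seed: int | None = None,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Random flat GO annotation with optional planted enrichments.

    Each (term, module) pair in ``planted_term_module`` makes that term
    cover ``planted_fraction`` of the module's genes and
    ``background_rate`` of all other genes; remaining terms are assigned
    uniformly at random at the background rate.

    Returns (gene_to_terms, term_meta) where term_meta has columns
    term_id, name, ontology.
    """
    planted = planted_term_module or []
    if n_terms < len(planted):
        raise ValueError(
            f"n_terms ({n_terms}) smaller than number of planted pairs ({len(planted)})"
        )
    labels = set(truth.module_membership.values())
    for term, module in planted:
        if module not in labels:
            raise ValueError(f"planted pair references unknown module {module!r}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    term_ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    ontologies = ["BP", "MF", "CC"]
    term_meta = pd.DataFrame(
        {
            "term_id": term_ids,
            "name": [f"synthetic process {i}" for i in range(1, n_terms + 1)],
            "ontology": [ontologies[i % 3] for i in range(n_terms)],
        }
    )
    # planted pair i is realized as term_ids[i]; the pair's own term name
    # is only a caller-side mnemonic
    gene_to_terms: dict[str, set[str]] = {g: set() for g in genes}
    for ti, (term, module) in enumerate(planted):
        tid = term_ids[ti]
        members = [g for g in genes if truth.module_membership.get(g) == module]
        n_in = int(round(planted_fraction * len(members)))
        chosen = rng.choice(members, size=n_in, replace=False) if n_in else []
        for gid in chosen:
            gene_to_terms[gid].add(tid)
        outside = [g for g in genes if truth.module_membership.get(g) != module]
        hits = rng.random(len(outside)) < background_rate
        for gid, h in zip(outside, hits):
            if h:
                gene_to_terms[gid].add(tid)
    # unplanted terms: uniform background rate everywhere
    for ti in range(len(planted), n_terms):
        tid = term_ids[ti]
        hits = rng.random(len(genes)) < background_rate
        for gid, h in zip(genes, hits):
            if h:
                gene_to_terms[gid].add(tid)
    return gene_to_terms, term_meta
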
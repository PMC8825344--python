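"""The RNA-marker bloom forecast model.

From Ct measurements of the two forecast markers and the control gene:
dCt = Ct_target - Ct_control per sample; a quadratic (CBFb) and a cubic
(CBFg) stage curve of dCt over days-to-flowering with an estimated
extremum day; and an interaction regression

    days_to_flowering ~ b_g*dCt_g + b_b*dCt_b + b_gb*dCt_g*dCt_b + b_0

fitted by ordinary least squares (a Gaussian identity-link model), valid
from 21 days before flowering to the flowering day. Days-to-flowering is
positive before bloom (so "20 DBF" is +20), zero at bloom, negative
after — the negation of the sample metadata's day offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SampleMetadata

__all__ = [
    "CtRecord",
    "StageCurve",
    "ForecastModel",
    "ROLES",
    "delta_ct",
    "build_delta_ct_series",
    "fit_stage_curve",
    "fit_forecast_model",
    "predict_days",
    "evaluate_predictions",
]

ROLES = ("CBFb", "CBFg", "CBFr")
VALIDITY_RANGE = (0.0, 21.0)


@dataclass
class CtRecord:
    sample_id: str
    role: str
    ct: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not 0.0 <= self.ct <= 60.0:
            raise ValueError(f"Ct {self.ct} outside plausible range [0, 60]")


@dataclass
class StageCurve:
    role: str
    degree: int
    coefficients: np.ndarray  # ascending powers of days-to-flowering
    fit_range: tuple[float, float]
    extremum_day: float | None
    rss: float

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(t, self.coefficients)


@dataclass
class ForecastModel:
    beta_g: float
    beta_b: float
    beta_gb: float
    beta_0: float
    validity_range: tuple[float, float] = VALIDITY_RANGE
    fit_diagnostics: dict = field(default_factory=dict)

    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.beta_g, self.beta_b, self.beta_gb, self.beta_0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta_g": self.beta_g,
                    "beta_b": self.beta_b,
                    "beta_gb": self.beta_gb,
                    "beta_0": self.beta_0,
                    "validity_range": list(self.validity_range),
                    "fit_diagnostics": self.fit_diagnostics,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ForecastModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            beta_g=d["beta_g"],
            beta_b=d["beta_b"],
            beta_gb=d["beta_gb"],
            beta_0=d["beta_0"],
            validity_range=tuple(d.get("validity_range", VALIDITY_RANGE)),
            fit_diagnostics=d.get("fit_diagnostics", {}),
        )


def delta_ct(ct_target: float, ct_control: float) -> float:
    """dCt = Ct_target - Ct_control (both in PCR cycles)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_control)):
        raise ValueError("Ct values must be finite")
    return float(ct_target) - float(ct_control)


def build_delta_ct_series(
    records: pd.DataFrame,
    metadata: SampleMetadata | pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample (dct_b, dct_g, days_to_flowering) from a Ct table.

    ``records`` needs columns sample_id, role, ct with roles CBFb, CBFg
    and CBFr present once per sample; days_to_flowering is the negated
    metadata day_offset.
    """
    req = {"sample_id", "role", "ct"}
    if not req <= set(records.columns):
        raise ValueError(f"Ct table missing columns: {sorted(req - set(records.columns))}")
    bad_roles = set(records["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown Ct role(s): {sorted(bad_roles)}")
    dup = records.duplicated(subset=["sample_id", "role"])
    if dup.any():
        pairs = records.loc[dup, ["sample_id", "role"]].values.tolist()
        raise ValueError(f"duplicate (sample, role) Ct records: {pairs[:5]}")
    meta_tbl = metadata.table if isinstance(metadata, SampleMetadata) else metadata
    day_of = meta_tbl.set_index("sample_id")["day_offset"]
    wide = records.pivot(index="sample_id", columns="role", values="ct")
    rows = []
    for sid, row in wide.iterrows():
        for role in ROLES:
            if role not in wide.columns or pd.isna(row.get(role)):
                raise ValueError(f"sample {sid!r} is missing a Ct value for {role}")
        if sid not in day_of.index:
            raise ValueError(f"sample {sid!r} missing from metadata")
        rows.append(
            {
                "sample_id": sid,
                "dct_b": delta_ct(row["CBFb"], row["CBFr"]),
                "dct_g": delta_ct(row["CBFg"], row["CBFr"]),
                "days_to_flowering": -float(day_of.loc[sid]),
            }
        )
    return pd.DataFrame(rows)


def fit_stage_curve(
    days: np.ndarray,
    dct: np.ndarray,
    degree: int,
) -> StageCurve:
    """Least-squares polynomial of dCt over days-to-flowering.

    ``extremum_day`` is the real root of the derivative inside the data
    range at which the curve has its interior extremum; for a cubic
    (which can have two stationary points) the one whose curve value is
    nearest the most extreme observed dCt is taken. None when no
    stationary point lies inside the range.
    """
    if degree not in (2, 3):
        raise ValueError("degree must be 2 or 3")
    days = np.asarray(days, dtype=float)
    dct = np.asarray(dct, dtype=float)
    distinct = np.unique(days)
    if distinct.size < degree + 2:
        raise ValueError(
            f"need at least degree+2={degree + 2} distinct day values, got {distinct.size}"
        )
    # plain Vandermonde least squares in the natural (unscaled) basis
    x_mat = np.vander(days, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(x_mat, dct, rcond=None)
    fitted = x_mat @ coef
    rss = float(((dct - fitted) ** 2).sum())
    lo, hi = float(days.min()), float(days.max())
    deriv = np.polynomial.polynomial.polyder(coef)
    roots = np.roots(deriv[::-1]) if len(deriv) > 1 else np.array([])
    interior = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 and lo < r.real < hi
    ]
    extremum = None
    if interior:
        if len(interior) == 1:
            extremum = interior[0]
        else:
            vals_at = np.polynomial.polynomial.polyval(np.array(interior), coef)
            mean = dct.mean()
            extreme_val = dct[np.argmax(np.abs(dct - mean))]
            extremum = interior[int(np.argmin(np.abs(vals_at - extreme_val)))]
    return StageCurve(
        role="",
        degree=degree,
        coefficients=coef,
        fit_range=(lo, hi),
        extremum_day=extremum,
        rss=rss,
    )


def _design(dct_g: np.ndarray, dct_b: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(dct_g), dct_g, dct_b, dct_g * dct_b]
    )


def fit_forecast_model(series: pd.DataFrame) -> ForecastModel:
    """OLS fit of days-to-flowering on (dCt_g, dCt_b, their interaction).

    ``series`` needs columns dct_g, dct_b, days_to_flowering with at
    least 5 samples and a full-rank design.
    """
    req = {"dct_g", "dct_b", "days_to_flowering"}
    if not req <= set(series.columns):
        raise ValueError(f"series missing columns: {sorted(req - set(series.columns))}")
    if len(series) < 5:
        raise ValueError("fit_forecast_model requires at least 5 samples")
    g = series["dct_g"].to_numpy(dtype=float)
    b = series["dct_b"].to_numpy(dtype=float)
    y = series["days_to_flowering"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(b)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the dCt series")
    x_mat = _design(g, b)
    if np.linalg.matrix_rank(x_mat) < 4:
        names = ["intercept", "dct_g", "dct_b", "dct_g:dct_b"]
        for j in (1, 2, 3):
            if np.allclose(x_mat[:, j], x_mat[0, j]):
                raise ValueError(f"rank-deficient design: column {names[j]} is constant")
        raise ValueError("rank-deficient design: collinear dCt columns")
    coef, *_ = np.linalg.lstsq(x_mat, y, rcond=None)
    fitted = x_mat @ coef
    rss = float(((y - fitted) ** 2).sum())
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(fitted, y)[0, 1])
    else:
        r = float("nan")
    return ForecastModel(
        beta_g=float(coef[1]),
        beta_b=float(coef[2]),
        beta_gb=float(coef[3]),
        beta_0=float(coef[0]),
        fit_diagnostics={"n": int(len(y)), "rss": rss, "r": r},
    )


def predict_days(
    model: ForecastModel,
    dct_g: float | np.ndarray,
    dct_b: float | np.ndarray,
) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Days to flowering predicted from a dCt pair, plus a validity flag.

    The flag is true when the prediction falls inside the model's
    validity window (default 0 to 21 days before flowering).
    """
    g = np.asarray(dct_g, dtype=float)
    b = np.asarray(dct_b, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(b))):
        raise ValueError("dCt inputs must be finite")
    days = model.beta_g * g + model.beta_b * b + model.beta_gb * g * b + model.beta_0
    lo, hi = model.validity_range
    flag = (days >= lo) & (days <= hi)
    if days.ndim == 0:
        return float(days), bool(flag)
    return days, flag


def evaluate_predictions(
    observed_days: np.ndarray,
    predicted_days: np.ndarray,
    restrict_to_range: bool = True,
    validity_range: tuple[float, float] = VALIDITY_RANGE,
) -> tuple[float, float, int]:
    """Pearson r, RMSE (days) and n over the (optionally windowed) pairs.

    When ``restrict_to_range`` is set, only samples whose observed days
    lie inside the validity window are compared.
    """
    obs = np.asarray(observed_days, dtype=float)
    pred = np.asarray(predicted_days, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted series must have equal length")
    if restrict_to_range:
        lo, hi = validity_range
        keep = (obs >= lo) & (obs <= hi)
        obs, pred = obs[keep], pred[keep]
    n = int(obs.size)
    if n < 2:
        raise ValueError(f"need >= 2 samples after restriction, got {n}")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if obs.std() == 0 or pred.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    return r, rmse, n
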
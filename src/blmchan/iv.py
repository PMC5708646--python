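"""Current-voltage relations and unitary conductance fitting.

Level-assigned opening events are pooled into one I-V point per
(voltage, level); the unitary conductance is reported as the zero-voltage
slope of a weighted least-squares fit (weights = event counts), in
pS = pA/mV x 1000.  When a quadratic term significantly improves the fit
(F-test, alpha = 0.05) - the signature of rectification - the zero-voltage
slope is the linear coefficient of the quadratic fit.  Rectification is
quantified descriptively as |slope at V>0| / |slope at V<0| from separate
fits on each polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FitError, ValidationError

__all__ = [
    "IVDataset",
    "ConductanceFit",
    "SaltScalingFit",
    "build_iv",
    "fit_conductance",
    "conductance_vs_salt",
]

IV_COLUMNS = ("voltage_mV", "mean_current_pA", "sd_pA", "n_events", "level")


@dataclass
class IVDataset:
    """I-V points (one per voltage and level) with a condition label."""

    points: pd.DataFrame
    condition_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in IV_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValidationError(f"IV dataset missing columns {missing}")

    def for_level(self, level: int) -> "IVDataset":
        pts = self.points[self.points["level"] == level].reset_index(drop=True)
        return IVDataset(points=pts, condition_label=self.condition_label)


@dataclass
class ConductanceFit:
    """Zero-voltage-slope conductance fit of one I-V relation."""

    g_pS: float
    reversal_x_intercept_mV: float
    fit_sd_pS: float
    rectification_ratio: float | None
    quadratic_used: bool
    n_points: int
    n_events: int

    def summary(self) -> str:
        lines = [
            "Unitary conductance fit",
            f"  points / events : {self.n_points} / {self.n_events}",
            f"  g (zero-V slope): {self.g_pS:.1f} +/- {self.fit_sd_pS:.1f} pS"
            + ("  [quadratic]" if self.quadratic_used else ""),
            f"  x-intercept     : {self.reversal_x_intercept_mV:+.2f} mV",
        ]
        if self.rectification_ratio is not None:
            lines.append(f"  rectification   : {self.rectification_ratio:.2f}")
        return "\n".join(lines)


def build_iv(
    events: pd.DataFrame,
    min_events_per_voltage: int = 1,
    condition_label: str = "",
) -> IVDataset:
    """Pool events into I-V points; drop voltages with too few events.

    Unassigned events (level <NA>) are excluded.  An empty event table gives
    an empty (valid) dataset.
    """
    if min_events_per_voltage < 1:
        raise ValidationError("min_events_per_voltage must be >= 1")
    rows = []
    if len(events):
        known = events[events["level"].notna()]
        for (lvl, v), grp in known.groupby(["level", "step_voltage_mV"], sort=True):
            amps = grp["amplitude_pA"].to_numpy(float)
            if amps.size < min_events_per_voltage:
                continue
            rows.append(
                (float(v), float(amps.mean()),
                 float(amps.std(ddof=1)) if amps.size > 1 else 0.0,
                 int(amps.size), int(lvl))
            )
    df = pd.DataFrame(rows, columns=list(IV_COLUMNS))
    return IVDataset(points=df, condition_label=condition_label)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via scaled normal equations.

    Returns (coefficients, weighted SSR, covariance of coefficients or None).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    ssr = float(resid @ resid)
    dof = X.shape[0] - X.shape[1]
    cov = None
    if dof > 0:
        XtX_inv = np.linalg.pinv(Xw.T @ Xw)
        cov = XtX_inv * (ssr / dof)
    return beta, ssr, cov


def fit_conductance(iv: IVDataset | pd.DataFrame) -> ConductanceFit:
    """Fit the unitary conductance as the zero-voltage slope of the I-V plot."""
    pts = iv.points if isinstance(iv, IVDataset) else iv
    if len(pts) < 2:
        raise ValidationError("conductance fit needs >= 2 I-V points")
    v = pts["voltage_mV"].to_numpy(float)
    i = pts["mean_current_pA"].to_numpy(float)
    w = pts["n_events"].to_numpy(float) if "n_events" in pts else np.ones_like(v)
    if np.ptp(v) == 0:
        raise FitError("all I-V points share one voltage; slope undefined")

    X1 = np.column_stack([np.ones_like(v), v])
    beta1, ssr1, cov1 = _wls(X1, i, w)
    scale = float(np.sum(w * i**2)) + 1e-300
    use_quad = False
    beta2 = cov2 = None
    if len(pts) >= 4 and np.unique(v).size >= 3 and ssr1 / scale > 1e-18:
        X2 = np.column_stack([np.ones_like(v), v, v**2])
        beta2, ssr2, cov2 = _wls(X2, i, w)
        dof2 = len(pts) - 3
        if ssr2 / scale <= 1e-18 and ssr1 / scale > 1e-18:
            use_quad = True  # exact quadratic
        elif dof2 > 0 and ssr2 > 0:
            f_stat = (ssr1 - ssr2) / (ssr2 / dof2)
            p = stats.f.sf(f_stat, 1, dof2)
            use_quad = p < 0.05

    if use_quad:
        beta, cov = beta2, cov2
    else:
        beta, cov = beta1, cov1
    intercept, slope = float(beta[0]), float(beta[1])
    if slope == 0:
        raise FitError("zero slope: conductance undefined")
    se = float(np.sqrt(cov[1, 1])) if cov is not None else 0.0

    rect = None
    pos, neg = pts[v > 0], pts[v < 0]
    if len(pos) >= 2 and len(neg) >= 2:
        def _side_slope(sub: pd.DataFrame) -> float:
            vv = sub["voltage_mV"].to_numpy(float)
            ii = sub["mean_current_pA"].to_numpy(float)
            ww = sub["n_events"].to_numpy(float) if "n_events" in sub else np.ones_like(vv)
            b, _, _ = _wls(np.column_stack([np.ones_like(vv), vv]), ii, ww)
            return float(b[1])

        s_pos, s_neg = _side_slope(pos), _side_slope(neg)
        if s_neg != 0:
            rect = abs(s_pos) / abs(s_neg)

    return ConductanceFit(
        g_pS=slope * 1000.0,
        reversal_x_intercept_mV=-intercept / slope,
        fit_sd_pS=se * 1000.0,
        rectification_ratio=rect,
        quadratic_used=use_quad,
        n_points=int(len(pts)),
        n_events=int(w.sum()),
    )


@dataclass
class SaltScalingFit:
    """Linear model of unitary conductance vs salt concentration."""

    slope_pS_per_mM: float
    intercept_pS: float
    r_squared: float
    n_concentrations: int

    def summary(self) -> str:
        return (
            "Conductance vs [salt]\n"
            f"  slope    : {self.slope_pS_per_mM:.4f} pS/mM\n"
            f"  intercept: {self.intercept_pS:.2f} pS\n"
            f"  r^2      : {self.r_squared:.4f}  (n = {self.n_concentrations})"
        )


def conductance_vs_salt(
    fits: list[tuple[float, "ConductanceFit | float"]],
) -> SaltScalingFit:
    """Ordinary least squares of conductance on salt concentration (mM).

    Duplicate concentrations are averaged first; needs >= 3 distinct
    concentrations.  The line is not forced through the origin.
    """
    conc = np.array([c for c, _ in fits], dtype=float)
    g = np.array(
        [f.g_pS if isinstance(f, ConductanceFit) else float(f) for _, f in fits]
    )
    uniq = np.unique(conc)
    if uniq.size < 3:
        raise ValidationError(
            f"conductance-salt fit needs >= 3 distinct concentrations, got {uniq.size}"
        )
    g_mean = np.array([g[conc == c].mean() for c in uniq])
    res = stats.linregress(uniq, g_mean)
    return SaltScalingFit(
        slope_pS_per_mM=float(res.slope),
        intercept_pS=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_concentrations=int(uniq.size),
    )
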
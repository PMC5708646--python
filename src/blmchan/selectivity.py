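"""Sweep averaging, baseline subtraction, reversal potential and selectivity.

The drug-block workflow averages repeated voltage-step sweeps, builds a
capacitive/leak baseline from the *inactivated* sweeps (sweeps in which the
channel never opened), and subtracts it from the average of the active
sweeps.  Bi-ionic selectivity comes from ramp recordings: the reversal
potential E_rev is the x-intercept of the averaged ramp trace, and relative
permeabilities follow from GHK-type bi-ionic equations.

With monovalent X+ replacing Na+ on one side (concentrations in mol/l, E_rev
in volts)::

    P_Na/P_K  = ([Na+]_in / [K+]_in) * exp(-F*E_rev/(R*T))

and for the divalent bi-ionic condition (Ca2+ vs Na+)::

    P_Na/P_Ca = (4*[Ca2+]_out / [Na+]_in) * exp(F*E_rev/(R*T))
                * (1 + exp(F*E_rev/(R*T)))

Both are implemented exactly in this printed form; under the equal
150/150 mM bi-ionic setup the monovalent prefactor is 1, so the choice of
in/out subscripts in the prefactor has no numeric effect there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import Trace

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "IonCondition",
    "AveragedTrace",
    "SelectivityResult",
    "average_sweeps",
    "classify_inactivated",
    "baseline_from_inactivated",
    "corrected_average",
    "estimate_reversal",
    "permeability_na_k",
    "permeability_na_ca",
    "reversal_from_na_k",
    "reversal_from_na_ca",
]

FARADAY = 96485.3  # s*A/mol
GAS_CONSTANT = 8.314  # J/K/mol


@dataclass(frozen=True)
class IonCondition:
    """Ion concentrations (mM) and temperature (K) entering the GHK equations."""

    na_in_mM: float | None = None
    k_in_mM: float | None = None
    ca_out_mM: float | None = None
    temperature_K: float = 295.0

    def __post_init__(self) -> None:
        for name in ("na_in_mM", "k_in_mM", "ca_out_mM"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if not (273.0 <= self.temperature_K <= 320.0):
            raise ValidationError(
                f"temperature {self.temperature_K} K outside [273, 320]"
            )

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage RT/F in mV (~25.4 mV at 295 K)."""
        return 1000.0 * GAS_CONSTANT * self.temperature_K / FARADAY


@dataclass
class AveragedTrace:
    """Pointwise-averaged sweeps sharing one protocol."""

    trace: Trace
    n_sweeps: int
    baseline_source: str = "none"


@dataclass
class SelectivityResult:
    """Reversal potential and relative permeabilities for one condition."""

    e_rev_mV: float
    condition: IonCondition
    n_sweeps_averaged: int
    p_na_over_pk: float | None = None
    p_na_over_pca: float | None = None

    def summary(self) -> str:
        lines = [
            "Bi-ionic selectivity",
            f"  sweeps averaged : {self.n_sweeps_averaged}",
            f"  E_rev           : {self.e_rev_mV:+.2f} mV",
            f"  temperature     : {self.condition.temperature_K:.0f} K",
        ]
        if self.p_na_over_pk is not None:
            lines.append(f"  P_Na/P_K        : {self.p_na_over_pk:.3f}")
        if self.p_na_over_pca is not None:
            lines.append(f"  P_Na/P_Ca       : {self.p_na_over_pca:.3f}")
        return "\n".join(lines)


def _check_same_grid(sweeps: list[Trace]) -> None:
    first = sweeps[0]
    for i, s in enumerate(sweeps[1:], start=1):
        if s.n_samples != first.n_samples:
            raise ValidationError(
                f"sweep {i} length {s.n_samples} != {first.n_samples}"
            )
        if abs(s.sample_rate - first.sample_rate) > 1e-6 * first.sample_rate:
            raise ValidationError(f"sweep {i} sample rate differs")
        if not np.allclose(s.voltage, first.voltage, atol=1e-9):
            raise ValidationError(f"sweep {i} was recorded under a different protocol")


def average_sweeps(sweeps: list[Trace]) -> AveragedTrace:
    """Pointwise mean of >= 2 sweeps recorded under one protocol."""
    if len(sweeps) < 2:
        raise ValidationError("averaging needs >= 2 sweeps")
    _check_same_grid(sweeps)
    mean = np.mean([s.current for s in sweeps], axis=0)
    out = sweeps[0].replace(current=mean, label=f"average of {len(sweeps)} sweeps")
    return AveragedTrace(trace=out, n_sweeps=len(sweeps))


def _activation_window(trace: Trace) -> np.ndarray:
    """Samples at the most depolarized command voltage (the activating step)."""
    vmax = float(np.max(trace.voltage))
    return np.flatnonzero(np.abs(trace.voltage - vmax) < 1e-9)


def classify_inactivated(
    sweeps: list[Trace], classifier_threshold_pA: float
) -> np.ndarray:
    """Boolean mask of sweeps whose activating-step mean excess current is
    below the threshold (channel never opened)."""
    from .idealize import estimate_baseline

    mask = np.zeros(len(sweeps), dtype=bool)
    for i, sw in enumerate(sweeps):
        base, _ = estimate_baseline(sw)
        win = _activation_window(sw)
        excess = abs(float(np.mean(sw.current[win])) - base)
        mask[i] = excess < classifier_threshold_pA
    return mask


def baseline_from_inactivated(
    sweeps: list[Trace], classifier_threshold_pA: float
) -> AveragedTrace:
    """Average of the sweeps classified as inactivated (baseline source)."""
    if not sweeps:
        raise ValidationError("no sweeps supplied")
    _check_same_grid(sweeps)
    mask = classify_inactivated(sweeps, classifier_threshold_pA)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(
            "no sweep classified as inactivated; raise classifier_threshold_pA"
        )
    mean = np.mean([s.current for s, m in zip(sweeps, mask) if m], axis=0)
    out = sweeps[0].replace(current=mean, label=f"inactivated baseline (n={n})")
    return AveragedTrace(trace=out, n_sweeps=n, baseline_source="inactivated sweeps")


def corrected_average(
    active_sweeps: list[Trace], baseline: AveragedTrace
) -> AveragedTrace:
    """Mean of active sweeps minus the inactivated baseline, pointwise."""
    if not active_sweeps:
        raise ValidationError("no active sweeps supplied")
    _check_same_grid(active_sweeps)
    if active_sweeps[0].n_samples != baseline.trace.n_samples:
        raise ValidationError("baseline length does not match the sweeps")
    mean = np.mean([s.current for s in active_sweeps], axis=0) - baseline.trace.current
    out = active_sweeps[0].replace(
        current=mean, label=f"baseline-corrected average of {len(active_sweeps)} sweeps"
    )
    return AveragedTrace(
        trace=out,
        n_sweeps=len(active_sweeps),
        baseline_source=f"subtracted {baseline.baseline_source} (n={baseline.n_sweeps})",
    )


def _ramp_slice(trace: Trace) -> slice:
    """Longest contiguous stretch with a constant nonzero voltage increment."""
    dv = np.diff(trace.voltage)
    dv = np.round(dv, 9)
    best = (0, 0)
    i = 0
    n = dv.size
    while i < n:
        if dv[i] == 0:
            i += 1
            continue
        j = i
        while j < n and dv[j] == dv[i]:
            j += 1
        if j - i > best[1] - best[0]:
            best = (i, j)
        i = j
    if best[1] - best[0] < 10:
        raise ValidationError("no ramp segment found in the averaged trace")
    return slice(best[0], best[1] + 1)


def estimate_reversal(avg: AveragedTrace, window_mV: float = 20.0) -> float:
    """Reversal potential (mV) as the x-intercept of an averaged ramp trace.

    The current is binned by command voltage along the ramp, the zero
    crossing of the binned means located, and a straight line fitted to all
    samples within ±``window_mV`` of the crossing; E_rev = -intercept/slope.
    """
    trace = avg.trace
    sl = _ramp_slice(trace)
    v = trace.voltage[sl]
    c = trace.current[sl]
    # coarse crossing from 2 mV voltage bins
    nbins = max(int(np.ptp(v) / 2.0), 4)
    edges = np.linspace(v.min(), v.max(), nbins + 1)
    idx = np.clip(np.digitize(v, edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=c, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    means = sums / np.maximum(counts, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sign = np.sign(means)
    flips = np.flatnonzero(np.diff(sign) != 0)
    if flips.size == 0:
        raise ValidationError(
            "averaged ramp current does not change sign "
            f"(min {c.min():.3g} pA, max {c.max():.3g} pA)"
        )
    k = flips[0]
    m0, m1 = means[k], means[k + 1]
    v_cross = centers[k] if m1 == m0 else centers[k] + (0 - m0) * (
        centers[k + 1] - centers[k]
    ) / (m1 - m0)
    win = np.abs(v - v_cross) <= window_mV
    if win.sum() < 10:
        raise ValidationError("too few samples in the reversal fit window")
    slope, intercept = np.polyfit(v[win], c[win], 1)
    if slope == 0:
        raise ValidationError("zero slope in the reversal fit window")
    return float(-intercept / slope)


# ---------------------------------------------------------------------------
# GHK bi-ionic permeability ratios
# ---------------------------------------------------------------------------

def permeability_na_k(e_rev_mV: float, cond: IonCondition) -> float:
    """P_Na/P_K from a Na+(cis)/K+(trans) bi-ionic reversal potential."""
    if cond.na_in_mM is None or cond.k_in_mM is None:
        raise ValidationError("condition needs na_in_mM and k_in_mM")
    x = e_rev_mV / cond.rt_over_f_mV  # F*E_rev/(R*T)
    return (cond.na_in_mM / cond.k_in_mM) * math.exp(-x)


def permeability_na_ca(e_rev_mV: float, cond: IonCondition) -> float:
    """P_Na/P_Ca from a Na+(cis)/Ca2+(trans) bi-ionic reversal potential."""
    if cond.na_in_mM is None or cond.ca_out_mM is None:
        raise ValidationError("condition needs na_in_mM and ca_out_mM")
    x = e_rev_mV / cond.rt_over_f_mV
    ex = math.exp(x)
    return (4.0 * cond.ca_out_mM / cond.na_in_mM) * ex * (1.0 + ex)


def reversal_from_na_k(ratio: float, cond: IonCondition) -> float:
    """Invert the Na/K permeability equation: E_rev (mV) giving ``ratio``."""
    if ratio <= 0:
        raise ValidationError("permeability ratio must be positive")
    return -cond.rt_over_f_mV * math.log(ratio * cond.k_in_mM / cond.na_in_mM)


def reversal_from_na_ca(ratio: float, cond: IonCondition) -> float:
    """Invert the Na/Ca permeability equation (quadratic in exp(F*E/RT))."""
    if ratio <= 0:
        raise ValidationError("permeability ratio must be positive")
    a = 4.0 * cond.ca_out_mM / cond.na_in_mM
    # ratio = a * (u^2 + u) with u = exp(F*E/RT)  ->  positive root
    u = (-1.0 + math.sqrt(1.0 + 4.0 * ratio / a)) / 2.0
    return cond.rt_over_f_mV * math.log(u)
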
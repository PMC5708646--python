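"""Trace conditioning and event idealization.

Raw BLM recordings are low-pass Bessel filtered (hardware stage ~1 kHz at
acquisition; an additional digital pass at 0.1-1 kHz is standard before
analysis), a closed-channel baseline is estimated from the all-points
amplitude distribution, and openings are idealized by the half-amplitude
threshold criterion: an event opens when |current - baseline| crosses 50% of
the nominal event amplitude and closes when it re-crosses below.

The digital filter here is applied zero-phase (forward-backward) so event
boundaries are not biased by filter delay; the hardware stage it emulates is
single-pass causal, a deliberate deviation.  Events shorter than the filter
rise time are unresolvable, hence the default minimum event duration of
2 x (0.33/cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.mixture import GaussianMixture

from .exceptions import ValidationError
from .io import EVENT_COLUMNS, Trace, empty_events

__all__ = [
    "FilterSpec",
    "lowpass",
    "lowpass_array",
    "estimate_baseline",
    "detect_events",
    "default_min_duration",
]

logger = logging.getLogger(__name__)

#: Empirical 10-90% rise time of the low-pass stage, s (times 1/cutoff_Hz).
RISE_TIME_FACTOR = 0.33


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Bessel filter: cutoff in Hz, order 4 or 8 (default 8)."""

    cutoff_hz: float
    order: int = 8
    kind: str = "bessel"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValidationError("filter cutoff must be positive")
        if self.order not in (4, 8):
            raise ValidationError(f"filter order must be 4 or 8, got {self.order}")
        if self.kind != "bessel":
            raise ValidationError(f"unsupported filter kind {self.kind!r}")


def default_min_duration(cutoff_hz: float) -> float:
    """Shortest resolvable event duration after filtering, s."""
    return 2.0 * RISE_TIME_FACTOR / cutoff_hz


def _design_sos(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    if spec.cutoff_hz >= sample_rate / 2:
        raise ValidationError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {sample_rate / 2} Hz"
        )
    sos = signal.bessel(
        spec.order, spec.cutoff_hz, btype="low", output="sos", norm="mag", fs=sample_rate
    )
    # pin DC gain to exactly 1
    gain = 1.0
    for sec in sos:
        gain *= (sec[0] + sec[1] + sec[2]) / (sec[3] + sec[4] + sec[5])
    sos[0, :3] /= gain
    return sos


def lowpass_array(x: np.ndarray, spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Zero-phase Bessel low-pass of a raw sample array."""
    sos = _design_sos(spec, sample_rate)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def lowpass(trace: Trace, spec: FilterSpec) -> Trace:
    """Zero-phase low-pass filter a trace; DC gain is exactly 1."""
    filtered = lowpass_array(trace.current, spec, trace.sample_rate)
    return trace.replace(current=filtered, filter_cutoff=spec.cutoff_hz)


def estimate_baseline(trace: Trace, max_samples: int = 100_000) -> tuple[float, float]:
    """Estimate the closed-channel baseline level and noise SD, both in pA.

    The all-points amplitude distribution is split into two Gaussian
    components; the baseline is the dominant component nearest 0 pA (channel
    closed most of the time in single-channel records), its sigma the noise
    SD.  A constant trace degenerates to (constant, 0).
    """
    cur = np.asarray(trace.current, dtype=float)
    if cur.size < 100:
        raise ValidationError("baseline estimation needs >= 100 samples")
    if np.ptp(cur) == 0:
        return float(cur[0]), 0.0
    if cur.size > max_samples:
        stride = cur.size // max_samples + 1
        cur = cur[::stride]
    # anchor on the low-amplitude mode: among histogram peaks of comparable
    # height, the closed level is the one nearest 0 pA; the two-component
    # split is then restricted to its neighbourhood so higher conducting
    # levels cannot drag it
    nbins = min(1000, max(cur.size // 50, 10))
    counts, edges = np.histogram(cur, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = signal.find_peaks(
        np.concatenate(([0.0], counts.astype(float), [0.0])), height=0
    )
    peaks -= 1
    if peaks.size:
        heights = props["peak_heights"]
        strong = peaks[heights >= 0.25 * heights.max()]
        mode = float(centers[strong[np.argmin(np.abs(centers[strong]))]])
    else:
        mode = float(centers[np.argmax(counts)])
    sigma0 = 1.4826 * float(np.median(np.abs(cur - mode)))
    if sigma0 <= 0:
        near = cur[np.abs(cur - mode) <= max(np.ptp(cur) * 1e-9, 1e-12)]
        return float(np.mean(near)), 0.0
    window = cur[np.abs(cur - mode) <= 8.0 * sigma0]
    if window.size < 100:
        window = cur
    try:
        gm = GaussianMixture(n_components=2, random_state=0, n_init=1).fit(
            window[:, None]
        )
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.reshape(-1))
        weights = gm.weights_.ravel()
    except Exception:  # degenerate distributions
        return float(np.median(window)), float(np.std(window))
    if abs(means[0] - means[1]) < 2.0 * max(sds):
        # single population split in two: report the pooled moments
        return float(np.mean(window)), float(np.std(window))
    # dominant low-conductance component: prefer the one nearer 0 unless its
    # weight is negligible, then fall back to the largest-weight component
    order = np.argsort(np.abs(means))
    pick = order[0] if weights[order[0]] >= 0.25 else int(np.argmax(weights))
    sd = float(sds[pick])
    if sd < 1e-6:  # regularization floor on (near-)noiseless data
        sd = 0.0
    return float(means[pick]), sd


def detect_events(
    trace: Trace,
    baseline: float,
    threshold_amplitude: float,
    min_duration_s: float,
    baseline_sd: float | None = None,
    trace_id: str = "trace",
) -> pd.DataFrame:
    """Idealize a filtered trace into opening events (half-amplitude criterion).

    An event opens when |current - baseline| rises past 50% of
    ``threshold_amplitude`` and closes when it falls back below; the dead
    time ``min_duration_s`` is imposed symmetrically (closures shorter than
    it are bridged, events shorter than it discarded), and events spanning a
    command-voltage step are split at the boundary (amplitudes are
    voltage-dependent).  ``amplitude_pA`` is the mean of the enclosed samples
    minus the baseline; ``step_voltage_mV`` the command voltage during the
    event.
    """
    if threshold_amplitude <= 0:
        raise ValidationError("threshold_amplitude must be positive")
    if baseline_sd is not None and threshold_amplitude <= 3 * baseline_sd:
        logger.warning(
            "event threshold %.3g pA <= 3x baseline SD (%.3g pA): false events likely",
            threshold_amplitude,
            baseline_sd,
        )
    dev = trace.current - baseline
    above = np.abs(dev) >= 0.5 * threshold_amplitude
    if not above.any():
        return empty_events()
    flanked = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(flanked.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]

    rate = trace.sample_rate
    min_len = min_duration_s * rate - 0.5  # half-sample slack against fp jitter

    # dead time imposed symmetrically: gaps shorter than the minimum
    # resolvable duration are as unresolvable as events of that length, so
    # sub-resolution closures (mostly noise dips through the threshold) are
    # bridged rather than splitting one opening into fragments
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and (s - merged[-1][1]) < min_len:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # split runs at command-voltage boundaries
    vstep = np.flatnonzero(np.abs(np.diff(trace.voltage)) > 1e-12) + 1
    rows = []
    for s, e in merged:
        cuts = vstep[(vstep > s) & (vstep < e)]
        bounds = np.concatenate(([s], cuts, [e]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if (b - a) < min_len:
                continue
            rows.append(
                (
                    trace_id,
                    trace.time[a],
                    (b - a) / rate,
                    float(np.mean(trace.current[a:b])) - baseline,
                    float(trace.voltage[a]),
                    pd.NA,
                )
            )
    if not rows:
        return empty_events()
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    df["level"] = df["level"].astype("Int64")
    return df
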
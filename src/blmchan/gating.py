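"""All-points histogram, Gaussian mixture decomposition, open probability.

Every current sample of a trace enters an all-points amplitude histogram;
Gaussian components of a mixture fitted to the samples correspond to the
closed level and the conducting sub-states, and their weights to state
occupancies.  The probability p_a that at least one of N independent
channels is open is 1 minus the closed-component weight; the single-channel
open probability follows from the multi-channel correction

    p_o = 1 - (1 - p_a)**(1/N).

Model order (number of mixture components) is selected by BIC with seeded,
histogram-peak-based initialization for determinism.  A component counts as
conducting when its mean is more than 3 closed-component SDs away from the
closed mean; selected components failing that criterion are absorbed into
the closed component's weight so exactly one closed component remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .exceptions import FitError, ValidationError
from .idealize import estimate_baseline
from .io import Trace

__all__ = [
    "MixtureComponent",
    "HistogramModel",
    "OpenProbabilityResult",
    "all_points_histogram",
    "fit_mixture",
    "open_probability",
    "assign_event_levels",
    "count_conducting_levels",
    "merge_level_conductances",
    "estimate_channel_count",
    "default_bin_width",
]

logger = logging.getLogger(__name__)

#: Conducting criterion: distance from the closed mean in closed-SD units.
CONDUCTING_SD_FACTOR = 3.0
#: Relative tolerance when merging level conductances across traces.
LEVEL_MERGE_REL_TOL = 0.25


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_pA: float
    sd_pA: float
    role: str  # "closed" | "conducting"


@dataclass
class HistogramModel:
    """All-points amplitude histogram, optionally with fitted components."""

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[MixtureComponent] = field(default_factory=list)
    n_components_selected: int = 0
    baseline_pA: float = 0.0
    samples: np.ndarray | None = None  # raw samples retained for fitting

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def density(self) -> np.ndarray:
        """Probability density function: counts / (total * bin_width)."""
        total = self.counts.sum()
        return self.counts / (total * self.bin_width)

    @property
    def closed(self) -> MixtureComponent:
        closed = [c for c in self.components if c.role == "closed"]
        if len(closed) != 1:
            raise ValidationError("histogram model needs exactly one closed component")
        return closed[0]

    @property
    def conducting(self) -> list[MixtureComponent]:
        """Conducting components ordered by distance from the closed mean."""
        closed_mean = self.closed.mean_pA
        comps = [c for c in self.components if c.role == "conducting"]
        return sorted(comps, key=lambda c: abs(c.mean_pA - closed_mean))

    def summary(self) -> str:
        lines = [f"All-points histogram: {self.counts.sum():.0f} samples, "
                 f"{len(self.bin_edges) - 1} bins of {self.bin_width:.3g} pA"]
        for c in self.components:
            lines.append(
                f"  {c.role:>10}: weight {c.weight:.3f}, "
                f"mean {c.mean_pA:+.3f} pA, sd {c.sd_pA:.3f} pA"
            )
        return "\n".join(lines)


@dataclass
class OpenProbabilityResult:
    """Single-channel open probability with the multi-channel correction."""

    p_a: float
    p_o: float
    n_channels: int
    per_level_probability: dict[int, float]
    voltage_mV: float | None = None

    def summary(self) -> str:
        lines = [
            f"Open probability (N = {self.n_channels} channels)",
            f"  p_a (any open)  : {self.p_a:.4f}",
            f"  p_o (one channel): {self.p_o:.4f}",
        ]
        for lvl, p in self.per_level_probability.items():
            lines.append(f"  level {lvl} occupancy: {p:.4f}")
        return "\n".join(lines)


def default_bin_width(baseline_sd: float) -> float:
    """Histogram bin width: baseline_SD/5 with a 0.01 pA floor."""
    return max(baseline_sd / 5.0, 0.01)


def dominant_step_trace(trace: Trace) -> tuple[Trace, float]:
    """Longest contiguous stretch of a trace at its dominant command voltage.

    Amplitude histograms only admit a conductance interpretation at a single
    driving force, so step-protocol traces are decomposed per voltage; this
    returns the test-step portion (and its voltage), excluding holds whose
    samples (e.g. tail currents) would otherwise masquerade as extra levels.
    """
    vals, counts = np.unique(trace.voltage, return_counts=True)
    v = float(vals[np.argmax(counts)])
    mask = np.concatenate(([False], trace.voltage == v, [False]))
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    runs = list(zip(edges[0::2], edges[1::2]))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    sub = Trace(
        time=np.arange(e - s) / trace.sample_rate,
        current=trace.current[s:e],
        voltage=trace.voltage[s:e],
        sample_rate=trace.sample_rate,
        filter_cutoff=trace.filter_cutoff,
        label=trace.label,
    )
    return sub, v


def all_points_histogram(trace: Trace, bin_width: float) -> HistogramModel:
    """Histogram of every current sample over uniform bins spanning the range."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    cur = np.asarray(trace.current, dtype=float)
    if cur.size < 100:
        raise ValidationError("all-points histogram needs >= 100 samples")
    lo, hi = float(cur.min()), float(cur.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(cur, bins=edges)
    return HistogramModel(bin_edges=edges, counts=counts.astype(float), samples=cur)


def _peak_means_init(hist: HistogramModel, k: int) -> np.ndarray:
    """Deterministic initial means: top-k separated histogram peaks.

    The counts are lightly smoothed and peaks must be separated by at least
    5 bins so noise shoulders next to a tall mode do not crowd out genuine
    low-occupancy levels; missing peaks are padded with sample quantiles.
    """
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smoothed = np.convolve(hist.counts, kernel / kernel.sum(), mode="same")
    peaks, props = find_peaks(smoothed, height=0, distance=5)
    if peaks.size:
        order = np.argsort(props["peak_heights"])[::-1]
        means = list(centers[peaks[order[:k]]])
    else:
        means = []
    if len(means) < k:
        qs = np.quantile(hist.samples, np.linspace(0.05, 0.95, k - len(means)))
        means.extend(qs.tolist())
    return np.sort(np.array(means[:k]))[:, None]


def fit_mixture(
    hist: HistogramModel,
    max_components: int = 4,
    seed: int = 0,
    baseline: float | None = None,
    max_fit_samples: int = 40_000,
) -> HistogramModel:
    """Fit a Gaussian mixture to the raw samples and fill the components.

    BIC selects the number of components over 1..max_components.  The closed
    component is the one nearest the baseline (default: the dominant
    low-amplitude mode estimated from the samples); others are conducting if
    they clear the 3-sigma criterion, otherwise their weight is absorbed
    into the closed component.
    """
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    if hist.samples is None:
        raise ValidationError("histogram was built without retaining samples")
    samples = hist.samples
    if samples.size > max_fit_samples:
        rng = np.random.default_rng(seed)
        samples = rng.choice(samples, size=max_fit_samples, replace=False)
    X = samples[:, None]
    best = None
    best_bic = np.inf
    failures = []
    for k in range(1, max_components + 1):
        inits = [dict(means_init=_peak_means_init(hist, k)), dict(init_params="kmeans")]
        for init_kw in inits:
            try:
                gm = GaussianMixture(
                    n_components=k,
                    random_state=seed,
                    n_init=1,
                    reg_covar=1e-10,
                    max_iter=300,
                    **init_kw,
                ).fit(X)
                bic = gm.bic(X)
            except Exception as exc:  # pragma: no cover - diagnostics path
                failures.append(f"k={k}: {exc}")
                continue
            if bic < best_bic:
                best, best_bic = gm, bic
    if best is None:
        raise FitError(
            "Gaussian mixture failed at every component count: " + "; ".join(failures)
        )
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.reshape(-1))
    weights = best.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    if baseline is None:
        baseline = float(np.median(samples))
    closed_idx = int(np.argmin(np.abs(means - baseline)))
    closed_mean, closed_sd = means[closed_idx], sds[closed_idx]
    closed_weight = weights[closed_idx]
    comps: list[MixtureComponent] = []
    for i in range(means.size):
        if i == closed_idx:
            continue
        if abs(means[i] - closed_mean) > CONDUCTING_SD_FACTOR * max(closed_sd, 1e-12):
            comps.append(
                MixtureComponent(float(weights[i]), float(means[i]), float(sds[i]),
                                 "conducting")
            )
        else:  # indistinguishable from closed: absorb its weight
            closed_weight += weights[i]
    comps.append(
        MixtureComponent(float(closed_weight), float(closed_mean), float(closed_sd),
                         "closed")
    )
    comps.sort(key=lambda c: c.mean_pA)
    return replace(
        hist,
        components=comps,
        n_components_selected=int(means.size),
        baseline_pA=float(closed_mean),
    )


def open_probability(
    hist: HistogramModel, n_channels: int, voltage_mV: float | None = None
) -> OpenProbabilityResult:
    """Open probability from fitted mixture weights with the N-channel correction."""
    if n_channels < 1:
        raise ValidationError("n_channels must be >= 1")
    if not hist.components:
        raise ValidationError("fit_mixture must be run before open_probability")
    p_a = 1.0 - hist.closed.weight
    p_a = min(max(p_a, 0.0), 1.0)
    if p_a >= 1.0 and n_channels > 1:
        logger.warning("p_a = 1 with N = %d: p_o saturates at 1", n_channels)
        p_o = 1.0
    else:
        p_o = 1.0 - (1.0 - p_a) ** (1.0 / n_channels)
    per_level = {
        i + 1: c.weight for i, c in enumerate(hist.conducting)
    }
    return OpenProbabilityResult(
        p_a=float(p_a),
        p_o=float(p_o),
        n_channels=n_channels,
        per_level_probability=per_level,
        voltage_mV=voltage_mV,
    )


def assign_event_levels(events: pd.DataFrame, hist: HistogramModel) -> pd.DataFrame:
    """Assign each idealized event to the nearest conducting component.

    Event amplitudes are baseline-subtracted, so they are compared with
    component means relative to the closed mean.  Ties go to the lower
    level; events farther than 3 component SDs from every mean stay
    unassigned (level <NA>).
    """
    events = events.copy()
    conducting = hist.conducting if hist.components else []
    if not conducting:
        logger.warning("no conducting components: all events left unassigned")
        events["level"] = pd.array([pd.NA] * len(events), dtype="Int64")
        return events
    closed_mean = hist.closed.mean_pA
    deltas = np.array([c.mean_pA - closed_mean for c in conducting])
    sds = np.array([c.sd_pA for c in conducting])
    # conducting is ordered by |delta|, so argmin ties resolve to lower level
    levels = []
    for amp in events["amplitude_pA"].to_numpy(float):
        dist = np.abs(amp - deltas)
        j = int(np.argmin(dist))
        levels.append(j + 1 if dist[j] <= CONDUCTING_SD_FACTOR * sds[j] else pd.NA)
    events["level"] = pd.array(levels, dtype="Int64")
    return events


def is_transition_artifact(
    comp: MixtureComponent, closed: MixtureComponent, sd_ratio: float = 5.0
) -> bool:
    """True for broad components that model filter-smeared level transitions.

    A discrete conducting level is as narrow as the baseline noise; a
    component several times wider than the closed component captures the
    rise/fall samples between levels, not a level itself, and is excluded
    from level counting and conductance pooling.
    """
    return comp.sd_pA > sd_ratio * max(closed.sd_pA, 1e-12)


def merge_level_conductances(
    conductances: np.ndarray,
    weights: np.ndarray | None = None,
    rel_tol: float = LEVEL_MERGE_REL_TOL,
) -> list[tuple[float, float]]:
    """Greedy 1-d clustering of level conductances (pS).

    Sorted conductances join the current cluster while they are within
    ``rel_tol`` of its weighted mean.  Returns (mean conductance, total
    weight) per cluster, ascending.
    """
    conductances = np.asarray(conductances, dtype=float)
    if weights is None:
        weights = np.ones_like(conductances)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(conductances)
    clusters: list[tuple[float, float]] = []
    for g, w in zip(conductances[order], weights[order]):
        if clusters:
            mean, wsum = clusters[-1]
            if abs(g - mean) <= rel_tol * mean:
                new_w = wsum + w
                clusters[-1] = ((mean * wsum + g * w) / new_w, new_w)
                continue
        clusters.append((float(g), float(w)))
    return clusters


def count_conducting_levels(
    traces: list[Trace],
    max_components: int = 4,
    seed: int = 0,
    e_rev_mV: float = 0.0,
    min_voltage_mV: float = 5.0,
) -> int:
    """Count distinct conducting levels across traces at activating voltages.

    Each trace is decomposed by :func:`fit_mixture`; component conductances
    (mean current relative to closed, divided by the driving voltage of the
    trace's dominant command step) are merged across traces by greedy
    clustering at 25% relative tolerance.
    """
    if not traces:
        raise ValidationError("count_conducting_levels needs >= 1 trace")
    gs: list[float] = []
    ws: list[float] = []
    for i, tr in enumerate(traces):
        step, v = dominant_step_trace(tr)
        if abs(v - e_rev_mV) < min_voltage_mV:
            continue  # driving force too small to resolve conductance
        base, base_sd = estimate_baseline(step)
        hist = all_points_histogram(step, default_bin_width(base_sd))
        fitted = fit_mixture(hist, max_components=max_components, seed=seed + i,
                             baseline=base)
        for c in fitted.conducting:
            if is_transition_artifact(c, fitted.closed):
                continue
            gs.append((c.mean_pA - fitted.closed.mean_pA) / (v - e_rev_mV) * 1000.0)
            ws.append(c.weight)
    if not gs:
        return 0
    gs_arr = np.abs(np.array(gs))
    clusters = merge_level_conductances(gs_arr, np.array(ws))
    return len(clusters)


def estimate_channel_count(
    trace: Trace,
    baseline: float,
    unitary_current_pA: float,
    quantile: float = 0.999,
) -> int:
    """Heuristic channel count: deepest observed stacking of unitary openings.

    Takes a high quantile of |current - baseline| (robust to filtered noise
    spikes) and divides by the unitary open-channel current.
    """
    if unitary_current_pA <= 0:
        raise ValidationError("unitary_current_pA must be positive")
    dev = np.abs(trace.current - baseline)
    peak = float(np.quantile(dev, quantile))
    return max(1, int(round(peak / unitary_current_pA)))
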
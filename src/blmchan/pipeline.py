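"""End-to-end workflows wiring simulate -> idealize -> gating -> iv -> selectivity.

Two canonical workflows are provided as library functions (the CLI wraps
them):

* :func:`sublevel_conductance_pipeline` - the single-channel step-protocol
  experiment: simulate a voltage-step series, low-pass filter, idealize into
  events, decompose each trace's all-points histogram into Gaussian levels,
  pool level conductances across traces, and fit a per-level zero-voltage-
  slope conductance.
* :func:`bi_ionic_pipeline` - the bi-ionic ramp experiment: simulate ramp
  sweeps, average, take the x-intercept as the reversal potential, and apply
  the GHK bi-ionic equations.

:func:`run_pipeline` executes a config-driven demo run and writes a manifest
(inputs, parameters, seeds, output hashes) so re-running an identical config
reproduces outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .exceptions import ValidationError
from .gating import (
    all_points_histogram,
    assign_event_levels,
    default_bin_width,
    dominant_step_trace,
    fit_mixture,
    is_transition_artifact,
    merge_level_conductances,
    open_probability,
)
from .idealize import default_min_duration, detect_events, estimate_baseline
from .io import (
    Segment,
    Trace,
    VoltageProtocol,
    write_events,
    write_trace,
)
from .iv import ConductanceFit, IVDataset, build_iv, fit_conductance
from .selectivity import (
    IonCondition,
    SelectivityResult,
    average_sweeps,
    estimate_reversal,
    permeability_na_ca,
    permeability_na_k,
)
from .sim import (
    DEFAULT_FILTER_CUTOFF,
    DEFAULT_SAMPLE_RATE,
    ChannelModel,
    Fixture,
    make_fixture,
    simulate_bi_ionic_ramp,
    simulate_experiment,
)

__all__ = [
    "fig4a_protocol",
    "fig2a_protocol",
    "bi_ionic_ramp_protocol",
    "SublevelAnalysis",
    "analyze_traces",
    "sublevel_conductance_pipeline",
    "bi_ionic_pipeline",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Seed stride between voltage steps of one experiment (repeats use +r).
VOLTAGE_SEED_STRIDE = 1000


def fig4a_protocol(step_mV: float, repeats: int = 5,
                   hold_s: float = 0.2, step_s: float = 10.0) -> VoltageProtocol:
    """Single-channel step protocol: hold -80 mV, step, return to -80 mV."""
    return VoltageProtocol(
        segments=(
            Segment("hold", -80.0, hold_s),
            Segment("step", step_mV, step_s),
            Segment("hold", -80.0, hold_s),
        ),
        repeats=repeats,
    )


def fig2a_protocol(step_mV: float, hold_s: float = 5.0,
                   step_s: float = 5.0) -> VoltageProtocol:
    """Macroscopic step protocol: hold -120 mV 5 s, 5 s step."""
    return VoltageProtocol(
        segments=(Segment("hold", -120.0, hold_s), Segment("step", step_mV, step_s)),
        repeats=1,
    )


def bi_ionic_ramp_protocol(start_mV: float = -100.0, end_mV: float = 100.0,
                           speed_mV_per_s: float = 100.0) -> VoltageProtocol:
    """Voltage ramp swept at ``speed_mV_per_s`` (default -100..+100 mV, 2 s)."""
    duration = abs(end_mV - start_mV) / speed_mV_per_s
    return VoltageProtocol(
        segments=(Segment("ramp", start_mV, duration, end_mV=end_mV),), repeats=1
    )


# ---------------------------------------------------------------------------
# sub-conductance-level workflow
# ---------------------------------------------------------------------------

@dataclass
class SublevelAnalysis:
    """Pooled results of the step-protocol single-channel workflow."""

    events: pd.DataFrame
    level_conductances_pS: list[float]
    level_centers_pS: list[float]  # merged cluster centers (pre-fit estimate)
    level_fits: dict[int, ConductanceFit]
    iv: IVDataset
    open_probability_by_voltage: dict[float, float]
    n_traces: int

    @property
    def n_levels(self) -> int:
        return len(self.level_conductances_pS)

    def summary(self) -> str:
        lines = [
            f"Sub-conductance analysis: {self.n_traces} traces, "
            f"{len(self.events)} events, {self.n_levels} levels"
        ]
        for lvl, fit in sorted(self.level_fits.items()):
            lines.append(
                f"  level {lvl}: g = {fit.g_pS:6.1f} +/- {fit.fit_sd_pS:.1f} pS "
                f"({fit.n_events} events)"
            )
        return "\n".join(lines)


def _trace_step_voltage(trace: Trace) -> float:
    vals, counts = np.unique(trace.voltage, return_counts=True)
    return float(vals[np.argmax(counts)])


def analyze_traces(
    traces: list[Trace],
    n_channels: int = 1,
    seed: int = 0,
    threshold_sd_factor: float = 6.0,
    min_duration_s: float | None = None,
    min_events_per_voltage: int = 5,
    min_cluster_voltage_mV: float = 20.0,
    min_cluster_events: int = 5,
    max_components: int = 4,
    e_rev_mV: float = 0.0,
) -> SublevelAnalysis:
    """Idealize, level-assign and pool a set of step-protocol traces.

    Per trace: estimate the closed baseline, detect events against it (at
    ``threshold_sd_factor`` baseline SDs), fit the all-points Gaussian
    mixture, and assign events to the trace's conducting components.
    Component conductances from traces with a driving force of at least
    ``min_cluster_voltage_mV`` and at least ``min_cluster_events`` assigned
    events define the global levels (greedy merge at 25% relative tolerance,
    weighted by assigned events); events are mapped through their component
    to a global level and pooled into per-level I-V points.

    I-V points whose expected unitary current (level conductance times
    driving voltage) falls below the detection threshold are dropped before
    fitting: events there are threshold-truncated, so their mean amplitude
    is biased.
    """
    if not traces:
        raise ValidationError("no traces supplied")
    all_events = []
    comp_records = []  # (trace_idx, comp_idx, conductance, n_events)
    thresholds: list[float] = []
    p_by_voltage: dict[float, list[float]] = {}
    for ti, tr in enumerate(traces):
        cutoff = tr.filter_cutoff or DEFAULT_FILTER_CUTOFF
        min_dur = min_duration_s if min_duration_s is not None else default_min_duration(cutoff)
        base, base_sd = estimate_baseline(tr)
        threshold = max(threshold_sd_factor * base_sd, 0.05)
        thresholds.append(threshold)
        events = detect_events(
            tr, base, threshold, min_dur, baseline_sd=base_sd, trace_id=f"trace{ti}"
        )
        v_step = _trace_step_voltage(tr)
        # keep only events during the test step: openings persisting into the
        # return-to-hold segment ride on the filter transient of a large
        # voltage jump and their amplitudes are unreliable (tail currents)
        events = events[events["step_voltage_mV"] == v_step].reset_index(drop=True)
        if len(events) == 0:
            continue
        # mixture on the test-step samples only: one driving force per fit
        step_tr, _ = dominant_step_trace(tr)
        hist = all_points_histogram(step_tr, default_bin_width(base_sd))
        fitted = fit_mixture(hist, max_components=max_components, seed=seed + ti,
                             baseline=base)
        events = assign_event_levels(events, fitted)
        pr = open_probability(fitted, n_channels, voltage_mV=v_step)
        p_by_voltage.setdefault(v_step, []).append(pr.p_o)
        conducting = fitted.conducting
        closed_mean = fitted.closed.mean_pA
        events["component"] = events["level"]
        events["trace_idx"] = ti
        all_events.append(events)
        if abs(v_step - e_rev_mV) >= min_cluster_voltage_mV:
            counts = events["level"].value_counts()
            for ci, comp in enumerate(conducting, start=1):
                n_ev = int(counts.get(ci, 0))
                if n_ev < min_cluster_events or is_transition_artifact(
                    comp, fitted.closed
                ):
                    continue
                g = abs((comp.mean_pA - closed_mean) / (v_step - e_rev_mV) * 1000.0)
                comp_records.append((ti, ci, g, n_ev))

    if not all_events or not comp_records:
        raise ValidationError(
            "no events detected at clustering voltages; nothing to analyze"
        )
    events = pd.concat(all_events, ignore_index=True)

    gs = np.array([r[2] for r in comp_records])
    ws = np.array([r[3] for r in comp_records], dtype=float)
    clusters = merge_level_conductances(gs, ws)
    centers = np.array([c[0] for c in clusters])

    # map every trace component (any voltage) to the nearest global level
    comp_to_level: dict[tuple[int, int], int] = {}
    for ti, ci, g, _ in comp_records:
        j = int(np.argmin(np.abs(centers - g)))
        comp_to_level[(ti, ci)] = j + 1
    # components from low-driving-force traces: match via absolute current at
    # each cluster's expected amplitude
    for ti, tr in enumerate(traces):
        v_step = _trace_step_voltage(tr)
        sub = events[events["trace_idx"] == ti]
        for ci in sub["component"].dropna().unique():
            key = (ti, int(ci))
            if key in comp_to_level:
                continue
            amp = sub.loc[sub["component"] == ci, "amplitude_pA"].mean()
            expected = centers * (v_step - e_rev_mV) / 1000.0
            j = int(np.argmin(np.abs(np.abs(amp) - np.abs(expected))))
            comp_to_level[key] = j + 1

    events["level"] = pd.array(
        [
            comp_to_level.get((ti, int(ci)), pd.NA) if pd.notna(ci) else pd.NA
            for ti, ci in zip(events["trace_idx"], events["component"])
        ],
        dtype="Int64",
    )
    events = events.drop(columns=["component", "trace_idx"])

    iv = build_iv(events, min_events_per_voltage=min_events_per_voltage)
    # resolvability filter: keep points where the expected unitary current
    # clears the (median) detection threshold with a 30% margin; points at
    # the threshold itself are dominated by partially resolved, selection-
    # biased events
    min_resolvable_pA = 1.3 * float(np.median(thresholds))
    pts = iv.points
    expected = np.array(
        [
            centers[int(lvl) - 1] * abs(v - e_rev_mV) / 1000.0
            for lvl, v in zip(pts["level"], pts["voltage_mV"])
        ]
    )
    iv = IVDataset(
        points=pts[expected >= min_resolvable_pA].reset_index(drop=True),
        condition_label=iv.condition_label,
    )
    level_fits: dict[int, ConductanceFit] = {}
    for lvl in sorted(iv.points["level"].unique()):
        sub = iv.for_level(int(lvl))
        if len(sub.points) >= 2:
            level_fits[int(lvl)] = fit_conductance(sub)
    level_g = [level_fits[l].g_pS for l in sorted(level_fits)]
    p_mean = {v: float(np.mean(ps)) for v, ps in sorted(p_by_voltage.items())}
    return SublevelAnalysis(
        events=events,
        level_centers_pS=[float(c) for c in centers],
        level_conductances_pS=level_g,
        level_fits=level_fits,
        iv=iv,
        open_probability_by_voltage=p_mean,
        n_traces=len(traces),
    )


def sublevel_conductance_pipeline(
    model: ChannelModel,
    voltages_mV: list[float],
    seed: int,
    repeats: int = 5,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    filter_cutoff: float = DEFAULT_FILTER_CUTOFF,
    **analyze_kwargs,
) -> SublevelAnalysis:
    """Simulate the step-protocol experiment and run the full analysis.

    Voltage step i uses base seed ``seed + i * VOLTAGE_SEED_STRIDE`` (its
    repeats add +r as documented by the simulator).
    """
    traces: list[Trace] = []
    for i, v in enumerate(voltages_mV):
        protocol = fig4a_protocol(v, repeats=repeats)
        traces.extend(
            simulate_experiment(
                model,
                protocol,
                seed=seed + i * VOLTAGE_SEED_STRIDE,
                sample_rate=sample_rate,
                filter_cutoff=filter_cutoff,
                label=f"step {v:+.0f} mV",
            )
        )
    n_ch = getattr(model, "n_channels", 1)
    return analyze_traces(traces, n_channels=n_ch, seed=seed, **analyze_kwargs)


# ---------------------------------------------------------------------------
# bi-ionic workflow
# ---------------------------------------------------------------------------

def bi_ionic_pipeline(
    fixture: Fixture,
    condition_key: str,
    seed: int,
    n_sweeps: int = 100,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    window_mV: float = 20.0,
    temperature_K: float = 295.0,
) -> SelectivityResult:
    """Simulate bi-ionic ramp sweeps, average, and estimate selectivity."""
    if condition_key not in fixture.conditions:
        raise ValidationError(
            f"fixture {fixture.name!r} has no condition {condition_key!r}; "
            f"available: {sorted(fixture.conditions)}"
        )
    cond = fixture.conditions[condition_key]
    model = fixture.ramp_model or fixture.model
    sweeps = simulate_bi_ionic_ramp(
        model, cond, bi_ionic_ramp_protocol(), n_sweeps, seed, sample_rate=sample_rate
    )
    avg = average_sweeps(sweeps)
    e_rev = estimate_reversal(avg, window_mV=window_mV)
    ion = IonCondition(
        na_in_mM=cond.cis_mM,
        k_in_mM=cond.trans_mM if cond.trans_ion == "K" else None,
        ca_out_mM=cond.trans_mM if cond.trans_ion == "Ca" else None,
        temperature_K=temperature_K,
    )
    result = SelectivityResult(
        e_rev_mV=e_rev, condition=ion, n_sweeps_averaged=avg.n_sweeps
    )
    if cond.trans_ion == "K":
        result.p_na_over_pk = permeability_na_k(e_rev, ion)
    elif cond.trans_ion == "Ca":
        result.p_na_over_pca = permeability_na_ca(e_rev, ion)
    return result


# ---------------------------------------------------------------------------
# config-driven demo run with manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute a config-driven demo run; returns (and writes) the manifest.

    Config keys: ``fixture`` (name), ``voltages_mV``, ``repeats``, ``seed``,
    ``sample_rate``, ``filter_cutoff``, optional ``step_s`` (step duration),
    optional ``selectivity`` (bool).  Outputs: per-voltage trace CSVs (first
    repeat only, as a browsable sample), ``events.tsv``, ``gating.tsv``,
    ``iv.tsv``, optional ``selectivity.tsv``, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config, "version": _version, "outputs": {}}
    failed_marker = out / "FAILED"
    try:
        fixture = make_fixture(config.get("fixture", "nachbac_default"))
        seed = int(config.get("seed", 0))
        voltages = [float(v) for v in config.get("voltages_mV", [35.0])]
        repeats = int(config.get("repeats", 5))
        rate = float(config.get("sample_rate", DEFAULT_SAMPLE_RATE))
        cutoff = float(config.get("filter_cutoff", DEFAULT_FILTER_CUTOFF))
        step_s = float(config.get("step_s", 10.0))

        traces = []
        for i, v in enumerate(voltages):
            protocol = fig4a_protocol(v, repeats=repeats, step_s=step_s)
            ts = simulate_experiment(
                fixture.model, protocol, seed=seed + i * VOLTAGE_SEED_STRIDE,
                sample_rate=rate, filter_cutoff=cutoff, label=f"step {v:+.0f} mV",
            )
            traces.extend(ts)
            sample_path = out / f"trace_{v:+.0f}mV_rep0.csv"
            write_trace(ts[0], sample_path)
            manifest["outputs"][sample_path.name] = None

        analysis = analyze_traces(traces, n_channels=fixture.model.n_channels,
                                  seed=seed)
        write_events(analysis.events, out / "events.tsv")
        manifest["outputs"]["events.tsv"] = None

        gating_rows = [
            {"step_voltage_mV": v, "p_open": p}
            for v, p in analysis.open_probability_by_voltage.items()
        ]
        pd.DataFrame(gating_rows).to_csv(out / "gating.tsv", sep="\t", index=False,
                                         float_format="%.6g")
        manifest["outputs"]["gating.tsv"] = None

        analysis.iv.points.to_csv(out / "iv.tsv", sep="\t", index=False,
                                  float_format="%.6g")
        manifest["outputs"]["iv.tsv"] = None
        levels = analysis.level_conductances_pS or analysis.level_centers_pS
        manifest["levels_pS"] = [round(g, 3) for g in levels]

        if config.get("selectivity", False):
            rows = []
            for key in sorted(fixture.conditions):
                res = bi_ionic_pipeline(fixture, key, seed=seed,
                                        n_sweeps=int(config.get("n_sweeps", 100)),
                                        sample_rate=rate)
                rows.append(
                    {
                        "condition": key,
                        "e_rev_mV": round(res.e_rev_mV, 4),
                        "p_na_over_pk": res.p_na_over_pk,
                        "p_na_over_pca": res.p_na_over_pca,
                        "n_sweeps": res.n_sweeps_averaged,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "selectivity.tsv", sep="\t", index=False)
            manifest["outputs"]["selectivity.tsv"] = None
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if failed_marker.exists():
        failed_marker.unlink()
    for name in manifest["outputs"]:
        manifest["outputs"][name] = _sha256(out / name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
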
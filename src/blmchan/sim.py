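"""Stochastic Markov gating simulator for NaChBac-like channels.

The channel is a discrete-time Markov chain at the sampling interval
dt = 1/sample_rate with one closed state and L conducting sub-states.  Per
step, a closed channel opens to level l with probability
k_open[l] * B(V) * dt, where B(V) = 1/(1 + exp(-(V - v_half)/slope)) is a
Boltzmann factor on the opening rates only (activation is voltage-dependent
mainly through the opening probability; closing rates are voltage-
independent).  An open channel closes with k_close[l] * dt, and may hop
directly between levels at a small optional ``inter_level_rate`` (default 0:
level switches are closed-mediated, matching the observation that most
openings start from the closed state, with direct level-to-level transitions
being rare).

Open-channel current is ohmic per level, g_l * (V - E_rev,l) / 1000 pA, with
white Gaussian noise added before the same zero-phase Bessel low-pass used by
the analysis.  GHK rectification of the open-channel I-V is not simulated.

Dwell times are sampled exactly (geometric per state, thinning where the
opening hazard varies along a voltage ramp), which is equivalent in
distribution to stepping the chain sample by sample but costs O(#events).
A validity guard rejects any k*dt > 0.1.

Seed contract: ``simulate_experiment``/``simulate_bi_ionic_ramp`` derive the
gating seed of repeat/sweep r as ``seed + r`` and the noise seed as
``seed + r + 1_000_003``; identical inputs and seed give bit-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import FormatError, ValidationError
from .idealize import FilterSpec, lowpass_array
from .io import Segment, Trace, VoltageProtocol, render_protocol
from .selectivity import IonCondition, reversal_from_na_ca, reversal_from_na_k

__all__ = [
    "SubLevel",
    "ChannelModel",
    "BiIonicCondition",
    "Fixture",
    "simulate_gating",
    "render_current",
    "simulate_experiment",
    "simulate_bi_ionic_ramp",
    "make_fixture",
    "stationary_distribution",
    "read_channel_model",
    "write_channel_model",
    "NOISE_SEED_OFFSET",
]

NOISE_SEED_OFFSET = 1_000_003
DEFAULT_SAMPLE_RATE = 12_500.0  # Hz
DEFAULT_FILTER_CUTOFF = 1_000.0  # Hz

#: Sub-state conductances reported for full-length NaChBac in 150/150 mM NaCl.
NACHBAC_CONDUCTANCES_PS = (26.0, 93.0, 268.0)
NACHBAC_CONDUCTANCE_SEMS_PS = (6.0, 18.0, 45.0)


@dataclass(frozen=True)
class SubLevel:
    """One conducting sub-state: ohmic conductance and reversal potential."""

    name: str
    conductance_pS: float
    reversal_mV: float = 0.0


@dataclass(frozen=True)
class ChannelModel:
    """Markov gating model: closed state + conducting sub-states.

    ``k_open`` are opening rates (1/s) at saturating depolarization, scaled
    by the Boltzmann factor B(V); ``k_close`` are voltage-independent closing
    rates (1/s).  ``noise_sd_pA`` is pre-filter white Gaussian noise.
    """

    levels: tuple[SubLevel, ...]
    k_open: tuple[float, ...]
    k_close: tuple[float, ...]
    v_half_mV: float
    slope_mV: float
    noise_sd_pA: float = 0.0
    n_channels: int = 1
    inter_level_rate: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "k_open", tuple(float(k) for k in self.k_open))
        object.__setattr__(self, "k_close", tuple(float(k) for k in self.k_close))
        g = [lv.conductance_pS for lv in self.levels]
        if len(g) == 0:
            raise ValidationError("model needs at least one conducting level")
        if any(x <= 0 for x in g) or any(b <= a for a, b in zip(g, g[1:])):
            raise ValidationError(
                f"conductances must be strictly positive and increasing, got {g}"
            )
        if len(self.k_open) != len(g) or len(self.k_close) != len(g):
            raise ValidationError("k_open/k_close must have one rate per level")
        if any(k < 0 for k in self.k_open + self.k_close) or self.inter_level_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.slope_mV == 0:
            raise ValidationError("Boltzmann slope must be nonzero")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.noise_sd_pA < 0:
            raise ValidationError("noise_sd_pA must be >= 0")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def boltzmann(self, voltage_mV: np.ndarray | float) -> np.ndarray | float:
        """Voltage-dependent opening factor B(V) in (0, 1)."""
        return 1.0 / (1.0 + np.exp(-(voltage_mV - self.v_half_mV) / self.slope_mV))

    def with_reversal(self, e_rev_mV: float) -> "ChannelModel":
        levels = tuple(
            dataclasses.replace(lv, reversal_mV=e_rev_mV) for lv in self.levels
        )
        return dataclasses.replace(self, levels=levels)

    def silenced(self) -> "ChannelModel":
        """Copy with all opening rates set to 0 (never opens)."""
        return dataclasses.replace(self, k_open=tuple(0.0 for _ in self.k_open))


@dataclass(frozen=True)
class BiIonicCondition:
    """Bi-ionic chamber composition and the simulator's true reversal potential."""

    cis_ion: str
    cis_mM: float
    trans_ion: str
    trans_mM: float
    true_reversal_mV: float

    def __post_init__(self) -> None:
        if self.cis_mM <= 0 or self.trans_mM <= 0:
            raise ValidationError("ion concentrations must be positive")


@dataclass(frozen=True)
class Fixture:
    """A named channel model plus its bi-ionic test conditions.

    ``ramp_model`` is the gating variant used for bi-ionic ramp recordings;
    for the NaChBac fixture it is effectively voltage-independent, since the
    bi-ionic recordings show gating that is not suppressed at negative
    voltages.
    """

    name: str
    model: ChannelModel
    conditions: dict[str, BiIonicCondition] = field(default_factory=dict)
    ramp_model: ChannelModel | None = None


# ---------------------------------------------------------------------------
# gating simulation
# ---------------------------------------------------------------------------

def _check_dt_validity(model: ChannelModel, dt: float) -> None:
    ks = list(model.k_open) + list(model.k_close) + [model.inter_level_rate]
    worst = max(ks) * dt
    if worst > 0.1:
        raise ValidationError(
            f"k*dt = {worst:.3g} > 0.1: increase the sample rate for this model"
        )


def _simulate_one_channel(
    path: np.ndarray,
    p_open: np.ndarray,
    q_closed: np.ndarray,
    q_max: float,
    p_exit_open: np.ndarray,
    close_weight: np.ndarray,
    n_levels: int,
    rng: np.random.Generator,
) -> None:
    """Fill one column of the state path in place (0 = closed, 1..L = level)."""
    n = q_closed.size
    t = 0
    state = 0
    while t < n:
        if state == 0:
            if q_max <= 0:
                return  # closed forever (path already zeroed)
            tc = t
            while True:
                tc += rng.geometric(q_max)
                if tc >= n:
                    return
                if rng.random() * q_max < q_closed[tc]:
                    break
            # transition happens at sample tc; pick the destination level
            w = p_open[tc]
            u = rng.random() * q_closed[tc]
            state = int(np.searchsorted(np.cumsum(w), u, side="right")) + 1
            state = min(state, n_levels)
            t = tc
        else:
            qe = p_exit_open[state - 1]
            if qe <= 0:
                path[t:] = state
                return
            dwell = rng.geometric(qe)
            end = min(t + dwell, n)
            path[t:end] = state
            t = end
            if t >= n:
                return
            # closing vs direct level switch
            if rng.random() < close_weight[state - 1]:
                state = 0
            else:
                others = [l for l in range(1, n_levels + 1) if l != state]
                state = others[rng.integers(len(others))]


def simulate_gating(
    model: ChannelModel,
    voltage: np.ndarray,
    sample_rate: float,
    seed: int,
) -> np.ndarray:
    """Simulate the gating chain under a command-voltage series.

    Returns the state path, shape (n_samples, n_channels), int8; 0 = closed,
    1..L = conducting level.  Reproducible: identical inputs + seed give an
    identical path.
    """
    voltage = np.asarray(voltage, dtype=float)
    if voltage.ndim != 1 or voltage.size < 2:
        raise ValidationError("voltage series must be 1-d with >= 2 samples")
    dt = 1.0 / sample_rate
    _check_dt_validity(model, dt)
    L = model.n_levels
    B = np.asarray(model.boltzmann(voltage), dtype=float)
    k_open = np.array(model.k_open)
    p_open = B[:, None] * k_open[None, :] * dt  # (n, L)
    q_closed = p_open.sum(axis=1)
    q_max = float(q_closed.max())
    inter = model.inter_level_rate
    exit_rates = np.array(model.k_close) + inter * (L - 1)
    p_exit_open = exit_rates * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        close_weight = np.where(
            exit_rates > 0, np.array(model.k_close) / exit_rates, 1.0
        )
    rng = np.random.default_rng(seed)
    path = np.zeros((voltage.size, model.n_channels), dtype=np.int8)
    for ch in range(model.n_channels):
        _simulate_one_channel(
            path[:, ch], p_open, q_closed, q_max, p_exit_open, close_weight, L, rng
        )
    return path


def stationary_distribution(model: ChannelModel, voltage_mV: float, dt: float) -> np.ndarray:
    """Stationary occupancy of the per-step transition matrix (oracle by
    linear algebra, independent of the stochastic path)."""
    L = model.n_levels
    B = float(model.boltzmann(voltage_mV))
    P = np.zeros((L + 1, L + 1))
    for l in range(1, L + 1):
        P[0, l] = model.k_open[l - 1] * B * dt
        P[l, 0] = model.k_close[l - 1] * dt
        for m in range(1, L + 1):
            if m != l:
                P[l, m] = model.inter_level_rate * dt
    np.fill_diagonal(P, 0)
    np.fill_diagonal(P, 1 - P.sum(axis=1))
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# current rendering
# ---------------------------------------------------------------------------

def render_current(
    path: np.ndarray,
    model: ChannelModel,
    voltage: np.ndarray,
    noise_sd: float,
    filter_cutoff: float | None,
    sample_rate: float,
    seed: int,
    label: str = "",
) -> Trace:
    """Render a state path to a current trace (pA).

    Per sample, summed over channel copies: g_level * (V - E_rev,level)/1000,
    plus white Gaussian noise (SD ``noise_sd`` pA) and the zero-phase Bessel
    low-pass at ``filter_cutoff`` (None = unfiltered).
    """
    path = np.asarray(path)
    if path.ndim == 1:
        path = path[:, None]
    voltage = np.asarray(voltage, dtype=float)
    if path.shape[0] != voltage.size:
        raise ValidationError("state path and voltage series differ in length")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    g = np.concatenate(([0.0], [lv.conductance_pS for lv in model.levels]))
    e = np.concatenate(([0.0], [lv.reversal_mV for lv in model.levels]))
    current = np.zeros(voltage.size)
    for ch in range(path.shape[1]):
        st = path[:, ch]
        current += g[st] * (voltage - e[st]) / 1000.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    if filter_cutoff is not None:
        current = lowpass_array(current, FilterSpec(filter_cutoff), sample_rate)
    meta = (
        f"{label + ' ' if label else ''}seed={seed} noise_sd={noise_sd} "
        f"cutoff={filter_cutoff} n_channels={path.shape[1]}"
    )
    return Trace(
        time=np.arange(voltage.size) / sample_rate,
        current=current,
        voltage=voltage,
        sample_rate=sample_rate,
        filter_cutoff=filter_cutoff,
        label=meta,
    )


def simulate_experiment(
    model: ChannelModel,
    protocol: VoltageProtocol,
    seed: int,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    filter_cutoff: float | None = DEFAULT_FILTER_CUTOFF,
    p_null: float = 0.0,
    label: str = "",
) -> list[Trace]:
    """Simulate one trace per protocol repeat.

    Repeat r uses gating seed ``seed + r`` and noise seed
    ``seed + r + NOISE_SEED_OFFSET``.  With probability ``p_null`` a repeat
    is an *inactivated* sweep: its opening rates are zeroed (the channel
    never opens), emulating the null sweeps used as the baseline source in
    the drug-block workflow; such traces are tagged ``inactivated=True`` in
    their label.
    """
    if not 0.0 <= p_null <= 1.0:
        raise ValidationError("p_null must be in [0, 1]")
    voltage = render_protocol(protocol, sample_rate, include_repeats=False)
    traces = []
    for r in range(protocol.repeats):
        rs = seed + r
        rng = np.random.default_rng(rs)
        is_null = p_null > 0 and rng.random() < p_null
        m = model.silenced() if is_null else model
        path = simulate_gating(m, voltage, sample_rate, seed=rs)
        tr = render_current(
            path,
            m,
            voltage,
            noise_sd=model.noise_sd_pA,
            filter_cutoff=filter_cutoff,
            sample_rate=sample_rate,
            seed=rs + NOISE_SEED_OFFSET,
            label=f"{label + ' ' if label else ''}repeat={r} inactivated={is_null}",
        )
        traces.append(tr)
    return traces


def simulate_bi_ionic_ramp(
    model: ChannelModel,
    condition: BiIonicCondition,
    protocol: VoltageProtocol,
    n_sweeps: int,
    seed: int,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    filter_cutoff: float | None = DEFAULT_FILTER_CUTOFF,
) -> list[Trace]:
    """Simulate independent bi-ionic ramp sweeps.

    The open-channel reversal potential of every level is overridden by the
    condition's true reversal potential; sweep s uses gating seed
    ``seed + s`` and noise seed ``seed + s + NOISE_SEED_OFFSET``.
    """
    if len(protocol.ramp_segments) != 1:
        raise ValidationError("bi-ionic protocol must contain exactly one ramp segment")
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    m = model.with_reversal(condition.true_reversal_mV)
    voltage = render_protocol(protocol, sample_rate, include_repeats=False)
    sweeps = []
    for s in range(n_sweeps):
        rs = seed + s
        path = simulate_gating(m, voltage, sample_rate, seed=rs)
        sweeps.append(
            render_current(
                path,
                m,
                voltage,
                noise_sd=m.noise_sd_pA,
                filter_cutoff=filter_cutoff,
                sample_rate=sample_rate,
                seed=rs + NOISE_SEED_OFFSET,
                label=f"{condition.cis_ion}/{condition.trans_ion} sweep={s}",
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _nachbac_levels(e_rev: float = 0.0) -> tuple[SubLevel, ...]:
    return tuple(
        SubLevel(name=f"L{i + 1}", conductance_pS=g, reversal_mV=e_rev)
        for i, g in enumerate(NACHBAC_CONDUCTANCES_PS)
    )


def make_fixture(name: str) -> Fixture:
    """Named channel fixtures used throughout the test and demo workflows.

    ``nachbac_default``
        Three sub-states at 26/93/268 pS with opening-rate weights
        L2 > L1 > L3 and a Boltzmann (v_half +20 mV, slope 8 mV) that
        concentrates openings at depolarized voltages (>= +30 mV).  The
        bi-ionic conditions carry true reversal potentials implied by the
        target permeability ratios at 150/150 mM, 295 K: Na/K 1.04 and
        Na/Ca 1.58.  Ramp sweeps use a gating variant that is effectively
        voltage-independent and more active, as observed in bi-ionic
        recordings.
    ``two_state_toy``
        One 100 pS level, k_open = k_close = 10/s, saturated Boltzmann:
        closed-form-checkable occupancy 0.5.
    ``macroscopic_n5``
        The default channel with 5 independent copies in the bilayer.
    """
    cond_ref = IonCondition(na_in_mM=150.0, k_in_mM=150.0, ca_out_mM=150.0,
                            temperature_K=295.0)
    if name == "nachbac_default" or name == "macroscopic_n5":
        model = ChannelModel(
            levels=_nachbac_levels(0.0),
            k_open=(4.0, 6.0, 1.2),
            k_close=(20.0, 20.0, 20.0),
            v_half_mV=20.0,
            slope_mV=8.0,
            noise_sd_pA=0.6,
            n_channels=5 if name == "macroscopic_n5" else 1,
            name=name,
        )
        ramp_model = dataclasses.replace(
            model,
            k_open=(8.0, 12.0, 2.4),
            v_half_mV=-300.0,
            slope_mV=25.0,
            n_channels=1,
            name=name + "_ramp",
        )
        conditions = {
            "na_k": BiIonicCondition(
                cis_ion="Na",
                cis_mM=150.0,
                trans_ion="K",
                trans_mM=150.0,
                true_reversal_mV=reversal_from_na_k(1.04, cond_ref),
            ),
            "na_ca": BiIonicCondition(
                cis_ion="Na",
                cis_mM=150.0,
                trans_ion="Ca",
                trans_mM=150.0,
                true_reversal_mV=reversal_from_na_ca(1.58, cond_ref),
            ),
        }
        return Fixture(name=name, model=model, conditions=conditions,
                       ramp_model=ramp_model)
    if name == "two_state_toy":
        model = ChannelModel(
            levels=(SubLevel(name="open", conductance_pS=100.0),),
            k_open=(10.0,),
            k_close=(10.0,),
            v_half_mV=-300.0,
            slope_mV=25.0,
            noise_sd_pA=0.0,
            name=name,
        )
        return Fixture(name=name, model=model)
    raise ValidationError(
        f"unknown fixture {name!r}; valid names: "
        "nachbac_default, two_state_toy, macroscopic_n5"
    )


# ---------------------------------------------------------------------------
# model config files (YAML)
# ---------------------------------------------------------------------------

def model_to_dict(model: ChannelModel) -> dict:
    return {
        "name": model.name,
        "levels": [
            {"name": lv.name, "conductance_pS": lv.conductance_pS,
             "reversal_mV": lv.reversal_mV}
            for lv in model.levels
        ],
        "k_open_per_s": list(model.k_open),
        "k_close_per_s": list(model.k_close),
        "v_half_mV": model.v_half_mV,
        "slope_mV": model.slope_mV,
        "noise_sd_pA": model.noise_sd_pA,
        "n_channels": model.n_channels,
        "inter_level_rate_per_s": model.inter_level_rate,
    }


def model_from_dict(d: dict) -> ChannelModel:
    try:
        levels = tuple(
            SubLevel(
                name=str(lv.get("name", f"L{i + 1}")),
                conductance_pS=float(lv["conductance_pS"]),
                reversal_mV=float(lv.get("reversal_mV", 0.0)),
            )
            for i, lv in enumerate(d["levels"])
        )
        return ChannelModel(
            levels=levels,
            k_open=tuple(float(k) for k in d["k_open_per_s"]),
            k_close=tuple(float(k) for k in d["k_close_per_s"]),
            v_half_mV=float(d["v_half_mV"]),
            slope_mV=float(d["slope_mV"]),
            noise_sd_pA=float(d.get("noise_sd_pA", 0.0)),
            n_channels=int(d.get("n_channels", 1)),
            inter_level_rate=float(d.get("inter_level_rate_per_s", 0.0)),
            name=str(d.get("name", "")),
        )
    except KeyError as exc:
        raise FormatError(f"channel model config missing key {exc}") from exc


def write_channel_model(model: ChannelModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def read_channel_model(path: str | Path) -> ChannelModel:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: channel model config must be a mapping")
    return model_from_dict(d)
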
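"""Membrane mechanisms: passive parameters, voltage-gated channel kinetics,
the calcium-activated nonselective cation (CAN) current, the submembrane
calcium pool, and the four synaptic conductances.

The channel repertoire follows the standard prefrontal layer-V pyramidal
complement: transient and persistent Na+ (Naf, Nap); delayed-rectifier,
A-type and slowly inactivating D-type K+ (Kdr, KA, KD); fast and slow
Ca2+-dependent K+ (fAHP, sAHP); H-current; low- and high-voltage-activated
Ca2+ channels (CaT, CaN, CaR, CaL); and the CAN current that generates the
slow delayed afterdepolarization (dADP).  Voltage-dependent gates use
Boltzmann steady states with bell-shaped (or constant) time constants, a
parameterisation into which any published rate set can be mapped.

The CAN gate follows the Destexhe-style calcium-dependent scheme

    alpha(cai) = beta * (cai / cac)**2
    m_inf      = alpha / (alpha + beta)
    tau_m      = 1 / (alpha + beta)

with beta = 1e-5 / ms and cac = 4e-4 mM.  An overall rate scale (a
temperature-adjustment-like factor applied in the integrator, not in the
canonical tau above) is calibrated so that the simulated dADP decays with
the experimentally observed ~3 s time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import curve_fit

FARADAY = 96485.3321  # C / mol

# gate table voltage grid (mV)
V_MIN, V_MAX, DV = -120.0, 70.0, 0.05


@dataclass
class PassiveParams:
    """Passive cable constants.

    Rm in kOhm*cm^2, Ra in Ohm*cm, capacitances in uF/cm^2 (the dendritic
    value is higher, standing in for spine membrane), resting potential in mV.
    """

    rm: float = 30.0
    ra: float = 100.0
    cm_soma: float = 1.2
    cm_dend: float = 2.0
    e_rest: float = -66.0
    e_leak: float = -66.0  # leak reversal; calibrated so the soma rests at e_rest

    def __post_init__(self):
        for name in ("rm", "ra", "cm_soma", "cm_dend"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GateParams:
    """One activation/inactivation gate.

    Steady state is a Boltzmann sigmoid 1/(1+exp(-(v-vhalf)/k)) (k < 0 for
    inactivation gates); the time constant is ``tau_min + tau_amp *
    exp(-((v-tau_vpeak)/tau_sigma)^2)`` in ms.
    """

    vhalf: float
    k: float
    tau_min: float
    tau_amp: float = 0.0
    tau_vpeak: float = 0.0
    tau_sigma: float = 20.0

    def inf(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.vhalf) / self.k))

    def tau(self, v):
        v = np.asarray(v, dtype=float)
        return self.tau_min + self.tau_amp * np.exp(
            -(((v - self.tau_vpeak) / self.tau_sigma) ** 2)
        )


# Gate order used by the integration kernel.  (channel, gate, power)
GATE_LAYOUT = (
    ("naf", "m", 3),
    ("naf", "h", 1),
    ("nap", "m", 1),
    ("kdr", "n", 2),
    ("ka", "a", 2),
    ("ka", "b", 1),
    ("kd", "a", 1),
    ("kd", "b", 1),
    ("h", "m", 1),
    ("cat", "m", 2),
    ("cat", "h", 1),
    ("can_ca", "m", 2),
    ("can_ca", "h", 1),
    ("car", "m", 2),
    ("car", "h", 1),
    ("cal", "m", 2),
    ("fahp", "m", 1),
)

N_GATES = len(GATE_LAYOUT)

# Channel order used by the kernel for conductance-density arrays.
CHANNELS = (
    "naf", "nap", "kdr", "ka", "kd", "fahp", "sahp", "h",
    "cat", "can_ca", "car", "cal", "can",
)


def default_gates() -> dict[tuple[str, str], GateParams]:
    """Default kinetic parameters, adapted from published layer-V PFC models."""
    return {
        ("naf", "m"): GateParams(-37.0, 6.5, 0.03, 0.08, -42.0, 15.0),
        ("naf", "h"): GateParams(-46.0, -6.0, 0.4, 5.0, -54.0, 18.0),
        ("nap", "m"): GateParams(-43.0, 2.5, 1.0),
        ("kdr", "n"): GateParams(-20.0, 8.0, 0.8, 1.2, -26.0, 25.0),
        ("ka", "a"): GateParams(-25.0, 9.0, 0.3),
        ("ka", "b"): GateParams(-70.0, -7.0, 8.0, 25.0, -70.0, 20.0),
        ("kd", "a"): GateParams(-42.0, 7.0, 2.0),
        ("kd", "b"): GateParams(-65.0, -7.0, 400.0),
        ("h", "m"): GateParams(-82.0, -8.0, 40.0, 50.0, -75.0, 25.0),
        ("cat", "m"): GateParams(-50.0, 6.5, 3.0),
        ("cat", "h"): GateParams(-74.0, -5.0, 25.0),
        ("can_ca", "m"): GateParams(-18.0, 7.0, 1.2),
        ("can_ca", "h"): GateParams(-40.0, -12.0, 80.0),
        ("car", "m"): GateParams(-15.0, 7.0, 1.5, 28.0, -50.0, 15.0),
        ("car", "h"): GateParams(-60.0, -6.0, 60.0),
        ("cal", "m"): GateParams(-22.0, 6.0, 2.0),
        # voltage part of the fast Ca- and V-dependent K current (BK-like);
        # the calcium dependence cai/(cai+kd) is applied in the kernel
        ("fahp", "m"): GateParams(-20.0, 9.0, 1.0),
    }


@dataclass
class CanParams:
    """CAN current parameters.

    g_can (S/cm^2) sets the dADP amplitude; beta (1/ms) and cac (mM) are the
    canonical rate parameters; rate_scale is the overall rate adjustment
    (calibrated against the ~3 s dADP decay); e_can is the mixed-cation
    reversal (about 70% of the underlying current is carried by Na+,
    na_fraction, which motivates the depolarised reversal).
    """

    g_can: float = 0.0
    beta: float = 1e-5
    cac: float = 4e-4
    e_can: float = -20.0
    na_fraction: float = 0.7
    rate_scale: float = 32.8

    def __post_init__(self):
        if not 0.0 <= self.na_fraction <= 1.0:
            raise ValueError("na_fraction must be in [0, 1]")
        if self.beta <= 0 or self.cac <= 0 or self.rate_scale <= 0:
            raise ValueError("beta, cac and rate_scale must be > 0")


def can_steady_state(cai, p: CanParams):
    """Steady state and canonical (unscaled) time constant of the CAN gate.

    Returns ``(m_inf, tau_m)`` with m_inf in [0, 1) monotone non-decreasing
    in cai and tau_m in ms monotone non-increasing in cai.  The integrator
    divides tau_m by ``p.rate_scale``.
    """
    cai = np.asarray(cai, dtype=float)
    if np.any(cai < 0):
        raise ValueError("cai must be >= 0")
    alpha = p.beta * (cai / p.cac) ** 2
    m_inf = alpha / (alpha + p.beta)
    tau_m = 1.0 / (alpha + p.beta)
    if np.ndim(cai) == 0:
        return float(m_inf), float(tau_m)
    return m_inf, tau_m


@dataclass
class CalciumPoolParams:
    """First-order submembrane calcium pool.

    depth is the shell depth (um), f_buffer the free (unbuffered) fraction of
    influx, tau (ms) the relaxation time towards the resting level cai0 (mM).

    Two calcium signals are maintained: a fast submembrane shell (f_buffer,
    tau) gating the fast and slow Ca-dependent K+ currents, and a slower,
    more heavily buffered compartment (f_can, tau_can) sensed by the CAN
    current.  The slow pool integrates spiking over hundreds of
    milliseconds, so sustained firing activates CAN far more strongly than
    a brief 5-spike burst - the basis of the regenerative persistent state.
    """

    depth: float = 0.1
    f_buffer: float = 0.024
    tau: float = 100.0
    cai0: float = 5e-5
    # slow pool sensed by the CAN current (deeper effective compartment:
    # smaller free fraction, slower clearance)
    f_can: float = 0.25
    tau_can: float = 800.0


def calcium_pool_step(cai: float, i_ca: float, dt: float,
                      p: CalciumPoolParams | None = None) -> float:
    """Advance the pool one step (reference scalar implementation).

    ``i_ca`` is the calcium current density in mA/cm^2 (inward negative).
    Exact exponential update of d(cai)/dt = -k*i_ca - (cai - cai0)/tau,
    clipped below at cai0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = p or CalciumPoolParams()
    # mA/cm^2 -> mM/ms through a shell of `depth` um: 1e4/(2*F*depth_um)
    k = p.f_buffer * 1e4 / (2.0 * FARADAY * p.depth)
    influx = -k * min(i_ca, 0.0)
    target = p.cai0 + influx * p.tau
    new = target + (cai - target) * math.exp(-dt / p.tau)
    return max(new, p.cai0)


# ---------------------------------------------------------------------------
# Synapses
# ---------------------------------------------------------------------------

SYN_KINDS = ("AMPA", "NMDA", "GABA_A", "GABA_B")


@dataclass(frozen=True)
class SynapseSpec:
    """Dual-exponential synaptic conductance.

    gmax is the peak conductance (nS) for a single activation; the NMDA kind
    additionally carries the sigmoidal Mg-block parameters and the
    inactivation factor b_nmda (1/ms) that sets its slow decay rate
    (tau_decay = 1/b_nmda; the control value is b = 1e-2, i.e. log10 b = -2).
    """

    kind: str
    gmax: float  # nS
    tau_rise: float  # ms
    tau_decay: float  # ms
    e_rev: float  # mV
    b_nmda: float = 1e-2
    mg_mm: float = 1.0
    mg_slope: float = 0.062  # 1/mV
    mg_scale: float = 3.57  # mM

    def __post_init__(self):
        if self.kind not in SYN_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        if not self.tau_decay > self.tau_rise > 0:
            raise ValueError("need tau_decay > tau_rise > 0")


def default_synapse(kind: str, gmax: float = 1.0, b_nmda: float = 1e-2) -> SynapseSpec:
    if kind == "AMPA":
        return SynapseSpec("AMPA", gmax, 0.5, 3.0, 0.0)
    if kind == "NMDA":
        return SynapseSpec("NMDA", gmax, 2.0, 1.0 / b_nmda, 0.0, b_nmda=b_nmda)
    if kind == "GABA_A":
        return SynapseSpec("GABA_A", gmax, 1.0, 7.0, -75.0)
    if kind == "GABA_B":
        return SynapseSpec("GABA_B", gmax, 30.0, 150.0, -93.0)
    raise ValueError(f"unknown synapse kind {kind!r}")


def dualexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def dualexp_norm(tau_rise: float, tau_decay: float) -> float:
    """1 / peak of (exp(-t/tau_decay) - exp(-t/tau_rise))."""
    tp = dualexp_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def mg_block(v, mg_mm: float = 1.0, slope: float = 0.062, scale: float = 3.57):
    """Sigmoidal voltage dependence of the NMDA Mg2+ block (1 = unblocked)."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + (mg_mm / scale) * np.exp(-slope * v))
    return float(out) if np.ndim(v) == 0 else out


def nmda_gating(t_since_event, v, s: SynapseSpec):
    """Normalised NMDA conductance multiplier: dual-exponential time course
    (decay set by 1/b_nmda) times the Mg-block factor at voltage ``v``."""
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be >= 0")
    tau_d = 1.0 / s.b_nmda
    # normalise against the control kinetics so that changing b_nmda
    # realistically changes both charge and peak
    norm = dualexp_norm(s.tau_rise, 1.0 / 1e-2)
    g = norm * (np.exp(-t / tau_d) - np.exp(-t / s.tau_rise))
    out = g * mg_block(v, s.mg_mm, s.mg_slope, s.mg_scale)
    return float(out) if np.ndim(t) == 0 and np.ndim(v) == 0 else out


# ---------------------------------------------------------------------------
# dADP trace analysis
# ---------------------------------------------------------------------------

@dataclass
class DadpMeasurement:
    amplitude: float  # mV above pre-stimulus baseline
    tau_decay: float  # ms, single-exponential fit of the post-peak tail
    t_peak: float  # ms
    baseline: float  # mV


def dadp_amplitude_from_trace(
    t: np.ndarray,
    v: np.ndarray,
    spike_times: np.ndarray,
    baseline_window: tuple[float, float],
    search_window: tuple[float, float] = (200.0, 1500.0),
    fit_span: float = 6000.0,
) -> DadpMeasurement:
    """Measure the delayed afterdepolarization from a somatic voltage trace.

    The amplitude is the maximum of (V - baseline) in the window
    ``last_spike + search_window`` (default 200-1500 ms after the last
    spike, excluding fast spike afterpotentials); the decay constant comes
    from a single-exponential fit of the tail from the peak over
    ``fit_span`` ms (or to the end of the trace).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    b0, b1 = baseline_window
    bmask = (t >= b0) & (t < b1)
    if not bmask.any():
        raise ValueError("baseline window outside trace")
    baseline = float(np.mean(v[bmask]))

    last_spike = float(np.max(spike_times)) if len(spike_times) else b1
    w0, w1 = last_spike + search_window[0], last_spike + search_window[1]
    if w1 > t[-1]:
        raise ValueError(
            f"dADP search window [{w0:.0f}, {w1:.0f}] ms extends beyond trace end {t[-1]:.0f} ms"
        )
    wmask = (t >= w0) & (t <= w1)
    rel = v - baseline
    i_peak = np.argmax(rel[wmask])
    idx = np.flatnonzero(wmask)[i_peak]
    amplitude = float(rel[idx])
    t_peak = float(t[idx])

    fmask = (t >= t_peak) & (t <= t_peak + fit_span)
    tf = t[fmask] - t_peak
    yf = rel[fmask]
    tau = math.nan
    if amplitude > 1e-3 and len(tf) > 10:
        try:
            popt, _ = curve_fit(
                lambda x, a, tau: a * np.exp(-x / tau),
                tf, yf, p0=(amplitude, 3000.0),
                bounds=([0.0, 10.0], [np.inf, 1e6]), maxfev=10000,
            )
            tau = float(popt[1])
        except RuntimeError:
            pass
    return DadpMeasurement(amplitude=amplitude, tau_decay=tau, t_peak=t_peak, baseline=baseline)


# ---------------------------------------------------------------------------
# Conductance-density tables
# ---------------------------------------------------------------------------

@dataclass
class ChannelDensities:
    """Per-region maximal conductance densities (S/cm^2), one map per channel."""

    g: dict[str, dict[str, float]] = field(default_factory=dict)

    def density(self, channel: str, region: str) -> float:
        return self.g.get(channel, {}).get(region, 0.0)

    def scaled(self, channel: str, factor: float) -> "ChannelDensities":
        out = {k: dict(v) for k, v in self.g.items()}
        if channel in out:
            out[channel] = {r: g * factor for r, g in out[channel].items()}
        return ChannelDensities(out)

    def to_dict(self) -> dict:
        return {k: dict(v) for k, v in self.g.items()}


def default_densities() -> ChannelDensities:
    """Baseline (regular-spiking) conductance densities, S/cm^2."""
    return ChannelDensities({
        "naf": {"soma": 0.12, "axon": 0.30, "basal": 0.03, "apical": 0.03},
        "nap": {"soma": 1.5e-4, "basal": 5e-5, "apical": 5e-5},
        "kdr": {"soma": 0.2, "axon": 0.25, "basal": 0.01, "apical": 0.01},
        "ka": {"soma": 0.025, "basal": 0.03, "apical": 0.03},
        "kd": {"soma": 5e-4},
        "fahp": {"soma": 8e-3, "basal": 1e-3, "apical": 1e-3},
        "sahp": {"soma": 3e-4, "basal": 2e-5, "apical": 2e-5},
        "h": {"soma": 5e-6, "basal": 5e-6, "apical": 1e-5},
        "cat": {"soma": 1e-5, "basal": 1e-5, "apical": 1e-5},
        "can_ca": {"soma": 3e-5, "basal": 1e-5, "apical": 1e-5},
        "car": {"soma": 8e-4, "basal": 3e-5, "apical": 3e-5},
        "cal": {"soma": 1e-5, "basal": 1e-5, "apical": 1e-5},
        "can": {"soma": 1.0},  # relative profile; scaled by CanParams.g_can
    })


# Ion reversals (mV) and auxiliary constants used by the kernel.
E_NA = 55.0
E_K = -90.0
E_H = -30.0
E_CA = 120.0
FAHP_KD = 1e-3  # mM, half-activation of the BK calcium factor
SAHP_KD = 8e-4  # mM
SAHP_TAU = 300.0  # ms


def sahp_inf(cai):
    cai = np.asarray(cai, dtype=float)
    return cai ** 2 / (cai ** 2 + SAHP_KD ** 2)


def build_gate_tables(gates: dict[tuple[str, str], GateParams], dt: float):
    """Tabulate, for each gate in GATE_LAYOUT, the steady state and the
    exponential-Euler factor (1 - exp(-dt/tau)) on the kernel voltage grid."""
    vgrid = np.arange(V_MIN, V_MAX + DV / 2, DV)
    ng = len(GATE_LAYOUT)
    inf_tab = np.empty((ng, len(vgrid)))
    fac_tab = np.empty((ng, len(vgrid)))
    for i, (chan, gate, _power) in enumerate(GATE_LAYOUT):
        gp = gates[(chan, gate)]
        inf_tab[i] = gp.inf(vgrid)
        fac_tab[i] = 1.0 - np.exp(-dt / gp.tau(vgrid))
    return inf_tab, fac_tab
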
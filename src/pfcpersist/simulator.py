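"""Compartmental cable simulator and the standard experimental protocols.

The cell is discretised into compartments with the d-lambda rule and
integrated by a Crank-Nicolson step on the branched cable (Hines tree
solve) with staggered exponential-Euler gating (see :mod:`._kernel`).

Protocols implemented here: somatic current steps with firing-pattern
classification (regular-spiking vs intrinsic-bursting), input-resistance
measurement, the burst-evoked dADP protocol, the dendritic NMDA-spike
assay, and the somatic voltage-clamp NMDA-to-AMPA current-ratio
measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace

import numpy as np

from . import channels as ch
from ._kernel import integrate, OK
from .channels import (
    CanParams, CalciumPoolParams, ChannelDensities, PassiveParams,
    build_gate_tables, default_densities, default_gates, default_synapse,
    dualexp_norm, dadp_amplitude_from_trace, DadpMeasurement,
    CHANNELS, GATE_LAYOUT, N_GATES, FARADAY,
)
from .morphology import BranchLocation, Morphology, make_surrogate_morphology

SOMA = BranchLocation(0, 0.5)
_KIND_INDEX = {"AMPA": 0, "NMDA": 1, "GABA_A": 2, "GABA_B": 3}


class IntegrationError(RuntimeError):
    """Numerical divergence, reporting time and site."""


class ProtocolError(RuntimeError):
    """A protocol's preconditions could not be met."""


# ---------------------------------------------------------------------------
# Cell specification
# ---------------------------------------------------------------------------

@dataclass
class SynapticParams:
    """Synaptic conductances and kinetics shared by all protocols.

    g_ampa is the per-synapse AMPA peak conductance (nS); the NMDA peak
    conductance is ``nmda_gain * 2.5 * nmda_ratio * g_ampa`` (so the nominal
    3:1 relation at the control ratio 1.2, scaled by a calibration gain that
    anchors the measured somatic +60/-70 mV current ratio at the nominal
    value).  b_nmda (1/ms) sets the NMDA decay rate, control 1e-2.
    """

    g_ampa: float = 0.35
    nmda_gain: float = 1.0
    g_gaba_a: float = 60.0
    g_gaba_b: float = 0.8
    b_nmda: float = 1e-2
    nmda_ca_frac: float = 0.1  # fraction of NMDA conductance feeding the CAN pool
    nmda_scale: float = 1.0  # extra multiplier (e.g. 0.9 = 10% NMDA reduction)
    ampa_scale: float = 1.0

    def g_nmda(self, nmda_ratio: float) -> float:
        return self.nmda_gain * 2.5 * nmda_ratio * self.g_ampa * self.nmda_scale


@dataclass
class NoiseParams:
    """Somatic Poisson shot-noise current (emulating channel noise)."""

    rate_hz: float = 50.0
    amp_pa: float = 25.0
    width_ms: float = 2.0
    enabled: bool = False


@dataclass
class CellSpec:
    morphology: Morphology
    passive: PassiveParams = field(default_factory=PassiveParams)
    densities: ChannelDensities = field(default_factory=default_densities)
    gates: dict = field(default_factory=default_gates)
    can: CanParams = field(default_factory=CanParams)
    pool: CalciumPoolParams = field(default_factory=CalciumPoolParams)
    syn: SynapticParams = field(default_factory=SynapticParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    phenotype: str = "RS"
    nmda_ratio: float = 1.2

    def __post_init__(self):
        if self.phenotype not in ("RS", "IB"):
            raise ValueError("phenotype must be 'RS' or 'IB'")
        if self.nmda_ratio <= 0:
            raise ValueError("nmda_ratio must be > 0")
        self._compiled: dict[float, CompiledCell] = {}

    def with_gcan(self, g_can: float) -> "CellSpec":
        out = replace(self, can=replace(self.can, g_can=g_can))
        return out

    def compiled(self, dt: float) -> "CompiledCell":
        key = round(dt, 9)
        if key not in self._compiled:
            self._compiled[key] = CompiledCell(self, dt)
        return self._compiled[key]


def build_cell(
    phenotype: str = "RS",
    nmda_ratio: float = 1.2,
    g_can: float = 0.0,
    morphology: Morphology | None = None,
    seed: int = 1,
    noise: bool = False,
    overrides: dict | None = None,
) -> CellSpec:
    """Assemble a cell of the given phenotype on the surrogate morphology.

    The intrinsic-bursting (IB) phenotype is the regular-spiking (RS)
    parameter set with the R-type calcium and persistent sodium maximal
    conductances doubled.  Calibrated defaults are loaded from the packaged
    parameter file when available.
    """
    from .config import load_calibrated

    cal = load_calibrated()

    def _hydrate(cls, d, **extra):
        known = {f.name for f in dc_fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known}, **extra)

    m = morphology or make_surrogate_morphology(seed=seed)
    dens = ChannelDensities(cal["densities"]) if "densities" in cal else default_densities()
    if phenotype == "IB":
        dens = dens.scaled("car", 2.0).scaled("nap", 2.0)
    passive = _hydrate(PassiveParams, cal.get("passive", {}))
    can = _hydrate(CanParams, {k: v for k, v in cal.get("can", {}).items()
                               if k != "g_can"}, g_can=g_can)
    pool = _hydrate(CalciumPoolParams, cal.get("pool", {}))
    syn = _hydrate(SynapticParams, cal.get("syn", {}))
    np_ = _hydrate(NoiseParams, cal.get("noise", {}))
    np_.enabled = noise
    spec = CellSpec(
        morphology=m, passive=passive, densities=dens, can=can, pool=pool,
        syn=syn, noise=np_, phenotype=phenotype, nmda_ratio=nmda_ratio,
    )
    for key, val in (overrides or {}).items():
        obj = spec
        *path, attr = key.split(".")
        for p in path:
            obj = getattr(obj, p)
        setattr(obj, attr, val)
    return spec


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurrentStep:
    loc: BranchLocation
    t0: float
    t1: float
    amp: float  # nA


@dataclass(frozen=True)
class SynapticDrive:
    """A set of synapses of one kind sharing event times."""

    kind: str
    placements: tuple  # of (BranchLocation, gmax_nS)
    events: tuple  # ms


@dataclass(frozen=True)
class VoltageClamp:
    loc: BranchLocation
    v: float  # mV
    g_series: float = 1e4  # uS (100 Ohm series resistance)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    t: np.ndarray  # ms
    v: dict  # site name -> mV trace
    spike_times: np.ndarray  # somatic, ms
    cai_soma: np.ndarray
    i_can_soma: np.ndarray  # nA
    i_clamp: np.ndarray | None
    dt: float
    seed: int | None


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with a refractory period; crossing times
    are linearly interpolated between samples."""
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tt = t[i] + frac * (t[i + 1] - t[i])
        if tt - last >= refractory:
            times.append(tt)
            last = tt
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Compiled cell
# ---------------------------------------------------------------------------

class CompiledCell:
    """Discretised cell: flat compartment arrays plus cached resting state."""

    def __init__(self, spec: CellSpec, dt: float = 0.025, d_lambda: float = 0.2):
        if not 0 < dt <= 0.1:
            raise ValueError("dt must be in (0, 0.1] ms")
        self.spec = spec
        self.dt = dt
        m = spec.morphology
        pas = spec.passive

        parent: list[int] = []
        area: list[float] = []  # cm^2
        cm: list[float] = []  # nF
        g_ax: list[float] = []  # uS
        region: list[str] = []
        sec_first: dict[int, int] = {}
        sec_nseg: dict[int, int] = {}
        half_r: dict[int, float] = {}  # MOhm, half-segment axial resistance

        for s in m.sections:
            lam = 1e5 * math.sqrt(
                s.diameter / (4 * math.pi * 100.0 * pas.ra *
                              (pas.cm_soma if s.region == "soma" else pas.cm_dend))
            )
            nseg = max(1, int(math.ceil(s.length / (d_lambda * lam))))
            lseg = s.length / nseg
            a = math.pi * s.diameter * lseg * 1e-8  # cm^2
            rh = pas.ra * (lseg * 1e-4 / 2) / (math.pi * (s.diameter * 1e-4 / 2) ** 2) * 1e-6
            cmv = (pas.cm_soma if s.region in ("soma", "axon") else pas.cm_dend)
            sec_first[s.id] = len(parent)
            sec_nseg[s.id] = nseg
            half_r[s.id] = rh
            for k in range(nseg):
                if k == 0:
                    if s.parent_id is None:
                        parent.append(-1)
                        g_ax.append(0.0)
                    else:
                        pid = s.parent_id
                        pidx = sec_first[pid] + sec_nseg[pid] - 1
                        parent.append(pidx)
                        g_ax.append(1.0 / (rh + half_r[pid]))
                else:
                    parent.append(len(parent) - 1)
                    g_ax.append(1.0 / (2 * rh))
                area.append(a)
                cm.append(cmv * a * 1e3)  # uF/cm^2 * cm^2 -> uF; *1e3 -> nF
                region.append(s.region)

        self.n = len(parent)
        self.parent = np.asarray(parent, dtype=np.int32)
        self.g_ax = np.asarray(g_ax)
        self.area = np.asarray(area)
        self.cm = np.asarray(cm)
        self.region = region
        self._sec_first = sec_first
        self._sec_nseg = sec_nseg

        self.g_leak = self.area / (pas.rm * 1e3) * 1e6  # uS
        gch = np.zeros((len(CHANNELS), self.n))
        for ci, cname in enumerate(CHANNELS):
            for i in range(self.n):
                dens = spec.densities.density(cname, region[i])
                if cname == "can":
                    dens *= spec.can.g_can
                gch[ci, i] = dens * self.area[i] * 1e6  # S -> uS
        self.gch = gch

        kca = np.zeros(self.n)
        ca_idx = [CHANNELS.index(c) for c in ("cat", "can_ca", "car", "cal")]
        for i in range(self.n):
            if any(gch[ci, i] > 0 for ci in ca_idx):
                kca[i] = spec.pool.f_buffer * 1e-2 / (
                    2 * FARADAY * self.area[i] * spec.pool.depth
                )
        self.kca = kca
        self.kca2 = kca * (spec.pool.f_can / spec.pool.f_buffer)

        self.inf_tab, self.fac_tab = build_gate_tables(spec.gates, dt)
        self._rest_state = None

    def comp_index(self, loc: BranchLocation) -> int:
        first = self._sec_first[loc.section_id]
        nseg = self._sec_nseg[loc.section_id]
        return first + min(nseg - 1, int(loc.position * nseg))

    # -- state -------------------------------------------------------------

    def _fresh_state(self):
        v = np.full(self.n, self.spec.passive.e_rest)
        gates = np.empty((N_GATES, self.n))
        for gi, (cn, gn, _p) in enumerate(GATE_LAYOUT):
            gates[gi, :] = self.spec.gates[(cn, gn)].inf(v)
        cai = np.full(self.n, self.spec.pool.cai0)
        cai2 = cai.copy()
        q = ch.sahp_inf(cai).copy()
        m_inf, _ = ch.can_steady_state(self.spec.pool.cai0, self.spec.can)
        m_can = np.full(self.n, m_inf)
        return v, gates, cai, cai2, q, m_can

    def rest_state(self, settle_ms: float = 1000.0):
        """Settled resting state (cached); deep-copied on access."""
        if self._rest_state is None:
            state = self._fresh_state()
            self._run_kernel(state, [], settle_ms, noise_i=None, clamp=None,
                             record_locs=[SOMA], t0=-settle_ms)
            self._rest_state = state
        return tuple(x.copy() for x in self._rest_state)

    # -- low-level run ------------------------------------------------------

    def _run_kernel(self, state, stimuli, duration, noise_i, clamp,
                    record_locs, t0=0.0):
        v, gates, cai, cai2, q, m_can = state
        dt = self.dt
        nsteps = int(round(duration / dt))
        spec = self.spec

        steps = [s for s in stimuli if isinstance(s, CurrentStep)]
        drives = [s for s in stimuli if isinstance(s, SynapticDrive)]
        ic_comp = np.asarray([self.comp_index(s.loc) for s in steps], dtype=np.int32)
        ic_t0 = np.asarray([s.t0 for s in steps])
        ic_t1 = np.asarray([s.t1 for s in steps])
        ic_amp = np.asarray([s.amp for s in steps])

        # synapse units: aggregate per (compartment, kind)
        agg: dict[tuple[int, int], float] = {}
        events: list[tuple[float, int]] = []
        for d in drives:
            k = _KIND_INDEX[d.kind]
            for loc, g in d.placements:
                key = (self.comp_index(loc), k)
                agg[key] = agg.get(key, 0.0) + g * 1e-3  # nS -> uS
            for te in d.events:
                events.append((te, k))
        units = sorted(agg)
        syn_comp = np.asarray([u[0] for u in units], dtype=np.int32)
        syn_kind = np.asarray([u[1] for u in units], dtype=np.int8)
        syn_w = np.asarray([agg[u] for u in units])
        events.sort()
        ev_t = np.asarray([e[0] for e in events])
        ev_kind = np.asarray([e[1] for e in events], dtype=np.int8)

        kin = [default_synapse(k, b_nmda=spec.syn.b_nmda) for k in ch.SYN_KINDS]
        k_dec_r = np.asarray([math.exp(-dt / s.tau_rise) for s in kin])
        k_dec_d = np.asarray([math.exp(-dt / s.tau_decay) for s in kin])
        k_e = np.asarray([s.e_rev for s in kin])
        # NMDA normalised against control kinetics so b_nmda changes peak+charge
        k_norm = np.asarray([
            dualexp_norm(s.tau_rise, 1.0 / 1e-2) if s.kind == "NMDA"
            else dualexp_norm(s.tau_rise, s.tau_decay)
            for s in kin
        ])
        k_is_nmda = np.asarray([1 if s.kind == "NMDA" else 0 for s in kin], dtype=np.int8)
        nm = kin[1]
        mg_a = nm.mg_mm / nm.mg_scale

        syn_a = np.zeros(len(units))
        syn_b = np.zeros(len(units))

        if noise_i is None:
            noise_i = np.empty(0)
        clamp_comp, clamp_v, clamp_g = (-1, 0.0, 0.0)
        if clamp is not None:
            clamp_comp = self.comp_index(clamp.loc)
            clamp_v = clamp.v
            clamp_g = clamp.g_series

        rec_comps = np.asarray([self.comp_index(l) for l in record_locs], dtype=np.int32)
        rec_v = np.empty((len(record_locs), nsteps + 1))
        rec_cai = np.empty(nsteps + 1)
        rec_ican = np.empty(nsteps + 1)
        rec_iclamp = np.empty(nsteps + 1)

        status, at_step = integrate(
            self.parent, self.g_ax, self.cm, self.g_leak, spec.passive.e_leak,
            self.gch, self.inf_tab, self.fac_tab,
            ch.E_NA, ch.E_K, ch.E_H, ch.E_CA,
            ch.FAHP_KD, ch.SAHP_KD, 1.0 - math.exp(-dt / ch.SAHP_TAU),
            spec.can.beta, spec.can.cac, spec.can.rate_scale, spec.can.e_can,
            spec.syn.nmda_ca_frac,
            self.kca, spec.pool.tau, self.kca2, spec.pool.tau_can, spec.pool.cai0,
            v, gates, cai, cai2, q, m_can,
            syn_comp, syn_w, syn_kind,
            k_dec_r, k_dec_d, k_e, k_norm, k_is_nmda,
            mg_a, nm.mg_slope,
            ev_t, ev_kind, syn_a, syn_b,
            ic_comp, ic_t0, ic_t1, ic_amp,
            np.int32(0), noise_i,
            clamp_comp, clamp_v, clamp_g,
            t0, dt, nsteps,
            rec_comps, rec_v, rec_cai, rec_ican, rec_iclamp,
        )
        if status != OK:
            raise IntegrationError(
                f"voltage diverged at t = {t0 + at_step * dt:.3f} ms "
                f"(|V| > 200 mV); check conductances/dt"
            )
        return rec_v, rec_cai, rec_ican, rec_iclamp


def make_noise(duration: float, dt: float, noise: NoiseParams, seed: int) -> np.ndarray:
    """Zero-mean Poisson shot-noise current waveform (nA per step)."""
    nsteps = int(round(duration / dt))
    out = np.zeros(nsteps)
    if not noise.enabled or noise.rate_hz <= 0 or noise.amp_pa == 0:
        return out
    rng = np.random.default_rng(seed)
    n_ev = rng.poisson(noise.rate_hz * duration / 1000.0)
    starts = np.sort(rng.uniform(0, duration, n_ev))
    w = max(1, int(round(noise.width_ms / dt)))
    amp = noise.amp_pa * 1e-3  # nA
    for s in starts:
        i = int(s / dt)
        out[i:i + w] += amp
    out -= noise.rate_hz * 1e-3 * noise.width_ms * amp  # zero mean
    return out


def run(
    cell: CellSpec,
    stimuli=(),
    duration: float = 1000.0,
    dt: float = 0.025,
    seed: int | None = None,
    record=(SOMA,),
    clamp: VoltageClamp | None = None,
    settle_ms: float = 1000.0,
) -> SimResult:
    """Integrate the cell for ``duration`` ms from its settled resting state.

    Deterministic given (cell, stimuli, seed): the seed drives only the
    somatic noise current.  Raises :class:`IntegrationError` (naming the
    time) if the voltage diverges.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    cc = cell.compiled(dt)
    state = cc.rest_state(settle_ms)
    noise_i = make_noise(duration, dt, cell.noise, 0 if seed is None else seed)
    rec_locs = list(record)
    if rec_locs[0] != SOMA:
        rec_locs = [SOMA] + rec_locs
    rec_v, rec_cai, rec_ican, rec_iclamp = cc._run_kernel(
        state, list(stimuli), duration, noise_i, clamp, rec_locs
    )
    t = np.arange(rec_v.shape[1]) * dt
    vdict = {}
    for i, loc in enumerate(rec_locs):
        name = "soma" if loc == SOMA else f"sec{loc.section_id}@{loc.position:g}"
        vdict[name] = rec_v[i]
    spikes = detect_spikes(t, rec_v[0])
    return SimResult(
        t=t, v=vdict, spike_times=spikes, cai_soma=rec_cai, i_can_soma=rec_ican,
        i_clamp=rec_iclamp if clamp is not None else None, dt=dt, seed=seed,
    )


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def measure_input_resistance(cell: CellSpec, amp_na: float = -0.1,
                             dur_ms: float = 500.0, dt: float = 0.025) -> float:
    """Steady-state input resistance (MOhm) from a small somatic step.

    Injects ``amp_na`` (default -100 pA) for ``dur_ms`` with noise off and
    channels active; Rin = delta-V / I with the deflection measured over the
    final fifth of the step.  Raises ProtocolError if the cell spikes.
    """
    quiet = replace(cell, noise=replace(cell.noise, enabled=False))
    pre = 200.0
    res = run(quiet, [CurrentStep(SOMA, pre, pre + dur_ms, amp_na)],
              duration=pre + dur_ms + 100.0, dt=dt)
    if np.any(res.spike_times <= pre + dur_ms):
        raise ProtocolError("cell spiked during the input-resistance protocol; "
                            "use a smaller current")
    v = res.v["soma"]
    base = v[(res.t > pre - 100) & (res.t < pre)].mean()
    vend = v[(res.t > pre + 0.8 * dur_ms) & (res.t < pre + dur_ms)].mean()
    return float((vend - base) / amp_na)


@dataclass
class StepResponse:
    result: SimResult
    pattern: str  # "RS" | "IB"
    n_spikes: int


def classify_firing_pattern(spike_times: np.ndarray) -> str:
    """IB if the first three spikes form an onset burst (span <= 40 ms) that
    is later followed by an interval more than twice the intra-burst ISI
    (the transition from burst to single-spike firing); RS otherwise."""
    s = np.asarray(spike_times)
    if len(s) < 4:
        return "RS"
    intra = s[2] - s[0]
    if intra > 40.0:
        return "RS"
    mean_isi = intra / 2.0
    isis = np.diff(s)
    return "IB" if np.any(isis[2:] > 2.0 * mean_isi) else "RS"


def step_response(cell: CellSpec, amp_pa: float = 200.0, dur_ms: float = 1000.0,
                  dt: float = 0.025) -> StepResponse:
    """Somatic step-pulse response with firing-pattern label."""
    if amp_pa < 0:
        raise ProtocolError("amplitude must be >= 0")
    quiet = replace(cell, noise=replace(cell.noise, enabled=False))
    pre = 200.0
    res = run(quiet, [CurrentStep(SOMA, pre, pre + dur_ms, amp_pa * 1e-3)],
              duration=pre + dur_ms + 300.0, dt=dt)
    return StepResponse(result=res, pattern=classify_firing_pattern(res.spike_times),
                        n_spikes=len(res.spike_times))


@dataclass
class DadpResult:
    measurement: DadpMeasurement
    result: SimResult
    n_spikes: int
    pulse_amp_na: float


def dadp_protocol(cell: CellSpec, n_pulses: int = 5, record_post_ms: float = 4000.0,
                  pulse_amp_na: float = 1.5, dt: float = 0.025) -> DadpResult:
    """Burst-evoked delayed afterdepolarization.

    Delivers ``n_pulses`` 5-ms suprathreshold somatic steps at 20 Hz (noise
    off), verifies exactly one action potential per pulse (one automatic
    amplitude adjustment and retry), and measures the dADP amplitude and
    decay constant relative to the pre-burst baseline.
    """
    if n_pulses < 1:
        raise ProtocolError("n_pulses must be >= 1")
    quiet = replace(cell, noise=replace(cell.noise, enabled=False))
    pre = 500.0
    period = 50.0  # 20 Hz

    def attempt(amp):
        pulses = [CurrentStep(SOMA, pre + k * period, pre + k * period + 5.0, amp)
                  for k in range(n_pulses)]
        res = run(quiet, pulses, duration=pre + n_pulses * period + record_post_ms, dt=dt)
        ok = len(res.spike_times) == n_pulses and all(
            ((res.spike_times >= pre + k * period) &
             (res.spike_times <= pre + k * period + 20.0)).sum() == 1
            for k in range(n_pulses)
        )
        return res, ok

    res, ok = attempt(pulse_amp_na)
    amp = pulse_amp_na
    if not ok:
        # automatic amplitude adjustment: walk a deterministic ladder
        for amp in np.arange(1.0, 2.45, 0.1):
            res, ok = attempt(float(amp))
            if ok:
                break
        else:
            raise ProtocolError(
                f"could not elicit exactly one AP per pulse for {n_pulses} pulses "
                f"at any tested amplitude (1.0-2.4 nA)"
            )
    meas = dadp_amplitude_from_trace(
        res.t, res.v["soma"], res.spike_times, baseline_window=(100.0, pre - 20.0)
    )
    return DadpResult(measurement=meas, result=res, n_spikes=len(res.spike_times),
                      pulse_amp_na=amp)


@dataclass
class NmdaSpikeResult:
    is_spike: bool
    amplitude: float  # local peak depolarisation, mV
    duration_half: float  # ms above half amplitude
    peak_v: float
    result: SimResult


def default_assay_branch(m: Morphology, target_um: float = 100.0) -> BranchLocation:
    """The basal branch whose centre is closest to ``target_um`` path distance."""
    best = min(m.basal_sections(), key=lambda s: abs(m.branch_center_distance(s.id) - target_um))
    return BranchLocation(best.id, 0.5)


def nmda_spike_assay(cell: CellSpec, branch: BranchLocation | None = None,
                     n_syn: int = 40, dt: float = 0.025) -> NmdaSpikeResult:
    """Synchronous AMPA+NMDA activation on one basal branch.

    ``n_syn`` synapses are evenly spaced along the branch and activated once;
    the regenerative-plateau criterion is a local dendritic depolarisation
    crossing -30 mV that stays above half-amplitude for at least 20 ms.
    """
    if n_syn < 1:
        raise ProtocolError("n_syn must be >= 1")
    m = cell.morphology
    branch = branch or default_assay_branch(m)
    if m.section(branch.section_id).region != "basal":
        raise ProtocolError("NMDA-spike assay requires a basal branch")
    quiet = replace(cell, noise=replace(cell.noise, enabled=False))
    t_ev = 100.0
    locs = tuple(BranchLocation(branch.section_id, (i + 0.5) / n_syn) for i in range(n_syn))
    g_nmda = cell.syn.g_nmda(cell.nmda_ratio)
    g_ampa = cell.syn.g_ampa * cell.syn.ampa_scale
    drives = [
        SynapticDrive("AMPA", tuple((l, g_ampa) for l in locs), (t_ev,)),
        SynapticDrive("NMDA", tuple((l, g_nmda) for l in locs), (t_ev,)),
    ]
    res = run(quiet, drives, duration=400.0, dt=dt, record=(branch,))
    name = f"sec{branch.section_id}@{branch.position:g}"
    vd = res.v[name]
    base = vd[res.t < t_ev].mean()
    peak = float(vd.max())
    ampl = peak - base
    half = base + ampl / 2.0
    duration_half = float((vd >= half).sum() * res.dt)
    return NmdaSpikeResult(
        is_spike=bool(peak >= -30.0 and duration_half >= 20.0),
        amplitude=ampl, duration_half=duration_half, peak_v=peak, result=res,
    )


def nmda_spike_threshold(cell: CellSpec, grid=(10, 20, 30, 40, 50),
                         branch: BranchLocation | None = None, dt: float = 0.025):
    """Smallest synapse count on the grid that evokes an NMDA plateau
    (None if none does)."""
    for n in grid:
        if nmda_spike_assay(cell, branch=branch, n_syn=n, dt=dt).is_spike:
            return n
    return None


def measure_nmda_ampa_ratio(cell: CellSpec, n_syn: int = 10, dt: float = 0.025,
                            hold_ms: float = 300.0) -> float:
    """NMDA-to-AMPA current ratio under somatic voltage clamp.

    ``n_syn`` basal synapses (one per branch, at the branch centre) are
    activated once while the soma is clamped at -70 mV and then at +60 mV;
    voltage-gated channels are blocked (synaptic currents pharmacologically
    isolated) so the ratio of peak clamp currents is purely synaptic.  The
    -70 mV peak is the fast AMPA component; the +60 mV (NMDA) peak is taken
    after the AMPA transient has decayed (> 15 ms post-event), the standard
    separation of the two components.
    """
    blocked = replace(
        cell,
        densities=ChannelDensities({}),
        can=replace(cell.can, g_can=0.0),
    )
    m = cell.morphology
    basal = m.basal_sections()
    locs = tuple(BranchLocation(s.id, 0.5) for s in basal[:n_syn])
    if len(locs) < n_syn:
        raise ProtocolError("not enough basal branches")
    g_nmda = cell.syn.g_nmda(cell.nmda_ratio)
    g_ampa = cell.syn.g_ampa * cell.syn.ampa_scale
    t_ev = hold_ms
    drives = [
        SynapticDrive("AMPA", tuple((l, g_ampa) for l in locs), (t_ev,)),
        SynapticDrive("NMDA", tuple((l, g_nmda) for l in locs), (t_ev,)),
    ]

    peaks = {}
    for vhold in (-70.0, 60.0):
        res = run(blocked, drives, duration=hold_ms + 300.0, dt=dt,
                  clamp=VoltageClamp(SOMA, vhold), settle_ms=200.0)
        i = res.i_clamp
        base = i[(res.t > t_ev - 50) & (res.t < t_ev)].mean()
        t_from = t_ev if vhold < 0 else t_ev + 15.0
        peaks[vhold] = float(np.abs(i[res.t >= t_from] - base).max())
    return peaks[60.0] / peaks[-70.0]
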
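"""The randomized basal-stimulation experiment: persistent-activity trials,
spike-train metrics, spatial analysis, and dADP-threshold sweeps.

A trial stimulates 200 excitatory (AMPA+NMDA) synapses, 20 on each of 10
basal branches drawn at random, with 10 synchronous events at 20 Hz, while
5 inhibitory (GABA_A+GABA_B) synapses at the soma fire at 50 Hz.  Recording
lasts 5 s; persistent activity is firing that continues for at least 3 s
past the end of the stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import ranksums

from . import simulator as sim
from .morphology import BranchLocation
from .simulator import CellSpec, SOMA, SynapticDrive, ProtocolError


class AnalysisError(ValueError):
    """Invalid input to a trial-set analysis."""


@dataclass
class TrialConfig:
    """Stimulation-protocol constants plus the trial seed."""

    n_branches: int = 10
    syn_per_branch: int = 20
    exc_events: int = 10
    exc_rate_hz: float = 20.0
    n_inh_synapses: int = 5
    inh_rate_hz: float = 50.0
    stim_onset_ms: float = 200.0
    record_duration_ms: float = 5000.0
    dt: float = 0.025
    trial_seed: int = 0

    @property
    def n_exc_synapses(self) -> int:
        return self.n_branches * self.syn_per_branch

    @property
    def stim_end_ms(self) -> float:
        return self.stim_onset_ms + self.exc_events * 1000.0 / self.exc_rate_hz

    def exc_event_times(self) -> tuple:
        period = 1000.0 / self.exc_rate_hz
        return tuple(self.stim_onset_ms + k * period for k in range(self.exc_events))

    def inh_event_times(self) -> tuple:
        period = 1000.0 / self.inh_rate_hz
        n = int(round((self.stim_end_ms - self.stim_onset_ms) / period))
        return tuple(self.stim_onset_ms + k * period for k in range(n))


@dataclass
class TrialResult:
    spike_times: np.ndarray
    stim_onset: float
    stim_end: float
    persistent: bool
    post_stim_duration: float
    activated_branches: tuple  # section ids
    mean_branch_distance: float
    ap_latency: float  # first spike - first stimulus event, ms
    isis: np.ndarray  # ISIs of the stimulus-period response, ms
    n_stim_spikes: int
    suprathreshold: bool
    seed: int

    def stimulus_rate_hz(self) -> float:
        dur = (self.stim_end - self.stim_onset) / 1000.0
        return self.n_stim_spikes / dur

    def post_rate_hz(self) -> float:
        post = self.spike_times[self.spike_times > self.stim_end]
        dur = (self.spike_times[-1] - self.stim_end) / 1000.0 if len(post) else 0.0
        return len(post) / dur if dur > 0 else 0.0


def classify_persistence(spike_times: np.ndarray, stim_end: float,
                         min_duration: float = 3000.0,
                         max_gap: float = 500.0) -> bool:
    """Persistent iff activity extends >= ``min_duration`` past stimulus end
    with no inter-spike gap longer than ``max_gap`` in that window."""
    s = np.asarray(spike_times, dtype=float)
    post = s[s > stim_end]
    if len(post) == 0 or post[-1] < stim_end + min_duration:
        return False
    pts = np.concatenate([[stim_end], post[post <= stim_end + min_duration],
                          [stim_end + min_duration]])
    return bool(np.max(np.diff(pts)) <= max_gap)


def post_stimulus_duration(spike_times, stim_end: float) -> float:
    """Time from stimulus end to the last spike (0 if none after)."""
    s = np.asarray(spike_times, dtype=float)
    post = s[s > stim_end]
    return float(post[-1] - stim_end) if len(post) else 0.0


def run_trial(cell: CellSpec, cfg: TrialConfig) -> TrialResult:
    """One randomized-placement stimulation trial.

    The trial seed drives branch selection (10 basal branches without
    replacement), the 20 uniform synapse positions per branch, and the
    somatic noise current.  Event times are identical across trials.
    """
    m = cell.morphology
    basal = m.basal_sections()
    if len(basal) < cfg.n_branches:
        raise ProtocolError(
            f"morphology has {len(basal)} basal branches; need >= {cfg.n_branches}"
        )
    rng = np.random.default_rng(cfg.trial_seed)
    chosen = rng.choice([s.id for s in basal], size=cfg.n_branches, replace=False)
    placements = []
    for sec_id in chosen:
        for pos in rng.uniform(0.0, 1.0, cfg.syn_per_branch):
            placements.append(BranchLocation(int(sec_id), float(pos)))

    g_ampa = cell.syn.g_ampa * cell.syn.ampa_scale
    g_nmda = cell.syn.g_nmda(cell.nmda_ratio)
    exc_t = cfg.exc_event_times()
    inh_t = cfg.inh_event_times()
    drives = [
        SynapticDrive("AMPA", tuple((l, g_ampa) for l in placements), exc_t),
        SynapticDrive("NMDA", tuple((l, g_nmda) for l in placements), exc_t),
        SynapticDrive("GABA_A", ((SOMA, cell.syn.g_gaba_a),) * cfg.n_inh_synapses, inh_t),
        SynapticDrive("GABA_B", ((SOMA, cell.syn.g_gaba_b),) * cfg.n_inh_synapses, inh_t),
    ]
    res = sim.run(cell, drives, duration=cfg.record_duration_ms, dt=cfg.dt,
                  seed=cfg.trial_seed)
    s = res.spike_times
    stim_mask = (s >= cfg.stim_onset_ms) & (s <= cfg.stim_end_ms)
    stim_spikes = s[stim_mask]
    latency = float(stim_spikes[0] - cfg.stim_onset_ms) if len(stim_spikes) else math.nan
    isis = np.diff(stim_spikes)
    mean_dist = float(np.mean([m.branch_center_distance(int(i)) for i in chosen]))
    return TrialResult(
        spike_times=s,
        stim_onset=cfg.stim_onset_ms,
        stim_end=cfg.stim_end_ms,
        persistent=classify_persistence(s, cfg.stim_end_ms),
        post_stim_duration=post_stimulus_duration(s, cfg.stim_end_ms),
        activated_branches=tuple(int(i) for i in chosen),
        mean_branch_distance=mean_dist,
        ap_latency=latency,
        isis=isis,
        n_stim_spikes=int(len(stim_spikes)),
        suprathreshold=bool(len(stim_spikes) >= 5),
        seed=cfg.trial_seed,
    )


def run_trials(cell: CellSpec, n_trials: int, base_seed: int = 1,
               cfg: TrialConfig | None = None) -> list[TrialResult]:
    """Seeded trial corpus: trial k uses seed base_seed + k (paired design
    across conditions)."""
    cfg = cfg or TrialConfig()
    out = []
    for k in range(n_trials):
        out.append(run_trial(cell, replace(cfg, trial_seed=base_seed + k)))
    return out


# ---------------------------------------------------------------------------
# Spike-train metrics
# ---------------------------------------------------------------------------

def cv_binned(spike_times, bin_ms: float = 250.0, t0: float = 0.0,
              t1: float | None = None, min_isis: int = 3) -> np.ndarray:
    """Coefficient of variation of ISIs per time bin.

    Each ISI is assigned to the bin containing its leading spike; bins with
    fewer than ``min_isis`` ISIs are masked (NaN).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    s = np.asarray(spike_times, dtype=float)
    if t1 is None:
        t1 = s[-1] if len(s) else t0 + bin_ms
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    out = np.full(len(edges) - 1, np.nan)
    if len(s) < 2:
        return out
    isis = np.diff(s)
    lead = s[:-1]
    for b in range(len(out)):
        m = (lead >= edges[b]) & (lead < edges[b + 1])
        if m.sum() >= min_isis:
            vals = isis[m]
            out[b] = np.std(vals) / np.mean(vals)
    return out


@dataclass
class SpatialSummary:
    mean_persistent: float
    mean_non_persistent: float
    p_value: float
    distances_persistent: np.ndarray
    distances_non_persistent: np.ndarray


def spatial_summary(trials: list[TrialResult]) -> SpatialSummary:
    """Mean activated-branch path distance per class plus a rank-sum test.

    Uses the per-trial mean of the 10 activated branch-centre distances;
    the comparison of interest is 'persistent' vs 'no persistent' trials.
    """
    pers = np.asarray([t.mean_branch_distance for t in trials if t.persistent])
    nonp = np.asarray([t.mean_branch_distance for t in trials if not t.persistent])
    if len(pers) < 2 or len(nonp) < 2:
        raise AnalysisError("need at least 2 trials in each class")
    if np.allclose(pers.mean(), nonp.mean()) and np.std(np.concatenate([pers, nonp])) == 0:
        p = 1.0
    else:
        p = float(ranksums(pers, nonp).pvalue)
    return SpatialSummary(
        mean_persistent=float(pers.mean()),
        mean_non_persistent=float(nonp.mean()),
        p_value=p,
        distances_persistent=pers,
        distances_non_persistent=nonp,
    )


# ---------------------------------------------------------------------------
# dADP-threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepLevel:
    g_can: float
    dadp_mv: float
    persist_fraction: float
    trials: list


@dataclass
class SweepResult:
    levels: list  # of SweepLevel, in evaluation order
    threshold_g_can: float | None
    threshold_dadp_mv: float | None

    def sorted_levels(self):
        return sorted(self.levels, key=lambda l: l.g_can)


class SweepError(RuntimeError):
    def __init__(self, msg, achieved_fraction):
        super().__init__(msg)
        self.achieved_fraction = achieved_fraction


def _dadp_at(cell: CellSpec, g_can: float) -> float:
    try:
        return sim.dadp_protocol(cell.with_gcan(g_can), 5).measurement.amplitude
    except ProtocolError:
        return math.nan  # suprathreshold dADP; amplitude not measurable


def find_dadp_threshold(
    cell: CellSpec,
    n_trials: int = 10,
    base_seed: int = 1,
    criterion: float = 0.5,
    g_lo: float = 5e-5,
    g_hi: float | None = None,
    resolution_mv: float = 0.1,
    cfg: TrialConfig | None = None,
    progress=None,
) -> SweepResult:
    """Smallest CAN conductance giving persistence in >= ``criterion`` of the
    seeded trials, reported as the dADP (mV) of the 5-pulse protocol there.

    Bisects over g_can with the same trial seeds at every level (paired
    design) until the dADP gap between the bracketing levels is below
    ``resolution_mv``.  Raises SweepError if the criterion is unreachable
    at ``g_hi``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    from .config import load_calibrated
    if g_hi is None:
        g_hi = load_calibrated().get("can", {}).get("g_can_max", 1.5e-3) * 1.4

    levels: list[SweepLevel] = []

    def frac_at(g_can: float) -> SweepLevel:
        trials = run_trials(cell.with_gcan(g_can), n_trials, base_seed, cfg)
        frac = float(np.mean([t.persistent for t in trials]))
        lvl = SweepLevel(g_can=g_can, dadp_mv=_dadp_at(cell, g_can),
                         persist_fraction=frac, trials=trials)
        levels.append(lvl)
        if progress:
            progress(lvl)
        return lvl

    lo_lvl = frac_at(g_lo)
    hi_lvl = frac_at(g_hi)
    if hi_lvl.persist_fraction < criterion:
        raise SweepError(
            f"persistence fraction {hi_lvl.persist_fraction:.2f} at the upper "
            f"g_can bound {g_hi:.2e}; criterion {criterion} unreachable",
            achieved_fraction=hi_lvl.persist_fraction,
        )
    if lo_lvl.persist_fraction >= criterion:
        return SweepResult(levels, lo_lvl.g_can, lo_lvl.dadp_mv)

    lo, hi = lo_lvl, hi_lvl
    for _ in range(30):
        gap = (hi.dadp_mv if not math.isnan(hi.dadp_mv) else 12.0) - \
              (lo.dadp_mv if not math.isnan(lo.dadp_mv) else 12.0)
        if abs(gap) <= 2 * resolution_mv:
            break
        mid = frac_at(0.5 * (lo.g_can + hi.g_can))
        if mid.persist_fraction >= criterion:
            hi = mid
        else:
            lo = mid
    return SweepResult(levels, hi.g_can, hi.dadp_mv)


def build_corpus(
    cell: CellSpec,
    n_persistent: int,
    n_non_persistent: int,
    base_seed: int = 1,
    max_trials: int = 160,
    cfg: TrialConfig | None = None,
) -> list[TrialResult]:
    """Run seeded trials until each class quota is met (the decoding corpora
    are stratified: e.g. 40 persistent / 20 no-persistent per condition).

    Trials beyond a filled quota are discarded; raises SweepError when the
    cap is hit first.
    """
    cfg = cfg or TrialConfig()
    pos: list[TrialResult] = []
    neg: list[TrialResult] = []
    k = 0
    while (len(pos) < n_persistent or len(neg) < n_non_persistent) and k < max_trials:
        t = run_trial(cell, replace(cfg, trial_seed=base_seed + k))
        k += 1
        if math.isnan(t.ap_latency) or len(t.isis) < 5:
            continue  # subthreshold response: unusable for decoding features
        if t.persistent and len(pos) < n_persistent:
            pos.append(t)
        elif not t.persistent and len(neg) < n_non_persistent:
            neg.append(t)
    if len(pos) < n_persistent or len(neg) < n_non_persistent:
        raise SweepError(
            f"corpus quota unmet after {k} trials "
            f"({len(pos)}/{n_persistent} persistent, {len(neg)}/{n_non_persistent} not)",
            achieved_fraction=len(pos) / max(k, 1),
        )
    return pos + neg
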
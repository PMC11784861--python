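"""Balanced-state spiking network with distance-dependent conduction delays.

Conductance-based leaky integrate-and-fire neurons (80 % excitatory, 20 %
inhibitory) are arranged on a lattice over a periodic 2-D sheet.  Each
cell makes a fixed number of synapses whose targets are drawn with a
probability that falls off as a Gaussian of torus distance; every synapse
carries a delay ``tau_ij = tau_s + d_ij / v_c`` that grows linearly with
distance at the conduction speed of unmyelinated horizontal axons.  After
a brief external kick the network self-sustains low-rate
asynchronous-irregular activity which, through the local coupling and the
delays, organizes into traveling waves.  A simulated LFP is pooled from
the summed magnitudes of excitatory and inhibitory synaptic currents in
non-overlapping 10 x 10-neuron pools and can be fed to the wave detector
unchanged.  Short Poisson feedback volleys onto a local patch (biased
toward inhibitory targets) sparsify spiking under a passing wave;
inhibitory stabilization shows up as a transient dip of both E and I
rates when the feedback ends.

Integration is forward Euler at dt = 0.1 ms with delayed spike delivery
through a circular event buffer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from .containers import SpikeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "FeedbackSpec",
    "Network",
    "build_network",
    "simulate",
    "detect_sim_waves",
    "apply_feedback",
    "sparsity_metrics",
    "ai_state_statistics",
]


@dataclass
class NetworkConfig:
    """Scaled-down network defaults holding the asynchronous-irregular state.

    The conductance increments were calibrated once (documented in the
    methods note) so that the default network self-sustains low-rate AI
    activity for the full simulated duration after the initial kick.
    """

    n_neurons: int = 20_000  # adjusted down to a full lattice
    frac_excitatory: float = 0.8
    area_mm: tuple = (2.0, 2.0)  # periodic sheet
    synapses_per_cell: int = 320
    connectivity_sigma_mm: float = 0.15  # excitatory reach
    connectivity_sigma_inh_mm: Optional[float] = 0.08  # inhibition is local
    tau_s_ms: float = 0.5  # fixed synaptic-release delay
    v_c: float = 0.05  # axonal conduction speed, m/s (scaled-down sheet)
    dt_ms: float = 0.1
    # LIF parameters (standard cortical values)
    c_m_pf: float = 100.0
    g_l_ns: float = 10.0  # tau_m = 10 ms
    e_leak_mv: float = -60.0
    e_exc_mv: float = 0.0
    e_inh_mv: float = -80.0
    v_thresh_mv: float = -50.0
    v_reset_mv: float = -60.0
    t_ref_ms: float = 5.0
    tau_e_ms: float = 5.0
    tau_i_ms: float = 5.0
    # per-spike conductance increments, nS (calibrated for the AI state)
    g_exc_ns: float = 2.0
    g_inh_ns: float = 63.0
    # initial kick
    kick_ms: float = 50.0
    kick_rate_hz: float = 300.0
    g_ext_ns: float = 2.0
    # simulated LFP: pools of pool_size x pool_size neurons
    pool_size: int = 20
    lfp_fs: float = 1000.0
    # safety ceiling on the population rate (Hz/neuron) before abort
    rate_ceiling_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_excitatory < 1.0):
            raise ValueError("frac_excitatory must be in (0, 1)")
        if self.dt_ms > 0.1:
            raise ValueError("dt must be <= 0.1 ms")
        if self.v_c <= 0 or self.tau_s_ms < 0:
            raise ValueError("invalid delay parameters")


@dataclass
class FeedbackSpec:
    """A short Poisson feedback volley onto a local patch.

    ``rate_hz`` is the summed input rate each targeted cell receives;
    ``p_target_inhibitory`` the fraction of the total feedback drive
    routed to inhibitory cells in the patch.
    """

    patch_center_mm: tuple = (1.0, 1.0)
    patch_size_mm: float = 0.4
    duration_ms: float = 20.0
    rate_hz: float = 3000.0
    p_target_inhibitory: float = 0.8
    onset_ms: Optional[float] = None  # None -> triggered on wave arrival

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_target_inhibitory <= 1.0):
            raise ValueError("p_target_inhibitory must be in [0, 1]")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")


class Network:
    """A built network: geometry, types, synapse table, delays."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w, h = cfg.area_mm
        rows = int(round(np.sqrt(cfg.n_neurons * h / w)))
        cols = cfg.n_neurons // max(rows, 1)
        self.rows, self.cols = rows, cols
        self.n = rows * cols
        if self.n != cfg.n_neurons:
            logger.info("lattice adjusted: %d neurons (%dx%d)", self.n, rows, cols)
        self.pitch_mm = (w / cols, h / rows)
        rr, cc = np.divmod(np.arange(self.n), cols)
        self.positions = np.column_stack([cc * self.pitch_mm[0], rr * self.pitch_mm[1]])
        n_exc = int(round(cfg.frac_excitatory * self.n))
        types = np.zeros(self.n, dtype=np.bool_)
        types[rng.choice(self.n, size=n_exc, replace=False)] = True
        self.is_excitatory = types

        if cfg.synapses_per_cell >= self.n:
            raise ValueError("synapses_per_cell exceeds population")

        # Gaussian offset kernels on the torus, shared by every neuron of a
        # type; inhibition may be shorter-range than excitation
        sigma_i = cfg.connectivity_sigma_inh_mm or cfg.connectivity_sigma_mm

        def offset_kernel(sigma):
            max_r = min(rows // 2, max(1, int(np.ceil(4 * sigma / self.pitch_mm[1]))))
            max_c = min(cols // 2, max(1, int(np.ceil(4 * sigma / self.pitch_mm[0]))))
            DR, DC = np.meshgrid(np.arange(-max_r, max_r + 1),
                                 np.arange(-max_c, max_c + 1), indexing="ij")
            dist_mm = np.hypot(DR * self.pitch_mm[1], DC * self.pitch_mm[0])
            wgt = np.exp(-0.5 * (dist_mm / sigma) ** 2)
            wgt[(DR == 0) & (DC == 0)] = 0.0  # no autapses
            return DR.ravel(), DC.ravel(), dist_mm.ravel(), wgt.ravel() / wgt.sum()

        K = cfg.synapses_per_cell
        off_dr = np.empty((self.n, K), dtype=np.int64)
        off_dc = np.empty((self.n, K), dtype=np.int64)
        d_mm = np.empty((self.n, K))
        for sigma, sel in ((cfg.connectivity_sigma_mm, types),
                           (sigma_i, ~types)):
            if not sel.any():
                continue
            DRf, DCf, distf, p = offset_kernel(sigma)
            ids = rng.choice(p.size, size=(int(sel.sum()), K), p=p)
            off_dr[sel] = DRf[ids]
            off_dc[sel] = DCf[ids]
            d_mm[sel] = distf[ids]
        src_r = rr[:, None]
        src_c = cc[:, None]
        tgt_r = (src_r + off_dr) % rows
        tgt_c = (src_c + off_dc) % cols
        self.targets = (tgt_r * cols + tgt_c).astype(np.int32).ravel()
        d_mm = d_mm.ravel()
        delay_ms = cfg.tau_s_ms + d_mm / cfg.v_c  # mm / (m/s) = ms
        self.delay_steps = np.maximum(
            1, np.round(delay_ms / cfg.dt_ms).astype(np.int32)
        )
        self.delays_ms = self.delay_steps * cfg.dt_ms
        self.distances_mm = d_mm
        self.K = K

        # LFP pools: pool_size x pool_size blocks of the lattice
        ps = cfg.pool_size
        pr, pc = rows // ps, cols // ps
        pool_id = np.full(self.n, -1, dtype=np.int32)
        prow, pcol = rr // ps, cc // ps
        inside = (prow < pr) & (pcol < pc)
        pool_id[inside] = (prow * pc + pcol)[inside]
        self.pool_id = pool_id
        self.pool_grid = (pr, pc)
        py, px = np.divmod(np.arange(pr * pc), pc)
        self.pool_coords = np.column_stack(
            [(px + 0.5) * ps * self.pitch_mm[0], (py + 0.5) * ps * self.pitch_mm[1]]
        )

    def patch_mask(self, center_mm: tuple, size_mm: float) -> np.ndarray:
        """Boolean mask of neurons inside a square patch (torus metric)."""
        w, h = self.cfg.area_mm
        if not (0 <= center_mm[0] <= w and 0 <= center_mm[1] <= h):
            raise ValueError("patch centre outside the simulated area")
        dx = np.abs(self.positions[:, 0] - center_mm[0])
        dy = np.abs(self.positions[:, 1] - center_mm[1])
        dx = np.minimum(dx, w - dx)
        dy = np.minimum(dy, h - dy)
        mask = (dx <= size_mm / 2) & (dy <= size_mm / 2)
        if not mask.any():
            raise ValueError("patch outside the simulated area")
        return mask


def build_network(cfg: NetworkConfig) -> Network:
    """Place neurons, draw Gaussian local connectivity and linear delays."""
    return Network(cfg)


@njit(cache=True)
def _run_kernel(
    n_steps, n, K, targets, delay_steps, is_exc,
    v, ge, gi, refr,
    dt_ms, c_m, g_l, e_l, e_e, e_i, v_th, v_re, ref_steps,
    dec_e, dec_i, w_e, w_i,
    ext_rate_per_step, ext_until_step, g_ext,
    fb_rate_per_step, fb_start, fb_end, fb_targets_rate,
    max_delay, pool_id, n_pools, lfp_stride, lfp_out,
    spikes_t, spikes_i, max_spikes, seed,
):
    np.random.seed(seed)
    ebuf = np.zeros((max_delay, n), dtype=np.float64)
    ibuf = np.zeros((max_delay, n), dtype=np.float64)
    acc = np.zeros(n_pools, dtype=np.float64)
    count = 0
    lfp_col = 0
    for step in range(n_steps):
        slot = step % max_delay
        for i in range(n):
            ge[i] = ge[i] * dec_e + ebuf[slot, i]
            gi[i] = gi[i] * dec_i + ibuf[slot, i]
            ebuf[slot, i] = 0.0
            ibuf[slot, i] = 0.0
        if step < ext_until_step:
            for i in range(n):
                k = np.random.poisson(ext_rate_per_step)
                if k > 0:
                    ge[i] += k * g_ext
        if fb_start <= step < fb_end:
            for i in range(n):
                if fb_targets_rate[i] > 0.0:
                    k = np.random.poisson(fb_targets_rate[i] * fb_rate_per_step)
                    if k > 0:
                        ge[i] += k * g_ext
        spiked_this = 0
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_re
            else:
                i_syn = (
                    g_l * (e_l - v[i])
                    + ge[i] * (e_e - v[i])
                    + gi[i] * (e_i - v[i])
                )
                # nS * mV / pF = pA / pF = mV per ms
                v[i] = v[i] + dt_ms * i_syn / c_m
            p = pool_id[i]
            if p >= 0:
                acc[p] += abs(ge[i] * (e_e - v[i])) + abs(gi[i] * (e_i - v[i]))
            if refr[i] == 0 and v[i] >= v_th:
                v[i] = v_re
                refr[i] = ref_steps
                spiked_this += 1
                if count < max_spikes:
                    spikes_t[count] = step
                    spikes_i[count] = i
                    count += 1
                else:
                    return -count  # runaway: spike budget exhausted
                base = i * K
                if is_exc[i]:
                    for s in range(K):
                        ebuf[(step + delay_steps[base + s]) % max_delay, targets[base + s]] += w_e
                else:
                    for s in range(K):
                        ibuf[(step + delay_steps[base + s]) % max_delay, targets[base + s]] += w_i
        if (step + 1) % lfp_stride == 0:
            if lfp_col < lfp_out.shape[1]:
                for p in range(n_pools):
                    lfp_out[p, lfp_col] = acc[p] / lfp_stride
                    acc[p] = 0.0
                lfp_col += 1
    return count


def simulate(
    net: Network,
    duration_s: float,
    feedback: Optional[FeedbackSpec] = None,
    feedback_onset_ms: Optional[float] = None,
    seed: Optional[int] = None,
    record_lfp: bool = True,
) -> SpikeRecord:
    """Integrate the network for ``duration_s`` seconds.

    The network receives an external Poisson kick for the first
    ``kick_ms`` to seed the self-sustained state; afterwards there is no
    external drive unless a :class:`FeedbackSpec` is active.  Raises
    ``RuntimeError`` on runaway activity (population rate ceiling hit).
    """
    cfg = net.cfg
    dt_s = cfg.dt_ms * 1e-3
    n_steps = int(round(duration_s / dt_s))
    max_delay = int(net.delay_steps.max()) + 1
    ref_steps = int(round(cfg.t_ref_ms / cfg.dt_ms))
    rng_seed = cfg.seed if seed is None else seed

    max_spikes = int(cfg.rate_ceiling_hz * net.n * duration_s) + net.n
    spikes_t = np.empty(max_spikes, dtype=np.int64)
    spikes_i = np.empty(max_spikes, dtype=np.int32)

    lfp_stride = max(1, int(round(1.0 / (cfg.lfp_fs * dt_s))))
    n_pools = net.pool_grid[0] * net.pool_grid[1]
    n_lfp = n_steps // lfp_stride if record_lfp else 0
    lfp_out = np.zeros((n_pools, max(n_lfp, 1)), dtype=np.float64)

    rng = np.random.default_rng(rng_seed)
    v0 = rng.uniform(cfg.v_reset_mv, cfg.v_thresh_mv, size=net.n)
    ge0 = np.zeros(net.n)
    gi0 = np.zeros(net.n)
    refr0 = np.zeros(net.n, dtype=np.int32)

    fb_targets_rate = np.zeros(net.n)
    fb_start = fb_end = -1
    fb_rate_per_step = 0.0
    if feedback is not None:
        onset_ms = feedback.onset_ms if feedback.onset_ms is not None else feedback_onset_ms
        if onset_ms is None:
            raise ValueError("feedback onset not set; use apply_feedback for wave triggering")
        mask = net.patch_mask(feedback.patch_center_mm, feedback.patch_size_mm)
        inh = mask & ~net.is_excitatory
        exc = mask & net.is_excitatory
        # route p_target_inhibitory of the total drive to inhibitory cells
        if inh.any():
            fb_targets_rate[inh] = feedback.p_target_inhibitory
        if exc.any():
            fb_targets_rate[exc] = 1.0 - feedback.p_target_inhibitory
        fb_start = int(round(onset_ms * 1e-3 / dt_s))
        fb_end = fb_start + int(round(feedback.duration_ms * 1e-3 / dt_s))
        fb_rate_per_step = feedback.rate_hz * dt_s

    count = _run_kernel(
        n_steps, net.n, net.K, net.targets, net.delay_steps,
        net.is_excitatory,
        v0, ge0, gi0, refr0,
        cfg.dt_ms, cfg.c_m_pf, cfg.g_l_ns, cfg.e_leak_mv, cfg.e_exc_mv,
        cfg.e_inh_mv, cfg.v_thresh_mv, cfg.v_reset_mv, ref_steps,
        float(np.exp(-cfg.dt_ms / cfg.tau_e_ms)),
        float(np.exp(-cfg.dt_ms / cfg.tau_i_ms)),
        cfg.g_exc_ns, cfg.g_inh_ns,
        cfg.kick_rate_hz * dt_s, int(round(cfg.kick_ms * 1e-3 / dt_s)),
        cfg.g_ext_ns,
        fb_rate_per_step, fb_start, fb_end, fb_targets_rate,
        max_delay, net.pool_id, n_pools, lfp_stride, lfp_out,
        spikes_t, spikes_i, max_spikes, int(rng_seed) % (2**31 - 1),
    )
    if count < 0:
        raise RuntimeError(
            f"runaway activity: spike budget ({max_spikes}) exhausted after "
            f"{-count} spikes; population rate ceiling "
            f"{cfg.rate_ceiling_hz} Hz/neuron exceeded"
        )
    spikes = np.column_stack([spikes_t[:count] * dt_s, spikes_i[:count]]).astype(float)
    return SpikeRecord(
        spikes=spikes,
        positions=net.positions,
        is_excitatory=net.is_excitatory,
        sim_lfp=lfp_out if record_lfp else None,
        lfp_coords=net.pool_coords,
        lfp_fs=cfg.lfp_fs,
        duration=duration_s,
    )


# ---------------------------------------------------------------------------
# Diagnostics


def ai_state_statistics(record: SpikeRecord, discard_s: float = 0.5,
                        bin_s: float = 0.02, n_pairs: int = 2000,
                        min_spikes: int = 5, seed: int = 0) -> dict:
    """Asynchronous-irregular diagnostics: rate, CV of ISIs, pairwise corr.

    The first ``discard_s`` (kick transient) is excluded.  CV of the
    inter-spike intervals is averaged over neurons with at least
    ``min_spikes`` spikes; the mean pairwise spike-count correlation uses
    ``n_pairs`` random active pairs at ``bin_s`` binning.
    """
    rng = np.random.default_rng(seed)
    t = record.spikes[:, 0]
    ids = record.spikes[:, 1].astype(int)
    keep = t >= discard_s
    t, ids = t[keep], ids[keep]
    span = record.duration - discard_s
    n = record.positions.shape[0]
    rates = np.bincount(ids, minlength=n) / span

    cvs = []
    order = np.argsort(ids, kind="stable")
    ids_s, t_s = ids[order], t[order]
    bounds = np.searchsorted(ids_s, np.arange(n + 1))
    for i in range(n):
        st = np.sort(t_s[bounds[i]:bounds[i + 1]])
        if st.size >= min_spikes:
            isi = np.diff(st)
            if isi.mean() > 0:
                cvs.append(isi.std() / isi.mean())
    cv = float(np.mean(cvs)) if cvs else float("nan")

    bins = np.arange(discard_s, record.duration + bin_s, bin_s)
    active = np.flatnonzero(rates > 1.0 / span)
    corr = float("nan")
    if active.size >= 10:
        counts = {}
        cors = []
        for _ in range(n_pairs):
            a, b = rng.choice(active, size=2, replace=False)
            for x in (a, b):
                if x not in counts:
                    counts[x] = np.histogram(t_s[bounds[x]:bounds[x + 1]], bins)[0]
            ca, cb = counts[a], counts[b]
            if ca.std() > 0 and cb.std() > 0:
                cors.append(np.corrcoef(ca, cb)[0, 1])
        corr = float(np.mean(cors)) if cors else float("nan")

    return {
        "mean_rate_hz": float(rates.mean()),
        "active_fraction": float((rates > 0).mean()),
        "cv_isi": cv,
        "mean_pairwise_corr": corr,
        "survived": bool(t.size > 0 and t.max() > record.duration - 2 * bin_s - 0.05),
    }


def detect_sim_waves(record: SpikeRecord, n_shuffles: int = 500,
                     edge: float = 0.1, seed: int = 0):
    """Run the traveling-wave detector on the pooled simulated LFP."""
    from .preprocess import bandpass
    from .waves import WaveDetector

    lfp = record.as_grid_lfp()
    lfp = bandpass(lfp, "wideband")
    det = WaveDetector(n_shuffles=n_shuffles, edge=edge, seed=seed)
    det.fit(lfp)
    events = det.detect()
    return events, det


# ---------------------------------------------------------------------------
# Feedback experiments


def _patch_rate(record: SpikeRecord, mask: np.ndarray, bin_s: float = 0.005) -> tuple:
    ids = record.spikes[:, 1].astype(int)
    sel = mask[ids]
    bins = np.arange(0.0, record.duration + bin_s, bin_s)
    counts = np.histogram(record.spikes[sel, 0], bins)[0]
    rate = counts / (bin_s * mask.sum())
    return rate, bins[:-1]


def apply_feedback(net: Network, fb: FeedbackSpec, duration_s: float = 1.5,
                   seed: Optional[int] = None,
                   trigger_after_s: float = 0.5) -> dict:
    """Seed-matched runs with and without the feedback volley.

    When ``fb.onset_ms`` is unset, the onset is triggered on wave arrival:
    a baseline run locates the first prominent peak of the patch
    population rate after ``trigger_after_s`` (a wave passing over the
    patch) and the feedback window is centred on it in the paired run.
    Returns both records plus patch rate time courses.
    """
    mask = net.patch_mask(fb.patch_center_mm, fb.patch_size_mm)
    base = simulate(net, duration_s, seed=seed)
    if fb.onset_ms is None:
        rate, tt = _patch_rate(base, mask)
        sel = tt >= trigger_after_s
        if not sel.any() or rate[sel].max() == 0:
            onset_ms = trigger_after_s * 1000.0
        else:
            peak_t = tt[sel][int(np.argmax(rate[sel]))]
            onset_ms = max(peak_t * 1000.0 - fb.duration_ms / 2.0, 0.0)
    else:
        onset_ms = fb.onset_ms
    with_fb = simulate(net, duration_s, feedback=fb, feedback_onset_ms=onset_ms,
                       seed=seed)
    rate_base, tt = _patch_rate(base, mask)
    rate_fb, _ = _patch_rate(with_fb, mask)
    return {
        "baseline": base,
        "feedback": with_fb,
        "onset_ms": onset_ms,
        "window_ms": (onset_ms, onset_ms + fb.duration_ms),
        "patch_mask": mask,
        "patch_rate_baseline": rate_base,
        "patch_rate_feedback": rate_fb,
        "rate_times_s": tt,
    }


def sparsity_metrics(record: SpikeRecord, patch_mask: np.ndarray,
                     windows: list) -> dict:
    """Per-wave-pass spiking sparsity in the patch.

    For each (start, end) window in seconds: the fraction of patch
    neurons that spike, and their mean rate.  Across passes, per-neuron
    reliability is the fraction of passes in which the neuron spiked.
    """
    ids = record.spikes[:, 1].astype(int)
    t = record.spikes[:, 0]
    patch_ids = np.flatnonzero(patch_mask)
    fractions, rates = [], []
    spk = np.zeros((len(windows), patch_ids.size), dtype=bool)
    pos = {int(x): j for j, x in enumerate(patch_ids)}
    for w, (a, b) in enumerate(windows):
        sel = (t >= a) & (t < b) & patch_mask[ids]
        who = np.unique(ids[sel])
        for x in who:
            spk[w, pos[int(x)]] = True
        fractions.append(who.size / patch_ids.size)
        rates.append(sel.sum() / (patch_ids.size * (b - a)))
    reliability = spk.mean(axis=0) if windows else np.zeros(0)
    return {
        "spiking_fraction": np.asarray(fractions),
        "mean_rate_hz": np.asarray(rates),
        "reliability": reliability,
    }
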
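"""Neuronal-ensemble detection from calcium rasters.

Pipeline: range-normalize the fluorescence, binarize the deconvolved event
trains against the noise floor (2.5 SD), remove solitary events with a
population-coactivity threshold from shuffled surrogates, bin the binary
matrix into 300-ms activity vectors, build the cosine similarity map
between vector pairs, keep eigenstates of the map whose eigenvalues beat
the shuffled-null threshold, and extract the co-active cells of each
eigenstate with a Sørensen-Dice connectivity graph (pairs with Dice > 0.25
are functional connections).  All significance thresholds are 99th
percentiles of spatiotemporally shuffled surrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .containers import CalciumRaster

logger = logging.getLogger(__name__)

__all__ = [
    "center_fluorescence",
    "binarize_events",
    "vectorize",
    "similarity_map",
    "shuffle_surrogates",
    "svd_ensembles",
    "sdc_connectivity",
    "dice",
    "split_by_late_wave",
    "transient_onsets",
    "Ensemble",
    "EnsembleDetector",
    "NullThresholds",
]


# ---------------------------------------------------------------------------
# Normalization and binarization


def center_fluorescence(raster: CalciumRaster) -> tuple:
    """Range-normalized fluorescence: (F - mean) / (max - min) per cell.

    Returns (centered, excluded) where ``excluded`` flags constant-trace
    cells (max == min), whose rows are set to NaN.
    """
    F = raster.dff
    favg = F.mean(axis=1, keepdims=True)
    frange = F.max(axis=1, keepdims=True) - F.min(axis=1, keepdims=True)
    excluded = frange[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        centered = (F - favg) / frange
    centered[excluded] = np.nan
    if excluded.any():
        logger.info("excluded %d constant-fluorescence cells", int(excluded.sum()))
    return centered, excluded


def estimate_noise_sd(raster: CalciumRaster) -> np.ndarray:
    """Per-cell noise floor of ΔF/F.

    Robust first-difference estimator: ``1.4826 * MAD(diff(F)) / sqrt(2)``.
    Unlike the raw trace SD, the frame-to-frame difference is insensitive
    to the slow calcium transients riding on the noise, so the estimate
    stays at the noise floor even for frequently active cells.
    """
    d = np.diff(raster.dff, axis=1)
    med = np.median(d, axis=1, keepdims=True)
    return 1.4826 * np.median(np.abs(d - med), axis=1) / np.sqrt(2.0)


def binarize_events(raster: CalciumRaster, k_sd: float = 2.5,
                    noise_sd: Optional[np.ndarray] = None) -> np.ndarray:
    """Binary event matrix: deconvolved events above ``k_sd`` noise SDs."""
    if noise_sd is None:
        noise_sd = estimate_noise_sd(raster)
    return raster.deconv > (k_sd * np.asarray(noise_sd))[:, None]


# ---------------------------------------------------------------------------
# Vectorization and similarity


def vectorize(binary: np.ndarray, frame_rate: float, bin_ms: float = 300.0) -> tuple:
    """Sum binary events in non-overlapping 300-ms bins.

    Returns (vectors, edges): vectors is (n_cells, n_bins); a partial final
    bin is dropped with a log entry.  Event counts are conserved over the
    retained bins.
    """
    fpb = max(1, int(round(bin_ms / 1000.0 * frame_rate)))
    n_bins = binary.shape[1] // fpb
    if binary.shape[1] % fpb:
        logger.info("dropping partial final bin of %d frames", binary.shape[1] % fpb)
    trimmed = binary[:, : n_bins * fpb]
    vectors = trimmed.reshape(binary.shape[0], n_bins, fpb).sum(axis=2)
    edges = np.arange(n_bins + 1) * fpb
    return vectors.astype(float), edges


def similarity_map(vectors: np.ndarray) -> np.ndarray:
    """Cosine similarity SI(i, j) between all column-vector pairs.

    ``vectors`` is (n_cells, n_bins); the map is (n_bins, n_bins) with unit
    diagonal on nonzero vectors and zero rows/columns for all-zero bins.
    """
    if vectors.shape[1] < 2:
        raise ValueError("need at least two activity vectors")
    norms = np.linalg.norm(vectors, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    unit = vectors / safe
    m = unit.T @ unit
    m[norms == 0, :] = 0.0
    m[:, norms == 0] = 0.0
    return m


# ---------------------------------------------------------------------------
# Shuffled surrogates and thresholds


@dataclass
class NullThresholds:
    """99th-percentile thresholds from spatiotemporally shuffled rasters."""

    coactivity: float
    similarity: float
    eigenvalue: float
    n_iter: int
    percentile: float = 99.0


def _spatiotemporal_shuffle(binary: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-neuron temporal permutation, then a cross-ROI event shuffle.

    The second stage permutes the neuron labels of the events within each
    frame, so both the temporal and the spatial structure of coactivity
    are destroyed while per-frame and (in expectation) per-neuron event
    counts are preserved.
    """
    n, t = binary.shape
    out = np.empty_like(binary)
    for i in range(n):
        out[i] = binary[i, rng.permutation(t)]
    # cross-ROI shuffle: permute neuron identity within each frame
    perm = rng.permutation(n)
    out = out[perm]
    return out


def shuffle_surrogates(binary: np.ndarray, frame_rate: float,
                       n_iter: int = 1000, bin_ms: float = 300.0,
                       percentile: float = 99.0, seed: int = 0) -> NullThresholds:
    """Build the coactivity / similarity / eigenvalue null thresholds.

    Each iteration shuffles the binary matrix, then measures (i) the
    maximum per-frame population coactivity, (ii) the off-diagonal cosine
    similarities of its binned vectors and (iii) the largest eigenvalue of
    its similarity map.  Thresholds are the ``percentile`` of each pooled
    statistic.
    """
    rng = np.random.default_rng(seed)
    n, t = binary.shape
    # Coactivity gate: chance = independent *background* activity at the
    # median per-cell rate (robust to a minority of high-rate ensemble
    # cells).  A frame below this threshold is explainable by solitary
    # background events and is removed.
    med_rate = float(np.median(binary.mean(axis=1)))
    coact_draws = rng.binomial(n, med_rate, size=(n_iter, t))
    coact_thr = float(np.percentile(coact_draws, percentile))

    sims, eigs = [], []
    for _ in range(n_iter):
        sh = _spatiotemporal_shuffle(binary, rng)
        vec, _ = vectorize(sh, frame_rate, bin_ms)
        m = similarity_map(vec)
        iu = np.triu_indices_from(m, k=1)
        off = m[iu]
        sims.append(np.percentile(off, percentile) if off.size else 0.0)
        # cosine maps of nonnegative vectors keep a global mean-rate mode
        # that shuffling cannot remove; the structure-sensitive chance
        # level is the *second* eigenvalue of the shuffled map
        lam = np.linalg.eigvalsh(m)
        eigs.append(lam[-2] if lam.size > 1 else lam[-1])
    return NullThresholds(
        coactivity=coact_thr,
        similarity=float(np.percentile(sims, percentile)),
        eigenvalue=float(np.percentile(eigs, percentile)),
        n_iter=n_iter,
        percentile=percentile,
    )


def coactivity_filter(binary: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out frames whose population coactivity is <= threshold.

    Removes solitary calcium events so that only co-active periods feed
    the ensemble analysis.
    """
    keep = binary.sum(axis=0) > threshold
    out = binary.copy()
    out[:, ~keep] = False
    return out


# ---------------------------------------------------------------------------
# Eigenstates and Dice connectivity


@dataclass
class Ensemble:
    """One detected cell assembly and its connectivity metrics."""

    members: list
    rank: int
    eigenvalue: float
    state_bins: np.ndarray
    weights: dict = dc_field(default_factory=dict)  # (i, j) -> Dice
    node_strength: dict = dc_field(default_factory=dict)
    n_connections: int = 0
    reactivation: float = float("nan")
    reactivation_count: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.members)


def svd_ensembles(m: np.ndarray, vectors: np.ndarray, null: NullThresholds,
                  var_capture: float = 0.9) -> list:
    """Eigenstates of the similarity map that beat the shuffled null.

    The map is first reduced to *reactivating* bins (bins with at least
    one significant off-diagonal similarity).  The symmetric
    eigendecomposition ``M = V diag(lam) V^T`` is kept for components with
    ``lam`` above the null eigenvalue threshold, truncated once the
    retained components cumulatively capture ``var_capture`` of the
    variance.  Each retained component yields candidate state bins: the
    bins whose loading on that component dominates.

    Returns a list of (rank, eigenvalue, state_bins_global_ids).
    """
    n_bins = m.shape[0]
    off = m - np.diag(np.diag(m))
    reactive = (off > null.similarity).any(axis=0)
    keep_bins = np.flatnonzero(reactive)
    if keep_bins.size < 2:
        return []
    sub = m[np.ix_(keep_bins, keep_bins)]
    lam, V = np.linalg.eigh(sub)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    total = lam[lam > 0].sum()
    sig = lam > null.eigenvalue
    out = []
    cum = 0.0
    assign = np.argmax(np.abs(V) * sig[None, :], axis=1) if sig.any() else None
    for r in range(len(lam)):
        if not sig[r]:
            break
        state_local = np.flatnonzero(assign == r)
        out.append((r, float(lam[r]), keep_bins[state_local]))
        cum += lam[r] / total if total > 0 else 0.0
        if cum >= var_capture:
            break
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen-Dice coefficient of two boolean event trains.

    ``2 |A ∩ B| / (|A| + |B|)``; 0 when both trains are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def sdc_connectivity(binary: np.ndarray, state_frames: np.ndarray,
                     dice_thresh: float = 0.25,
                     coactivity_threshold: float = 0.0,
                     min_participation: float = 0.05) -> Optional[Ensemble]:
    """Dice connectivity of event trains restricted to state frames.

    Neuron pairs with Dice > ``dice_thresh`` form functional connections;
    ensemble members are the connected neurons, one ensemble per
    connected component of the Dice graph (returned as a list, strongest
    first).  Node strength is the sum of a node's connection weights.
    Neurons with zero events in the state frames — or active in fewer
    than ``min_participation`` of them, where a couple of chance
    background coincidences would make the Dice of two near-empty trains
    arbitrarily large — are excluded from pairing.  Ensemble reactivation
    is the proportion of members active in at least one state frame whose
    population coactivity beats the shuffled-chance threshold.
    """
    if state_frames.size == 0:
        return []
    sub = binary[:, state_frames]
    ev_counts = sub.sum(axis=1)
    active = np.flatnonzero(
        ev_counts >= max(1, min_participation * state_frames.size)
    )
    if active.size < 2:
        return []
    weights, strength = {}, {}
    parent = {int(i): int(i) for i in active}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            i, j = int(active[ai]), int(active[bi])
            w = dice(sub[i], sub[j])
            if w > dice_thresh:
                weights[(i, j)] = w
                strength[i] = strength.get(i, 0.0) + w
                strength[j] = strength.get(j, 0.0) + w
                parent[find(i)] = find(j)

    if not strength:
        return []
    # one ensemble per connected component of the Dice graph: a mixed
    # activity state (bins carrying two groups' reactivations) yields
    # disconnected cliques that are distinct cell assemblies
    comps: dict = {}
    for i in strength:
        comps.setdefault(find(i), []).append(i)
    coactive_frames = sub.sum(axis=0) > coactivity_threshold
    out = []
    for members in comps.values():
        members = sorted(members)
        mset = set(members)
        wsub = {p: w for p, w in weights.items() if p[0] in mset}
        n_react = sum(1 for m in members if sub[m][coactive_frames].any())
        out.append(Ensemble(
            members=members,
            rank=-1,
            eigenvalue=float("nan"),
            state_bins=state_frames,
            weights=wsub,
            node_strength={m: strength[m] for m in members},
            n_connections=len(wsub),
            reactivation=n_react / len(members),
            reactivation_count=float(n_react),
        ))
    out.sort(key=lambda e: -sum(e.node_strength.values()))
    return out


# ---------------------------------------------------------------------------
# Estimator


class EnsembleDetector(BaseEstimator):
    """Similarity/SVD/Dice ensemble detection with shuffled-null gating.

    Parameters
    ----------
    bin_ms : float
        Activity-vector bin width, ms.
    k_sd : float
        Event binarization threshold in noise SDs.
    dice_thresh : float
        Minimum Dice coefficient for a functional connection.
    n_shuffles : int
        Surrogate count for all three null thresholds.

    Attributes (after ``fit``)
    --------------------------
    ensembles_ : list of :class:`Ensemble`
    thresholds_ : :class:`NullThresholds`
    similarity_ : ndarray
        The bin-by-bin cosine similarity map.
    reactivation_index_ : ndarray
        Per-bin count and fraction of significant partners, shape (2, B).
    """

    def __init__(self, bin_ms: float = 300.0, k_sd: float = 2.5,
                 dice_thresh: float = 0.25, n_shuffles: int = 1000,
                 var_capture: float = 0.9, percentile: float = 99.0,
                 seed: int = 0):
        self.bin_ms = bin_ms
        self.k_sd = k_sd
        self.dice_thresh = dice_thresh
        self.n_shuffles = n_shuffles
        self.var_capture = var_capture
        self.percentile = percentile
        self.seed = seed

    def fit(self, raster: CalciumRaster, y=None) -> "EnsembleDetector":
        binary = binarize_events(raster, self.k_sd)
        self.binary_ = binary
        self.thresholds_ = shuffle_surrogates(
            binary, raster.frame_rate, self.n_shuffles, self.bin_ms,
            self.percentile, self.seed,
        )
        filtered = coactivity_filter(binary, self.thresholds_.coactivity)
        self.filtered_ = filtered
        vectors, edges = vectorize(filtered, raster.frame_rate, self.bin_ms)
        self.vectors_ = vectors
        self.bin_edges_ = edges
        self.similarity_ = similarity_map(vectors)
        off = self.similarity_ - np.diag(np.diag(self.similarity_))
        sig_partners = (off > self.thresholds_.similarity).sum(axis=0)
        denom = max(self.similarity_.shape[0] - 1, 1)
        self.reactivation_index_ = np.vstack([sig_partners, sig_partners / denom])

        candidates = svd_ensembles(
            self.similarity_, vectors, self.thresholds_, self.var_capture
        )
        ensembles = []
        seen = []
        fpb = max(1, int(round(self.bin_ms / 1000.0 * raster.frame_rate)))
        for rank, lam, state_bins in candidates:
            frames = np.concatenate(
                [np.arange(b * fpb, (b + 1) * fpb) for b in state_bins]
            ) if state_bins.size else np.array([], dtype=int)
            comps = sdc_connectivity(
                filtered, frames, self.dice_thresh, self.thresholds_.coactivity
            )
            for ens in comps:
                key = set(ens.members)
                if any(len(key & s) / len(key | s) >= 0.8 for s in seen):
                    continue  # same assembly surfaced by another eigenstate
                seen.append(key)
                ens.rank = rank
                ens.eigenvalue = lam
                ensembles.append(ens)
        self.ensembles_ = ensembles
        return self

    def fit_predict(self, raster: CalciumRaster, y=None) -> list:
        """Fit and return the member lists of the detected ensembles."""
        self.fit(raster)
        return [e.members for e in self.ensembles_]


# ---------------------------------------------------------------------------
# Late-wave grouping and transient onsets


def split_by_late_wave(raster: CalciumRaster, trial_frames: Sequence[tuple],
                       labels: Sequence[str], detector: Optional[EnsembleDetector] = None,
                       min_trials: int = 3) -> dict:
    """Run ensemble detection separately on strong- and weak-late trials.

    ``trial_frames`` lists (start_frame, end_frame) per trial (the -500 ms
    to +4 s touch window); ``labels`` the matching 'strong'/'weak' late
    labels.  Returns per-group ensemble metrics; groups with fewer than
    ``min_trials`` trials are flagged unstable and skipped.
    """
    detector = detector or EnsembleDetector()
    out = {}
    for group in ("strong", "weak"):
        rows = [tf for tf, lb in zip(trial_frames, labels) if lb == group]
        if len(rows) < min_trials:
            out[group] = {"unstable": True, "n_trials": len(rows)}
            continue
        frames = np.concatenate([np.arange(a, b) for a, b in rows])
        frames = frames[(frames >= 0) & (frames < raster.n_frames)]
        sub = CalciumRaster(
            raster.dff[:, frames], raster.deconv[:, frames],
            raster.centroids, raster.frame_rate,
        )
        det = EnsembleDetector(**detector.get_params()).fit(sub)
        sizes = [e.size for e in det.ensembles_]
        out[group] = {
            "unstable": False,
            "n_trials": len(rows),
            "n_ensembles": len(det.ensembles_),
            "sizes": sizes,
            "n_connections": [e.n_connections for e in det.ensembles_],
            "reactivation": [e.reactivation for e in det.ensembles_],
            "weights": [w for e in det.ensembles_ for w in e.weights.values()],
        }
    return out


def transient_onsets(raster: CalciumRaster, touch_times: Sequence[float],
                     window: float = 1.0, responsive_window: float = 2.0,
                     baseline: float = 0.5) -> dict:
    """Touch-locked calcium transient onsets per cell.

    Per cell, the event threshold is the 99th percentile of its deconvolved
    event amplitudes.  For each touch, the largest supra-threshold event
    within ``window`` seconds is located; the onset is the preceding
    inflection point of the deconvolved trace and the time of maximum
    ΔF/F slope is also returned.  A cell is touch-responsive when its mean
    evoked ΔF/F maximum within ``responsive_window`` exceeds 3 baseline
    SDs.
    """
    fr = raster.frame_rate
    n_w = int(round(window * fr))
    n_b = int(round(baseline * fr))
    out = {"onset_s": {}, "max_slope_s": {}, "responsive": np.zeros(raster.n_cells, bool)}
    for c in range(raster.n_cells):
        ev = raster.deconv[c][raster.deconv[c] > 0]
        thr = np.percentile(ev, 99) if ev.size else np.inf
        onsets, slopes = [], []
        evoked_max, base_sd = [], []
        for tt in touch_times:
            i0 = int(round((tt - raster.t0) * fr))
            if i0 - n_b < 0 or i0 + max(n_w, int(responsive_window * fr)) > raster.n_frames:
                continue
            base = raster.dff[c, i0 - n_b:i0]
            base_sd.append(base.std())
            evoked_max.append(
                raster.dff[c, i0:i0 + int(responsive_window * fr)].max() - base.mean()
            )
            seg = raster.deconv[c, i0:i0 + n_w]
            supra = np.flatnonzero(seg >= thr)
            if supra.size == 0:
                onsets.append(np.nan)  # silent trial
                slopes.append(np.nan)
                continue
            peak = supra[np.argmax(seg[supra])]
            # preceding inflection point: last frame before the event where
            # the deconvolved trace stops decreasing (start of the rise)
            j = peak
            while j > 0 and seg[j - 1] > 0 and seg[j - 1] <= seg[j]:
                j -= 1
            onsets.append(tt + j / fr)
            dff_seg = raster.dff[c, i0:i0 + n_w]
            d = np.diff(dff_seg)
            slopes.append(tt + (int(np.argmax(d)) + 1) / fr if d.size else np.nan)
        out["onset_s"][c] = np.asarray(onsets)
        out["max_slope_s"][c] = np.asarray(slopes)
        if base_sd:
            out["responsive"][c] = np.mean(evoked_max) > 3.0 * np.mean(base_sd)
    return out
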
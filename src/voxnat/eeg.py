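"""Epoch handling, LDA-beamformer single-trial ERPs, and spatiotemporal
cluster-based permutation statistics.

The analysis is per subject: trials are the observations.  Epochs cover
-0.5..1.0 s around word onset at 256 Hz (384 samples); baseline
correction subtracts the per-trial, per-channel mean over -500..200 ms
(the recording protocol's printed range).  Condition effects are tested
sample-by-sample (channel x time) and corrected by cluster-level
permutation inference with sensor neighborhoods on the 10-20 template.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .audio import rescale
from .errors import (
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
    VoxnatError,
)
from .montage import CHANNELS_32, NEIGHBOR_FRACTION, channel_positions, neighbor_matrix

__all__ = [
    "EEGEpochs",
    "ComponentWindow",
    "COMPONENT_WINDOWS",
    "BeamformerModel",
    "ClusterResult",
    "detect_bad_channels",
    "epoch_baseline",
    "fit_lda_beamformer",
    "extract_single_trial_erp",
    "cluster_permutation_test",
    "amplitude_dispersion",
]

RATE = 256
EPOCH_WINDOW = (-0.5, 1.0)
BASELINE = (-0.5, 0.2)


@dataclass(frozen=True)
class ComponentWindow:
    """Named ERP component analysis window (ms after onset)."""

    name: str
    start_ms: float
    end_ms: float


#: the three windows used for single-trial component extraction
COMPONENT_WINDOWS = {
    "P200": ComponentWindow("P200", 150.0, 250.0),
    "earlyLPP": ComponentWindow("earlyLPP", 400.0, 700.0),
    "lateLPP": ComponentWindow("lateLPP", 700.0, 1000.0),
}


@dataclass
class EEGEpochs:
    """Trials x channels x samples epochs with per-trial labels.

    `labels` is a DataFrame with one row per trial (columns such as
    subject, emotion, level, word, block).  `times` is the epoch time
    axis in seconds relative to stimulus onset.
    """

    data: np.ndarray  # (trials, channels, samples), microvolts
    times: np.ndarray
    labels: pd.DataFrame
    ch_names: list = field(default_factory=lambda: list(CHANNELS_32))
    rate: float = RATE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, start_s: float, end_s: float) -> np.ndarray:
        return (self.times >= start_s) & (self.times <= end_s)

    def window_mask(self, window: ComponentWindow) -> np.ndarray:
        return self.time_mask(window.start_ms / 1000.0, window.end_ms / 1000.0)

    def select(self, mask) -> "EEGEpochs":
        mask = np.asarray(mask)
        return EEGEpochs(
            self.data[mask],
            self.times,
            self.labels.iloc[mask].reset_index(drop=True),
            list(self.ch_names),
            self.rate,
        )

    # -- container I/O (array + JSON/CSV sidecars) ------------------------
    def to_dir(self, path) -> None:
        import os

        os.makedirs(path, exist_ok=True)
        np.save(os.path.join(path, "data.npy"), self.data)
        self.labels.to_csv(os.path.join(path, "labels.csv"), index=False)
        meta = {"rate": self.rate, "ch_names": self.ch_names, "times": self.times.tolist()}
        json.dump(meta, open(os.path.join(path, "meta.json"), "w"))

    @classmethod
    def from_dir(cls, path) -> "EEGEpochs":
        import os

        meta = json.load(open(os.path.join(path, "meta.json")))
        return cls(
            np.load(os.path.join(path, "data.npy")),
            np.array(meta["times"]),
            pd.read_csv(os.path.join(path, "labels.csv")),
            meta["ch_names"],
            meta["rate"],
        )


# --------------------------------------------------------------------------
# bad channels
# --------------------------------------------------------------------------

def detect_bad_channels(
    recording: np.ndarray,
    rate: float,
    flatline_s: float = 5.0,
    line_noise_sd: float = 4.0,
    prob_sd: float = 5.0,
    line_split_hz: float = 45.0,
) -> list:
    """Flag bad channels on a continuous recording.

    Criteria (each flag carries its criterion id):

    1. flatline longer than `flatline_s` seconds;
    2. high-band ("line") noise relative to signal more than
       `line_noise_sd` robust SDs above the channel population;
    3. joint log-probability of the amplitude distribution more than
       `prob_sd` robust SDs from the population mean.
    """
    rec = np.asarray(recording, dtype=float)
    n_ch, n_s = rec.shape
    if n_ch < 8:
        raise InsufficientDataError("need >= 8 channels for population statistics")
    if n_s / rate < flatline_s:
        raise InsufficientDataError(
            f"recording shorter than the {flatline_s:.0f} s flatline criterion"
        )
    flags = []

    # (1) flatline: longest run of ~zero first difference
    tiny = 1e-10
    for c in range(n_ch):
        still = np.abs(np.diff(rec[c])) < tiny
        if not still.any():
            continue
        edges = np.diff(np.concatenate(([0], still.view(np.int8), [0])))
        runs = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        if runs.size and runs.max() / rate >= flatline_s:
            flags.append((c, 1, f"flatline of {runs.max() / rate:.1f} s"))

    def robust_z(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        return (v - med) / max(mad, 1e-12)

    # (2) line-noise-to-signal ratio across the population
    from scipy.signal import welch

    nper = min(n_s, int(2 * rate))
    f, pxx = welch(rec, fs=rate, nperseg=nper)
    hi = f >= line_split_hz
    lo = (f >= 1.0) & (f < line_split_hz)
    ratio = 10 * np.log10(pxx[:, hi].sum(axis=1) / np.maximum(pxx[:, lo].sum(axis=1), 1e-30))
    z = robust_z(ratio)
    for c in np.flatnonzero(z > line_noise_sd):
        flags.append((int(c), 2, f"line-noise ratio z = {z[c]:.1f}"))

    # (3) joint log probability of channel amplitudes under the pooled
    # (standardized) distribution
    pooled_sd = rec.std() or 1.0
    zdata = (rec - rec.mean()) / pooled_sd
    nll = 0.5 * np.mean(zdata**2, axis=1)  # mean Gaussian NLL up to a constant
    zp = robust_z(nll)
    for c in np.flatnonzero(np.abs(zp) > prob_sd):
        flags.append((int(c), 3, f"joint log-probability z = {zp[c]:.1f}"))
    return flags


# --------------------------------------------------------------------------
# epoching
# --------------------------------------------------------------------------

def epoch_baseline(
    recording: np.ndarray,
    events: np.ndarray,
    rate: float = RATE,
    window: tuple = EPOCH_WINDOW,
    baseline: tuple = BASELINE,
    labels: pd.DataFrame | None = None,
    ch_names: list | None = None,
) -> EEGEpochs:
    """Cut epochs around event samples and baseline-correct them.

    The per-trial, per-channel mean over the `baseline` range (default
    -500..200 ms, as recorded in the protocol) is subtracted.  Events too
    close to the recording edges are dropped with a warning.
    """
    if not (window[0] <= baseline[0] and baseline[1] <= window[1]):
        raise DesignError("baseline must lie within the epoch window")
    rec = np.asarray(recording, dtype=float)
    n_ch, n_s = rec.shape
    i0 = int(round(window[0] * rate))
    i1 = int(round(window[1] * rate))
    n_t = i1 - i0
    keep, epochs = [], []
    for k, ev in enumerate(np.asarray(events, dtype=int)):
        lo, hi = ev + i0, ev + i0 + n_t
        if lo < 0 or hi > n_s:
            continue
        keep.append(k)
        epochs.append(rec[:, lo:hi])
    dropped = len(events) - len(keep)
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) too close to the record edge")
    if not epochs:
        raise InsufficientDataError("no epoch fits inside the recording")
    data = np.stack(epochs)
    times = (np.arange(n_t) + i0) / rate
    bmask = (times >= baseline[0]) & (times <= baseline[1])
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)
    if labels is None:
        labels = pd.DataFrame({"event": np.asarray(events)[keep]})
    else:
        labels = labels.iloc[keep].reset_index(drop=True)
    return EEGEpochs(data, times, labels, ch_names or list(CHANNELS_32), rate)


# --------------------------------------------------------------------------
# LDA beamformer
# --------------------------------------------------------------------------

@dataclass
class BeamformerModel:
    """Unit-gain spatial filter for one ERP component.

    w = C_g^-1 p / (p' C_g^-1 p) with C_g = (1 - g) C + g (tr C / d) I,
    so w'p = 1: the filter passes the component's spatial pattern p at
    unit gain while minimizing variance from other sources.
    """

    pattern: np.ndarray  # p, per channel (microvolts)
    cov: np.ndarray  # pooled channel covariance C
    gamma: float
    weights: np.ndarray  # w, per channel
    window: ComponentWindow | None = None
    ch_names: list = field(default_factory=list)


def fit_lda_beamformer(
    epochs: EEGEpochs, window: ComponentWindow, gamma: float = 0.5
) -> BeamformerModel:
    """Fit the spatial filter for a component window.

    The pattern is the trial-and-time average amplitude per channel over
    the window; the covariance pools every sample of every trial
    (conditions included); shrinkage `gamma` regularizes toward the
    scaled identity.
    """
    if epochs.n_trials < 2:
        raise InsufficientDataError("need at least 2 trials")
    tmask = epochs.window_mask(window)
    if not tmask.any():
        raise DesignError(f"window {window.name} outside the epoch")
    p = epochs.data[:, :, tmask].mean(axis=(0, 2))
    d = p.size
    flat = epochs.data.transpose(1, 0, 2).reshape(d, -1)
    c = np.cov(flat)
    c_g = (1.0 - gamma) * c + gamma * (np.trace(c) / d) * np.eye(d)
    if np.linalg.cond(c_g) > 1e12:
        raise VoxnatError(
            "covariance is (numerically) singular; use a regularization gamma > 0"
        )
    try:
        ci_p = np.linalg.solve(c_g, p)
    except np.linalg.LinAlgError as exc:
        raise VoxnatError(
            "covariance is singular; use a regularization gamma > 0"
        ) from exc
    denom = float(p @ ci_p)
    if denom <= 0 or not np.isfinite(denom):
        raise VoxnatError(
            "covariance is numerically singular; use a regularization gamma > 0"
        )
    w = ci_p / denom
    return BeamformerModel(p, c, gamma, w, window, list(epochs.ch_names))


def extract_single_trial_erp(epochs: EEGEpochs, model: BeamformerModel) -> np.ndarray:
    """Project every trial through the spatial filter: trials x samples."""
    if epochs.data.shape[1] != model.weights.size:
        raise VoxnatError("channel count mismatch between epochs and model")
    return np.einsum("c,ncs->ns", model.weights, epochs.data)


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    clusters: list  # dicts: nodes, channels, start_s, end_s, stat, p, significant
    nperm: int
    mode: str
    factor: str
    alpha: float
    cluster_alpha: float
    neighbor_fraction: float
    threshold: float

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c["significant"]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clusters):
            rows.append(
                {
                    "cluster": i,
                    "channels": " ".join(str(ch) for ch in sorted(c["channels"])),
                    "start_s": c["start_s"],
                    "end_s": c["end_s"],
                    "stat": c["stat"],
                    "p": c["p"],
                    "significant": c["significant"],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pointwise_f(flat: np.ndarray, groups: list) -> np.ndarray:
    """One-way F across condition groups at every (channel, time) point."""
    n = flat.shape[0]
    k = len(groups)
    grand = flat.mean(axis=0)
    sst = (flat**2).sum(axis=0) - n * grand**2
    ssb = np.zeros_like(grand)
    for g in groups:
        m = flat[g].mean(axis=0)
        ssb += g.size * m**2
    ssb -= n * grand**2
    ssw = np.maximum(sst - ssb, 1e-30)
    return (ssb / (k - 1)) / (ssw / (n - k))


def _pointwise_t(flat: np.ndarray, groups: list) -> np.ndarray:
    """Two-sample pooled-variance t at every point."""
    a, b = flat[groups[0]], flat[groups[1]]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    return (a.mean(axis=0) - b.mean(axis=0)) / np.maximum(se, 1e-30)


def _grid_adjacency(n_ch: int, n_t: int, neighbors: np.ndarray) -> sparse.csr_matrix:
    """Sparse adjacency of the (channel, time) grid.

    Edges: temporal succession within a channel, and sensor neighborhood
    at the same time point.
    """
    rows, cols = [], []
    idx = np.arange(n_ch * n_t).reshape(n_ch, n_t)
    rows.append(idx[:, :-1].ravel())
    cols.append(idx[:, 1:].ravel())
    nb_i, nb_j = np.nonzero(neighbors)
    up = nb_i < nb_j
    nb_i, nb_j = nb_i[up], nb_j[up]
    rows.append((nb_i[:, None] * n_t + np.arange(n_t)[None, :]).ravel())
    cols.append((nb_j[:, None] * n_t + np.arange(n_t)[None, :]).ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = n_ch * n_t
    adj = sparse.coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n, n))
    return (adj + adj.T).tocsr()


def _cluster_sums(
    stat: np.ndarray, mask: np.ndarray, adj: sparse.csr_matrix, n_t: int,
    collect: bool = False,
):
    """Cluster the suprathreshold grid points and sum the statistic.

    Only clusters spanning >= 2 distinct sensors count.  Returns the list
    of (nodes, sum) when `collect`, else just the max |sum|.
    """
    nodes = np.flatnonzero(mask.ravel())
    if nodes.size == 0:
        return [] if collect else 0.0
    sub = adj[nodes][:, nodes]
    n_comp, assign = connected_components(sub, directed=False)
    sums = np.zeros(n_comp)
    np.add.at(sums, assign, stat.ravel()[nodes])
    chans = nodes // n_t
    best = 0.0
    out = []
    for comp in range(n_comp):
        sel = assign == comp
        if np.unique(chans[sel]).size < 2:
            continue
        s = sums[comp]
        if collect:
            out.append((nodes[sel], float(s)))
        best = max(best, abs(s))
    return out if collect else best


def cluster_permutation_test(
    epochs: EEGEpochs,
    factor: str,
    mode: str = "anova",
    nperm: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float | None = None,
    window: tuple = (0.0, 1.0),
    neighbor_fraction: float = NEIGHBOR_FRACTION,
    seed: int | None = 0,
) -> ClusterResult:
    """Spatiotemporal cluster-based permutation test within one subject.

    Conditions (levels of `factor` in the trial labels) are compared at
    every (channel, sample) by a one-way F across trials (`anova`) or a
    two-sample t (`ttest`); suprathreshold points (parametric p <
    `cluster_alpha`) are clustered over sensor neighborhoods and temporal
    adjacency (clusters need >= 2 neighboring sensors), cluster
    statistics are the sum of F (or t) values, and the Monte-Carlo null
    is the max cluster statistic over `nperm` label shuffles.  The t mode
    is two-sided: default significance alpha is 0.025 per side.
    """
    if factor not in epochs.labels.columns:
        raise DesignError(f"unknown factor {factor!r}")
    cond = epochs.labels[factor].to_numpy()
    levels = np.unique(cond)
    k = levels.size
    if k < 2:
        raise DesignError("need at least 2 conditions")
    if mode == "ttest" and k != 2:
        raise DesignError("ttest mode needs exactly 2 conditions")
    if mode not in ("anova", "ttest"):
        raise ValueError(f"unknown mode {mode!r}")
    if alpha is None:
        alpha = 0.025 if mode == "ttest" else 0.05
    counts = pd.Series(cond).value_counts()
    if counts.min() < 2:
        raise DesignError("need >= 2 trials per condition")

    tmask = epochs.time_mask(*window)
    data = epochs.data[:, :, tmask]
    n, n_ch, n_t = data.shape
    flat = data.reshape(n, -1)
    groups = [np.flatnonzero(cond == lv) for lv in levels]
    if mode == "anova":
        stat = _pointwise_f(flat, groups)
        threshold = float(stats.f.isf(cluster_alpha, k - 1, n - k))
        masks = [(stat > threshold, 1.0)]
    else:
        stat = _pointwise_t(flat, groups)
        threshold = float(stats.t.isf(cluster_alpha / 2, n - 2))
        masks = [(stat > threshold, 1.0), (stat < -threshold, -1.0)]

    neighbors = neighbor_matrix(channel_positions(tuple(epochs.ch_names)),
                                fraction=neighbor_fraction)
    adj = _grid_adjacency(n_ch, n_t, neighbors)

    observed = []
    for m, _sign in masks:
        observed.extend(_cluster_sums(stat.reshape(n_ch, n_t),
                                      m.reshape(n_ch, n_t), adj, n_t, collect=True))

    rng = np.random.default_rng(seed)
    null = np.zeros(nperm)
    sizes = [g.size for g in groups]
    split = np.cumsum(sizes)[:-1]
    for i in range(nperm):
        perm = rng.permutation(n)
        pgroups = np.split(perm, split)
        if mode == "anova":
            pstat = _pointwise_f(flat, pgroups)
            pmasks = [pstat > threshold]
        else:
            pstat = _pointwise_t(flat, pgroups)
            pmasks = [pstat > threshold, pstat < -threshold]
        best = 0.0
        for m in pmasks:
            best = max(
                best,
                _cluster_sums(pstat.reshape(n_ch, n_t), m.reshape(n_ch, n_t), adj, n_t),
            )
        null[i] = best

    times = epochs.times[tmask]
    clusters = []
    for nodes, s in observed:
        p = float((1 + np.sum(null >= abs(s))) / (nperm + 1))
        chans = sorted({epochs.ch_names[c] for c in nodes // n_t})
        tidx = nodes % n_t
        clusters.append(
            {
                "nodes": nodes,
                "channels": chans,
                "start_s": float(times[tidx.min()]),
                "end_s": float(times[tidx.max()]),
                "stat": float(s),
                "p": p,
                "significant": p < alpha,
            }
        )
    clusters.sort(key=lambda c: abs(c["stat"]), reverse=True)
    return ClusterResult(
        clusters, nperm, mode, factor, alpha, cluster_alpha,
        neighbor_fraction, threshold,
    )


# --------------------------------------------------------------------------
# amplitude dispersion
# --------------------------------------------------------------------------

def amplitude_dispersion(
    values: np.ndarray, axis: int = 0, normalize: str = "global"
) -> np.ndarray:
    """SD along `axis` after min-max rescaling of the amplitudes.

    With the default ``global`` normalization the whole array is mapped
    onto [0, 1] once, so dispersions measured along different axes (each
    subject over trials vs each trial over subjects) stay comparable on
    a common scale.  ``axis`` normalization instead rescales every slice
    along the analysis axis, which removes per-slice scale entirely.
    Constant data short-circuits to SD = 0 (min-max undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.shape[axis] < 2:
        raise InsufficientDataError("need >= 2 entries along the analysis axis")
    if normalize == "global":
        if np.ptp(v) == 0:
            return np.zeros(tuple(s for i, s in enumerate(v.shape) if i != axis))
        return np.std(rescale(v, "minmax"), axis=axis, ddof=1)
    if normalize != "axis":
        raise ValueError(f"unknown normalization {normalize!r}")
    v = np.moveaxis(v, axis, 0)
    out = np.empty(v.shape[1:])
    flatv = v.reshape(v.shape[0], -1)
    flato = out.reshape(-1)
    for j in range(flatv.shape[1]):
        col = flatv[:, j]
        if np.ptp(col) == 0:
            flato[j] = 0.0
        else:
            flato[j] = float(np.std(rescale(col, "minmax"), ddof=1))
    return out
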
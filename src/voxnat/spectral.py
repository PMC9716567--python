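"""Inter-trial phase coherence and Higuchi fractal dimension.

ITPC is the magnitude of the mean unit phase vector across repetitions
(trials, or subjects), computed from Morlet wavelet phases on a fixed
52-frequency (linear 2.2-30 Hz) x 200-time-bin (-200..1000 ms) grid.
HFD summarizes the geometric complexity of a single-trial ERP series
between 1 (smooth curve) and 2 (space-filling noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "ITPCMap",
    "HFDResult",
    "morlet_itpc",
    "itpc_significance",
    "higuchi_fd",
    "select_kmax",
]

FREQ_RANGE = (2.2, 30.0)
N_FREQS = 52
TIME_RANGE_MS = (-200.0, 1000.0)
N_TIME_BINS = 200
CYCLE_RANGE = (1.0, 2.8)
PAD_RATIO = 4


def wavelet_cycles(freqs: np.ndarray) -> np.ndarray:
    """Cycle count per frequency, linear from 1 @ 2.2 Hz to 2.8 @ 30 Hz."""
    f0, f1 = FREQ_RANGE
    c0, c1 = CYCLE_RANGE
    return c0 + (c1 - c0) * (np.asarray(freqs) - f0) / (f1 - f0)


@dataclass
class ITPCMap:
    """ITPC values on the fixed frequency x time grid.

    `valid` marks bins whose wavelet support lies fully inside the epoch;
    `mask` (after :func:`itpc_significance`) marks bins significantly
    phase-locked relative to baseline.
    """

    values: np.ndarray  # (n_freqs, n_bins) in [0, 1]
    freqs: np.ndarray
    times_ms: np.ndarray
    n: int  # entries along the coherence axis
    valid: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (self.freqs.size, self.times_ms.size):
            raise ValueError("grid shape mismatch")

    def summary(
        self, fmax: float = 10.0, significant_only: bool = False
    ) -> float:
        """Scalar phase-locking level of the map.

        Mean ITPC over valid post-stimulus bins in the evoked band
        (frequencies <= `fmax`, where the stimulus-locked response
        carries its energy).  With `significant_only` (and a computed
        mask) the mean is restricted to significantly locked bins.
        """
        sel = self.valid & (self.times_ms[None, :] >= 0)
        if fmax is not None:
            sel = sel & (self.freqs[:, None] <= fmax)
        if significant_only and self.mask is not None:
            sel = sel & self.mask
        if not sel.any():
            return float("nan")
        return float(self.values[sel].mean())

    def to_csv(self, path, what: str = "values") -> None:
        """Write the map (or its validity/significance grid) as CSV with
        frequency rows and time-bin columns."""
        import pandas as pd

        grid = {"values": self.values, "valid": self.valid, "mask": self.mask}[what]
        if grid is None:
            raise ValueError("no significance mask computed yet")
        pd.DataFrame(
            grid, index=np.round(self.freqs, 3), columns=np.round(self.times_ms, 1)
        ).rename_axis("freq_hz", axis=0).rename_axis("time_ms", axis=1).to_csv(path)


def _morlet_phases(
    data: np.ndarray, rate: float, freqs: np.ndarray, epoch_t0: float
) -> tuple:
    """Wavelet phases of each row of `data` at the grid bins.

    Returns (phases: (n, f, bins), valid: (f, bins), bin centers ms).
    """
    n, n_s = data.shape
    cycles = wavelet_cycles(freqs)
    n_fft = PAD_RATIO * int(2 ** np.ceil(np.log2(2 * n_s)))
    spec = np.fft.fft(data, n_fft, axis=1)
    fft_freqs = np.fft.fftfreq(n_fft, d=1.0 / rate)

    bin_ms = np.linspace(*TIME_RANGE_MS, N_TIME_BINS)
    epoch_times = epoch_t0 + np.arange(n_s) / rate
    bin_idx = np.clip(
        np.round((bin_ms / 1000.0 - epoch_t0) * rate).astype(int), 0, n_s - 1
    )

    phases = np.empty((n, freqs.size, bin_ms.size))
    valid = np.empty((freqs.size, bin_ms.size), dtype=bool)
    for i, (f, c) in enumerate(zip(freqs, cycles)):
        sigma_t = c / (2 * np.pi * f)
        # frequency-domain Gaussian (analytic Morlet): exp(-(w - w0)^2 s^2/2)
        win = np.exp(-((fft_freqs - f) ** 2) * (2 * np.pi * sigma_t) ** 2 / 2.0)
        win[fft_freqs < 0] = 0.0
        conv = np.fft.ifft(spec * win[None, :], axis=1)[:, :n_s]
        phases[:, i, :] = np.angle(conv[:, bin_idx])
        half_support = 2.5 * sigma_t
        valid[i] = (epoch_times[bin_idx] - half_support >= epoch_times[0]) & (
            epoch_times[bin_idx] + half_support <= epoch_times[-1]
        )
    return phases, valid, bin_ms


def morlet_itpc(
    data: np.ndarray,
    rate: float,
    epoch_t0: float = -0.5,
    freqs: np.ndarray | None = None,
) -> ITPCMap:
    """ITPC over the rows of `data` (trials, or subjects).

    data : (n, samples) series sharing a time axis that starts at
    `epoch_t0` seconds relative to stimulus onset.  ITPC(f, t) =
    |mean_n exp(i phase_n(f, t))|; amplitude plays no role.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise InsufficientDataError("need >= 2 entries along the coherence axis")
    if freqs is None:
        freqs = np.linspace(*FREQ_RANGE, N_FREQS)
    phases, valid, bin_ms = _morlet_phases(data, rate, freqs, epoch_t0)
    itpc = np.abs(np.exp(1j * phases).mean(axis=0))
    return ITPCMap(itpc, freqs, bin_ms, data.shape[0], valid)


def itpc_significance(
    itpc_map: ITPCMap,
    data: np.ndarray,
    rate: float,
    epoch_t0: float = -0.5,
    baseline: tuple = (-0.5, 0.2),
    n_boot: int = 200,
    p: float = 0.01,
    seed: int | None = 0,
) -> np.ndarray:
    """Bootstrap significance mask for an ITPC map, FDR corrected.

    The null distribution per frequency resamples the baseline-window
    ITPC values of that frequency (computed from the same trials on a
    grid over `baseline`); per-bin bootstrap p-values are then
    Benjamini-Hochberg corrected across the whole grid at level `p`.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    freqs = itpc_map.freqs
    cycles = wavelet_cycles(freqs)
    lowest_len = cycles[0] / freqs[0]
    if (baseline[1] - baseline[0]) < lowest_len:
        raise InsufficientDataError(
            f"baseline shorter than one wavelet at {freqs[0]:.1f} Hz "
            f"({lowest_len * 1000:.0f} ms)"
        )
    phases, valid, bin_ms = _morlet_phases(data, rate, freqs, epoch_t0)
    bmask = (bin_ms / 1000.0 >= baseline[0]) & (bin_ms / 1000.0 <= baseline[1])
    base_itpc = np.abs(np.exp(1j * phases[:, :, bmask]).mean(axis=0))

    rng = np.random.default_rng(seed)
    pvals = np.ones_like(itpc_map.values)
    for i in range(freqs.size):
        pool = base_itpc[i][valid[i, bmask]] if valid[i, bmask].any() else base_itpc[i]
        if pool.size == 0:
            continue
        null = rng.choice(pool, size=n_boot, replace=True)
        exceed = (null[None, :] >= itpc_map.values[i][:, None]).sum(axis=1)
        pvals[i] = (1.0 + exceed) / (n_boot + 1.0)

    sel = itpc_map.valid
    mask = np.zeros_like(sel)
    flat_p = pvals[sel]
    m = flat_p.size
    order = np.argsort(flat_p)
    thresh = p * (np.arange(1, m + 1)) / m
    passed = flat_p[order] <= thresh
    sig = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        sig[order[: kmax + 1]] = True
    mask[sel] = sig
    itpc_map.mask = mask
    return mask


# --------------------------------------------------------------------------
# Higuchi fractal dimension
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HFDResult:
    hfd: float
    kmax: int
    window: str | None = None


def higuchi_fd(series: np.ndarray, kmax: int, window: str | None = None) -> HFDResult:
    """Higuchi's fractal dimension of a 1-D series.

    For every scale k = 1..kmax and offset m, the normalized decimated
    curve length L_m(k) = (sum |x[m+ik] - x[m+(i-1)k]|) * (N-1) /
    (floor((N-m)/k) * k) / k is averaged over offsets; the dimension is
    the slope of log L(k) against log(1/k) (ordinary least squares,
    natural log).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 2 * kmax:
        raise ValueError("need N >= 2*kmax samples")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has zero curve length")
    ks = np.arange(1, kmax + 1)
    logl = np.empty(ks.size)
    for j, k in enumerate(ks):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            nmax = idx.size - 1
            lm = np.abs(np.diff(x[idx])).sum() * (n - 1) / (nmax * k) / k
            lengths.append(lm)
        logl[j] = np.log(np.mean(lengths))
    slope = np.polyfit(np.log(1.0 / ks), logl, 1)[0]
    return HFDResult(hfd=float(slope), kmax=int(kmax), window=window)


def select_kmax(
    series: np.ndarray, eps: float = 0.01, consecutive: int = 3
) -> int:
    """Smallest kmax where the HFD-vs-kmax curve has plateaued.

    The plateau is `consecutive` successive increments below `eps`;
    without one, N/2 is returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples")
    cap = n // 2
    hfds = {}

    def h(k: int) -> float:
        if k not in hfds:
            hfds[k] = higuchi_fd(x, k).hfd
        return hfds[k]

    run = 0
    for k in range(2, cap):
        if abs(h(k + 1) - h(k)) < eps:
            run += 1
            if run >= consecutive:
                return k + 1 - consecutive
        else:
            run = 0
    warnings.warn("no HFD plateau before N/2; returning N/2")
    return cap
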
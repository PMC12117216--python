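"""Time-of-flight distributions and TCSPC histogram processing.

Two halves:

* From simulation: a weighted Gaussian KDE over detected-packet exit times
  (Silverman bandwidth, effective sample size for weighted data), then
  convolution with a Gaussian instrument response function (IRF).
* From (synthetic) experiment: TCSPC photon-count histograms — Poisson
  signal over a laser period plus uniform dark counts — background
  subtraction, Savitzky-Golay smoothing, and standard-error bands computed
  across repeated exposures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .transport import DetectedPackets

__all__ = [
    "ToFDistribution",
    "IRFSpec",
    "TCSPCSeries",
    "SmoothingConfig",
    "kde_tof",
    "silverman_bandwidth",
    "convolve_irf",
    "simulate_tcspc",
    "process_histograms",
]

LASER_PERIOD_NS = 12.5          # 80 MHz repetition rate
DEFAULT_N_BINS = 4096


@dataclass
class ToFDistribution:
    """Probability density of photon time of flight on a uniform time axis."""

    time_axis: np.ndarray       # ns, uniform
    density: np.ndarray         # 1/ns, trapezoid-normalized to 1
    bandwidth: float            # Silverman h, ns (0 if not from a KDE)
    convolved: bool = False

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        dt = np.diff(self.time_axis)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time axis must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    def mean_time(self) -> float:
        return float(np.trapezoid(self.time_axis * self.density, self.time_axis))

    def peak_time(self) -> float:
        return float(self.time_axis[np.argmax(self.density)])

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.time_axis, self.density]),
                   delimiter=",", header="time_ns,density_per_ns", comments="")


@dataclass(frozen=True)
class IRFSpec:
    """Gaussian instrument response function.

    ``fwhm`` in ns (default 0.300 ns); ``peak_time`` defines time zero —
    all traces are aligned to the IRF peak.
    """

    fwhm: float = 0.300
    peak_time: float = 0.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("IRF fwhm must be > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class TCSPCSeries:
    """A stack of TCSPC exposures: integer counts per (exposure, time bin)."""

    bin_width: float            # ns
    counts: np.ndarray          # (n_exposures, n_bins), nonnegative ints
    exposure_seconds: float
    kind: str = "signal"        # "signal" | "background"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be (n_exposures, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.shape[1] * self.bin_width > LASER_PERIOD_NS * (1 + 1e-9):
            raise ValueError("bins x bin_width exceeds the 12.5 ns laser period")

    @property
    def time_axis(self) -> np.ndarray:
        return (np.arange(self.counts.shape[1]) + 0.5) * self.bin_width

    def save_csv(self, path: str | Path) -> None:
        n_exp, n_bins = self.counts.shape
        header = "bin_start_ns," + ",".join(f"counts_exposure_{i+1}" for i in range(n_exp))
        starts = np.arange(n_bins) * self.bin_width
        np.savetxt(path, np.column_stack([starts, self.counts.T]),
                   delimiter=",", header=header, comments="", fmt="%.6g")


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay smoothing parameters (window in bins, odd)."""

    window: int = 251
    order: int = 3
    edge_mode: str = "mirror"

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.order >= self.window:
            raise ValueError("order must be smaller than window")


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= w.sum()
    return float(np.interp(q, cdf, x))


def silverman_bandwidth(times: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Silverman's rule-of-thumb bandwidth for a weighted sample.

    ``h = 0.9 * min(sigma_w, IQR_w / 1.34) * n_eff^(-1/5)`` with weighted
    standard deviation and interquartile range, and effective sample size
    ``n_eff = (sum w)^2 / sum w^2``.
    """
    times = np.asarray(times, dtype=float)
    if weights is None:
        weights = np.ones_like(times)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    mean = (weights * times).sum() / wsum
    var = (weights * (times - mean) ** 2).sum() / wsum
    sigma = np.sqrt(var)
    iqr = (_weighted_quantile(times, weights, 0.75)
           - _weighted_quantile(times, weights, 0.25))
    n_eff = wsum**2 / (weights**2).sum()
    spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
    if spread <= 0:
        raise ValueError("all exit times identical; cannot set a bandwidth")
    return float(0.9 * spread * n_eff ** (-0.2))


def kde_tof(records: DetectedPackets | tuple[np.ndarray, np.ndarray],
            time_axis: np.ndarray) -> ToFDistribution:
    """Weighted Gaussian KDE of the detected exit-time distribution.

    ``records`` is a :class:`DetectedPackets` or a ``(times, weights)``
    pair. Bandwidth by Silverman's rule (weighted); the density is
    trapezoid-normalized on the given axis.
    """
    if isinstance(records, DetectedPackets):
        times, weights = records.exit_time, records.weight
    else:
        times, weights = records
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if times.size < 2 or np.unique(times).size < 2:
        raise ValueError(
            "need >= 2 records with distinct exit times; widen the detector "
            "patch or run more packets")
    h = silverman_bandwidth(times, weights)
    axis = np.asarray(time_axis, dtype=float)
    dens = np.zeros_like(axis)
    wnorm = weights / weights.sum()
    # chunked direct evaluation keeps memory bounded for large ensembles
    chunk = max(1, int(2e7 // max(axis.size, 1)))
    for lo in range(0, times.size, chunk):
        t = times[lo:lo + chunk, None]
        w = wnorm[lo:lo + chunk, None]
        dens += (w * np.exp(-0.5 * ((axis[None, :] - t) / h) ** 2)).sum(axis=0)
    dens /= h * np.sqrt(2.0 * np.pi)
    area = np.trapezoid(dens, axis)
    if area <= 0:
        raise ValueError("density vanishes on the given axis; widen the axis")
    return ToFDistribution(axis, dens / area, bandwidth=h)


def convolve_irf(tof: ToFDistribution, irf: IRFSpec) -> ToFDistribution:
    """Convolve a ToF density with a unit-area Gaussian IRF.

    The kernel is centered (symmetric), so a unimodal input broadens while
    its mean is preserved; the output is renormalized on the same axis.
    """
    if irf.fwhm < tof.dt:
        # near-identity limit: kernel narrower than one bin
        kern_half = 1
    else:
        kern_half = int(np.ceil(5 * irf.sigma / tof.dt))
    k = np.arange(-kern_half, kern_half + 1) * tof.dt
    kernel = np.exp(-0.5 * (k / irf.sigma) ** 2)
    kernel /= kernel.sum()
    out = np.convolve(tof.density, kernel, mode="same")
    area = np.trapezoid(out, tof.time_axis)
    axis = tof.time_axis - irf.peak_time  # align time zero to the IRF peak
    return ToFDistribution(axis, out / area, bandwidth=tof.bandwidth, convolved=True)


def simulate_tcspc(
    tof: ToFDistribution,
    signal_rate: float = 1.0,           # detected signal photons per second
    background_rate: float = 15.0,      # dark counts per second
    n_exposures: int = 15,
    exposure_seconds: float = 120.0,
    bin_width: float = LASER_PERIOD_NS / DEFAULT_N_BINS,
    seed: int = 0,
    n_background_exposures: int | None = None,
) -> tuple[TCSPCSeries, TCSPCSeries]:
    """Synthesize TCSPC signal and background exposure stacks.

    Per exposure and bin, counts are Poisson with mean
    ``exposure * (signal_rate * density * bin_width + background_rate / n_bins)``;
    the background series omits the signal term. Defaults emulate a
    1 count/s transmitted signal over 15 x 2-min exposures against a
    15 count/s dark rate. ``n_background_exposures`` defaults to one
    background per five signal exposures (at least 2).
    """
    if signal_rate < 0 or background_rate < 0:
        raise ValueError("rates must be >= 0")
    n_bins = int(np.floor(LASER_PERIOD_NS / bin_width + 1e-9))
    axis = (np.arange(n_bins) + 0.5) * bin_width
    dens = np.interp(axis, tof.time_axis, tof.density, left=0.0, right=0.0)
    area = dens.sum() * bin_width
    prob = dens * bin_width / area if area > 0 else np.zeros(n_bins)
    if n_background_exposures is None:
        n_background_exposures = max(2, n_exposures // 5)
    rng = np.random.default_rng(seed)
    mean_sig = exposure_seconds * (signal_rate * prob + background_rate / n_bins)
    mean_bkg = np.full(n_bins, exposure_seconds * background_rate / n_bins)
    sig = rng.poisson(mean_sig, size=(n_exposures, n_bins))
    bkg = rng.poisson(mean_bkg, size=(n_background_exposures, n_bins))
    return (
        TCSPCSeries(bin_width, sig, exposure_seconds, kind="signal"),
        TCSPCSeries(bin_width, bkg, exposure_seconds, kind="background"),
    )


def process_histograms(
    signal: TCSPCSeries,
    background: TCSPCSeries,
    smoothing: SmoothingConfig = SmoothingConfig(),
    band_center: str = "filtered",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Background-subtract, smooth, and band a TCSPC exposure stack.

    Returns ``(trace, upper, lower)``:

    * ``trace`` — Savitzky-Golay-filtered (mean signal - mean background)
    * per-bin SEM over signal exposures, computed *before* filtering
    * ``upper``/``lower`` — the filtered (unfiltered mean +/- SEM)

    ``band_center="raw"`` instead returns ``filtered(mean) +/- filtered(SEM)``
    added after filtering (the alternative reading of the band recipe).
    """
    if signal.counts.shape[1] != background.counts.shape[1] or \
            abs(signal.bin_width - background.bin_width) > 1e-12:
        raise ValueError("signal and background must share bin structure")
    if signal.counts.shape[0] < 2:
        raise ValueError("need >= 2 signal exposures to form a standard error")
    mean_sig = signal.counts.mean(axis=0)
    mean_bkg = background.counts.mean(axis=0)
    raw = mean_sig - mean_bkg
    sem = signal.counts.std(axis=0, ddof=1) / np.sqrt(signal.counts.shape[0])

    def _sg(x):
        return savgol_filter(x, smoothing.window, smoothing.order,
                             mode=smoothing.edge_mode)

    trace = _sg(raw)
    if band_center == "filtered":
        upper = _sg(raw + sem)
        lower = _sg(raw - sem)
    elif band_center == "raw":
        s = _sg(sem)
        upper = trace + s
        lower = trace - s
    else:
        raise ValueError("band_center must be 'filtered' or 'raw'")
    return trace, upper, lower
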
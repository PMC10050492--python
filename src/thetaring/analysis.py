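"""Derived quantities: LFP proxy, spectra, bump tracking, phase locking.

The local-field-potential proxy (pLFP) is the population mean of the
GABAR-mediated current onto principal cells, delayed by the GABA decay
time — a standard stand-in for the LFP in point-neuron networks.  Spectra
use Welch's method (Hamming window, 256-sample segments, 128 overlap,
1024-point FFT at 200 Hz, per-segment mean removal).  The bump centre is
tracked by the population activity vector (PAV): because the default
network holds two bumps 180 deg apart, neuron angles are doubled before
forming the rate-weighted resultant, which superimposes the two bumps;
halving the argument recovers the bump centre up to the 180-deg branch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .results import POP_E, POP_I, SimulationResult

__all__ = [
    "ANALYSIS_WINDOW_MS",
    "PlfpSeries",
    "SpectralResult",
    "PavSeries",
    "BumpProfileMetrics",
    "PhaseLockingResult",
    "compute_plfp",
    "welch_psd",
    "primary_peak_metrics",
    "theta_power",
    "bin_spike_counts",
    "pav_series",
    "sigma_pav",
    "pav_diffusion",
    "rate_profile",
    "bump_profile",
    "bump_profile_aligned",
    "sharpness",
    "spike_phase_locking",
    "spike_phase_locking_cosine",
    "trial_metrics",
]

# cue and initial transient excluded from all spectral / drift statistics
ANALYSIS_WINDOW_MS = (1000.0, 8000.0)

WELCH_NPERSEG = 256
WELCH_NOVERLAP = 128
WELCH_NFFT = 1024


@dataclass
class PlfpSeries:
    """LFP proxy sampled on the trace grid (200 Hz)."""

    t: np.ndarray  # ms
    values: np.ndarray  # pA

    def window(self, t0: float, t1: float) -> "PlfpSeries":
        m = (self.t >= t0) & (self.t <= t1)
        return PlfpSeries(self.t[m], self.values[m])


@dataclass
class SpectralResult:
    """One-sided Welch power spectral density."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray


@dataclass
class PavSeries:
    """Bump-centre trajectory from sliding-window population vectors."""

    t: np.ndarray          # window centres, ms
    theta_pav: np.ndarray  # bump centre, deg in [0, 360); NaN if undefined
    magnitude: np.ndarray  # |P|, rate-weighted resultant length (Hz)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.theta_pav)


@dataclass
class BumpProfileMetrics:
    height: float     # peak firing rate in the bump, Hz
    fwhm: float       # full width at half maximum, deg
    sharpness: float  # 4th/2nd-moment ratio; 3.0 Gaussian, 1.8 plateau


@dataclass
class PhaseLockingResult:
    """Rayleigh vector of spike phases relative to a reference rhythm."""

    modulus: float  # |Phi| in [0, 1]; NaN when undefined
    arg_deg: float  # preferred phase in [0, 360); NaN when undefined
    n_spikes: int

    @property
    def defined(self) -> bool:
        return self.n_spikes > 0


# ---------------------------------------------------------------------------
# pLFP and spectra
# ---------------------------------------------------------------------------

def compute_plfp(result: SimulationResult,
                 tau_gaba: Optional[float] = None) -> PlfpSeries:
    """Population-mean, tau_GABA-delayed inhibitory current onto E cells.

    The delay (10 ms default = 2 samples at 200 Hz) is applied by shifting
    the trace; the first samples repeat the initial value, which never
    intersects the analysis window.
    """
    if result.igaba_e is None:
        raise ValueError("per-cell GABA current traces were not recorded")
    if tau_gaba is None:
        tau_gaba = result.model.syn.tau_gaba
    mean_ig = result.igaba_e.mean(axis=1).astype(float)
    shift = int(round(tau_gaba / result.protocol.record_every_ms))
    values = np.empty_like(mean_ig)
    if shift > 0:
        values[:shift] = mean_ig[0]
        values[shift:] = mean_ig[:mean_ig.size - shift]
    else:
        values[:] = mean_ig
    return PlfpSeries(t=result.t.astype(float), values=values)


def welch_psd(values: np.ndarray, fs: float = 200.0) -> SpectralResult:
    """Welch PSD with the fixed analysis settings (see module docstring)."""
    values = np.asarray(values, float)
    if values.size < WELCH_NPERSEG:
        raise ValueError(
            f"signal too short for Welch analysis: {values.size} < "
            f"{WELCH_NPERSEG} samples")
    freqs, psd = sps.welch(values, fs=fs, window="hamming",
                           nperseg=WELCH_NPERSEG, noverlap=WELCH_NOVERLAP,
                           nfft=WELCH_NFFT, detrend="constant")
    return SpectralResult(freqs=freqs, psd=psd)


def primary_peak_metrics(spec: SpectralResult,
                         convention: str = "mean",
                         f_max: float = 50.0,
                         half_bin: float = 1.0) -> tuple[float, float]:
    """Primary peak frequency and relative peak power of a PSD.

    The peak frequency is the argmax of the PSD over (0, f_max] Hz (the DC
    bin is excluded).  The peak power relates the 2-Hz band centred on the
    peak to the whole 0-50 Hz range; ``convention`` selects how:

    * ``"mean"`` — ratio of mean spectral densities (band mean / range
      mean).  Exceeds 1 for any concentrated spectrum, approaching
      ``f_max / (2 half_bin)`` = 25 in the single-bin limit.
    * ``"integrated"`` — ratio of trapezoid-integrated powers, a fraction
      in [0, 1].
    """
    if spec.freqs.size == 0:
        raise ValueError("empty spectrum")
    search = (spec.freqs > 0) & (spec.freqs <= f_max)
    if not np.any(search):
        raise ValueError("no frequency bins in the search range")
    fsel = spec.freqs[search]
    f_peak = float(fsel[np.argmax(spec.psd[search])])

    band = (spec.freqs >= f_peak - half_bin) & (spec.freqs <= f_peak + half_bin)
    full = (spec.freqs >= 0) & (spec.freqs <= f_max)
    if convention == "mean":
        power = float(spec.psd[band].mean() / spec.psd[full].mean())
    elif convention == "integrated":
        power = float(np.trapezoid(spec.psd[band], spec.freqs[band])
                      / np.trapezoid(spec.psd[full], spec.freqs[full]))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return f_peak, power


def theta_power(spec: SpectralResult, band: tuple[float, float] = (4.0, 12.0),
                f_max: float = 50.0) -> float:
    """Mean spectral density in the theta band over the 0-50 Hz mean."""
    in_band = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    full = (spec.freqs >= 0) & (spec.freqs <= f_max)
    return float(spec.psd[in_band].mean() / spec.psd[full].mean())


def theta_peak_frequency(spec: SpectralResult,
                         band: tuple[float, float] = (4.0, 12.0)) -> float:
    """Peak frequency restricted to the theta band."""
    in_band = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return float(spec.freqs[in_band][np.argmax(spec.psd[in_band])])


def bin_spike_counts(spike_t: np.ndarray, t_start: float, t_stop: float,
                     bin_ms: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts in half-open bins [edge, edge + bin) over a window.

    Returns (counts, edges); a spike exactly on an interior edge falls in
    the later bin.
    """
    n_bins = int(round((t_stop - t_start) / bin_ms))
    edges = t_start + np.arange(n_bins + 1) * bin_ms
    spike_t = np.asarray(spike_t, float)
    sel = (spike_t >= t_start) & (spike_t < t_stop)
    counts = np.bincount(
        np.floor((spike_t[sel] - t_start) / bin_ms).astype(int),
        minlength=n_bins)[:n_bins]
    return counts.astype(float), edges


# ---------------------------------------------------------------------------
# population activity vector
# ---------------------------------------------------------------------------

def _window_rates(spike_idx, spike_t, n_neurons, t_start, t_stop,
                  window_ms, stride_ms):
    """Per-neuron firing rates in sliding windows; returns (centres, rates)."""
    n_strides = int(round((t_stop - t_start) / stride_ms))
    wbins = int(round(window_ms / stride_ms))
    if n_strides < wbins:
        raise ValueError("analysis window shorter than the sliding window")
    counts = np.zeros((n_strides, n_neurons))
    sel = (spike_t >= t_start) & (spike_t < t_stop)
    b = np.floor((spike_t[sel] - t_start) / stride_ms).astype(int)
    np.add.at(counts, (b, spike_idx[sel]), 1.0)
    csum = np.vstack([np.zeros((1, n_neurons)), np.cumsum(counts, axis=0)])
    win_counts = csum[wbins:] - csum[:-wbins]
    rates = win_counts / (window_ms / 1000.0)
    centres = t_start + window_ms / 2.0 + np.arange(rates.shape[0]) * stride_ms
    return centres, rates


def pav_series(spike_idx: np.ndarray, spike_t: np.ndarray, n_e: int,
               t_start: float = ANALYSIS_WINDOW_MS[0],
               t_stop: float = ANALYSIS_WINDOW_MS[1],
               window_ms: float = 400.0, stride_ms: float = 5.0,
               init_deg: float = 90.0) -> PavSeries:
    """Sliding-window population activity vector of principal-cell firing.

    Angles are doubled before the rate-weighted resultant
    ``P = (1/N_E) sum_i f_i exp(j 2 theta_i)`` so the two antipodal bumps
    superimpose; halving arg(P) leaves a 180-deg branch ambiguity, resolved
    by continuity with the previous window and initialized at the branch
    nearer ``init_deg``.  Windows without spikes get magnitude 0 and an
    undefined (NaN) angle.
    """
    centres, rates = _window_rates(spike_idx, spike_t, n_e, t_start, t_stop,
                                   window_ms, stride_ms)
    theta = np.arange(n_e) * (360.0 / n_e)
    phasor = np.exp(1j * np.deg2rad(2.0 * theta))
    p = rates @ phasor / n_e
    mag = np.abs(p)
    base = np.mod(np.rad2deg(np.angle(p)) / 2.0, 180.0)

    out = np.full(base.size, np.nan)
    prev = init_deg
    for k in range(base.size):
        if mag[k] == 0.0:
            continue
        c0, c1 = base[k], base[k] + 180.0
        d0 = abs((c0 - prev + 180.0) % 360.0 - 180.0)
        d1 = abs((c1 - prev + 180.0) % 360.0 - 180.0)
        out[k] = c0 if d0 <= d1 else c1
        prev = out[k]
    return PavSeries(t=centres, theta_pav=out, magnitude=mag)


def sigma_pav(trials: Sequence[PavSeries],
              t_ms: Optional[float] = None) -> np.ndarray | float:
    """Across-trial circular SD of the bump centre, in degrees.

    theta_PAV is periodic with period 180 deg, so the SD is computed on
    doubled angles and halved.  Undefined angles are excluded with a
    warning.  Returns the whole time series, or a scalar when ``t_ms``
    names one window-centre time.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    t = trials[0].t
    for tr in trials[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ValueError("trials must share a common time grid")
    angles = np.vstack([tr.theta_pav for tr in trials])
    if np.isnan(angles).any():
        warnings.warn("undefined PAV angles excluded from sigma_pav")
    z = np.exp(1j * np.deg2rad(2.0 * angles))
    z[np.isnan(angles)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.abs(np.nanmean(z, axis=0))
    r = np.clip(r, 1e-300, 1.0)
    sd = np.rad2deg(np.sqrt(-2.0 * np.log(r))) / 2.0
    if t_ms is None:
        return sd
    k = int(np.argmin(np.abs(t - t_ms)))
    return float(sd[k])


# ---------------------------------------------------------------------------
# bump profile
# ---------------------------------------------------------------------------

def pav_diffusion(trials: Sequence[PavSeries],
                  lag_ms: float = 1000.0) -> float:
    """Angular diffusion rate of the bump centre, deg^2 per second.

    Pools squared circular displacements of theta_PAV over ``lag_ms``
    intervals across trials (computed on doubled angles, halved).  A far
    better-powered drift statistic at small trial counts than the
    across-trial circular SD at one time point, because every trial
    contributes many independent increments of the random walk.
    """
    sq = []
    for tr_ in trials:
        t, a = tr_.t, tr_.theta_pav
        step = int(round(lag_ms / (t[1] - t[0])))
        for k in range(0, a.size - step, step):
            if np.isfinite(a[k]) and np.isfinite(a[k + step]):
                d = (2.0 * (a[k + step] - a[k]) + 180.0) % 360.0 - 180.0
                sq.append((d / 2.0) ** 2)
    if not sq:
        raise ValueError("no valid displacement pairs")
    return float(np.mean(sq) / (lag_ms / 1000.0))


def rate_profile(spike_idx: np.ndarray, spike_t: np.ndarray, n_e: int,
                 t_start: float, t_stop: float) -> np.ndarray:
    """Mean firing rate (Hz) of every principal cell over a window."""
    sel = (spike_t >= t_start) & (spike_t < t_stop)
    counts = np.bincount(np.asarray(spike_idx[sel], int), minlength=n_e)
    return counts / ((t_stop - t_start) / 1000.0)


def sharpness(rates: np.ndarray, offsets_deg: np.ndarray) -> float:
    """Moment-ratio sharpness of a bump profile.

    ``S = <F d^4> / <F d^2>^2`` with F the rates and d the angular offsets
    from the bump centre; rate-weighted moments make S invariant to uniform
    rate rescaling.  S = 3.0 for a Gaussian profile and 1.8 for an ideal
    plateau (top-hat) profile.
    """
    f = np.asarray(rates, float)
    d = np.asarray(offsets_deg, float)
    w = f.sum()
    if w <= 0:
        raise ValueError("all-zero rate profile")
    m2 = np.sum(f * d**2) / w
    m4 = np.sum(f * d**4) / w
    if m2 == 0:
        raise ValueError("degenerate profile concentrated at the centre")
    return float(m4 / m2**2)


def _profile_metrics(f: np.ndarray, d: np.ndarray) -> BumpProfileMetrics:
    """Metrics of a rate profile given as rates f over sorted offsets d."""
    if f.sum() <= 0:
        raise ValueError("all-zero rate profile in the half-ring")
    height = float(f.max())
    hm = height / 2.0
    kpk = int(np.argmax(f))

    def _crossing(side: int) -> float:
        k = kpk
        while 0 <= k + side < f.size and f[k + side] >= hm:
            k += side
        if not 0 <= k + side < f.size:
            return d[k]  # flank never falls below half max inside the half-ring
        f1, f2 = f[k], f[k + side]
        d1, d2 = d[k], d[k + side]
        return d1 + (d2 - d1) * (f1 - hm) / (f1 - f2)

    left = _crossing(-1)
    right = _crossing(+1)
    return BumpProfileMetrics(height=height, fwhm=float(right - left),
                              sharpness=sharpness(f, d))


def bump_profile(spike_idx: np.ndarray, spike_t: np.ndarray, n_e: int,
                 theta0: float, t_start: float, t_stop: float
                 ) -> BumpProfileMetrics:
    """Height, FWHM and sharpness of the bump centred at ``theta0``.

    The profile is the time-averaged rate of the half-ring (N_E / 2 cells)
    centred on a fixed ``theta0``; the FWHM interpolates the half-maximum
    crossings linearly on each flank.  For drifting bumps prefer
    :func:`bump_profile_aligned`, which re-centres each sliding window on
    its own bump position before averaging.
    """
    rates = rate_profile(spike_idx, spike_t, n_e, t_start, t_stop)
    theta = np.arange(n_e) * (360.0 / n_e)
    offs = (theta - theta0 + 180.0) % 360.0 - 180.0  # signed, (-180, 180]
    half = np.abs(offs) <= 90.0
    f = rates[half]
    d = offs[half]
    order = np.argsort(d)
    return _profile_metrics(f[order], d[order])


def bump_profile_aligned(spike_idx: np.ndarray, spike_t: np.ndarray,
                         n_e: int,
                         t_start: float = ANALYSIS_WINDOW_MS[0],
                         t_stop: float = ANALYSIS_WINDOW_MS[1],
                         window_ms: float = 400.0, stride_ms: float = 5.0,
                         ) -> BumpProfileMetrics:
    """Bump metrics from drift-aligned sliding-window rate profiles.

    Each 400-ms window's profile is circularly shifted so its own PAV
    angle sits at offset zero, then the shifted profiles are averaged;
    this measures the instantaneous bump shape independently of how far
    the bump wanders over the trial.
    """
    pav = pav_series(spike_idx, spike_t, n_e, t_start=t_start,
                     t_stop=t_stop, window_ms=window_ms,
                     stride_ms=stride_ms)
    _, rates = _window_rates(spike_idx, spike_t, n_e, t_start, t_stop,
                             window_ms, stride_ms)
    dtheta = 360.0 / n_e
    valid = pav.valid
    if not valid.any():
        raise ValueError("no window with a defined bump position")
    acc = np.zeros(n_e)
    for k in np.flatnonzero(valid):
        shift = int(round(pav.theta_pav[k] / dtheta)) % n_e
        acc += np.roll(rates[k], -shift)
    acc /= valid.sum()
    offs = (np.arange(n_e) * dtheta + 180.0) % 360.0 - 180.0
    half = np.abs(offs) <= 90.0
    order = np.argsort(offs[half])
    return _profile_metrics(acc[half][order], offs[half][order])


# ---------------------------------------------------------------------------
# phase locking
# ---------------------------------------------------------------------------

def _rayleigh(phases_deg: np.ndarray) -> PhaseLockingResult:
    n = phases_deg.size
    if n == 0:
        return PhaseLockingResult(modulus=np.nan, arg_deg=np.nan, n_spikes=0)
    z = np.mean(np.exp(1j * np.deg2rad(phases_deg)))
    return PhaseLockingResult(modulus=float(np.abs(z)),
                              arg_deg=float(np.rad2deg(np.angle(z)) % 360.0),
                              n_spikes=int(n))


def instantaneous_phase(series: PlfpSeries,
                        band: tuple[float, float] = (4.0, 12.0),
                        fs: float = 200.0,
                        order: int = 4) -> np.ndarray:
    """Theta phase of a reference series, in degrees with peak = 0.

    Zero-phase (forward-backward) Butterworth band-pass followed by the
    Hilbert analytic signal; the angle of the analytic signal is 0 at the
    peaks of the filtered wave.  Returned unwrapped (monotone up to noise)
    for safe interpolation at spike times.
    """
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, series.values - series.values.mean())
    phase = np.angle(sps.hilbert(filt))
    return np.rad2deg(np.unwrap(phase))


def spike_phase_locking(spike_t: np.ndarray, reference: PlfpSeries,
                        band: tuple[float, float] = (4.0, 12.0),
                        fs: float = 200.0) -> PhaseLockingResult:
    """Rayleigh vector of one neuron's spike phases relative to a rhythm.

    The reference is band-passed (zero-phase) and its Hilbert phase is
    interpolated at the spike times.  Spikes must fall inside the span of
    the reference series.  With zero spikes the result is flagged
    undefined (NaN modulus/argument).
    """
    spike_t = np.asarray(spike_t, float)
    if spike_t.size and (spike_t.min() < reference.t[0]
                         or spike_t.max() > reference.t[-1]):
        raise ValueError("spikes outside the reference series span")
    if spike_t.size == 0:
        return _rayleigh(spike_t)
    phase_u = instantaneous_phase(reference, band=band, fs=fs)
    phases = np.interp(spike_t, reference.t, phase_u) % 360.0
    return _rayleigh(phases)


def spike_phase_locking_cosine(spike_t: np.ndarray,
                               f_hz: float) -> PhaseLockingResult:
    """Rayleigh vector relative to a cosine input of known frequency.

    The input phase is taken directly from the cosine argument,
    ``360 f t``, so the waveform peak at t = 0 is phase 0.
    """
    spike_t = np.asarray(spike_t, float)
    if spike_t.size == 0:
        return _rayleigh(spike_t)
    phases = (360.0 * f_hz * spike_t / 1000.0) % 360.0
    return _rayleigh(phases)


# ---------------------------------------------------------------------------
# per-trial metric bundle
# ---------------------------------------------------------------------------

def trial_metrics(result: SimulationResult,
                  window: tuple[float, float] = ANALYSIS_WINDOW_MS,
                  peak_power_convention: str = "mean") -> dict:
    """All scalar metrics of one trial used by sweeps and reports."""
    t0, t1 = window
    out: dict = {}

    plfp = compute_plfp(result).window(t0, t1)
    spec = welch_psd(plfp.values, fs=result.fs)
    f_peak, p_peak = primary_peak_metrics(spec,
                                          convention=peak_power_convention)
    out["plfp_peak_freq"] = f_peak
    out["plfp_peak_power"] = p_peak
    out["plfp_theta_power"] = theta_power(spec)
    out["plfp_theta_freq"] = theta_peak_frequency(spec)

    e_idx, e_t = result.population_spikes(POP_E)
    counts, _ = bin_spike_counts(e_t, t0, t1)
    spec_sc = welch_psd(counts, fs=result.fs)
    out["spikecount_peak_freq"] = primary_peak_metrics(spec_sc)[0]

    vm = result.vm_trace(POP_E, result.vm_e_idx[0])
    m = (result.t >= t0) & (result.t <= t1)
    spec_vm = welch_psd(vm[m], fs=result.fs)
    out["vm_peak_freq"] = primary_peak_metrics(spec_vm)[0]

    rates = rate_profile(e_idx, e_t, result.n_e, t0, t1)
    out["max_mean_rate"] = float(rates.max())

    pav = pav_series(e_idx, e_t, result.n_e, t_start=t0, t_stop=t1)
    out["pav_magnitude_mean"] = float(np.mean(pav.magnitude))
    out["pav_magnitude_cv"] = float(np.std(pav.magnitude)
                                    / np.mean(pav.magnitude)) \
        if np.mean(pav.magnitude) > 0 else np.nan

    try:
        bump = bump_profile_aligned(e_idx, e_t, result.n_e,
                                    t_start=t0, t_stop=t1)
        out["bump_height"] = bump.height
        out["bump_fwhm"] = bump.fwhm
        out["bump_sharpness"] = bump.sharpness
    except ValueError:
        out["bump_height"] = np.nan
        out["bump_fwhm"] = np.nan
        out["bump_sharpness"] = np.nan

    plfp_full = compute_plfp(result).window(t0, t1)
    e90 = int(result.vm_e_idx[0])
    i90 = int(result.vm_i_idx[0])
    spk_e90 = result.spikes_of(POP_E, e90)
    spk_e90 = spk_e90[(spk_e90 >= t0) & (spk_e90 <= t1)]
    spk_i90 = result.spikes_of(POP_I, i90)
    spk_i90 = spk_i90[(spk_i90 >= t0) & (spk_i90 <= t1)]
    lock_e = spike_phase_locking(spk_e90, plfp_full)
    lock_i = spike_phase_locking(spk_i90, plfp_full)
    out["lock_e_modulus"] = lock_e.modulus
    out["lock_e_arg"] = lock_e.arg_deg
    out["lock_e_nspikes"] = lock_e.n_spikes
    out["lock_i_modulus"] = lock_i.modulus
    out["lock_i_arg"] = lock_i.arg_deg
    out["lock_i_nspikes"] = lock_i.n_spikes

    if result.model.ext.f_ms > 0:
        lock_ms = spike_phase_locking_cosine(spk_e90, result.model.ext.f_ms)
        out["lock_ms_modulus"] = lock_ms.modulus
        out["lock_ms_arg"] = lock_ms.arg_deg
    return out
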
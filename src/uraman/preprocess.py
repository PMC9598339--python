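"""Spectral pre-processing for urine Raman spectra.

The chain runs, in order: cosmic-ray despiking, fluorescence baseline
removal by an iteratively clipped fifth-order polynomial fit, and
normalization by the area of the water band at 1660 cm^-1.  Spectra with
signal-to-noise ratio below a threshold (default 10) are then excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Group, SpectraSet, Spectrum

__all__ = [
    "PreprocessConfig",
    "ExcessiveSpikeError",
    "NormalizationError",
    "despike",
    "remove_baseline",
    "normalize_water_band",
    "estimate_snr",
    "qc_filter",
    "preprocess_spectrum",
    "preprocess_set",
    "group_mean_and_difference",
]


class ExcessiveSpikeError(ValueError):
    """More than 20% of channels flagged as spikes — signal, not artifact."""


class NormalizationError(ValueError):
    """Water-band area is not positive; normalization impossible."""


@dataclass
class PreprocessConfig:
    """Tunable parameters of the pre-processing chain.

    Defaults follow standard urine-Raman practice: despiking by a
    running-median z-score (window 5 channels, 8 robust SDs), a 5th-order
    iteratively clipped polynomial baseline, water band integrated over
    1610-1710 cm^-1 (center 1660, half-width 50), and SNR measured as the
    peak signal in the dominant urea-band region 950-1050 cm^-1 over the
    detrended noise SD in the quiet 1750-1800 cm^-1 window.
    """

    despike_window: int = 5
    despike_z: float = 8.0
    baseline_order: int = 5
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    water_band_center: float = 1660.0
    water_band_halfwidth: float = 50.0
    snr_threshold: float = 10.0
    snr_signal_window: tuple[float, float] = (950.0, 1050.0)
    snr_noise_window: tuple[float, float] = (1750.0, 1800.0)

    def __post_init__(self) -> None:
        if self.despike_window % 2 == 0 or self.despike_window < 3:
            raise ValueError("despike_window must be an odd integer >= 3")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be > 0")
        if self.water_band_halfwidth <= 0:
            raise ValueError("water_band_halfwidth must be > 0")

    @property
    def water_window(self) -> tuple[float, float]:
        c, h = self.water_band_center, self.water_band_halfwidth
        return (c - h, c + h)


def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    # edge channels use a shrunken window (reflect-free, order-statistic)
    from scipy.ndimage import median_filter

    return median_filter(y, size=window, mode="nearest")


def despike(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Replace cosmic-ray spikes by linear interpolation.

    A channel is a spike when its deviation from the running median exceeds
    ``despike_z`` robust standard deviations.  The robust SD is the noise
    scale estimated from first differences (1.4826 * MAD of diff(y) over
    sqrt(2)), which is insensitive both to smooth trends — where the
    median-filter residual collapses to zero and would wreck a MAD taken
    on it — and to the spikes themselves.  Flagged channels are replaced
    by linear interpolation between flanking unflagged channels; the count
    is recorded as ``meta.n_spikes_removed``.
    """
    cfg = cfg or PreprocessConfig()
    y = s.intensity
    if cfg.despike_window >= y.size:
        raise ValueError("despike window must be smaller than the spectrum")
    med = _running_median(y, cfg.despike_window)
    resid = y - med
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    robust_sd = 1.4826 * mad / np.sqrt(2.0)
    if robust_sd == 0.0:
        # a spectrum the median filter reproduces exactly except at isolated
        # channels: those channels are the spikes
        flagged = np.abs(resid) > 0
    else:
        flagged = np.abs(resid) > cfg.despike_z * robust_sd
    n_flagged = int(flagged.sum())
    if n_flagged > 0.2 * y.size:
        raise ExcessiveSpikeError(
            f"{n_flagged}/{y.size} channels flagged as spikes; this looks like"
            " signal, not cosmic rays"
        )
    if n_flagged == 0:
        return s.with_intensity(y, n_spikes_removed=0)
    out = y.copy()
    good = ~flagged
    x = s.axis.values
    out[flagged] = np.interp(x[flagged], x[good], y[good])
    return s.with_intensity(out, n_spikes_removed=n_flagged)


def remove_baseline(
    s: Spectrum, cfg: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Subtract the fluorescence baseline by iterative polynomial clipping.

    A polynomial of ``baseline_order`` (default 5) is least-squares fitted;
    intensities above the fit are clipped to the fit and the fit repeated
    until it changes by less than ``baseline_tol`` in relative norm or
    ``baseline_max_iter`` is reached.  Peaks, lying above the smooth
    background, are thereby excluded from the fit.  Returns (corrected,
    baseline) with corrected + baseline == input to 1e-9.
    """
    cfg = cfg or PreprocessConfig()
    y = s.intensity
    if y.size <= cfg.baseline_order + 1:
        raise ValueError("spectrum too short for the requested baseline order")
    x = s.axis.values
    # map to [-1, 1] for conditioning
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    work = y.copy()
    fit = np.zeros_like(y)
    converged = False
    for _ in range(cfg.baseline_max_iter):
        coef = np.polynomial.polynomial.polyfit(t, work, cfg.baseline_order)
        new_fit = np.polynomial.polynomial.polyval(t, coef)
        denom = np.linalg.norm(new_fit)
        change = np.linalg.norm(new_fit - fit) / denom if denom > 0 else 0.0
        fit = new_fit
        work = np.minimum(work, fit)
        if change < cfg.baseline_tol:
            converged = True
            break
    corrected = s.with_intensity(y - fit, baseline_converged=converged)
    baseline = s.with_intensity(fit)
    return corrected, baseline


def _band_area(s: Spectrum, window: tuple[float, float]) -> float:
    mask = s.axis.window_mask(*window)
    if mask.sum() < 2:
        raise NormalizationError("water-band window covers fewer than 2 channels")
    return float(np.trapezoid(s.intensity[mask], s.axis.values[mask]))


def normalize_water_band(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Divide by the trapezoidal area of the water band (default 1610-1710).

    After normalization the band area is exactly 1, making intensities
    comparable across acquisitions with different collection efficiency.
    """
    cfg = cfg or PreprocessConfig()
    area = _band_area(s, cfg.water_window)
    if not area > 0:
        raise NormalizationError(
            f"water-band area {area} is not positive; baseline correction may"
            " have failed or the band is empty"
        )
    return s.with_intensity(s.intensity / area)


def estimate_snr(s: Spectrum, cfg: PreprocessConfig | None = None) -> float:
    """Signal-to-noise ratio of a baseline-corrected spectrum.

    Ratio of the maximum intensity in the signal window (default 950-1050
    cm^-1, the dominant urea band region) to the standard deviation of the
    linearly detrended intensity in the noise window (default 1750-1800
    cm^-1, free of analyte bands).  Returns ``inf`` for zero noise.
    """
    cfg = cfg or PreprocessConfig()
    sig_mask = s.axis.window_mask(*cfg.snr_signal_window)
    noise_mask = s.axis.window_mask(*cfg.snr_noise_window)
    if sig_mask.sum() == 0 or noise_mask.sum() < 3:
        raise ValueError("SNR windows do not cover enough channels of the axis")
    signal = float(np.max(s.intensity[sig_mask]))
    xn = s.axis.values[noise_mask]
    yn = s.intensity[noise_mask]
    slope, intercept = np.polyfit(xn, yn, 1)
    noise_sd = float(np.std(yn - (slope * xn + intercept), ddof=1))
    if noise_sd == 0.0:
        return float("inf")
    return max(signal, 0.0) / noise_sd


def qc_filter(spectra: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Exclude spectra with SNR below ``snr_threshold`` (default 10).

    Records ``meta.snr`` and ``meta.qc_pass`` on every spectrum.  Raises if
    nothing survives.
    """
    cfg = cfg or PreprocessConfig()
    kept = []
    for s in spectra:
        snr = estimate_snr(s, cfg)
        passed = snr >= cfg.snr_threshold
        s.meta.snr = snr
        s.meta.qc_pass = passed
        if passed:
            kept.append(s)
    if not kept:
        raise ValueError("all spectra excluded by the SNR filter")
    return SpectraSet(spectra.axis, kept)


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full chain on one spectrum: despike -> baseline -> water normalize."""
    cfg = cfg or PreprocessConfig()
    s = despike(s, cfg)
    s, _ = remove_baseline(s, cfg)
    return normalize_water_band(s, cfg)


def preprocess_set(
    spectra: SpectraSet, cfg: PreprocessConfig | None = None, qc: bool = True
) -> SpectraSet:
    """Apply the full chain to every spectrum, then (optionally) QC-filter.

    SNR is measured on the baseline-corrected (pre-normalization) scale;
    the retained spectra are water-band normalized.
    """
    cfg = cfg or PreprocessConfig()
    corrected = []
    for s in spectra:
        d = despike(s, cfg)
        c, _ = remove_baseline(d, cfg)
        corrected.append(c)
    out = SpectraSet(spectra.axis, corrected)
    if qc:
        out = qc_filter(out, cfg)
    else:
        for s in out:
            s.meta.snr = estimate_snr(s, cfg)
            s.meta.qc_pass = True
    return SpectraSet(out.axis, [normalize_water_band(s, cfg) for s in out])


def group_mean_and_difference(
    spectra: SpectraSet,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Channel-wise group means and their difference (DM&HBP - CT)."""
    from .core import SpectrumMeta

    mats = {}
    for g in (Group.CT, Group.DMHBP):
        sub = spectra.select_group(g)
        if len(sub) == 0:
            raise ValueError(f"group {g.value} has no spectra")
        mats[g] = sub.intensity_matrix().mean(axis=0)
    mean_ct = Spectrum(spectra.axis, mats[Group.CT], SpectrumMeta("mean_CT"))
    mean_dm = Spectrum(spectra.axis, mats[Group.DMHBP], SpectrumMeta("mean_DMHBP"))
    diff = Spectrum(
        spectra.axis,
        mats[Group.DMHBP] - mats[Group.CT],
        SpectrumMeta("difference_DMHBP_minus_CT"),
    )
    return mean_ct, mean_dm, diff
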
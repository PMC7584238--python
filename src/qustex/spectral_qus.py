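"""Per-window power spectra, reference normalization and the five QUS
parameters: MBF, SS, SI (linear fit to the normalized dB spectrum) and
ASD, AAC (spherical-Gaussian form-factor linearization of the normalized
backscatter coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from qustex.phantom_sim import GAUSSIAN_FF_CONST, DEFAULT_SPEED_OF_SOUND

DEFAULT_BAND = (4e6, 9e6)
DEFAULT_CENTER = 7e6
#: smallest reportable average scatterer diameter (um); nonphysical
#: (positive-slope) fits are clamped here and flagged
MIN_ASD_UM = 1.0


@dataclass
class PowerSpectrum:
    """Averaged per-line periodogram of one analysis window, in dB."""

    frequencies: np.ndarray
    power_db: np.ndarray
    window_origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.frequencies.shape != self.power_db.shape:
            raise ValueError("frequency and power grids must match")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def is_degenerate(self) -> bool:
        return not np.all(np.isfinite(self.power_db))

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        return (self.frequencies >= band[0]) & (self.frequencies <= band[1])


@dataclass(frozen=True)
class SpectralFit:
    """Linear fit to a normalized dB spectrum over the analysis band.

    Satisfies MBF = SI + SS * f_c(MHz) by construction.
    """

    MBF: float  # dBr
    SS: float  # dBr/MHz
    SI: float  # dBr
    band: tuple[float, float]
    center_frequency: float
    valid: bool = True


@dataclass(frozen=True)
class ScattererEstimate:
    ASD: float  # um (diameter = 2x effective Gaussian radius)
    AAC: float  # dB/cm^3 convention (log-scale acoustic concentration)
    valid: bool = True
    clamped: bool = False


def window_power_spectrum(
    rf_window: np.ndarray,
    sampling_frequency: float,
    taper: str = "hann",
    nfft: int | None = None,
    window_origin: tuple[int, int] = (0, 0),
) -> PowerSpectrum:
    """Average the tapered per-line periodograms of one RF window.

    Spectra are averaged in linear power before the dB conversion.  An
    all-zero window yields -inf dB everywhere and is flagged degenerate
    rather than raising.
    """
    rf_window = np.asarray(rf_window, dtype=float)
    if rf_window.ndim != 2:
        raise ValueError("rf_window must be 2-D (samples x lines)")
    n_samples, n_lines = rf_window.shape
    if n_samples < 16 or n_lines < 2:
        raise ValueError(
            f"window too small ({n_samples} samples x {n_lines} lines); "
            "need >= 16 samples and >= 2 lines"
        )
    w = get_window(taper, n_samples, fftbins=True)
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(2 * n_samples)))
    tapered = rf_window * w[:, None]
    spec = np.fft.rfft(tapered, nfft, axis=0)
    # per-line periodogram, averaged in linear power across lines
    power = np.mean(np.abs(spec) ** 2, axis=1) / (np.sum(w**2) * sampling_frequency)
    freqs = np.fft.rfftfreq(nfft, 1.0 / sampling_frequency)
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    return PowerSpectrum(freqs, power_db, window_origin)


def normalize_to_reference(
    sample: PowerSpectrum,
    reference: PowerSpectrum,
    known_bsc: np.ndarray | float = 1.0,
) -> PowerSpectrum:
    """Reference-phantom normalization.

    normalized_dB = sample_dB - reference_dB + 10 log10(known_bsc),
    cancelling the system/transducer transfer function exactly.
    ``known_bsc`` is the reference phantom's linear backscatter coefficient
    on the sample's frequency grid (scalar or array).
    """
    if sample.frequencies.shape != reference.frequencies.shape or np.any(
        sample.frequencies != reference.frequencies
    ):
        raise ValueError("sample and reference frequency grids differ")
    bsc = np.broadcast_to(np.asarray(known_bsc, dtype=float), sample.power_db.shape)
    if np.any(bsc <= 0):
        raise ValueError("known_bsc must be strictly positive")
    norm_db = sample.power_db - reference.power_db + 10.0 * np.log10(bsc)
    return PowerSpectrum(sample.frequencies.copy(), norm_db, sample.window_origin)


def fit_spectral_band(
    norm: PowerSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    center: float = DEFAULT_CENTER,
) -> SpectralFit:
    """Least-squares line on dB vs frequency (MHz) restricted to ``band``.

    SS is the slope, SI the 0-MHz extrapolation, MBF the line value at
    ``center``.  A degenerate spectrum yields an invalid fit (NaNs) instead
    of an exception.
    """
    sel = norm.band_slice(band)
    if sel.sum() < 4:
        raise ValueError("need >= 4 frequency bins inside the analysis band")
    f_mhz = norm.frequencies[sel] / 1e6
    y = norm.power_db[sel]
    if not np.all(np.isfinite(y)):
        return SpectralFit(np.nan, np.nan, np.nan, band, center, valid=False)
    slope, intercept = np.polyfit(f_mhz, y, 1)
    mbf = intercept + slope * (center / 1e6)
    return SpectralFit(
        MBF=float(mbf), SS=float(slope), SI=float(intercept),
        band=band, center_frequency=center,
    )


def estimate_scatterer_properties(
    norm: PowerSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND,
) -> ScattererEstimate:
    """ASD and AAC from a normalized (BSC-scale) spectrum.

    The spherical-Gaussian backscatter model
        BSC(f) = eta * (f/1MHz)^4 * exp(-0.827 k^2 a_eff^2),  k = 2 pi f / c
    linearizes as
        ln BSC - 4 ln(f/1MHz) = ln(eta) - 0.827 (2 pi / c)^2 a_eff^2 * f^2,
    so regressing the left side on f^2 gives
        a_eff = sqrt(-slope / (0.827 (2 pi / c)^2)),   ASD = 2 a_eff,
        AAC  = 10 log10(eta) from the intercept.
    A nonphysical positive slope clamps ASD to MIN_ASD_UM with a flag.
    """
    sel = norm.band_slice(band)
    if sel.sum() < 4:
        raise ValueError("need >= 4 frequency bins inside the analysis band")
    y_db = norm.power_db[sel]
    if not np.all(np.isfinite(y_db)):
        return ScattererEstimate(np.nan, np.nan, valid=False)
    f = norm.frequencies[sel]
    ln_bsc = y_db * (np.log(10.0) / 10.0)
    y = ln_bsc - 4.0 * np.log(f / 1e6)
    slope, intercept = np.polyfit(f**2, y, 1)
    coef = GAUSSIAN_FF_CONST * (2.0 * np.pi / speed_of_sound) ** 2
    clamped = slope >= 0
    if clamped:
        asd_um = MIN_ASD_UM
    else:
        a_eff = np.sqrt(-slope / coef)
        asd_um = max(MIN_ASD_UM, 2.0 * a_eff * 1e6)
    aac_db = 10.0 * intercept / np.log(10.0)
    return ScattererEstimate(
        ASD=float(asd_um), AAC=float(aac_db), valid=True, clamped=bool(clamped)
    )
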
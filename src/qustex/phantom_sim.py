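"""Pulse-echo RF simulation from random point-scatterer phantoms.

The scattering model is deliberately simple so that every downstream
estimator has an analytic ground truth:

* a frame is an impulse train (one weighted delta per scatterer per line)
  convolved axially with a Gaussian-enveloped cosine pulse;
* scatterer size enters as a spherical-Gaussian form factor that low-pass
  filters the echo spectrum;
* the backscatter coefficient of a field is therefore

      BSC(f) = eta * (f / 1 MHz)^4 * exp(-0.827 * k^2 * a_eff^2)

  with ``k = 2*pi*f/c``, ``a_eff`` the effective scatterer radius and
  ``eta = number_density * E[amplitude^2]`` the acoustic concentration
  (simulator units: mm^-2 * squared echogenicity).  ``0.827`` is the
  standard spherical-Gaussian form-factor constant.

No frequency-dependent tissue attenuation is applied by default, which keeps
reference-phantom normalization exact in tests (a dB/(cm MHz) hook exists on
:class:`ReferencePhantom` for real data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

GAUSSIAN_FF_CONST = 0.827
DEFAULT_SPEED_OF_SOUND = 1540.0  # m/s, standard soft-tissue value


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseModel:
    """Transmit pulse / transducer description.

    ``fractional_bandwidth`` is the -6 dB (power) full bandwidth divided by
    the center frequency.
    """

    center_frequency: float
    fractional_bandwidth: float
    sampling_frequency: float
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND

    def __post_init__(self) -> None:
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError(
                f"fractional_bandwidth must be in (0, 2), got {self.fractional_bandwidth}"
            )
        if self.sampling_frequency <= 4.0 * self.center_frequency:
            raise ValueError(
                "sampling_frequency must exceed 4x center_frequency "
                f"({self.sampling_frequency:g} <= 4*{self.center_frequency:g})"
            )
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")

    @property
    def wavelength(self) -> float:
        """Wavelength at the center frequency, in meters."""
        return self.speed_of_sound / self.center_frequency

    @property
    def envelope_sigma_t(self) -> float:
        """Std of the Gaussian time envelope implied by the -6 dB bandwidth."""
        bw = self.fractional_bandwidth * self.center_frequency
        # -6 dB (power) half width: exp(-d^2/(2 s^2)) = 10^-0.6
        sigma_f = bw / (2.0 * np.sqrt(2.0 * 0.6 * np.log(10.0)))
        return 1.0 / (2.0 * np.pi * sigma_f)


@dataclass(frozen=True)
class ScattererField:
    """Random point-scatterer realization inside a rectangular extent."""

    positions: np.ndarray  # (n, 2) [axial m, lateral m]
    amplitudes: np.ndarray  # (n,) dimensionless echogenicity
    effective_radius: float  # um
    number_density: float  # per mm^2
    extent: tuple[float, float]  # (axial m, lateral m)
    seed: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        amp = np.asarray(self.amplitudes, dtype=float).ravel()
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)
        if pos.shape[0] != amp.shape[0]:
            raise ValueError("positions and amplitudes length mismatch")
        if pos.size and (
            pos.min() < 0
            or pos[:, 0].max() > self.extent[0]
            or pos[:, 1].max() > self.extent[1]
        ):
            raise ValueError("scatterer positions outside extent")
        if self.effective_radius <= 0:
            raise ValueError("effective_radius must be positive")

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    def mean_square_amplitude(self) -> float:
        if self.n_scatterers == 0:
            return 0.0
        return float(np.mean(self.amplitudes**2))

    def acoustic_concentration(self) -> float:
        """eta = density * E[amp^2] (mm^-2 units)."""
        return self.number_density * self.mean_square_amplitude()


@dataclass
class RFVolume:
    """Stack of RF frames plus the acquisition geometry."""

    frames: list[np.ndarray]  # each (n_samples, n_lines)
    sampling_frequency: float
    line_spacing: float  # m
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND
    frame_spacing: float = 0.01  # m; tumor scanned at 1 cm intervals

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if not self.frames:
            raise ValueError("RFVolume needs at least one frame")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share a shape")
        if self.sampling_frequency <= 0 or self.frame_spacing <= 0:
            raise ValueError("sampling_frequency and frame_spacing must be positive")
        if self.line_spacing <= 0:
            raise ValueError("line_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def axial_pitch(self) -> float:
        """Axial distance per RF sample, in meters (pulse-echo: c / 2fs)."""
        return self.speed_of_sound / (2.0 * self.sampling_frequency)


@dataclass
class ReferencePhantom:
    """Reference acquisition with tabulated known backscatter coefficient."""

    rf: RFVolume
    bsc_frequencies: np.ndarray  # Hz
    bsc_values: np.ndarray  # linear BSC on bsc_frequencies
    attenuation: float = 0.0  # dB/(cm MHz)

    def __post_init__(self) -> None:
        self.bsc_frequencies = np.asarray(self.bsc_frequencies, dtype=float)
        self.bsc_values = np.asarray(self.bsc_values, dtype=float)
        if self.bsc_frequencies.shape != self.bsc_values.shape:
            raise ValueError("bsc grids mismatch")
        if np.any(self.bsc_values <= 0):
            raise ValueError("known BSC must be strictly positive")

    def bsc_at(self, frequencies: np.ndarray) -> np.ndarray:
        """Interpolate the tabulated BSC onto ``frequencies`` (Hz)."""
        return np.interp(frequencies, self.bsc_frequencies, self.bsc_values)


@dataclass
class SimulatedTumor:
    """One labelled synthetic patient: RF volume, per-frame ROI masks, truth."""

    rf: RFVolume
    masks: list[np.ndarray]
    label: str
    truth: dict = field(default_factory=dict)

    def __iter__(self):
        # allow (rf, masks, label) unpacking
        return iter((self.rf, self.masks, self.label))


# ---------------------------------------------------------------------------
# analytic backscatter model (shared ground-truth convention)
# ---------------------------------------------------------------------------


def analytic_bsc(
    frequencies: np.ndarray,
    effective_radius_um: float,
    acoustic_concentration: float,
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND,
) -> np.ndarray:
    """BSC(f) = eta * (f/1MHz)^4 * exp(-0.827 k^2 a^2) of the simulator model."""
    f = np.asarray(frequencies, dtype=float)
    a = effective_radius_um * 1e-6
    k = 2.0 * np.pi * f / speed_of_sound
    return acoustic_concentration * (f / 1e6) ** 4 * np.exp(
        -GAUSSIAN_FF_CONST * k**2 * a**2
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_scatterer_field(
    extent: tuple[float, float],
    number_density: float,
    effective_radius: float,
    amplitude_cv: float = 0.0,
    seed: int = 0,
) -> ScattererField:
    """Draw a Poisson point-scatterer field.

    Parameters
    ----------
    extent : (axial m, lateral m)
    number_density : scatterers per mm^2
    effective_radius : um
    amplitude_cv : coefficient of variation of the (positive, mean-1)
        per-scatterer echogenicity; 0 means uniform unit amplitude.
    """
    if number_density < 0:
        raise ValueError(f"number_density must be >= 0, got {number_density}")
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    if effective_radius <= 0:
        raise ValueError("effective_radius must be positive")
    if amplitude_cv < 0:
        raise ValueError("amplitude_cv must be >= 0")

    rng = np.random.default_rng(seed)
    area_mm2 = extent[0] * extent[1] * 1e6
    n = int(rng.poisson(number_density * area_mm2))
    positions = np.column_stack(
        [rng.uniform(0, extent[0], n), rng.uniform(0, extent[1], n)]
    )
    if amplitude_cv > 0:
        # gamma with mean 1 and CV amplitude_cv
        shape = 1.0 / amplitude_cv**2
        amplitudes = rng.gamma(shape, scale=1.0 / shape, size=n)
    else:
        amplitudes = np.ones(n)
    return ScattererField(
        positions=positions,
        amplitudes=amplitudes,
        effective_radius=effective_radius,
        number_density=number_density,
        extent=tuple(extent),
        seed=seed,
    )


def _pulse_kernel(pulse: PulseModel, effective_radius_um: float) -> np.ndarray:
    """Gaussian-enveloped cosine, size-filtered by sqrt of the form factor."""
    fs = pulse.sampling_frequency
    sigma_t = pulse.envelope_sigma_t
    half = max(8, int(np.ceil(4.0 * sigma_t * fs)))
    t = np.arange(-half, half + 1) / fs
    kernel = np.cos(2.0 * np.pi * pulse.center_frequency * t) * np.exp(
        -(t**2) / (2.0 * sigma_t**2)
    )
    a = effective_radius_um * 1e-6
    n_fft = 4 * len(kernel)
    spec = np.fft.rfft(kernel, n_fft)
    f = np.fft.rfftfreq(n_fft, 1.0 / fs)
    k = 2.0 * np.pi * f / pulse.speed_of_sound
    # amplitude filter = sqrt(power form factor)
    spec *= np.exp(-0.5 * GAUSSIAN_FF_CONST * k**2 * a**2)
    # zero-phase filter: output stays centered at sample `half`; the 4x padding
    # keeps circular wrap-around of the short filter tails negligible
    filtered = np.fft.irfft(spec, n_fft)
    return filtered[: 2 * half + 1]


def synthesize_rf(
    field: ScattererField,
    pulse: PulseModel,
    n_lines: int,
    line_spacing: float,
    beam_sigma_lines: float = 1.0,
    noise_rms: float = 0.0,
    seed: int = 0,
    frame_spacing: float = 0.01,
) -> RFVolume:
    """Synthesize one RF frame from a scatterer field.

    Each scan line sums, over scatterers within the (Gaussian) lateral beam,
    a size-filtered pulse echo at delay ``2 * axial / c``, weighted by the
    scatterer amplitude and the lateral beam profile.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if line_spacing <= 0:
        raise ValueError("line_spacing must be positive")

    fs = pulse.sampling_frequency
    c = pulse.speed_of_sound
    n_samples = max(16, int(round(2.0 * field.extent[0] * fs / c)))
    impulses = np.zeros((n_samples, n_lines))

    if field.n_scatterers:
        z = field.positions[:, 0]
        x = field.positions[:, 1]
        amp = field.amplitudes
        order = np.argsort(x)
        z, x, amp = z[order], x[order], amp[order]
        sigma_x = beam_sigma_lines * line_spacing
        reach = 3.0 * sigma_x
        delay = 2.0 * z / c * fs  # fractional sample index
        i0 = np.floor(delay).astype(int)
        frac = delay - i0
        for line in range(n_lines):
            x_line = line * line_spacing
            lo, hi = np.searchsorted(x, [x_line - reach, x_line + reach])
            if lo == hi:
                continue
            w = amp[lo:hi] * np.exp(-((x[lo:hi] - x_line) ** 2) / (2.0 * sigma_x**2))
            j0, fr = i0[lo:hi], frac[lo:hi]
            ok = j0 < n_samples - 1
            np.add.at(impulses[:, line], j0[ok], w[ok] * (1.0 - fr[ok]))
            np.add.at(impulses[:, line], j0[ok] + 1, w[ok] * fr[ok])

    kernel = _pulse_kernel(pulse, field.effective_radius)
    frame = fftconvolve(impulses, kernel[:, None], mode="same", axes=0)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_rms, frame.shape)
    return RFVolume(
        frames=[frame],
        sampling_frequency=fs,
        line_spacing=line_spacing,
        speed_of_sound=c,
        frame_spacing=frame_spacing,
    )


def resolution_cell_area_mm2(pulse: PulseModel, line_spacing: float,
                             beam_sigma_lines: float = 1.0) -> float:
    """Approximate resolution-cell area: axial pulse length x lateral beam FWHM."""
    fwhm_t = 2.355 * pulse.envelope_sigma_t
    axial_mm = fwhm_t * pulse.speed_of_sound / 2.0 * 1e3
    lateral_mm = 2.355 * beam_sigma_lines * line_spacing * 1e3
    return axial_mm * lateral_mm


def generate_reference(
    pulse: PulseModel,
    n_lines: int = 96,
    line_spacing: float = 3e-4,
    seed: int = 0,
    extent_axial: float = 0.015,
    effective_radius_um: float = 10.0,
    min_scatterers_per_cell: float = 15.0,
    attenuation: float = 0.0,
) -> ReferencePhantom:
    """Dense small-scatterer reference phantom with analytically known BSC."""
    cell = resolution_cell_area_mm2(pulse, line_spacing)
    density = max(150.0, min_scatterers_per_cell / cell)
    extent = (extent_axial, n_lines * line_spacing)
    fld = generate_scatterer_field(
        extent, density, effective_radius_um, amplitude_cv=0.0, seed=seed
    )
    rf = synthesize_rf(fld, pulse, n_lines, line_spacing)
    freqs = np.linspace(1e6, pulse.sampling_frequency / 2.0, 257)
    bsc = analytic_bsc(
        freqs, effective_radius_um, fld.acoustic_concentration(), pulse.speed_of_sound
    )
    return ReferencePhantom(
        rf=rf, bsc_frequencies=freqs, bsc_values=bsc, attenuation=attenuation
    )


@dataclass(frozen=True)
class ClassParams:
    """Per-class (mean, sd) distributions of tumor scatterer microstructure."""

    radius_um: tuple[float, float] = (30.0, 3.0)
    density_mm2: tuple[float, float] = (150.0, 10.0)
    amplitude_cv: tuple[float, float] = (0.3, 0.05)


def _draw_positive(rng: np.random.Generator, mean_sd: tuple[float, float],
                   noise: float, floor: float) -> float:
    mean, sd = mean_sd
    val = rng.normal(mean, sd + noise * mean)
    return max(floor, float(val))


def _ellipse_mask(
    n_samples: int,
    n_lines: int,
    axial_pitch: float,
    line_spacing: float,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
) -> np.ndarray:
    z = np.arange(n_samples) * axial_pitch
    x = np.arange(n_lines) * line_spacing
    zz, xx = np.meshgrid(z, x, indexing="ij")
    return ((zz - center[0]) / semi_axes[0]) ** 2 + (
        (xx - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def generate_cohort(
    n_per_class: int,
    class_params: dict[str, ClassParams],
    noise: float = 0.0,
    seed: int = 0,
    pulse: PulseModel | None = None,
    n_lines: int = 48,
    line_spacing: float = 3e-4,
    extent_axial: float = 0.010,
    n_frames: int = 1,
    background: ClassParams = ClassParams((30.0, 0.0), (120.0, 0.0), (0.2, 0.0)),
) -> list[SimulatedTumor]:
    """Two-class labelled synthetic tumors: elliptical ROI inside a background
    field whose scatterer statistics differ from the tumor interior.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if len(class_params) != 2:
        raise ValueError("exactly two classes required")
    labels = sorted(class_params)
    if class_params[labels[0]] == class_params[labels[1]] and noise == 0:
        warnings.warn(
            "identical class parameters with noise=0: classes are inseparable "
            "by construction",
            stacklevel=2,
        )
    if pulse is None:
        pulse = PulseModel(7e6, 5.0 / 7.0, 40e6)

    rng = np.random.default_rng(seed)
    extent = (extent_axial, n_lines * line_spacing)
    cohort: list[SimulatedTumor] = []
    for label in labels:
        params = class_params[label]
        for i in range(n_per_class):
            pseed = int(rng.integers(0, 2**31 - 1))
            prng = np.random.default_rng(pseed)
            radius = _draw_positive(prng, params.radius_um, noise, 1.0)
            density = _draw_positive(prng, params.density_mm2, noise, 5.0)
            amp_cv = _draw_positive(prng, params.amplitude_cv, noise, 0.0)
            center = (
                extent[0] * prng.uniform(0.45, 0.55),
                extent[1] * prng.uniform(0.45, 0.55),
            )
            semi = (
                extent[0] * prng.uniform(0.30, 0.38),
                extent[1] * prng.uniform(0.30, 0.38),
            )
            frames, masks = [], []
            for fidx in range(n_frames):
                fseed = int(prng.integers(0, 2**31 - 1))
                bg = generate_scatterer_field(
                    extent, background.density_mm2[0], background.radius_um[0],
                    background.amplitude_cv[0], seed=fseed,
                )
                tum = generate_scatterer_field(
                    extent, density, radius, amp_cv, seed=fseed + 1
                )

                def _inside(f: ScattererField) -> np.ndarray:
                    return (
                        ((f.positions[:, 0] - center[0]) / semi[0]) ** 2
                        + ((f.positions[:, 1] - center[1]) / semi[1]) ** 2
                    ) <= 1.0

                bg_keep = ~_inside(bg) if bg.n_scatterers else np.zeros(0, bool)
                tum_keep = _inside(tum) if tum.n_scatterers else np.zeros(0, bool)
                bg_f = ScattererField(
                    bg.positions[bg_keep], bg.amplitudes[bg_keep],
                    bg.effective_radius, bg.number_density, extent, fseed,
                )
                tum_f = ScattererField(
                    tum.positions[tum_keep], tum.amplitudes[tum_keep],
                    radius, density, extent, fseed + 1,
                )
                rf_bg = synthesize_rf(bg_f, pulse, n_lines, line_spacing)
                rf_tum = synthesize_rf(tum_f, pulse, n_lines, line_spacing)
                frame = rf_bg.frames[0] + rf_tum.frames[0]
                frames.append(frame)
                masks.append(
                    _ellipse_mask(
                        frame.shape[0], frame.shape[1],
                        pulse.speed_of_sound / (2.0 * pulse.sampling_frequency),
                        line_spacing, center, semi,
                    )
                )
            rf = RFVolume(
                frames=frames,
                sampling_frequency=pulse.sampling_frequency,
                line_spacing=line_spacing,
                speed_of_sound=pulse.speed_of_sound,
            )
            cohort.append(
                SimulatedTumor(
                    rf=rf,
                    masks=masks,
                    label=label,
                    truth={
                        "radius_um": radius,
                        "density_mm2": density,
                        "amplitude_cv": amp_cv,
                        "seed": pseed,
                    },
                )
            )
    return cohort
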
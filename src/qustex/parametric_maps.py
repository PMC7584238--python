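"""Sub-ROI planning and assembly of the five QUS parametric maps.

The tumor ROI is tiled with square analysis windows of physical side ten
wavelengths (10 * c / f_c) overlapping ~94% in both directions; each window
contributes one pixel per map on the sub-ROI step lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from qustex.phantom_sim import PulseModel, ReferencePhantom, RFVolume
from qustex.spectral_qus import (
    DEFAULT_BAND,
    DEFAULT_CENTER,
    PowerSpectrum,
    estimate_scatterer_properties,
    fit_spectral_band,
)

MAP_NAMES = ("MBF", "SS", "SI", "ASD", "AAC")
MAP_UNITS = {"MBF": "dBr", "SS": "dBr/MHz", "SI": "dBr", "ASD": "um", "AAC": "dB/cm^3"}

WINDOW_WAVELENGTHS = 10.0  # physical window side, in wavelengths
DEFAULT_OVERLAP = 0.94


def validate_roi_mask(mask: np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    """Check a per-frame boolean ROI mask against the RF lattice."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frame_shape}"
        )
    return mask


@dataclass
class SubROIGrid:
    """Planned analysis windows on the RF sample x line lattice."""

    window_samples: int
    window_lines: int
    step_samples: int
    step_lines: int
    #: lattice coordinates (window origins) shared by all frames
    s_positions: np.ndarray
    l_positions: np.ndarray
    #: per frame: boolean (len(s_positions), len(l_positions)) inclusion grid
    included: list[np.ndarray] = field(default_factory=list)
    window_extent: tuple[float, float] = (0.0, 0.0)  # physical side (m), axial/lateral

    @property
    def is_empty(self) -> bool:
        return not any(inc.any() for inc in self.included)

    @property
    def n_windows(self) -> int:
        return int(sum(inc.sum() for inc in self.included))

    @property
    def window_side_mm(self) -> tuple[float, float]:
        """Physical window side in mm (axial, lateral)."""
        return (self.window_extent[0] * 1e3, self.window_extent[1] * 1e3)


@dataclass
class ParametricMap:
    """One QUS quantity on the sub-ROI lattice of a single frame.

    NaN marks sub-ROIs outside the ROI or with invalid fits.  ``geometry``
    is the physical distance between neighboring map pixels in mm
    (step * pitch along each axis).
    """

    name: str
    values: np.ndarray
    geometry: tuple[float, float]
    units: str = ""

    def __post_init__(self) -> None:
        if self.name not in MAP_NAMES:
            raise ValueError(f"unknown map name {self.name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            self.units = MAP_UNITS[self.name]

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())

    def valid_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def _round_to_odd(x: float, minimum: int = 3) -> int:
    k = int(round(x))
    if k % 2 == 0:
        k = k + 1 if (k + 1 - x) <= (x - (k - 1)) else k - 1
    return max(minimum, k)


def plan_subrois(
    masks: list[np.ndarray] | np.ndarray,
    pulse: PulseModel,
    rf: RFVolume,
    overlap: float = DEFAULT_OVERLAP,
    inclusion: str = "center",
) -> SubROIGrid:
    """Plan the overlapping sub-ROI windows inside the tumor ROI.

    Window side targets ``WINDOW_WAVELENGTHS * lambda`` physically in both
    axes, converted independently through the axial sample pitch
    (c / 2 fs) and the lateral line pitch; pixel counts are rounded to the
    nearest odd number so window centers are well defined.  Step is
    ``max(1, round((1 - overlap) * window))`` per axis.  A window is kept
    when its center pixel lies inside the mask (``inclusion="center"``,
    default) or when it is fully inside (``inclusion="inside"``).
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if inclusion not in ("center", "inside"):
        raise ValueError("inclusion must be 'center' or 'inside'")
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks]
    if len(masks) != rf.n_frames:
        raise ValueError("one mask per frame required")
    frame_shape = rf.frame_shape
    masks = [validate_roi_mask(m, frame_shape) for m in masks]

    side = WINDOW_WAVELENGTHS * pulse.wavelength  # physical window side (m)
    axial_pitch = rf.axial_pitch
    ws = _round_to_odd(side / axial_pitch, minimum=17)
    wl = _round_to_odd(side / rf.line_spacing, minimum=3)
    n_samples, n_lines = frame_shape
    step_s = max(1, int(round((1.0 - overlap) * ws)))
    step_l = max(1, int(round((1.0 - overlap) * wl)))

    s_pos = np.arange(0, max(n_samples - ws + 1, 0), step_s)
    l_pos = np.arange(0, max(n_lines - wl + 1, 0), step_l)
    included = []
    for mask in masks:
        inc = np.zeros((len(s_pos), len(l_pos)), dtype=bool)
        if len(s_pos) and len(l_pos):
            if inclusion == "center":
                centers_s = s_pos + ws // 2
                centers_l = l_pos + wl // 2
                inc = mask[np.ix_(centers_s, centers_l)]
            else:
                for i, s0 in enumerate(s_pos):
                    for j, l0 in enumerate(l_pos):
                        inc[i, j] = mask[s0 : s0 + ws, l0 : l0 + wl].all()
        included.append(inc)
    return SubROIGrid(
        window_samples=ws,
        window_lines=wl,
        step_samples=step_s,
        step_lines=step_l,
        s_positions=s_pos,
        l_positions=l_pos,
        included=included,
        window_extent=(side, side),
    )


def _block_line_periodograms(
    block: np.ndarray, taper: np.ndarray, nfft: int, fs: float
) -> np.ndarray:
    """Per-line tapered periodograms of an axial block, shape (nf, n_lines)."""
    spec = np.fft.rfft(block * taper[:, None], nfft, axis=0)
    return np.abs(spec) ** 2 / (np.sum(taper**2) * fs)


def _reference_spectrum_db(
    reference: ReferencePhantom, s0: int, ws: int, taper: np.ndarray,
    nfft: int, fs: float,
) -> np.ndarray:
    """Reference-phantom dB spectrum at axial origin s0 (all lines, all frames)."""
    acc = []
    for frame in reference.rf.frames:
        acc.append(
            _block_line_periodograms(frame[s0 : s0 + ws, :], taper, nfft, fs).mean(axis=1)
        )
    power = np.mean(acc, axis=0)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power)


def build_parametric_maps(
    rf: RFVolume,
    masks: list[np.ndarray] | np.ndarray,
    grid: SubROIGrid,
    reference: ReferencePhantom,
    band: tuple[float, float] = DEFAULT_BAND,
    center: float = DEFAULT_CENTER,
    taper: str = "hann",
) -> list[dict[str, ParametricMap] | None]:
    """One MBF/SS/SI/ASD/AAC value per planned sub-ROI, per frame.

    Windows are normalized by the reference-phantom spectrum at the same
    depth (all reference lines averaged) times the known BSC, then fitted.
    Frames with no included windows yield ``None``; invalid fits yield NaN
    map pixels.
    """
    if grid.is_empty:
        raise ValueError("sub-ROI grid is empty: ROI smaller than one window")
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks]
    fs = rf.sampling_frequency
    if abs(reference.rf.sampling_frequency - fs) > 1e-9 * fs:
        raise ValueError("reference sampling frequency incompatible with sample")
    ws, wl = grid.window_samples, grid.window_lines
    if reference.rf.frame_shape[0] < grid.s_positions.max(initial=0) + ws:
        raise ValueError("reference phantom shallower than the analysis ROI")

    nfft = int(2 ** np.ceil(np.log2(2 * ws)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    w = get_window(taper, ws, fftbins=True)
    band_sel = (freqs >= band[0]) & (freqs <= band[1])
    if band_sel.sum() < 4:
        raise ValueError("fewer than 4 frequency bins in analysis band")
    known_bsc_db = 10.0 * np.log10(reference.bsc_at(freqs[band_sel]))
    f_mhz = freqs[band_sel] / 1e6

    ref_cache: dict[int, np.ndarray] = {}
    geometry = (
        grid.step_samples * rf.axial_pitch * 1e3,
        grid.step_lines * rf.line_spacing * 1e3,
    )
    out: list[dict[str, ParametricMap] | None] = []
    for frame, inc in zip(rf.frames, grid.included):
        if not inc.any():
            out.append(None)
            continue
        shape = (len(grid.s_positions), len(grid.l_positions))
        vals = {name: np.full(shape, np.nan) for name in MAP_NAMES}
        for i, s0 in enumerate(grid.s_positions):
            cols = np.nonzero(inc[i])[0]
            if cols.size == 0:
                continue
            if s0 not in ref_cache:
                ref_cache[s0] = _reference_spectrum_db(reference, int(s0), ws, w, nfft, fs)
            ref_db = ref_cache[s0][band_sel]
            periodograms = _block_line_periodograms(frame[s0 : s0 + ws, :], w, nfft, fs)
            # sliding window-of-lines mean via cumulative sum
            csum = np.cumsum(periodograms, axis=1)
            csum = np.hstack([np.zeros((csum.shape[0], 1)), csum])
            for j in cols:
                l0 = grid.l_positions[j]
                power = (csum[:, l0 + wl] - csum[:, l0]) / wl
                with np.errstate(divide="ignore"):
                    samp_db = 10.0 * np.log10(power[band_sel])
                norm_db = samp_db - ref_db + known_bsc_db
                spectrum = PowerSpectrum(freqs[band_sel], norm_db, (int(s0), int(l0)))
                fit = fit_spectral_band(spectrum, band=band, center=center)
                if fit.valid:
                    vals["MBF"][i, j] = fit.MBF
                    vals["SS"][i, j] = fit.SS
                    vals["SI"][i, j] = fit.SI
                est = estimate_scatterer_properties(
                    spectrum, band=band, speed_of_sound=rf.speed_of_sound
                )
                if est.valid:
                    vals["ASD"][i, j] = est.ASD
                    vals["AAC"][i, j] = est.AAC
        out.append(
            {name: ParametricMap(name, vals[name], geometry) for name in MAP_NAMES}
        )
    return out


def volume_mean(
    frame_maps: list[dict[str, ParametricMap] | None], name: str
) -> float:
    """Unweighted mean over all valid sub-ROI values pooled across frames."""
    if name not in MAP_NAMES:
        raise ValueError(f"unknown map name {name!r}")
    pooled: list[np.ndarray] = []
    for maps in frame_maps:
        if maps is None:
            continue
        pooled.append(maps[name].valid_values())
    if not pooled:
        return float("nan")
    values = np.concatenate(pooled)
    if values.size == 0:
        return float("nan")
    return float(values.mean())
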
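"""Grey-level co-occurrence texture features with missing-value support.

First pass: CON/ENE/COR/HOM of each QUS parametric map (scalars and sliding
texture maps).  Second pass ("texture derivatives"): the same operator
re-applied to the first-pass texture maps.  The 105-entry feature vector is
5 QUS means + 20 first-pass + 80 second-pass scalars.

The co-occurrence counter is implemented here (not delegated) because map
pixels can be missing (sub-ROIs outside the tumor or failed fits) and pairs
touching a missing pixel must be skipped, which standard library GLCMs do
not support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

QUS_BASES = ("MBF", "SS", "SI", "ASD", "AAC")
TEXTURE_FEATURES = ("CON", "ENE", "COR", "HOM")


class DegenerateMapError(ValueError):
    """Raised when a map has no usable pixels or pixel pairs."""


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True
    #: HOM variant: "inverse_difference" (1/(1+|i-j|)) or
    #: "inverse_difference_moment" (1/(1+(i-j)^2))
    homogeneity: str = "inverse_difference"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if self.homogeneity not in ("inverse_difference", "inverse_difference_moment"):
            raise ValueError(f"unknown homogeneity variant {self.homogeneity!r}")

    def offsets(self) -> list[tuple[int, int]]:
        """(row, col) displacement per (distance, angle), skimage convention."""
        offs = []
        for d in self.distances:
            for ang in self.angles:
                rad = np.deg2rad(ang)
                dr = -int(round(d * np.sin(rad)))
                dc = int(round(d * np.cos(rad)))
                offs.append((dr, dc))
        return offs


@dataclass
class GLCM:
    matrix: np.ndarray
    config: GLCMConfig

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        L = self.config.levels
        if self.matrix.shape != (L, L):
            raise ValueError("GLCM shape does not match config.levels")
        if np.any(self.matrix < 0):
            raise ValueError("GLCM entries must be non-negative")


@dataclass
class Quantized:
    grid: np.ndarray  # integer levels, 0..levels-1 (0 where missing)
    missing: np.ndarray  # boolean
    degenerate: bool  # fewer than 2 distinct finite values


@dataclass
class TextureMap:
    """GLCM feature evaluated on a sliding neighborhood of a source map."""

    parent: str  # e.g. "MBF" (first pass) or "MBF-CON" (second pass)
    feature: str  # CON | ENE | COR | HOM
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.feature not in TEXTURE_FEATURES:
            raise ValueError(f"unknown texture feature {self.feature!r}")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def name(self) -> str:
        return f"{self.parent}-{self.feature}"


def quantize(
    map_values: np.ndarray, levels: int = 16, range_policy: str = "minmax"
) -> Quantized:
    """Equal-width binning of valid pixels into ``levels`` grey levels.

    The bin range is the [min, max] of the map's own valid pixels (per-map,
    per-patient), making the downstream features invariant to strictly
    increasing affine rescaling of the map.
    """
    if range_policy != "minmax":
        raise ValueError(f"unknown range_policy {range_policy!r}")
    values = np.asarray(map_values, dtype=float)
    missing = ~np.isfinite(values)
    valid = values[~missing]
    if valid.size == 0:
        raise DegenerateMapError("all-missing map cannot be quantized")
    lo, hi = valid.min(), valid.max()
    degenerate = np.unique(valid).size < 2
    grid = np.zeros(values.shape, dtype=np.intp)
    if not degenerate:
        filled = np.where(missing, lo, values)
        scaled = (filled - lo) / (hi - lo)
        grid = np.clip((scaled * levels).astype(np.intp), 0, levels - 1)
        grid[missing] = 0
    return Quantized(grid=grid, missing=missing, degenerate=degenerate)


def _cooccurrence_counts(
    grid: np.ndarray, missing: np.ndarray, config: GLCMConfig
) -> np.ndarray:
    L = config.levels
    counts = np.zeros(L * L)
    for dr, dc in config.offsets():
        h, w = grid.shape
        if abs(dr) >= h or abs(dc) >= w:
            continue
        r0 = slice(max(0, -dr), min(h, h - dr))
        r1 = slice(max(0, dr), min(h, h + dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        c1 = slice(max(0, dc), min(w, w + dc))
        a = grid[r0, c0]
        b = grid[r1, c1]
        ok = ~(missing[r0, c0] | missing[r1, c1])
        if not ok.any():
            continue
        idx = a[ok] * L + b[ok]
        counts += np.bincount(idx, minlength=L * L)
    return counts.reshape(L, L)


def compute_glcm(
    grid: np.ndarray, missing: np.ndarray | None, config: GLCMConfig = GLCMConfig()
) -> GLCM:
    """Normalized co-occurrence matrix over all configured offsets.

    Pairs touching a missing pixel are skipped; counts from all offsets are
    accumulated into one matrix, optionally symmetrized, and normalized to
    sum 1.
    """
    grid = np.asarray(grid)
    if missing is None:
        missing = np.zeros(grid.shape, dtype=bool)
    if grid.min(initial=0) < 0 or grid.max(initial=0) >= config.levels:
        raise ValueError("grid values outside [0, levels)")
    counts = _cooccurrence_counts(grid, np.asarray(missing, bool), config)
    if config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateMapError("no valid pixel pairs for the GLCM")
    return GLCM(matrix=counts / total, config=config)


def glcm_features(g: GLCM) -> dict[str, float]:
    """CON, ENE, COR, HOM of a normalized GLCM.

    COR of a zero-variance GLCM (all mass in one row/column) is defined as 1,
    the limit of a perfectly correlated constant field.
    """
    p = g.matrix
    L = g.config.levels
    i = np.arange(L)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    con = float(np.sum(p * (ii - jj) ** 2))
    ene = float(np.sum(p**2))
    if g.config.homogeneity == "inverse_difference":
        hom = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    else:
        hom = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum(p * (ii - mu_i) ** 2))
    var_j = float(np.sum(p * (jj - mu_j) ** 2))
    if var_i <= 0 or var_j <= 0:
        cor = 1.0
    else:
        cor = float(np.sum(p * (ii - mu_i) * (jj - mu_j)) / np.sqrt(var_i * var_j))
    return {"CON": con, "ENE": ene, "COR": cor, "HOM": hom}


_MISSING_FEATURES = {name: float("nan") for name in TEXTURE_FEATURES}


def texture_scalar(
    map_values: np.ndarray, config: GLCMConfig = GLCMConfig()
) -> dict[str, float]:
    """Whole-map GLCM features of one 2-D map (NaN pixels are missing).

    A degenerate map (all missing, or no valid pairs) yields 4 NaNs rather
    than raising.
    """
    try:
        q = quantize(map_values, levels=config.levels)
        g = compute_glcm(q.grid, q.missing, config)
    except DegenerateMapError:
        return dict(_MISSING_FEATURES)
    return glcm_features(g)


def texture_map(
    map_values: np.ndarray,
    config: GLCMConfig = GLCMConfig(),
    neighborhood: int = 15,
    step: int = 1,
    min_valid_fraction: float = 0.5,
    parent: str = "",
) -> dict[str, TextureMap]:
    """Sliding-neighborhood GLCM features over a map lattice.

    The map is quantized once (whole-map min-max range); a GLCM is then
    computed inside each ``neighborhood`` x ``neighborhood`` window.  Output
    dimensions are ``(dim - neighborhood) // step + 1`` per axis.  Windows
    with fewer than ``min_valid_fraction`` valid pixels (or no valid pairs)
    are missing.
    """
    if neighborhood < 3:
        raise ValueError("neighborhood must be >= 3 map pixels")
    values = np.asarray(map_values, dtype=float)
    h, w = values.shape
    if neighborhood > h or neighborhood > w:
        out = {
            feat: TextureMap(parent, feat, np.zeros((0, 0)))
            for feat in TEXTURE_FEATURES
        }
        return out
    try:
        q = quantize(values, levels=config.levels)
    except DegenerateMapError:
        nh = (h - neighborhood) // step + 1
        nw = (w - neighborhood) // step + 1
        return {
            feat: TextureMap(parent, feat, np.full((nh, nw), np.nan))
            for feat in TEXTURE_FEATURES
        }
    nh = (h - neighborhood) // step + 1
    nw = (w - neighborhood) // step + 1
    out_values = {feat: np.full((nh, nw), np.nan) for feat in TEXTURE_FEATURES}
    min_valid = min_valid_fraction * neighborhood * neighborhood
    for r in range(nh):
        r0 = r * step
        for c in range(nw):
            c0 = c * step
            sub_missing = q.missing[r0 : r0 + neighborhood, c0 : c0 + neighborhood]
            if (~sub_missing).sum() < min_valid:
                continue
            sub = q.grid[r0 : r0 + neighborhood, c0 : c0 + neighborhood]
            try:
                g = compute_glcm(sub, sub_missing, config)
            except DegenerateMapError:
                continue
            feats = glcm_features(g)
            for feat in TEXTURE_FEATURES:
                out_values[feat][r, c] = feats[feat]
    return {
        feat: TextureMap(parent, feat, out_values[feat]) for feat in TEXTURE_FEATURES
    }


def texture_derivatives(
    texture_maps: dict[str, TextureMap], config: GLCMConfig = GLCMConfig()
) -> dict[str, float]:
    """Second-pass scalars: the first-pass operator re-applied to each
    first-pass texture map (name-keyed, order-free)."""
    out: dict[str, float] = {}
    for name in sorted(texture_maps):
        tmap = texture_maps[name]
        feats = texture_scalar(tmap.values, config)
        for feat in TEXTURE_FEATURES:
            out[f"{tmap.name}-{feat}"] = feats[feat]
    return out


# ---------------------------------------------------------------------------
# feature-vector assembly
# ---------------------------------------------------------------------------


def feature_names() -> list[str]:
    """Canonical order of the 105 feature names."""
    names = list(QUS_BASES)
    for base in QUS_BASES:
        for t1 in TEXTURE_FEATURES:
            names.append(f"{base}-{t1}")
    for base in QUS_BASES:
        for t1 in TEXTURE_FEATURES:
            for t2 in TEXTURE_FEATURES:
                names.append(f"{base}-{t1}-{t2}")
    return names


def parse_feature_name(name: str) -> tuple[str, str | None, str | None]:
    """Split BASE[-TEX1[-TEX2]] and validate the grammar."""
    parts = name.split("-")
    if not 1 <= len(parts) <= 3:
        raise ValueError(f"malformed feature name {name!r}")
    base, *texes = parts
    if base not in QUS_BASES:
        raise ValueError(f"unknown QUS base in {name!r}")
    for t in texes:
        if t not in TEXTURE_FEATURES:
            raise ValueError(f"unknown texture feature in {name!r}")
    t1 = texes[0] if len(texes) >= 1 else None
    t2 = texes[1] if len(texes) >= 2 else None
    return base, t1, t2


@dataclass
class FeatureVector:
    """The 105 named scalars of one tumor, in canonical order."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical = feature_names()
        for name in self.values:
            parse_feature_name(name)
        if sorted(self.values) != sorted(canonical):
            missing = set(canonical) - set(self.values)
            extra = set(self.values) - set(canonical)
            raise ValueError(
                f"feature vector must have exactly the 105 canonical entries; "
                f"missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )
        self.values = {name: float(self.values[name]) for name in canonical}

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def group(self, which: str) -> dict[str, float]:
        """'qus' (5), 'tex1' (20) or 'tex2' (80) subset."""
        depth = {"qus": 1, "tex1": 2, "tex2": 3}[which]
        return {
            k: v for k, v in self.values.items() if len(k.split("-")) == depth
        }


def assemble_feature_vector(
    qus_means: dict[str, float],
    tex1: dict[str, float],
    tex2: dict[str, float],
) -> FeatureVector:
    """Merge the three groups (5 + 20 + 80) into one validated vector."""
    merged: dict[str, float] = {}
    for group in (qus_means, tex1, tex2):
        for name, value in group.items():
            if name in merged:
                raise ValueError(f"duplicate feature name {name!r}")
            merged[name] = value
    return FeatureVector(merged)
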
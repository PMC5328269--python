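"""Per-block color/texture feature extraction from 4-band rasters.

A scene is a set of four co-registered reflectance channels (red, green,
blue, near-infrared) in [0, 1].  Classification operates not on pixels but
on 8x8-pixel blocks: each block is summarized by a vector of statistical
moments, co-occurrence (Haralick) texture features, mid-frequency DCT
coefficients, and vegetation indices, computed on the derived hue,
saturation, intensity and NIR channels.  The default catalog has 112 named
features; its composition is documented in :func:`default_catalog`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.fft import dctn
from skimage.feature import graycomatrix

__all__ = [
    "RasterScene",
    "FeatureTable",
    "rgb_to_hsi",
    "block_partition",
    "vegetation_indices",
    "channel_moments",
    "cooccurrence_matrix",
    "haralick_features",
    "dct_features",
    "default_catalog",
    "extract_feature_table",
    "read_scene",
    "write_scene",
]

#: guard for near-zero denominators in band-ratio indices
EPS = 1e-6

CHANNELS = ("hue", "saturation", "intensity", "nir")

MOMENT_FEATURES = ("mean", "std", "skewness", "kurtosis", "min", "max")
CCM_FEATURES = (
    "entropy",
    "asm",
    "energy",
    "autocorrelation",
    "variance",
    "sum_entropy",
    "homogeneity",
    "contrast",
    "correlation",
)
INDEX_FEATURES = ("ndvi", "sr", "evi", "arvi")

#: mid-frequency DCT band: (u, v) with 2 <= u+v <= 4 (DC and near-DC excluded)
DCT_MID_BAND = tuple(
    (u, v) for u in range(8) for v in range(8) if 2 <= u + v <= 4
)


@dataclass
class RasterScene:
    """Four co-registered 2-D reflectance channels plus an optional label mask.

    All channels are float arrays with values in [0, 1] and identical shape.
    ``labels``, when present, is a binary {0, 1} array marking the positive
    class (tree cover) per pixel.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    nir: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {c.shape for c in (self.red, self.green, self.blue, self.nir)}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name in ("red", "green", "blue", "nir"):
            ch = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"non-finite values in channel {name!r}")
            if ch.min() < 0 or ch.max() > 1:
                raise ValueError(f"channel {name!r} outside [0, 1]")
            setattr(self, name, ch)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != self.red.shape:
                raise ValueError("label mask shape differs from channels")
            self.labels = (lab > 0).astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass
class FeatureTable:
    """Per-block feature vectors with optional +/-1 labels.

    ``features`` holds one row per block (columns in catalog order);
    ``labels`` is None for unlabeled prediction tables.
    """

    features: pd.DataFrame
    labels: np.ndarray | None = None
    block_coords: np.ndarray | None = None  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("missing feature values")
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if not np.isin(self.labels, (-1, 1)).all():
                raise ValueError("labels must be +/-1")
            if len(self.labels) != len(self.features):
                raise ValueError("label / feature length mismatch")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        df = self.features.copy()
        if self.block_coords is not None:
            df.insert(0, "block_row", self.block_coords[:, 0])
            df.insert(1, "block_col", self.block_coords[:, 1])
        else:
            df.insert(0, "block_row", np.arange(len(df)))
            df.insert(1, "block_col", 0)
        lab = "" if self.labels is None else self.labels
        df.insert(2, "label", lab)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        coords = df[["block_row", "block_col"]].to_numpy(dtype=int)
        labels = None
        if df["label"].notna().all():
            labels = df["label"].to_numpy(dtype=int)
        feats = df.drop(columns=["block_row", "block_col", "label"])
        return cls(features=feats, labels=labels, block_coords=coords)


# ---------------------------------------------------------------------------
# color space


def rgb_to_hsi(scene: RasterScene) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert RGB channels to hue, saturation, intensity.

    Uses the classic HSI model of color image processing: I = (R+G+B)/3,
    S = 1 - 3 min(R,G,B)/(R+G+B), and hue from the arccos chromaticity
    formula, normalized to [0, 1).  Achromatic pixels (zero chroma) get
    hue 0 and saturation 0 by convention so that downstream texture
    statistics are always defined.
    """
    r, g, b = scene.red, scene.green, scene.blue
    total = r + g + b
    intensity = total / 3.0

    minc = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * minc / np.where(total > 0, total, 1.0), 0.0)
    saturation = np.clip(saturation, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den < 1e-12
    cosang = np.clip(np.where(achromatic, 1.0, num / np.where(achromatic, 1.0, den)), -1.0, 1.0)
    theta = np.arccos(cosang) / (2.0 * np.pi)  # in [0, 1/2]
    hue = np.where(b > g, 1.0 - theta, theta)
    hue = np.where(achromatic, 0.0, hue)
    hue = np.where(hue >= 1.0, 0.0, hue)
    return hue, saturation, intensity


# ---------------------------------------------------------------------------
# blocks


def block_partition(
    scene: RasterScene, block_size: int = 8
) -> list[tuple[tuple[int, int], dict[str, np.ndarray], int | None]]:
    """Tile the scene into non-overlapping ``block_size`` squares.

    Returns a list of ``((block_row, block_col), channels, label)`` where
    ``channels`` maps hue/saturation/intensity/nir to the block sub-arrays.
    Blocks truncated at the right/bottom margins are dropped.  The block
    label is the majority vote of the pixel labels (ties break positive);
    None when the scene is unlabeled.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    h, w = scene.shape
    nrows, ncols = h // block_size, w // block_size
    if nrows == 0 or ncols == 0:
        warnings.warn("scene smaller than one block; empty partition")
        return []
    hue, sat, inten = rgb_to_hsi(scene)
    planes = {"hue": hue, "saturation": sat, "intensity": inten, "nir": scene.nir}
    out = []
    half = block_size * block_size / 2.0
    for br in range(nrows):
        r0 = br * block_size
        for bc in range(ncols):
            c0 = bc * block_size
            sl = (slice(r0, r0 + block_size), slice(c0, c0 + block_size))
            chans = {k: v[sl] for k, v in planes.items()}
            label = None
            if scene.labels is not None:
                npos = int(scene.labels[sl].sum())
                label = 1 if npos >= half else -1  # tie -> positive
            out.append(((br, bc), chans, label))
    return out


# ---------------------------------------------------------------------------
# vegetation indices


def _guard(den: np.ndarray | float) -> np.ndarray | float:
    """Clamp a denominator away from zero, preserving sign (0 -> +eps)."""
    s = np.where(np.asarray(den) < 0, -1.0, 1.0)
    return s * np.maximum(np.abs(den), EPS)


def vegetation_indices(red: float, blue: float, nir: float) -> dict[str, float]:
    """Band-ratio vegetation indices from block mean reflectances.

    NDVI = (NIR-R)/(NIR+R); SR = NIR/R;
    EVI = 2.5 (NIR-R)/(NIR + 6R - 7.5B + 1)  (G=2.5, C1=6, C2=7.5, L=1);
    ARVI = (NIR - (2R - B))/(NIR + 2R - B)   (gamma = 1).
    Denominators are clamped to magnitude >= 1e-6 so values are always finite.
    """
    ndvi = (nir - red) / _guard(nir + red)
    sr = nir / _guard(red)
    evi = 2.5 * (nir - red) / _guard(nir + 6.0 * red - 7.5 * blue + 1.0)
    arvi = (nir - (2.0 * red - blue)) / _guard(nir + 2.0 * red - blue)
    return {"ndvi": float(ndvi), "sr": float(sr), "evi": float(evi), "arvi": float(arvi)}


# ---------------------------------------------------------------------------
# moments


def channel_moments(block: np.ndarray) -> dict[str, float]:
    """Population moments of a channel block (plus min/max).

    Skewness and kurtosis (excess) of a constant block are defined as 0.
    """
    x = np.asarray(block, dtype=float).ravel()
    mean = float(x.mean())
    var = float(x.var())  # population
    std = float(np.sqrt(var))
    if std < 1e-12:
        skew = kurt = 0.0
    else:
        z = (x - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    return {
        "mean": mean,
        "std": std,
        "skewness": skew,
        "kurtosis": kurt,
        "min": float(x.min()),
        "max": float(x.max()),
    }


# ---------------------------------------------------------------------------
# co-occurrence texture

#: distance-1 offsets in 4 directions (E, NE, N, NW), accumulated symmetrically
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def quantize_block(block: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize a block's value *range* into ``levels`` bins."""
    x = np.asarray(block, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros(x.shape, dtype=np.uint8)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1).astype(np.uint8)


def cooccurrence_matrix(
    block: np.ndarray,
    levels: int = 8,
    offsets: Sequence[tuple[int, int]] = DEFAULT_OFFSETS,
) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix of a block.

    The block's value range is quantized uniformly into ``levels`` bins and
    pair frequencies are accumulated symmetrically over all offsets; entries
    sum to 1.  A constant block puts all mass on one diagonal entry.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    offsets = list(offsets)
    if not offsets:
        raise ValueError("offsets must be non-empty")
    q = quantize_block(block, levels)
    # graycomatrix angles: offset (dr, dc) = (-d sin a, d cos a)
    angles = [np.arctan2(-dr, dc) for dr, dc in offsets]
    glcm = graycomatrix(q, distances=[1], angles=angles, levels=levels, symmetric=True)
    mat = glcm[:, :, 0, :].sum(axis=-1).astype(float)
    total = mat.sum()
    if total == 0:  # degenerate block smaller than any offset reach
        mat[0, 0] = 1.0
        return mat
    return mat / total


def haralick_features(ccm: np.ndarray) -> dict[str, float]:
    """Haralick statistics of a normalized co-occurrence matrix.

    Levels are indexed 1..L for the weighted statistics.  Entropies are in
    bits with 0*log(0) := 0; correlation of a zero-variance matrix is 0.
    """
    p = np.asarray(ccm, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("ccm must be a normalized non-negative matrix")
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    asm = float((p**2).sum())
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    variance = float((((ii - mu) ** 2) * p).sum())

    # p_{x+y}(k), k = 2..2L
    k = (ii + jj).astype(int)
    pxy = np.bincount(k.ravel(), weights=p.ravel(), minlength=2 * L + 1)[2:]
    nzs = pxy[pxy > 0]
    sum_entropy = float(-(nzs * np.log2(nzs)).sum())

    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    autocorr = float((ii * jj * p).sum())

    py = p.sum(axis=0)
    mux, muy = mu, float((i * py).sum())
    sx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - muy) ** 2 * py).sum()))
    if sx < 1e-12 or sy < 1e-12:
        correlation = 0.0
    else:
        correlation = float((autocorr - mux * muy) / (sx * sy))

    return {
        "entropy": entropy,
        "asm": asm,
        "energy": float(np.sqrt(asm)),
        "autocorrelation": autocorr,
        "variance": variance,
        "sum_entropy": sum_entropy,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
    }


# ---------------------------------------------------------------------------
# DCT


def dct_features(
    block: np.ndarray, selection: Sequence[tuple[int, int]] = DCT_MID_BAND
) -> np.ndarray:
    """Selected coefficients of the orthonormal type-II 2-D DCT of a block."""
    selection = list(selection)
    if not selection:
        raise ValueError("empty DCT coefficient selection")
    coeffs = dctn(np.asarray(block, dtype=float), type=2, norm="ortho")
    return np.array([coeffs[u, v] for u, v in selection])


# ---------------------------------------------------------------------------
# catalog & table extraction


def default_catalog() -> list[str]:
    """The default 112-feature catalog.

    Composition (a documented reconstruction): per channel in {hue,
    saturation, intensity, nir}: 6 statistics (mean, std, skewness,
    kurtosis, min, max), 9 co-occurrence features (entropy, ASM, energy,
    autocorrelation, variance, sum entropy, homogeneity, contrast,
    correlation), and 12 mid-frequency DCT coefficients (2 <= u+v <= 4);
    4 x 27 = 108, plus the 4 vegetation indices (NDVI, SR, EVI, ARVI).
    """
    names: list[str] = []
    for ch in CHANNELS:
        names += [f"{ch}_{m}" for m in MOMENT_FEATURES]
        names += [f"{ch}_ccm_{h}" for h in CCM_FEATURES]
        names += [f"{ch}_dct_{u}_{v}" for u, v in DCT_MID_BAND]
    names += list(INDEX_FEATURES)
    return names


def _parse_catalog_entry(name: str) -> tuple[str, str, tuple]:
    """Split a feature name into (channel, kind, args); '' channel for indices."""
    if name in INDEX_FEATURES:
        return "", "index", (name,)
    parts = name.split("_")
    ch = parts[0]
    if ch not in CHANNELS:
        raise ValueError(f"unknown channel in catalog entry {name!r}")
    rest = parts[1:]
    if rest and rest[0] == "ccm":
        feat = "_".join(rest[1:])
        if feat not in CCM_FEATURES:
            raise ValueError(f"unknown co-occurrence feature in {name!r}")
        return ch, "ccm", (feat,)
    if rest and rest[0] == "dct":
        if len(rest) != 3:
            raise ValueError(f"malformed DCT catalog entry {name!r}")
        return ch, "dct", (int(rest[1]), int(rest[2]))
    feat = "_".join(rest)
    if feat not in MOMENT_FEATURES:
        raise ValueError(f"unknown feature in catalog entry {name!r}")
    return ch, "moment", (feat,)


def extract_block_features(
    chans: dict[str, np.ndarray],
    catalog: Sequence[str],
    red_mean: float,
    blue_mean: float,
    levels: int = 8,
) -> np.ndarray:
    """Feature vector of one block, in catalog order."""
    parsed = [_parse_catalog_entry(n) for n in catalog]
    need_moments = {ch for ch, kind, _ in parsed if kind == "moment"}
    need_ccm = {ch for ch, kind, _ in parsed if kind == "ccm"}
    need_dct = {ch for ch, kind, _ in parsed if kind == "dct"}
    moments = {ch: channel_moments(chans[ch]) for ch in need_moments}
    haralick = {
        ch: haralick_features(cooccurrence_matrix(chans[ch], levels=levels))
        for ch in need_ccm
    }
    dcts = {
        ch: dctn(np.asarray(chans[ch], dtype=float), type=2, norm="ortho")
        for ch in need_dct
    }
    indices = None
    if any(kind == "index" for _, kind, _ in parsed):
        indices = vegetation_indices(red_mean, blue_mean, float(chans["nir"].mean()))
    out = np.empty(len(parsed))
    for pos, (ch, kind, args) in enumerate(parsed):
        if kind == "moment":
            out[pos] = moments[ch][args[0]]
        elif kind == "ccm":
            out[pos] = haralick[ch][args[0]]
        elif kind == "dct":
            out[pos] = dcts[ch][args[0], args[1]]
        else:
            out[pos] = indices[args[0]]
    return out


def extract_feature_table(
    scene: RasterScene,
    catalog: Sequence[str] | None = None,
    block_size: int = 8,
    levels: int = 8,
) -> FeatureTable:
    """Extract the per-block feature table of a scene.

    One row per complete block, columns in catalog order.  Deterministic:
    identical scene + catalog produce a bit-identical table.
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    for name in catalog:  # validate up front, naming the bad entry
        _parse_catalog_entry(name)
    blocks = block_partition(scene, block_size=block_size)
    # red/blue block means for vegetation indices come from the raw bands
    rows, coords, labels = [], [], []
    bs = block_size
    for (br, bc), chans, label in blocks:
        sl = (slice(br * bs, (br + 1) * bs), slice(bc * bs, (bc + 1) * bs))
        rows.append(
            extract_block_features(
                chans,
                catalog,
                red_mean=float(scene.red[sl].mean()),
                blue_mean=float(scene.blue[sl].mean()),
                levels=levels,
            )
        )
        coords.append((br, bc))
        labels.append(label)
    if not rows:
        feats = pd.DataFrame(np.empty((0, len(catalog))), columns=catalog)
        return FeatureTable(features=feats, block_coords=np.empty((0, 2), dtype=int))
    feats = pd.DataFrame(np.vstack(rows), columns=catalog)
    lab = None if labels[0] is None else np.array(labels, dtype=int)
    return FeatureTable(features=feats, labels=lab, block_coords=np.array(coords))


# ---------------------------------------------------------------------------
# raster I/O (plain multiband TIFF / PNG + NIR sidecar; 8- or 16-bit)


def _normalize_band(band: np.ndarray) -> np.ndarray:
    band = np.asarray(band)
    if np.issubdtype(band.dtype, np.integer):
        scale = 255.0 if band.dtype.itemsize == 1 else 65535.0
        band = band.astype(float) / scale
    else:
        band = band.astype(float)
    if not np.all(np.isfinite(band)):
        raise ValueError("NaN/Inf pixels in raster band")
    return np.clip(band, 0.0, 1.0)


def read_scene(
    path, nir_path=None, labels_path=None
) -> RasterScene:
    """Read a 4-band TIFF, or an RGB image plus a single-band NIR sidecar."""
    import tifffile

    p = str(path)
    if p.lower().endswith((".tif", ".tiff")) and nir_path is None:
        arr = tifffile.imread(p)
        if arr.ndim != 3:
            raise ValueError("expected a multiband raster")
        if arr.shape[0] in (3, 4) and arr.shape[0] < arr.shape[-1]:
            arr = np.moveaxis(arr, 0, -1)
        if arr.shape[-1] < 4:
            raise ValueError("4 bands (R,G,B,NIR) required")
        bands = [_normalize_band(arr[..., i]) for i in range(4)]
    else:
        rgb = np.asarray(Image.open(p))
        if rgb.ndim != 3 or rgb.shape[-1] < 3:
            raise ValueError("RGB image required")
        if nir_path is None:
            raise ValueError("NIR sidecar required for RGB input")
        nir = np.asarray(Image.open(str(nir_path)))
        if nir.ndim == 3:
            nir = nir[..., 0]
        bands = [_normalize_band(rgb[..., i]) for i in range(3)]
        bands.append(_normalize_band(nir))
    labels = None
    if labels_path is not None:
        lp = str(labels_path)
        if lp.lower().endswith((".tif", ".tiff")):
            lab = tifffile.imread(lp)
        else:
            lab = np.asarray(Image.open(lp))
        if lab.ndim == 3:
            lab = lab[..., 0]
        labels = (lab > 0).astype(np.int8)
    return RasterScene(*bands, labels=labels)


def write_scene(scene: RasterScene, path, mask_path=None) -> None:
    """Write a scene as a 4-band uint8 TIFF (and the mask as 0/255)."""
    import tifffile

    stack = np.stack(
        [scene.red, scene.green, scene.blue, scene.nir], axis=-1
    )
    tifffile.imwrite(str(path), np.round(stack * 255).astype(np.uint8))
    if mask_path is not None:
        if scene.labels is None:
            raise ValueError("scene has no label mask")
        tifffile.imwrite(str(mask_path), scene.labels.astype(np.uint8) * 255)
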
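"""The 80-descriptor feature vector of a segmented cell.

16 shape descriptors of the nucleus/cytoplasm geometry, 54 texture
descriptors (13 grey-level co-occurrence statistics at 0/45/90/135
degrees plus skewness and kurtosis of the nucleus L* histogram), and 10
colour descriptors from the a*/b* chroma planes.  The schema order is
frozen: shape block, texture block, colour block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import feature as skfeature
from skimage import measure

from sdmclust.imaging import CYTOPLASM, NUCLEUS, LabImage, rgb_to_cielab

EPS = 1e-9

SHAPE_NAMES = [
    "shape.cytoplasm_area",
    "shape.nucleus_area",
    "shape.nucleus_cytoplasm_ratio",
    "shape.length_diameter_ratio",
    "shape.major_axis_length",
    "shape.orientation",
    "shape.filled_area",
    "shape.perimeter",
    "shape.solidity",
    "shape.eccentricity",
    "shape.minor_axis_length",
    "shape.convex_area",
    "shape.form_factor",
    "shape.compactness_1",
    "shape.compactness_2",
    "shape.roundness",
]

GLCM_DESCRIPTORS = [
    "correlation",
    "sum_variance",
    "idm_normalized",
    "sum_average",
    "contrast",
    "difference_variance",
    "entropy",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "homogeneity",
    "id_normalized",
]

ANGLE_NAMES = ["deg0", "deg45", "deg90", "deg135"]
ANGLES = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]

TEXTURE_NAMES = [f"glcm.{d}.{a}" for d in GLCM_DESCRIPTORS for a in ANGLE_NAMES] + [
    "stat.skewness",
    "stat.kurtosis",
]

COLOUR_NAMES = [
    "colour.nucleus_a_mean",
    "colour.nucleus_a_sd",
    "colour.nucleus_b_mean",
    "colour.nucleus_b_sd",
    "colour.cytoplasm_a_mean",
    "colour.cytoplasm_a_sd",
    "colour.cytoplasm_b_mean",
    "colour.cytoplasm_b_sd",
    "colour.cyto_over_nuc_a_mean",
    "colour.cyto_over_nuc_b_mean",
]

ALL_FEATURE_NAMES = SHAPE_NAMES + TEXTURE_NAMES + COLOUR_NAMES


@dataclass
class GlcmConfig:
    """Co-occurrence settings: 16 grey levels, offset 1, the four standard
    angles, symmetric accumulation, matrices normalised to sum 1."""

    n_levels: int = 16
    distance: int = 1
    symmetric: bool = True
    normalised: bool = True


@dataclass
class FeatureVector:
    names: list[str] = field(default_factory=lambda: list(ALL_FEATURE_NAMES))
    values: np.ndarray = None
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def shape_features(mask: np.ndarray) -> dict[str, float]:
    """16 geometric descriptors; the region properties are computed on the
    nucleus, with areas in pixels.

    form factor = 4*pi*A/P^2; the two compactness variants are P^2/(4*pi*A)
    and P^2/A; roundness = 4*A/(pi*major_axis^2); length-to-diameter =
    major_axis / equivalent circular diameter.
    """
    mask = np.asarray(mask)
    nucleus = (mask == NUCLEUS).astype(np.uint8)
    area_n = int(nucleus.sum())
    area_c = int((mask == CYTOPLASM).sum())
    if area_n == 0:
        raise ValueError("empty nucleus region")
    props = measure.regionprops(nucleus)[0]
    A = float(props.area)
    # Crofton (4-direction) perimeter: far less rasterisation bias on smooth
    # outlines than pixel-edge counting, so a disc's form factor sits near 1
    P = float(props.perimeter_crofton)
    major = float(props.axis_major_length)
    eq_diam = float(np.sqrt(4.0 * A / np.pi))
    out = {
        "shape.cytoplasm_area": float(area_c),
        "shape.nucleus_area": float(area_n),
        "shape.nucleus_cytoplasm_ratio": area_n / (area_c + EPS),
        "shape.length_diameter_ratio": major / (eq_diam + EPS),
        "shape.major_axis_length": major,
        "shape.orientation": float(props.orientation),
        "shape.filled_area": float(props.area_filled),
        "shape.perimeter": P,
        "shape.solidity": float(props.solidity),
        "shape.eccentricity": float(props.eccentricity),
        "shape.minor_axis_length": float(props.axis_minor_length),
        "shape.convex_area": float(props.area_convex),
        "shape.form_factor": 4.0 * np.pi * A / (P ** 2 + EPS),
        "shape.compactness_1": P ** 2 / (4.0 * np.pi * A),
        "shape.compactness_2": P ** 2 / A,
        "shape.roundness": 4.0 * A / (np.pi * major ** 2 + EPS),
    }
    return out


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def quantise(gray: np.ndarray, mask: np.ndarray, n_levels: int = 16) -> np.ndarray:
    """Quantise ``gray`` inside ``mask`` to integer levels 0..n_levels-1
    (min-max over the masked pixels; constant regions map to level 0)."""
    gray = np.asarray(gray, dtype=np.float64)
    vals = gray[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(gray.shape, dtype=np.uint8)
    if hi > lo:
        scaled = (gray - lo) / (hi - lo) * n_levels
        q = np.clip(np.floor(scaled), 0, n_levels - 1).astype(np.uint8)
    return q


def glcm_matrix(gray_q: np.ndarray, mask: np.ndarray, cfg: GlcmConfig | None = None
                ) -> np.ndarray:
    """Masked grey-level co-occurrence matrices, one per angle.

    Only pixel pairs with both members inside ``mask`` are counted (an
    out-of-region sentinel level is appended and its row/column dropped).
    Returns an (n_levels, n_levels, 4) array; each angle slice is
    symmetric and sums to 1.
    """
    cfg = cfg or GlcmConfig()
    G = cfg.n_levels
    img = np.where(mask, gray_q, G).astype(np.uint8)
    P = skfeature.graycomatrix(img, [cfg.distance], ANGLES, levels=G + 1,
                               symmetric=cfg.symmetric, normed=False)
    P = P[:G, :G, 0, :].astype(np.float64)  # drop sentinel row/column
    out = np.empty_like(P)
    for k, aname in enumerate(ANGLE_NAMES):
        total = P[:, :, k].sum()
        if total < 2:
            raise ValueError(f"fewer than 2 in-mask pixel pairs at angle {aname}")
        out[:, :, k] = P[:, :, k] / total if cfg.normalised else P[:, :, k]
    return out


def haralick_descriptors(p: np.ndarray) -> dict[str, float]:
    """The 13 co-occurrence statistics of one normalised matrix ``p``.

    Entropy uses log base 2 with 0*log0 := 0; the normalised inverse
    difference (moment) variants divide |i-j| (resp. (i-j)^2) by the
    number of grey levels (its square).  Correlation of a constant matrix
    (zero marginal variance) is defined as 1.
    """
    G = p.shape[0]
    i = np.arange(G, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # diagonal-sum and diagonal-difference marginals
    k_sum = np.arange(2 * G - 1, dtype=np.float64)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj).astype(int), p)
    k_diff = np.arange(G, dtype=np.float64)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)

    sum_avg = float(np.sum(k_sum * p_sum))
    diff_avg = float(np.sum(k_diff * p_diff))
    if sd_x * sd_y > 0:
        correlation = float(np.sum((ii - mu_x) * (jj - mu_y) * p) / (sd_x * sd_y))
    else:
        correlation = 1.0
    nz = p > 0
    return {
        "correlation": correlation,
        "sum_variance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "idm_normalized": float(np.sum(p / (1.0 + (ii - jj) ** 2 / G ** 2))),
        "sum_average": sum_avg,
        "contrast": float(np.sum((ii - jj) ** 2 * p)),
        "difference_variance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "cluster_prominence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "cluster_shade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "energy": float(np.sum(p ** 2)),
        "homogeneity": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "id_normalized": float(np.sum(p / (1.0 + np.abs(ii - jj) / G))),
    }


def texture_features(gray: np.ndarray, mask: np.ndarray, cfg: GlcmConfig | None = None
                     ) -> dict[str, float]:
    """54 texture descriptors of the nucleus: 13 co-occurrence statistics
    at each of the four angles, plus skewness and (plain, non-excess)
    kurtosis of the raw nucleus intensities."""
    cfg = cfg or GlcmConfig()
    region = np.asarray(mask) == NUCLEUS
    if not region.any():
        raise ValueError("empty nucleus region")
    q = quantise(gray, region, cfg.n_levels)
    mats = glcm_matrix(q, region, cfg)
    out: dict[str, float] = {}
    per_angle = [haralick_descriptors(mats[:, :, k]) for k in range(len(ANGLE_NAMES))]
    for d in GLCM_DESCRIPTORS:
        for k, aname in enumerate(ANGLE_NAMES):
            out[f"glcm.{d}.{aname}"] = per_angle[k][d]
    vals = np.asarray(gray, dtype=np.float64)[region]
    sd = vals.std()
    out["stat.skewness"] = float(stats.skew(vals)) if sd > 0 else 0.0
    out["stat.kurtosis"] = float(stats.kurtosis(vals, fisher=False)) if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# colour
# ---------------------------------------------------------------------------

def colour_features(lab: LabImage, mask: np.ndarray) -> dict[str, float]:
    """Mean and population SD of a*/b* per region, plus the
    cytoplasm-over-nucleus ratio of the a* and b* means."""
    mask = np.asarray(mask)
    nuc = mask == NUCLEUS
    cyt = mask == CYTOPLASM
    if not nuc.any() or not cyt.any():
        raise ValueError("colour features require non-empty nucleus and cytoplasm")
    out = {}
    for region, rname in ((nuc, "nucleus"), (cyt, "cytoplasm")):
        for plane, pname in ((lab.a, "a"), (lab.b, "b")):
            out[f"colour.{rname}_{pname}_mean"] = float(plane[region].mean())
            out[f"colour.{rname}_{pname}_sd"] = float(plane[region].std())
    for pname, plane in (("a", lab.a), ("b", lab.b)):
        num = plane[cyt].mean()
        den = plane[nuc].mean()
        out[f"colour.cyto_over_nuc_{pname}_mean"] = float(num / (den if abs(den) > EPS else EPS))
    return out


# ---------------------------------------------------------------------------
# assembly and scaling
# ---------------------------------------------------------------------------

def extract_all(image: np.ndarray | LabImage, mask: np.ndarray,
                glcm_cfg: GlcmConfig | None = None) -> FeatureVector:
    """Concatenate shape (16) + texture (54) + colour (10) in schema order.

    ``image`` may be an RGB array or precomputed CIELAB planes; texture is
    computed on the L* plane within the nucleus.
    """
    lab = image if isinstance(image, LabImage) else rgb_to_cielab(image)
    feats = {}
    feats.update(shape_features(mask))
    feats.update(texture_features(lab.L, mask, glcm_cfg))
    feats.update(colour_features(lab, mask))
    values = np.array([feats[n] for n in ALL_FEATURE_NAMES], dtype=np.float64)
    return FeatureVector(names=list(ALL_FEATURE_NAMES), values=values)


def scale_features(train: np.ndarray, apply: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Per-feature min-max mapping to [-1, 1], fit on the training rows only.

    Constant columns map to 0; held-out values outside the training range
    are kept unclipped (they may exceed [-1, 1]).
    """
    train = np.asarray(train, dtype=np.float64)
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    constant = span <= 0

    def transform(X):
        X = np.asarray(X, dtype=np.float64)
        out = np.zeros_like(X)
        nc = ~constant
        out[:, nc] = 2.0 * (X[:, nc] - lo[nc]) / span[nc] - 1.0
        return out

    scaler = {"min": lo, "max": hi, "constant": constant}
    return transform(train), (transform(apply) if apply is not None else None), scaler
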
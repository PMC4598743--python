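"""Synthetic single-cell fixtures with known ground truth.

Generates lymphocyte-like sub-images: a bright background, a
mid-luminance cytoplasm ring and a dark elliptical nucleus carrying
chromatin speckle texture, plus class-dependent differences (nucleus to
cytoplasm area ratio, chromatin density, stain chroma) between "normal"
and "blast" cells.  Every cell comes with an exact 3-label truth mask,
so segmentation, feature extraction and classification are testable
without any external image database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from sdmclust.imaging import BACKGROUND, CYTOPLASM, NUCLEUS, LabImage, cielab_to_rgb


@dataclass
class CellSpec:
    """Geometry, luminance and texture parameters of one synthetic cell.

    Luminance targets are mean L* values in [0, 100] and must satisfy
    ``L_background > L_cytoplasm > L_nucleus`` (nuclei are darker than
    cytoplasm, cytoplasm darker than the slide background).
    ``chromatin_contrast`` is the signed L* offset of speckle pixels and
    ``chromatin_density`` the fraction of nucleus pixels speckled.
    ``ab_*`` are (a*, b*) chroma pairs per region, emulating stain colour.
    """

    image_size: tuple[int, int] = (48, 48)
    nucleus_center: tuple[float, float] | None = None  # (row, col); None = image centre
    nucleus_axes: tuple[float, float] = (13.0, 11.0)  # semi-axes in pixels
    nucleus_orientation: float = 0.0  # radians, CCW from the column axis
    nucleus_lobulation: float = 0.0  # radial modulation amplitude in [0, 0.5)
    cytoplasm_margin: float = 9.0  # ring width in pixels; cells fill most of the crop
    L_background: float = 90.0
    L_cytoplasm: float = 60.0
    L_nucleus: float = 40.0
    chromatin_density: float = 0.15
    chromatin_contrast: float = -15.0
    ab_background: tuple[float, float] = (0.0, 0.0)
    ab_cytoplasm: tuple[float, float] = (8.0, -8.0)
    ab_nucleus: tuple[float, float] = (20.0, -18.0)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if not (self.L_background > self.L_cytoplasm > self.L_nucleus):
            raise ValueError("luminance ordering L_background > L_cytoplasm > L_nucleus violated")
        if not 0.0 <= self.chromatin_density <= 1.0:
            raise ValueError("chromatin_density must lie in [0, 1]")
        outer = max(self.nucleus_axes) + self.cytoplasm_margin
        if 2 * outer >= min(h, w):
            raise ValueError(
                f"cell (outer radius {outer:.1f}) does not fit inside a {h}x{w} image"
            )


@dataclass
class LabeledCell:
    """A generated cell: RGB image, exact CIELAB planes, truth mask, class."""

    image: np.ndarray  # H x W x 3 uint8
    lab: LabImage  # exact planes, before 8-bit quantisation
    truth: np.ndarray  # H x W uint8 in {0, 1, 2}
    klass: str  # "normal" | "blast"
    spec: CellSpec = field(repr=False, default=None)


def _ellipse_mask(shape, center, axes, orientation, lobulation=0.0):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    # rotate into the ellipse frame
    u = dc * np.cos(orientation) + dr * np.sin(orientation)
    v = -dc * np.sin(orientation) + dr * np.cos(orientation)
    if lobulation:
        theta = np.arctan2(v, u)
        scale = 1.0 + lobulation * np.cos(3 * theta)
    else:
        scale = 1.0
    return (u / (axes[0] * scale)) ** 2 + (v / (axes[1] * scale)) ** 2 <= 1.0


def generate_cell(spec: CellSpec, klass: str = "normal") -> LabeledCell:
    """Render one cell deterministically from ``spec`` (seeded RNG).

    The truth mask partitions every pixel; chromatin speckles are confined
    to the nucleus region and drawn as single-pixel L* offsets of
    ``chromatin_contrast`` at rate ``chromatin_density``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    center = spec.nucleus_center or ((h - 1) / 2.0, (w - 1) / 2.0)

    nucleus = _ellipse_mask((h, w), center, spec.nucleus_axes, spec.nucleus_orientation,
                            spec.nucleus_lobulation)
    outer_axes = (spec.nucleus_axes[0] + spec.cytoplasm_margin,
                  spec.nucleus_axes[1] + spec.cytoplasm_margin)
    membrane = _ellipse_mask((h, w), center, outer_axes, spec.nucleus_orientation)
    cytoplasm = membrane & ~nucleus

    truth = np.full((h, w), BACKGROUND, dtype=np.uint8)
    truth[cytoplasm] = CYTOPLASM
    truth[nucleus] = NUCLEUS

    L = np.full((h, w), spec.L_background, dtype=np.float64)
    L[cytoplasm] = spec.L_cytoplasm
    L[nucleus] = spec.L_nucleus
    if spec.chromatin_density > 0 and spec.chromatin_contrast != 0:
        speckle = nucleus & (rng.random((h, w)) < spec.chromatin_density)
        L[speckle] += spec.chromatin_contrast
    if spec.noise_sd > 0:
        L = L + rng.normal(0.0, spec.noise_sd, size=(h, w))
    L = np.clip(L, 0.0, 100.0)

    a = np.full((h, w), spec.ab_background[0])
    b = np.full((h, w), spec.ab_background[1])
    a[cytoplasm], b[cytoplasm] = spec.ab_cytoplasm
    a[nucleus], b[nucleus] = spec.ab_nucleus
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd / 2.0, size=(h, w))
        b = b + rng.normal(0.0, spec.noise_sd / 2.0, size=(h, w))

    lab = LabImage(L=L, a=a, b=b)
    return LabeledCell(image=cielab_to_rgb(lab), lab=lab, truth=truth, klass=klass, spec=spec)


def low_contrast_spec(seed: int = 0) -> CellSpec:
    """Preset emulating the hard cases: nucleus and cytoplasm L* nearly equal.

    The nucleus body sits only 3 L* units below the cytoplasm while sparse,
    strongly contrasted chromatin speckles form a separate dark mode.  A
    purely within-scatter objective tends to spend a cluster on that mode,
    leaving nucleus body and cytoplasm merged; the anatomical area
    constraints of the GA fitness forbid such degenerate nuclei.
    """
    return CellSpec(
        image_size=(48, 48),
        nucleus_axes=(9.0, 8.0),
        cytoplasm_margin=12.0,
        L_background=90.0,
        L_cytoplasm=62.0,
        L_nucleus=58.0,
        chromatin_density=0.45,
        chromatin_contrast=-20.0,
        noise_sd=2.0,
        seed=seed,
    )


def _class_spec(klass: str, difficulty: str, rng: np.random.Generator, seed: int) -> CellSpec:
    """Draw one per-cell spec; blast cells have larger nucleus:cytoplasm
    ratio, denser chromatin and a stronger basophilic (a*, b*) shift."""
    easy = difficulty == "easy"
    # whole-cell size drawn so the membrane fills most of the crop, as in
    # pre-cropped single-cell sub-images; classes differ in the fraction of
    # the cell the nucleus occupies
    outer_a = rng.uniform(20.5, 22.0)
    outer_b = outer_a * rng.uniform(0.92, 0.97)
    if klass == "normal":
        frac = rng.uniform(0.36, 0.44) if easy else rng.uniform(0.45, 0.52)
        density = rng.uniform(0.05, 0.15)
        L_nuc = rng.uniform(42.0, 48.0)
        ab_nuc = (rng.uniform(10.0, 14.0), rng.uniform(-12.0, -8.0))
    else:  # blast: big immature nucleus, thin cytoplasm rim, dense chromatin
        frac = rng.uniform(0.62, 0.72) if easy else rng.uniform(0.55, 0.62)
        density = rng.uniform(0.30, 0.45) if easy else rng.uniform(0.18, 0.30)
        L_nuc = rng.uniform(34.0, 40.0) if easy else rng.uniform(38.0, 44.0)
        ab_nuc = ((rng.uniform(22.0, 28.0), rng.uniform(-26.0, -20.0)) if easy
                  else (rng.uniform(16.0, 20.0), rng.uniform(-18.0, -13.0)))
    nuc_a = outer_a * frac
    nuc_b = outer_b * frac
    return CellSpec(
        image_size=(48, 48),
        nucleus_axes=(nuc_a, nuc_b),
        nucleus_orientation=rng.uniform(0.0, np.pi),
        cytoplasm_margin=outer_a - nuc_a,
        L_background=rng.uniform(86.0, 92.0),
        L_cytoplasm=rng.uniform(58.0, 64.0),
        L_nucleus=L_nuc,
        chromatin_density=density,
        chromatin_contrast=-15.0,
        ab_nucleus=ab_nuc,
        noise_sd=1.5,
        seed=seed,
    )


def generate_two_class_dataset(
    n_normal: int, n_blast: int, difficulty: str = "easy", seed: int = 0
) -> list[LabeledCell]:
    """Generate a stratified two-class dataset of single-cell images.

    ``difficulty="hard"`` narrows every inter-class gap (size ratio,
    chromatin density, nucleus luminance and chroma).
    """
    if n_normal < 1 or n_blast < 1:
        raise ValueError("need at least one cell per class")
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    root = np.random.SeedSequence(seed)
    cell_seeds = root.generate_state(n_normal + n_blast) >> 1  # keep below 2**31
    rng = np.random.default_rng(root.spawn(1)[0])
    cells = []
    for i in range(n_normal + n_blast):
        klass = "normal" if i < n_normal else "blast"
        spec = _class_spec(klass, difficulty, rng, int(cell_seeds[i]))
        cells.append(generate_cell(spec, klass=klass))
    return cells
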
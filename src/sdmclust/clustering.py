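"""Threshold clustering of the L* plane driven by discriminant measures.

A candidate segmentation is a pair of L* thresholds (t1, t2) splitting
pixels into three clusters (low / mid / high).  A real-coded genetic
algorithm searches threshold space; its fitness is a ratio of a
within-cluster scatter to a between-cluster scatter, minimised:

* SDM within-scatter ``S_W``: per cluster, the *maximum* squared
  deviation of any member from the cluster centre, summed over clusters
  — the worst-case spread rather than the average.
* SDM between-scatter ``S_B``: for every unordered cluster pair (j, l),
  the closest approach ``d_jl = min(min_x in j |x - c_l|^2,
  min_x in l |x - c_j|^2)`` — a boundary-to-centre separation — summed
  over the R(R-1)/2 pairs.

Baseline objectives under the identical GA: classic LDA scatter sums,
and two fuzzy compactness-and-separation (FCS) variants whose
memberships use the standard (non-negative) FCM formula.  Fuzzy C-means
itself is provided both as a clustering baseline and as the seed that
initialises one GA individual.

Anatomical constraints enter the fitness as a penalty: the nucleus and
cytoplasm areas must each be at least 10% of the other, and the
background must not outgrow the whole cell membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from sdmclust.imaging import BACKGROUND, CYTOPLASM, NUCLEUS

EPS = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdChromosome:
    """A GA individual: two ordered L* thresholds defining 3 clusters."""

    t1: float
    t2: float

    def __post_init__(self):
        if not self.t1 < self.t2:
            raise ValueError(f"thresholds must satisfy t1 < t2, got ({self.t1}, {self.t2})")


@dataclass
class Partition:
    """A hard 3-way partition of the L* plane.

    ``labels`` are cluster indices 0/1/2 ordered low/mid/high in L*;
    these are *cluster* indices, not anatomical roles — see
    :func:`assign_roles`.  ``centers`` holds NaN for empty clusters.
    """

    labels: np.ndarray
    samples: list[np.ndarray]
    centers: np.ndarray
    mutual_center: float

    @property
    def n_clusters(self) -> int:
        return len(self.samples)

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.size for s in self.samples])

    def nonempty(self) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.size > 0]


@dataclass
class ScatterSummary:
    """The two SDM scatter statistics of a partition."""

    S_W_sdm: float
    S_B_sdm: float
    per_pair: list[tuple[int, int, float]]
    penalty_applied: bool = False


@dataclass
class GaConfig:
    """GA settings; crossover/mutation rates, generation gap and the
    generation cap follow the standard configuration for this problem."""

    population_size: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    generation_gap: float = 0.9
    max_generations: int = 100
    mutation_sd: float = 5.0  # L* units, reflected into [0, 100]
    penalty: float | None = None  # None: 1e3 x median unpenalised fitness of init pop
    seed: int = 0
    objective: str = "SDM"  # SDM | LDA | FCS1 | FCS2
    sb_aggregate: str = "sum"  # sum | min over the pairwise separations

    def __post_init__(self):
        for r in (self.crossover_rate, self.mutation_rate, self.generation_gap):
            if not 0.0 <= r <= 1.0:
                raise ValueError("GA rates must lie in [0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.objective not in ("SDM", "LDA", "FCS1", "FCS2"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class FcmConfig:
    n_clusters: int = 3
    m: float = 2.0  # fuzzifier, >= 1
    tolerance: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.m < 1.0:
            raise ValueError("fuzzifier m must be >= 1")


# ---------------------------------------------------------------------------
# partitioning and scatter measures
# ---------------------------------------------------------------------------

def partition_by_thresholds(L: np.ndarray, chrom: ThresholdChromosome) -> Partition:
    """Hard-assign pixels: low if L < t1, mid if t1 <= L < t2, high if L >= t2."""
    L = np.asarray(L, dtype=np.float64)
    labels = np.digitize(L, [chrom.t1, chrom.t2])
    flat = L.ravel()
    lflat = labels.ravel()
    samples = [flat[lflat == j] for j in range(3)]
    centers = np.array([s.mean() if s.size else np.nan for s in samples])
    return Partition(labels=labels, samples=samples, centers=centers,
                     mutual_center=float(flat.mean()))


def partition_from_labels(L: np.ndarray, labels: np.ndarray, n_clusters: int = 3) -> Partition:
    """Build a :class:`Partition` from an arbitrary label image."""
    L = np.asarray(L, dtype=np.float64)
    flat, lflat = L.ravel(), np.asarray(labels).ravel()
    samples = [flat[lflat == j] for j in range(n_clusters)]
    centers = np.array([s.mean() if s.size else np.nan for s in samples])
    return Partition(labels=np.asarray(labels), samples=samples, centers=centers,
                     mutual_center=float(flat.mean()))


def within_cluster_scatter_sdm(part: Partition) -> float:
    """Sum over clusters of the maximum squared deviation from the centre.

    Empty and singleton clusters contribute 0.
    """
    if not part.nonempty():
        raise ValueError("all clusters are empty")
    total = 0.0
    for j in part.nonempty():
        s = part.samples[j]
        if s.size > 1:
            total += float(np.max((s - part.centers[j]) ** 2))
    return total


def between_cluster_scatter_sdm(part: Partition, aggregate: str = "sum"
                                ) -> tuple[float, list[tuple[int, int, float]]]:
    """Pairwise boundary separation: for each cluster pair, the smaller of
    the two minimum member-to-other-centre squared distances.

    Pairs with an empty member contribute 0.  ``aggregate`` selects sum
    (default, keeps all pair information) or min over the pairs.
    """
    nonempty = part.nonempty()
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty clusters for between-cluster scatter")
    R = part.n_clusters
    per_pair: list[tuple[int, int, float]] = []
    for j in range(R):
        for l in range(j + 1, R):
            if part.samples[j].size == 0 or part.samples[l].size == 0:
                per_pair.append((j, l, 0.0))
                continue
            d_jl = np.min((part.samples[j] - part.centers[l]) ** 2)
            d_lj = np.min((part.samples[l] - part.centers[j]) ** 2)
            per_pair.append((j, l, float(min(d_jl, d_lj))))
    values = [d for _, _, d in per_pair]
    if aggregate == "sum":
        agg = float(np.sum(values))
    elif aggregate == "min":
        agg = float(np.min([v for (j, l, v) in per_pair
                            if part.samples[j].size and part.samples[l].size]))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return agg, per_pair


def lda_objective(part: Partition) -> float:
    """Classic scatter ratio: sum of squared deviations within clusters over
    count-weighted squared centre-to-mutual-centre distances."""
    if not part.nonempty():
        raise ValueError("all clusters are empty")
    s_w = sum(float(np.sum((part.samples[j] - part.centers[j]) ** 2)) for j in part.nonempty())
    s_b = sum(part.samples[j].size * float((part.centers[j] - part.mutual_center) ** 2)
              for j in part.nonempty())
    return s_w / (s_b + EPS)


def fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Inverse-distance FCM memberships of samples ``x`` w.r.t. ``centers``.

    Rows sum to 1; a sample coinciding with a centre gets membership 1
    there.  Values always lie in [0, 1], which is the non-negativity
    repair used for the FCS objectives.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64)
    d2 = (x[:, None] - centers[None, :]) ** 2
    zero = d2 < 1e-24
    u = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        ratio = d2[rest][:, :, None] / d2[rest][:, None, :]
        u[rest] = 1.0 / np.sum(ratio ** (1.0 / (m - 1.0)), axis=2)
    return u


def fcs_objective(part: Partition, variant: str = "FCS1", m: float = 2.0,
                  eta: float | None = None, memberships: np.ndarray | None = None) -> float:
    """Fuzzy compactness-and-separation objective of a hard partition.

    Memberships are the non-negative FCM-style memberships of all pixels
    w.r.t. the partition centres.  Both variants return
    ``compactness - eta * separation`` (minimised): FCS1 measures
    separation by membership-weighted squared distances of *all samples*
    to the mutual centre; FCS2 by cluster-mass-weighted squared distances
    of the *fuzzy sample means* to the mutual centre.  ``eta`` defaults
    to 1/C with C clusters; ``eta = 0`` recovers plain FCM compactness.
    """
    if variant not in ("FCS1", "FCS2"):
        raise ValueError(f"unknown FCS variant {variant!r}")
    nonempty = part.nonempty()
    if not nonempty:
        raise ValueError("all clusters are empty")
    if eta is None:
        eta = 1.0 / part.n_clusters
    x = np.concatenate([part.samples[j] for j in range(part.n_clusters)])
    centers = np.where(np.isnan(part.centers), part.mutual_center, part.centers)
    if memberships is None:
        memberships = fcm_memberships(x, centers, m)
    um = memberships ** m
    d2 = (x[:, None] - centers[None, :]) ** 2
    compactness = float(np.sum(um * d2))
    cbar = part.mutual_center
    if variant == "FCS1":
        separation = float(np.sum(um * (x[:, None] - cbar) ** 2))
    else:
        mass = um.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            fuzzy_means = np.where(mass > 0, (um * x[:, None]).sum(axis=0) / np.maximum(mass, EPS),
                                   cbar)
        separation = float(np.sum(mass * (fuzzy_means - cbar) ** 2))
    return compactness - eta * separation


# ---------------------------------------------------------------------------
# fitness with anatomical constraints
# ---------------------------------------------------------------------------

def _role_areas(part: Partition) -> tuple[int, int, int]:
    """(nucleus, cytoplasm, background) pixel counts under centre-ordered roles."""
    order = _role_order(part)
    areas = {role: 0 for role in (NUCLEUS, CYTOPLASM, BACKGROUND)}
    for cluster, role in order.items():
        areas[role] += part.samples[cluster].size
    return areas[NUCLEUS], areas[CYTOPLASM], areas[BACKGROUND]


def constraints_violated(part: Partition) -> bool:
    """True if the nucleus/cytoplasm 10% mutual-area rule or the
    background-vs-membrane rule is broken."""
    a_n, a_c, a_b = _role_areas(part)
    if a_n < 0.10 * a_c or a_c < 0.10 * a_n:
        return True
    return a_b > a_n + a_c


def objective_value(part: Partition, objective: str = "SDM",
                    sb_aggregate: str = "sum") -> float:
    """Unpenalised scatter-ratio objective (minimised) for one partition."""
    if objective == "SDM":
        s_w = within_cluster_scatter_sdm(part)
        if len(part.nonempty()) < 2:
            return s_w / EPS
        s_b, _ = between_cluster_scatter_sdm(part, aggregate=sb_aggregate)
        return s_w / (s_b + EPS)
    if objective == "LDA":
        return lda_objective(part)
    if objective in ("FCS1", "FCS2"):
        return fcs_objective(part, variant=objective)
    raise ValueError(f"unknown objective {objective!r}")


def fitness(part: Partition, cfg: GaConfig, penalty: float | None = None) -> float:
    """GA fitness: objective ratio plus a constant penalty when the
    anatomical area constraints are violated."""
    base = objective_value(part, cfg.objective, cfg.sb_aggregate)
    pen = penalty if penalty is not None else (cfg.penalty if cfg.penalty is not None else 0.0)
    if constraints_violated(part):
        base += pen
    return base


# ---------------------------------------------------------------------------
# fuzzy c-means on the 1-D L* values
# ---------------------------------------------------------------------------

def fcm_cluster(L: np.ndarray, cfg: FcmConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray, Partition]:
    """Standard fuzzy C-means on the flattened L* values.

    Centres are initialised k-means++-style on the pixel values, then
    centre/membership updates alternate until the objective change drops
    below ``tolerance`` or ``max_iter``.  Returns sorted centres, the
    membership matrix (pixels x clusters, rows summing to 1), and the
    hard partition by maximum membership.
    """
    cfg = cfg or FcmConfig()
    L = np.asarray(L, dtype=np.float64)
    x = L.ravel()
    if np.unique(x).size < cfg.n_clusters:
        raise ValueError("fewer distinct L* values than clusters")
    rng = np.random.default_rng(cfg.seed)

    # k-means++ style seeding on scalar values
    centers = [x[rng.integers(x.size)]]
    for _ in range(cfg.n_clusters - 1):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        if d2.sum() == 0:
            centers.append(x[rng.integers(x.size)])
        else:
            centers.append(x[rng.choice(x.size, p=d2 / d2.sum())])
    centers = np.array(centers, dtype=np.float64)

    prev_obj = np.inf
    for _ in range(cfg.max_iter):
        u = fcm_memberships(x, centers, cfg.m)
        um = u ** cfg.m
        centers = (um * x[:, None]).sum(axis=0) / np.maximum(um.sum(axis=0), EPS)
        obj = float(np.sum(um * (x[:, None] - centers[None, :]) ** 2))
        if abs(prev_obj - obj) < cfg.tolerance:
            break
        prev_obj = obj

    order = np.argsort(centers)
    centers = centers[order]
    u = fcm_memberships(x, centers, cfg.m)
    labels = np.argmax(u, axis=1).reshape(L.shape)
    part = partition_from_labels(L, labels, cfg.n_clusters)
    return centers, u, part


def fcm_seed_chromosome(L: np.ndarray, cfg: FcmConfig | None = None) -> ThresholdChromosome:
    """Thresholds at midpoints between adjacent sorted FCM centres (the
    hard-assignment boundary of 1-D FCM as the fuzzifier approaches 1)."""
    centers, _, _ = fcm_cluster(L, cfg)
    mids = (centers[:-1] + centers[1:]) / 2.0
    t1, t2 = float(mids[0]), float(mids[-1])
    if not t1 < t2:
        t2 = t1 + 1e-6
    return ThresholdChromosome(t1, t2)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def _sus_select(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: n equally spaced pointers over the
    cumulative weight wheel, one random phase."""
    total = weights.sum()
    step = total / n
    start = rng.uniform(0.0, step)
    pointers = start + step * np.arange(n)
    cum = np.cumsum(weights)
    return np.minimum(np.searchsorted(cum, pointers), weights.size - 1)


def _repair(genes: np.ndarray) -> ThresholdChromosome:
    t1, t2 = float(min(genes)), float(max(genes))
    if not t1 < t2:
        t2 = t1 + 1e-6
    return ThresholdChromosome(t1, t2)


def _reflect(v: np.ndarray, lo: float = 0.0, hi: float = 100.0) -> np.ndarray:
    v = np.where(v < lo, 2 * lo - v, v)
    return np.where(v > hi, 2 * hi - v, v)


def ga_optimize(L: np.ndarray, cfg: GaConfig | None = None,
                fcm_cfg: FcmConfig | None = None
                ) -> tuple[ThresholdChromosome, Partition, list[float]]:
    """Evolve threshold pairs to minimise the configured scatter objective.

    The population starts uniform on [0, 100]^2 (sorted), with one
    individual replaced by the FCM-seeded chromosome.  Each generation:
    rank-weighted stochastic universal sampling, single-point crossover at
    the gene boundary (swapping t2) with probability ``crossover_rate``,
    Gaussian mutation (sd ``mutation_sd``, reflected into range) with
    probability ``mutation_rate`` per offspring, and an elitist ranked
    merge replacing ``generation_gap`` of the parents.  The best-ever
    fitness trace is monotone non-increasing.
    """
    cfg = cfg or GaConfig()
    L = np.asarray(L, dtype=np.float64)
    if np.unique(L).size < 3:
        raise ValueError("image must contain at least 3 distinct L* values")
    rng = np.random.default_rng(cfg.seed)
    k = cfg.population_size

    genes = np.sort(rng.uniform(0.0, 100.0, size=(k, 2)), axis=1)
    pop = [_repair(g) for g in genes]
    pop[0] = fcm_seed_chromosome(L, fcm_cfg or FcmConfig(seed=cfg.seed))

    parts = [partition_by_thresholds(L, c) for c in pop]
    if cfg.penalty is None:
        base = np.array([objective_value(p, cfg.objective, cfg.sb_aggregate) for p in parts])
        penalty = 1e3 * max(float(np.median(base)), EPS)
    else:
        penalty = cfg.penalty
    fits = np.array([fitness(p, cfg, penalty) for p in parts])

    best_i = int(np.argmin(fits))
    best_chrom, best_part, best_fit = pop[best_i], parts[best_i], float(fits[best_i])
    trace = [best_fit]

    n_off = max(2, int(round(cfg.generation_gap * k)))
    n_off += n_off % 2  # pair offspring
    for _ in range(cfg.max_generations):
        ranks = np.empty(k)
        ranks[np.argsort(fits)] = np.arange(k)  # 0 = best
        weights = (k - ranks).astype(np.float64)  # linear ranking, best heaviest
        chosen = _sus_select(weights, n_off, rng)
        rng.shuffle(chosen)

        offspring: list[ThresholdChromosome] = []
        for a, b in zip(chosen[0::2], chosen[1::2]):
            g1 = np.array([pop[a].t1, pop[a].t2])
            g2 = np.array([pop[b].t1, pop[b].t2])
            if rng.random() < cfg.crossover_rate:  # single point at the gene boundary
                g1[1], g2[1] = g2[1], g1[1]
            for g in (g1, g2):
                if rng.random() < cfg.mutation_rate:
                    g += rng.normal(0.0, cfg.mutation_sd, size=2)
                offspring.append(_repair(np.clip(_reflect(g), 0.0, 100.0)))

        off_parts = [partition_by_thresholds(L, c) for c in offspring]
        off_fits = np.array([fitness(p, cfg, penalty) for p in off_parts])

        merged = list(zip(fits, pop, parts)) + list(zip(off_fits, offspring, off_parts))
        merged.sort(key=lambda t: t[0])
        merged = merged[:k]
        fits = np.array([t[0] for t in merged])
        pop = [t[1] for t in merged]
        parts = [t[2] for t in merged]

        if fits[0] < best_fit:
            best_fit, best_chrom, best_part = float(fits[0]), pop[0], parts[0]
        trace.append(best_fit)
    return best_chrom, best_part, trace


# ---------------------------------------------------------------------------
# role assignment and morphological refinement
# ---------------------------------------------------------------------------

def _role_order(part: Partition) -> dict[int, int]:
    """Map cluster index -> anatomical role by centre luminance.

    Darkest non-empty cluster becomes the nucleus and the brightest the
    background; with only two non-empty clusters the cytoplasm is empty,
    with one everything is nucleus.  Exact centre ties are broken by
    making the larger cluster the background.
    """
    nonempty = part.nonempty()
    counts = part.counts
    order = sorted(nonempty, key=lambda j: (part.centers[j], counts[j]))
    roles: dict[int, int] = {}
    if len(order) == 3:
        assign = [NUCLEUS, CYTOPLASM, BACKGROUND]
    elif len(order) == 2:
        assign = [NUCLEUS, BACKGROUND]
    else:
        assign = [NUCLEUS]
    for cluster, role in zip(order, assign):
        roles[cluster] = role
    return roles


def assign_roles(part: Partition) -> np.ndarray:
    """Relabel a cluster partition into the anatomical 3-label mask
    (0=background, 1=cytoplasm, 2=nucleus)."""
    roles = _role_order(part)
    mask = np.full(part.labels.shape, BACKGROUND, dtype=np.uint8)
    for cluster, role in roles.items():
        mask[part.labels == cluster] = role
    return mask


def refine_morphology(mask: np.ndarray, min_size: int = 30) -> np.ndarray:
    """Clean "salt and pepper" artefacts in a 3-label mask.  Idempotent.

    For nucleus then cytoplasm: isolated components smaller than
    ``min_size`` (8-connected) are dissolved into their surrounding
    label first, then enclosed holes smaller than ``min_size``
    (4-connected interiors) are filled and the filled pixels removed
    from whichever class held them.  Dissolving specks before filling
    matters on noisy masks: a fragmented nucleus would otherwise be
    swallowed piecemeal as "holes" of the surrounding cytoplasm.  The
    size cap keeps anatomically real cavities — notably the nucleus,
    which is the cytoplasm ring's one big hole — intact.
    """
    mask = np.asarray(mask).astype(np.uint8).copy()
    for role in (NUCLEUS, CYTOPLASM):
        region = mask == role
        comp_labels, n_comp = ndimage.label(region, structure=np.ones((3, 3)))
        sizes = np.bincount(comp_labels.ravel())
        for ci in range(1, n_comp + 1):
            if sizes[ci] >= min_size:
                continue
            comp = comp_labels == ci
            ring = ndimage.binary_dilation(comp, structure=np.ones((3, 3))) & ~comp
            neighbours = mask[ring]
            neighbours = neighbours[neighbours != role]
            if neighbours.size:
                counts = np.bincount(neighbours, minlength=3)
                mask[comp] = int(np.argmax(counts))
            else:  # speck fills its whole neighbourhood; fall back to the other class
                mask[comp] = CYTOPLASM if role == NUCLEUS else NUCLEUS
    for role in (NUCLEUS, CYTOPLASM):
        region = mask == role
        filled = ndimage.binary_fill_holes(region)  # 4-connected background fill
        holes = filled & ~region
        if holes.any():
            # size-vet holes as 8-connected groups so a legitimate fragment of
            # the other class is not split into sub-threshold cavities
            hole_labels, n_holes = ndimage.label(holes, structure=np.ones((3, 3)))
            sizes = np.bincount(hole_labels.ravel())
            small = np.zeros(n_holes + 1, dtype=bool)
            small[1:] = sizes[1:] < min_size
            mask[small[hole_labels]] = role
    return mask


def scatter_summary(part: Partition, sb_aggregate: str = "sum") -> ScatterSummary:
    """Convenience bundle of both SDM scatter statistics."""
    s_w = within_cluster_scatter_sdm(part)
    s_b, per_pair = between_cluster_scatter_sdm(part, aggregate=sb_aggregate)
    return ScatterSummary(S_W_sdm=s_w, S_B_sdm=s_b, per_pair=per_pair,
                          penalty_applied=constraints_violated(part))


def segment(L: np.ndarray, cfg: GaConfig | None = None, morphology_refine: bool = True,
            min_size: int = 30) -> tuple[np.ndarray, ThresholdChromosome, list[float]]:
    """GA threshold clustering followed by role assignment and (optionally)
    morphological refinement.  Returns (mask, best thresholds, trace)."""
    cfg = cfg or GaConfig()
    chrom, part, trace = ga_optimize(L, cfg)
    mask = assign_roles(part)
    if morphology_refine:
        refined = refine_morphology(mask, min_size=min_size)
        # refinement must not erase an anatomical region outright
        if all((refined == r).any() for r in (NUCLEUS, CYTOPLASM)):
            mask = refined
    return mask, chrom, trace


def fcm_segment(L: np.ndarray, cfg: FcmConfig | None = None) -> np.ndarray:
    """Baseline: hard FCM partition relabelled into anatomical roles."""
    _, _, part = fcm_cluster(L, cfg)
    return assign_roles(part)
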
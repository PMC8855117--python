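"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* stochastic binary-branching astrocyte arbors, grouped into morphotype
  classes whose branching probability, depth and segment lengths differ so
  that pooled complexity and hull volume are multimodal;
* rectangular tissue sections with Poisson-scattered somata for exercising
  the stereological probe-grid sampling;
* diploid dinucleotide genotype tables drawn in Hardy–Weinberg proportions
  from a discretised normal on the 2 bp allele ladder, with per-species means
  that increase with migratory distance.

The branching model is deliberately simple — each segment ends in a
bifurcation with a fixed per-class probability until a maximum centrifugal
order — because its segment-count and terminal-order expectations have closed
forms, which the test-suite oracles exploit.  All randomness flows from one
root seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology_io import CellMorphology, validate_tree
from .popgen_assoc import DEFAULT_MIGRATORY_DISTANCES_KM

__all__ = [
    "MorphClassSpec",
    "SpeciesGenotypeSpec",
    "GenotypeSpec",
    "DEFAULT_THREE_CLASSES",
    "DEFAULT_FOUR_CLASSES",
    "default_genotype_spec",
    "flat_genotype_spec",
    "generate_astrocyte",
    "generate_population",
    "generate_section",
    "generate_genotypes",
]


@dataclass
class MorphClassSpec:
    """Growth parameters of one morphotype class."""

    class_id: str
    n_primary: int = 5                       # primary branches from the soma
    branch_prob: float = 0.5                 # per-segment bifurcation probability
    max_order: int = 4                       # deepest centrifugal order
    segment_length: tuple[float, float] = (25.0, 5.0)   # mean, sd (μm)
    wiggle: float = 0.15                     # direction noise per step (rad)
    base_radius: float = 1.5                 # primary-branch radius (μm)
    taper: float = 0.8                       # radius ratio per order step
    step: float = 5.0                        # node spacing along segments (μm)
    branch_angle: float = 0.6                # half-angle at bifurcations (rad)
    soma_radius: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.segment_length[0] <= 0:
            raise ValueError("segment length must be positive")
        if not 0.0 < self.taper <= 1.0:
            raise ValueError("taper must lie in (0, 1]")
        if self.n_primary < 1:
            raise ValueError("spec yields no primary branches")


# Default class ladders: shallow to deep arbors.  A high, shared bifurcation
# probability keeps the within-class spread of log-complexity small (branching
# is nearly saturated, so terminal counts concentrate), while maximum order,
# primary count and segment length step up between classes.  The resulting
# decimal-log complexity and hull-volume distributions are clearly multimodal
# with roughly evenly spaced, well-separated modes — the structure expected of
# mixed astrocyte morphotype populations.
DEFAULT_THREE_CLASSES = [
    MorphClassSpec("simple", n_primary=3, branch_prob=0.9, max_order=2,
                   segment_length=(20.0, 4.0), base_radius=1.2, step=5.0),
    MorphClassSpec("intermediate", n_primary=5, branch_prob=0.9, max_order=4,
                   segment_length=(40.0, 6.0), base_radius=1.5, step=8.0),
    MorphClassSpec("complex", n_primary=9, branch_prob=0.9, max_order=6,
                   segment_length=(65.0, 8.0), base_radius=1.8, step=11.0),
]

DEFAULT_FOUR_CLASSES = [
    DEFAULT_THREE_CLASSES[0],
    MorphClassSpec("intermediate", n_primary=5, branch_prob=0.9, max_order=3,
                   segment_length=(42.0, 6.0), base_radius=1.4, step=8.0),
    MorphClassSpec("rich", n_primary=5, branch_prob=0.9, max_order=5,
                   segment_length=(42.0, 6.0), base_radius=1.6, step=8.0),
    DEFAULT_THREE_CLASSES[2],
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    return _unit(rng.normal(size=3))


def _perp(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.normal(size=3)
    u -= np.dot(u, v) * v
    return _unit(u)


def generate_astrocyte(spec: MorphClassSpec, seed,
                       cell_id: str = "cell", species: str = "",
                       individual: str = "") -> CellMorphology:
    """Grow one stochastic arbor; the same seed reproduces the same cell.

    Primaries leave the soma in random directions; each segment integrates its
    direction with per-step wiggle noise and, below ``max_order``, ends in a
    bifurcation with probability ``branch_prob``.
    """
    rng = np.random.default_rng(seed)
    ids = [1]
    parents = [-1]
    xyz = [np.zeros(3)]
    radius = [spec.soma_radius]
    ttag = [1]
    next_id = 2

    def grow_segment(parent_id: int, pos: np.ndarray, direction: np.ndarray,
                     order: int) -> None:
        nonlocal next_id
        mean, sd = spec.segment_length
        length = max(rng.normal(mean, sd), spec.step)
        n_steps = max(int(round(length / spec.step)), 1)
        step_len = length / n_steps
        r = spec.base_radius * spec.taper ** (order - 1)
        d = direction.copy()
        p = pos.copy()
        last = parent_id
        for _ in range(n_steps):
            d = _unit(d + spec.wiggle * rng.normal(size=3))
            p = p + step_len * d
            ids.append(next_id)
            parents.append(last)
            xyz.append(p.copy())
            radius.append(r)
            ttag.append(7)
            last = next_id
            next_id += 1
        if order < spec.max_order and rng.random() < spec.branch_prob:
            u = _perp(d, rng)
            a = spec.branch_angle
            d1 = _unit(np.cos(a) * d + np.sin(a) * u)
            d2 = _unit(np.cos(a) * d - np.sin(a) * u)
            grow_segment(last, p, d1, order + 1)
            grow_segment(last, p, d2, order + 1)

    for _ in range(spec.n_primary):
        grow_segment(1, np.zeros(3), _random_unit(rng), 1)

    cell = CellMorphology(cell_id, np.array(ids), np.array(parents),
                          np.array(xyz), np.array(radius), np.array(ttag),
                          species=species, individual=individual)
    report = validate_tree(cell)
    assert report.ok, report.issues
    return cell


def generate_population(classes: list[MorphClassSpec], n_per_class: int,
                        species_assignment=None, seed=None
                        ) -> tuple[list[CellMorphology], np.ndarray, pd.DataFrame]:
    """Generate a labelled multi-class cell population.

    Returns (cells, true class labels 1..k, metadata table).  The optional
    ``species_assignment`` maps each cell index to a species name; by default
    all cells belong to one synthetic species.
    """
    if len(classes) < 2:
        raise ValueError("need >= 2 morphotype classes")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(classes) * n_per_class)
    cells: list[CellMorphology] = []
    labels = []
    meta_rows = []
    idx = 0
    for ci, spec in enumerate(classes, start=1):
        for j in range(n_per_class):
            cid = f"cell_{idx:04d}"
            sp = (species_assignment(idx) if callable(species_assignment)
                  else "synthetic") or "synthetic"
            cell = generate_astrocyte(spec, child_seeds[idx], cell_id=cid,
                                      species=sp, individual=f"ind_{ci}")
            cells.append(cell)
            labels.append(ci)
            meta_rows.append({"cell_id": cid, "species": sp,
                              "individual": f"ind_{ci}", "region": "HF",
                              "true_class": ci, "class_id": spec.class_id})
            idx += 1
    return cells, np.array(labels), pd.DataFrame(meta_rows)


def generate_section(region: tuple[float, float], soma_density: float,
                     seed=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Rectangular section contour with Poisson-scattered somata.

    ``region`` is (width, height) in μm; ``soma_density`` is somata per mm².
    """
    w, h = float(region[0]), float(region[1])
    if w <= 0 or h <= 0:
        raise ValueError("region must have positive area")
    if soma_density <= 0:
        raise ValueError("soma density must be positive")
    rng = np.random.default_rng(seed)
    area_mm2 = w * h / 1e6
    n = rng.poisson(soma_density * area_mm2)
    xs = rng.uniform(0, w, size=n)
    ys = rng.uniform(0, h, size=n)
    contour = np.array([[0, 0], [w, 0], [w, h], [0, h], [0, 0]], dtype=float)
    somata = pd.DataFrame({"cell_id": [f"soma_{i:05d}" for i in range(n)],
                           "x": xs, "y": ys})
    return contour, somata


@dataclass
class SpeciesGenotypeSpec:
    species: str
    n: int
    mean_bp: float
    sd_bp: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 individuals per species")


@dataclass
class GenotypeSpec:
    """Per-species allele-size distributions on a shared dinucleotide ladder."""

    species: list[SpeciesGenotypeSpec]
    ladder_min: int = 168
    ladder_max: int = 204
    ladder_step: int = 2
    distances_km: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIGRATORY_DISTANCES_KM))

    def ladder(self) -> np.ndarray:
        return np.arange(self.ladder_min, self.ladder_max + 1, self.ladder_step)


def default_genotype_spec(delta_bp: float = 4.0, sd_bp: float = 2.0) -> GenotypeSpec:
    """Four-species spec with mean allele size increasing with distance.

    Sample sizes match the study design (12-14 individuals per species);
    successive species in distance order differ by ``delta_bp`` in mean size.
    """
    order = sorted(DEFAULT_MIGRATORY_DISTANCES_KM,
                   key=DEFAULT_MIGRATORY_DISTANCES_KM.get)
    ns = {"Charadrius collaris": 14, "Charadrius semipalmatus": 13,
          "Calidris pusilla": 14, "Actitis macularius": 12}
    base = 172.0
    species = [SpeciesGenotypeSpec(sp, ns[sp], base + i * delta_bp, sd_bp)
               for i, sp in enumerate(order)]
    return GenotypeSpec(species=species)


def flat_genotype_spec(mean_bp: float = 178.0, sd_bp: float = 2.0) -> GenotypeSpec:
    """Null spec: identical allele-size distribution in every species."""
    spec = default_genotype_spec()
    for s in spec.species:
        s.mean_bp = mean_bp
        s.sd_bp = sd_bp
    return spec


def generate_genotypes(spec: GenotypeSpec, seed=None) -> pd.DataFrame:
    """Draw a diploid genotype table in Hardy–Weinberg proportions.

    Each individual's two alleles are independent draws from a discretised
    normal on the 2 bp ladder (sd = 0 collapses to the nearest ladder value).
    """
    rng = np.random.default_rng(seed)
    ladder = spec.ladder()
    rows = []
    for sps in spec.species:
        if sps.sd_bp > 0:
            w = np.exp(-0.5 * ((ladder - sps.mean_bp) / sps.sd_bp) ** 2)
            w = w / w.sum()
        else:
            w = np.zeros(len(ladder))
            w[int(np.argmin(np.abs(ladder - sps.mean_bp)))] = 1.0
        draws = rng.choice(ladder, size=(sps.n, 2), p=w)
        draws.sort(axis=1)
        for i in range(sps.n):
            rows.append({"individual": f"{sps.species[:3]}_{i:03d}",
                         "species": sps.species,
                         "allele1": int(draws[i, 0]),
                         "allele2": int(draws[i, 1])})
    return pd.DataFrame(rows)
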
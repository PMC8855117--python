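"""Microsatellite diversity, differentiation, and migratory-distance association.

Works on a diploid single-locus genotype table: one row per individual with two
allele sizes in base pairs (a dinucleotide locus steps in 2 bp).  Provides the
standard single-locus battery — allele counts, observed and unbiased expected
heterozygosity, a Monte-Carlo Hardy–Weinberg exact test by re-pairing of gene
copies, pairwise Weir–Cockerham FST and its allele-size analogue RST — plus
the association of per-individual mean allele size with each species'
migratory distance (Spearman rank correlation with a permutation p-value, and
the least-squares correlation R), and a univariate PERMANOVA comparison of
allele size among species.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .perm_stats import DistanceMatrix, PermutationResult, _one_factor_permanova, \
    pairwise_pseudo_t
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DEFAULT_MIGRATORY_DISTANCES_KM",
    "load_genotypes",
    "read_genepop",
    "validate_genotypes",
    "allele_summary",
    "hwe_test",
    "fst_rst",
    "DifferentiationMatrix",
    "weir_cockerham_fst",
    "size_variance_rst",
    "distance_association",
    "AssociationResult",
    "allele_size_group_comparison",
]

#: Migratory distance (km) from the North-American breeding grounds to the
#: Bragança estuary wintering area; the resident collared plover is assigned 0.
DEFAULT_MIGRATORY_DISTANCES_KM = {
    "Charadrius collaris": 0.0,
    "Charadrius semipalmatus": 8039.0,
    "Calidris pusilla": 9309.0,
    "Actitis macularius": 13139.0,
}

_COLUMNS = ["individual", "species", "allele1", "allele2"]


def validate_genotypes(g: pd.DataFrame) -> pd.DataFrame:
    """Check and normalise a genotype table (warns on off-ladder spacing)."""
    missing = [c for c in _COLUMNS if c not in g.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    g = g[_COLUMNS].copy()
    for c in ("allele1", "allele2"):
        g[c] = g[c].astype(int)
        if (g[c] <= 0).any():
            raise ValueError(f"non-positive allele sizes in column {c}")
    sizes = np.unique(np.r_[g["allele1"], g["allele2"]])
    if len(sizes) > 1 and np.any(np.diff(sizes) % 2 != 0):
        warnings.warn("allele sizes are not on a 2 bp ladder; "
                      "check for off-ladder calls", stacklevel=2)
    return g


def load_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a CSV with columns individual,species,allele1,allele2 (bp).

    Header variants ``allele1_bp``/``allele2_bp`` are accepted.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={"allele1_bp": "allele1", "allele2_bp": "allele2"})
    return validate_genotypes(df)


def read_genepop(path: str | Path) -> pd.DataFrame:
    """Read a single-locus GenePop file (3-digit allele coding = size in bp).

    Population names are taken from the first individual label of each block.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("not a GenePop file")
    rows = []
    pop_idx = 0
    in_pop = False
    for line in lines[2:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            in_pop = True
            continue
        if not in_pop:
            continue  # extra locus-name lines
        if "," not in s:
            raise ValueError(f"malformed GenePop line: {s!r}")
        name, geno = s.split(",", 1)
        geno = geno.strip()
        if len(geno) == 6:
            a1, a2 = int(geno[:3]), int(geno[3:])
        elif len(geno) == 4:
            a1, a2 = int(geno[:2]), int(geno[2:])
        else:
            raise ValueError(f"unsupported GenePop genotype {geno!r}")
        rows.append({"individual": name.strip(), "species": f"pop{pop_idx}",
                     "allele1": a1, "allele2": a2})
    return validate_genotypes(pd.DataFrame(rows))


def _species_alleles(g: pd.DataFrame) -> dict[str, np.ndarray]:
    return {sp: np.r_[sub["allele1"].to_numpy(int), sub["allele2"].to_numpy(int)]
            for sp, sub in g.groupby("species", sort=True)}


def allele_summary(g: pd.DataFrame) -> pd.DataFrame:
    """Per-species diversity summary: n, A, private alleles, Ho, He.

    He uses the unbiased small-sample correction ``(2n/(2n-1)) (1 - sum p^2)``
    with 2n the number of gene copies.
    """
    g = validate_genotypes(g)
    copies = _species_alleles(g)
    all_counts = {sp: set(np.unique(c)) for sp, c in copies.items()}
    rows = []
    for sp, sub in g.groupby("species", sort=True):
        c = copies[sp]
        two_n = len(c)
        alleles, counts = np.unique(c, return_counts=True)
        p = counts / two_n
        he = 0.0 if len(alleles) == 1 else \
            (two_n / (two_n - 1.0)) * (1.0 - float(np.sum(p ** 2)))
        ho = 0.0 if len(alleles) == 1 else \
            float(np.mean(sub["allele1"].to_numpy() != sub["allele2"].to_numpy()))
        private = sum(1 for a in alleles
                      if all(a not in all_counts[o] for o in all_counts if o != sp))
        rows.append({"species": sp, "n": len(sub), "A": len(alleles),
                     "private_alleles": private, "Ho": ho, "He": he})
    return pd.DataFrame(rows).set_index("species")


def _per_allele_het(a1: np.ndarray, a2: np.ndarray,
                    alleles: np.ndarray) -> np.ndarray:
    """Counts of heterozygotes carrying each allele, along the last axis."""
    het = a1 != a2
    return np.stack([(het & ((a1 == al) | (a2 == al))).sum(axis=-1)
                     for al in alleles], axis=-1)


def hwe_test(g: pd.DataFrame, n_perm: int = 999,
             seed: int | None = None) -> pd.Series:
    """Monte-Carlo Hardy–Weinberg test per species.

    Gene copies are randomly re-paired into diploid genotypes.  The statistic
    is heterozygosity-based with per-allele resolution: the summed absolute
    deviation of each allele's heterozygote count from its re-pairing
    expectation (the coarser total-heterozygote count yields a badly discrete
    permutation null).  Monomorphic species return p = 1.
    """
    g = validate_genotypes(g)
    rng = np.random.default_rng(seed)
    out = {}
    for sp, sub in g.groupby("species", sort=True):
        a1 = sub["allele1"].to_numpy(int)
        a2 = sub["allele2"].to_numpy(int)
        copies = np.r_[a1, a2]
        alleles = np.unique(copies)
        if len(alleles) == 1:
            out[sp] = 1.0
            continue
        if len(sub) < 5:
            warnings.warn(f"species {sp!r} has < 5 individuals; HWE test skipped",
                          stacklevel=2)
            out[sp] = np.nan
            continue
        n_ind = len(sub)
        perms = rng.permuted(np.tile(copies, (n_perm, 1)), axis=1)
        het_perm = _per_allele_het(perms[:, :n_ind], perms[:, n_ind:],
                                   alleles).astype(float)
        het_obs = _per_allele_het(a1[None, :], a2[None, :], alleles)[0]
        expect = het_perm.mean(axis=0)
        t_obs = np.abs(het_obs - expect).sum()
        t_perm = np.abs(het_perm - expect).sum(axis=1)
        count = int(np.count_nonzero(t_perm >= t_obs - 1e-9))
        out[sp] = (count + 1) / (n_perm + 1)
    return pd.Series(out, name="hwe_p")


def weir_cockerham_fst(alleles_by_pop: list[np.ndarray],
                       het_by_pop: list[np.ndarray]) -> float:
    """Weir & Cockerham theta for one locus over r populations.

    ``alleles_by_pop[i]`` holds the gene copies of population i;
    ``het_by_pop[i]`` is a boolean per-individual heterozygosity vector.
    Returns NaN when the pooled locus is monomorphic.
    """
    r = len(alleles_by_pop)
    n_i = np.array([len(a) / 2.0 for a in alleles_by_pop])  # individuals
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1)
    all_alleles = np.unique(np.concatenate(alleles_by_pop))
    if len(all_alleles) == 1:
        return float("nan")
    a_sum = b_sum = c_sum = 0.0
    for al in all_alleles:
        p_i = np.array([np.mean(pop == al) for pop in alleles_by_pop])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        h_i = np.array([np.mean(het & ((pop[:len(het)] == al) | (pop[len(het):] == al)))
                        for pop, het in zip(alleles_by_pop, het_by_pop)])
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a_sum += (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                      - hbar / 4.0) / (nbar - 1))
        b_sum += (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                        - (2 * nbar - 1) / (4 * nbar) * hbar)
        c_sum += hbar / 2.0
    denom = a_sum + b_sum + c_sum
    return float(a_sum / denom) if denom != 0 else float("nan")


def size_variance_rst(alleles_by_pop: list[np.ndarray]) -> float:
    """RST: among-population component of allele-*size* variance.

    One-way variance components on gene-copy sizes grouped by population;
    RST = sigma_between / (sigma_between + sigma_within).
    """
    sizes = [np.asarray(a, dtype=float) for a in alleles_by_pop]
    r = len(sizes)
    n_i = np.array([len(a) for a in sizes])
    N = n_i.sum()
    grand = np.concatenate(sizes).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in sizes)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in sizes)
    msb = ssb / (r - 1)
    dfw = N - r
    msw = ssw / dfw if dfw > 0 else 0.0
    n0 = (N - np.sum(n_i ** 2) / N) / (r - 1)
    sig_b = max((msb - msw) / n0, 0.0)
    denom = sig_b + msw
    return float(sig_b / denom) if denom > 0 else float("nan")


@dataclass
class DifferentiationMatrix:
    species: list[str]
    fst: pd.DataFrame
    rst: pd.DataFrame
    fst_p: pd.DataFrame
    rst_p: pd.DataFrame


def _pair_stats(sub: pd.DataFrame, sp1: str, sp2: str) -> tuple[float, float]:
    pops, hets = [], []
    for sp in (sp1, sp2):
        s = sub[sub["species"] == sp]
        a1 = s["allele1"].to_numpy(int)
        a2 = s["allele2"].to_numpy(int)
        pops.append(np.r_[a1, a2])
        hets.append(a1 != a2)
    return weir_cockerham_fst(pops, hets), size_variance_rst(pops)


def fst_rst(g: pd.DataFrame, n_perm: int = 999,
            seed: int | None = None) -> DifferentiationMatrix:
    """Pairwise FST (Weir–Cockerham) and RST with permutation p-values.

    p-values permute individuals between the two populations of each pair.
    Pairs whose pooled locus is monomorphic report NaN.
    """
    g = validate_genotypes(g)
    species = sorted(g["species"].unique())
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    for sp in species:
        if (g["species"] == sp).sum() < 2:
            raise ValueError(f"species {sp!r} has < 2 individuals")
    k = len(species)
    fst = pd.DataFrame(0.0, index=species, columns=species)
    rst = pd.DataFrame(0.0, index=species, columns=species)
    fst_p = pd.DataFrame(np.nan, index=species, columns=species)
    rst_p = pd.DataFrame(np.nan, index=species, columns=species)
    rng = np.random.default_rng(seed)
    for sp1, sp2 in itertools.combinations(species, 2):
        sub = g[g["species"].isin([sp1, sp2])].reset_index(drop=True)
        f_obs, r_obs = _pair_stats(sub, sp1, sp2)
        labels = sub["species"].to_numpy()
        cf = cr = 0
        if np.isfinite(f_obs):
            for _ in range(n_perm):
                perm = sub.copy()
                perm["species"] = rng.permutation(labels)
                f_p, r_p = _pair_stats(perm, sp1, sp2)
                if f_p >= f_obs:
                    cf += 1
                if r_p >= r_obs:
                    cr += 1
            fst_p.loc[sp1, sp2] = fst_p.loc[sp2, sp1] = (cf + 1) / (n_perm + 1)
            rst_p.loc[sp1, sp2] = rst_p.loc[sp2, sp1] = (cr + 1) / (n_perm + 1)
        fst.loc[sp1, sp2] = fst.loc[sp2, sp1] = f_obs
        rst.loc[sp1, sp2] = rst.loc[sp2, sp1] = r_obs
    return DifferentiationMatrix(species, fst, rst, fst_p, rst_p)


@dataclass
class AssociationResult:
    rho: float
    p: float
    regression_r: float
    n: int
    n_perm: int
    seed: int | None


def distance_association(g: pd.DataFrame,
                         dmap: dict[str, float] | None = None,
                         n_perm: int = 9999,
                         seed: int | None = None) -> AssociationResult:
    """Spearman correlation of per-individual mean allele size with distance.

    ``dmap`` maps species to migratory distance in km (defaults to the
    built-in four-species map).  Ties use midranks; the p-value permutes
    distances across individuals.  Also reports the ordinary least-squares
    correlation R.
    """
    g = validate_genotypes(g)
    if dmap is None:
        dmap = DEFAULT_MIGRATORY_DISTANCES_KM
    missing = set(g["species"]) - set(dmap)
    if missing:
        raise ValueError(f"no migratory distance for species: {sorted(missing)}")
    size = (g["allele1"] + g["allele2"]).to_numpy(float) / 2.0
    dist = g["species"].map(dmap).to_numpy(float)
    if len(np.unique(dist)) < 3:
        raise ValueError("need >= 3 distinct migratory distances")
    rho = float(stats.spearmanr(dist, size).statistic)
    r_ols = float(stats.pearsonr(dist, size).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rho_p = stats.spearmanr(rng.permutation(dist), size).statistic
        if abs(rho_p) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AssociationResult(rho=rho, p=float(p), regression_r=r_ols,
                             n=len(g), n_perm=n_perm, seed=seed)


def allele_size_group_comparison(g: pd.DataFrame, n_perm: int = 9999,
                                 seed: int | None = None
                                 ) -> tuple[PermutationResult, pd.DataFrame]:
    """Univariate PERMANOVA of per-individual mean allele size among species.

    Uses unrestricted (free) permutation of raw observations, plus a pairwise
    pseudo-t table.
    """
    g = validate_genotypes(g)
    size = (g["allele1"] + g["allele2"]).to_numpy(float)[:, None] / 2.0
    d = squareform(pdist(size))
    labels = g["species"].to_numpy()
    overall = _one_factor_permanova(d, labels, n_perm, seed, "species")
    dm = DistanceMatrix(ids=list(g["individual"]), d=d)
    pairs = pairwise_pseudo_t(dm, labels, n_perm=n_perm, seed=seed)
    return overall, pairs
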
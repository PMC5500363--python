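"""Synthetic yeast-cross generator.

Emulates the data a pooled bulk-segregant mapping study produces: a diploid
parent heterozygous at thousands of marker sites, haploid monosporic-clone
segregants derived by meiosis with Poisson crossovers (no interference, i.e.
Haldane's mapping function), a two-locus epistatic resistance phenotype with
an Intermediate noise class, pooled short-read allele counts, read-depth
coverage tracks with planted whole-chromosome copy-number changes, and an
RNA-seq count matrix with a chromosome-wide dosage effect.

Everything is seeded and bit-reproducible; each operation derives its random
stream from an explicit integer seed.

Coordinates are 1-based throughout, matching VCF convention.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "PHENOTYPES",
    "SENSITIVE",
    "RESISTANT_PARENTAL",
    "RESISTANT_EVOLVED",
    "INTERMEDIATE",
    "CrossConfig",
    "DepthModel",
    "SegregantSet",
    "simulate_parent_sites",
    "simulate_meiosis",
    "assign_phenotypes",
    "simulate_pool_reads",
    "simulate_parent_counts",
    "simulate_coverage",
    "simulate_expression",
    "write_bedgraph",
    "write_expression_tsv",
    "write_truth",
]

SENSITIVE = "Sensitive"
RESISTANT_PARENTAL = "ResistantParental"
RESISTANT_EVOLVED = "ResistantEvolved"
INTERMEDIATE = "Intermediate"
PHENOTYPES = (SENSITIVE, RESISTANT_PARENTAL, RESISTANT_EVOLVED, INTERMEDIATE)

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-operation stream derived from one integer seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated cross.

    ``qtl_major`` is the large-effect resistance locus (the chrXII analogue),
    ``qtl_minor`` the modifier distinguishing the two resistant classes (the
    chrIV analogue). ``intermediate_fraction`` is the probability that a
    resistant-genotype segregant is relabeled Intermediate, modelling the
    phenotyping noise class that is never pooled.
    """

    n_segregants: int = 69
    qtl_major: tuple[str, int] = ("chrXII", 543_500)
    qtl_minor: tuple[str, int] = ("chrIV", 471_500)
    intermediate_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segregants < 1:
            raise ValueError("n_segregants must be >= 1")
        if not 0 <= self.intermediate_fraction < 1:
            raise ValueError("intermediate_fraction must be in [0, 1)")

    def validate_against(self, genome: GenomeSpec) -> None:
        for label, (chrom, pos) in (("qtl_major", self.qtl_major), ("qtl_minor", self.qtl_minor)):
            if chrom not in genome.names:
                raise ValueError(f"{label}: unknown chromosome {chrom!r}")
            if not 1 <= pos <= genome.length_of(chrom):
                raise ValueError(f"{label}: position {pos} outside {chrom}")


@dataclass(frozen=True)
class DepthModel:
    """Pooled-sequencing depth model: Poisson site depth, symmetric read error.

    ``mean_depth`` brackets the study design this generator emulates (pool
    coverages in the 66-133x range); ``error_rate`` is the per-read chance of
    reporting the wrong allele.
    """

    mean_depth: float = 80.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must be in [0, 0.01)")


@dataclass
class SegregantSet:
    """Haploid segregant genotypes over a marker map, with phenotype labels.

    ``sites`` has columns (chrom, pos, ref, alt); ``genotypes`` is a
    (n_segregants, n_sites) array of 0/1 haplotype codes (0 = parental
    haplotype A carrying the reference allele, 1 = haplotype B carrying the
    alternate). ``phenotypes`` is filled by :func:`assign_phenotypes`.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    phenotypes: np.ndarray | None = None

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def pool_members(self, label: str) -> np.ndarray:
        if self.phenotypes is None:
            raise ValueError("phenotypes not assigned yet")
        return np.flatnonzero(self.phenotypes == label)


def simulate_parent_sites(
    n_sites: int, genome: GenomeSpec | None = None, seed: int = 0
) -> pd.DataFrame:
    """Place heterozygous marker sites uniformly across the genome.

    Sites are allocated to chromosomes in proportion to length (a single
    uniform draw over genome coordinates), unique, and sorted in genome
    order. The default marker count used by the pipeline, 18,047, matches a
    realistic filtered heterozygous-site map for a heterozygous wine strain.

    Returns a DataFrame with columns ``chrom, pos, ref, alt``.
    """
    genome = genome or GenomeSpec()
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    total = genome.total_length
    if n_sites > total:
        raise ValueError(
            f"n_sites={n_sites} exceeds total genome length {total}: infeasible density"
        )
    rng = _rng(seed, 0)
    # Draw global offsets with replacement, deduplicate, top up until unique.
    offsets: np.ndarray = np.empty(0, dtype=np.int64)
    while offsets.size < n_sites:
        need = n_sites - offsets.size
        draw = rng.integers(0, total, size=max(need * 2, 16))
        offsets = np.unique(np.concatenate([offsets, draw]))
    offsets = np.sort(rng.choice(offsets, size=n_sites, replace=False))

    bounds = np.cumsum([l for _, l in genome.chromosomes])
    chrom_idx = np.searchsorted(bounds, offsets, side="right")
    starts = np.concatenate([[0], bounds[:-1]])
    pos = offsets - starts[chrom_idx] + 1  # 1-based within chromosome

    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    names = np.array(genome.names)
    return pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_idx, categories=list(names)).astype(str),
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
        }
    )


def simulate_meiosis(
    sites: pd.DataFrame, cross: CrossConfig, genome: GenomeSpec | None = None
) -> SegregantSet:
    """Generate haploid segregants as recombinant mosaics of two haplotypes.

    Each chromosome of each segregant starts from haplotype A or B with
    probability 1/2; the crossover count is Poisson with mean equal to the
    chromosome's genetic length in Morgans and breakpoints are uniform, so
    recombination between two points follows Haldane's mapping function
    c = (1 - exp(-2d)) / 2.
    """
    genome = genome or GenomeSpec()
    cross.validate_against(genome)
    if len(sites) == 0:
        raise ValueError("sites must be nonempty")
    rng = _rng(cross.seed, 1)
    n = cross.n_segregants
    geno = np.empty((n, len(sites)), dtype=np.int8)
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        positions = sites["pos"].to_numpy()[idx]
        length = genome.length_of(str(chrom))
        morgans = genome.genetic_length_morgans(str(chrom))
        starts = rng.integers(0, 2, size=n)
        n_cross = rng.poisson(morgans, size=n)
        for s in range(n):
            if n_cross[s] == 0:
                geno[s, idx] = starts[s]
            else:
                breaks = np.sort(rng.uniform(0, length, size=n_cross[s]))
                crossings = np.searchsorted(breaks, positions)
                geno[s, idx] = (starts[s] + crossings) % 2
    return SegregantSet(sites=sites.reset_index(drop=True), genotypes=geno)


def _nearest_site_index(sites: pd.DataFrame, locus: tuple[str, int]) -> int:
    chrom, pos = locus
    on_chrom = np.flatnonzero(sites["chrom"].to_numpy() == chrom)
    if on_chrom.size == 0:
        raise ValueError(f"no marker sites on chromosome {chrom!r}")
    dist = np.abs(sites["pos"].to_numpy()[on_chrom] - pos)
    return int(on_chrom[np.argmin(dist)])


def assign_phenotypes(segregants: SegregantSet, cross: CrossConfig) -> SegregantSet:
    """Label segregants by a deterministic two-locus epistatic rule.

    Genotype at the marker nearest each QTL decides the class: haplotype A
    (allele 0) at the major locus is Sensitive regardless of the modifier;
    haplotype B at the major locus is ResistantEvolved when it also carries
    haplotype B at the minor locus and ResistantParental otherwise. Each
    resistant-genotype segregant is independently relabeled Intermediate with
    probability ``intermediate_fraction`` (intermediates are never pooled).
    Labels are written in place and the set is returned.
    """
    i_major = _nearest_site_index(segregants.sites, cross.qtl_major)
    i_minor = _nearest_site_index(segregants.sites, cross.qtl_minor)
    g_major = segregants.genotypes[:, i_major]
    g_minor = segregants.genotypes[:, i_minor]
    labels = np.where(
        g_major == 0,
        SENSITIVE,
        np.where(g_minor == 1, RESISTANT_EVOLVED, RESISTANT_PARENTAL),
    ).astype(object)
    rng = _rng(cross.seed, 2)
    resistant = g_major == 1
    noise = rng.random(segregants.n_segregants) < cross.intermediate_fraction
    labels[resistant & noise] = INTERMEDIATE
    segregants.phenotypes = labels.astype("U20")
    return segregants


def _sample_counts(
    freqs: np.ndarray, depth: DepthModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    dp = rng.poisson(depth.mean_depth, size=freqs.size)
    p = freqs * (1 - depth.error_rate) + (1 - freqs) * depth.error_rate
    alt = rng.binomial(dp, p)
    return dp - alt, alt


def simulate_pool_reads(
    segregants: SegregantSet, pool_label: str, depth: DepthModel
) -> pd.DataFrame:
    """Pooled sequencing of all segregants carrying ``pool_label``.

    Per site, the true pool frequency f is the mean genotype among pool
    members; site depth is Poisson(mean_depth) and alternate reads are
    Binomial(depth, f(1-eps) + (1-f)eps).

    Returns a DataFrame ``chrom, pos, ref_depth, alt_depth`` aligned to the
    marker map, with the pool name in ``.attrs['pool']``.
    """
    members = segregants.pool_members(pool_label)
    if members.size == 0:
        raise ValueError(f"pool {pool_label!r} is empty")
    f = segregants.genotypes[members].mean(axis=0)
    rng = _rng(depth.seed, zlib.crc32(pool_label.encode()) % (2**31))
    ref, alt = _sample_counts(f, depth, rng)
    out = segregants.sites[["chrom", "pos"]].copy()
    out["ref_depth"] = ref
    out["alt_depth"] = alt
    out.attrs["pool"] = pool_label
    return out


def simulate_parent_counts(sites: pd.DataFrame, depth: DepthModel) -> pd.DataFrame:
    """Sequencing counts for the heterozygous diploid parent (f = 1/2 everywhere)."""
    rng = _rng(depth.seed, 3)
    f = np.full(len(sites), 0.5)
    ref, alt = _sample_counts(f, depth, rng)
    out = sites[["chrom", "pos"]].copy()
    out["ref_depth"] = ref
    out["alt_depth"] = alt
    out.attrs["pool"] = "parent"
    return out


def simulate_coverage(
    genome: GenomeSpec | None = None,
    copy_numbers: dict[str, int] | None = None,
    window: int = 1000,
    mean_depth: float = 100.0,
    seed: int = 0,
    baseline_ploidy: int = 2,
) -> pd.DataFrame:
    """Tile the genome with fixed windows and draw per-window mean depth.

    A chromosome at copy number k in a baseline-ploidy-p strain has expected
    per-base depth mean_depth * k / p; the window's summed base coverage is
    Poisson with that mean times the window length. Windows tile each
    chromosome; the final partial window keeps its true length.

    Returns a DataFrame ``chrom, start, end, mean_depth`` (1-based closed).
    """
    genome = genome or GenomeSpec()
    copy_numbers = copy_numbers or {}
    for chrom, k in copy_numbers.items():
        if chrom not in genome.names:
            raise ValueError(f"unknown chromosome in copy_numbers: {chrom!r}")
        if k < 1:
            raise ValueError("copy numbers must be >= 1")
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    smallest = min(l for _, l in genome.chromosomes)
    if window > smallest:
        raise ValueError(f"window {window} larger than smallest chromosome ({smallest} bp)")
    rng = _rng(seed, 4)
    rows = []
    for chrom, length in genome.chromosomes:
        k = copy_numbers.get(chrom, baseline_ploidy)
        starts = np.arange(1, length + 1, window)
        ends = np.minimum(starts + window - 1, length)
        lens = ends - starts + 1
        lam = mean_depth * (k / baseline_ploidy) * lens
        depths = rng.poisson(lam) / lens
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "mean_depth": depths}))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["window"] = window
    return out


def simulate_expression(
    n_genes: int = 5000,
    gene_chromosomes: dict[str, str] | None = None,
    dosage: dict[str, float] | None = None,
    n_reps: tuple[int, int] = (3, 1),
    dispersion: float = 0.05,
    seed: int = 0,
    genome: GenomeSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RNA-seq counts for a parent/evolved strain pair with a dosage effect.

    Gene baseline means are log-uniform over roughly 10-3000 counts; genes on
    a chromosome listed in ``dosage`` have their evolved-strain mean
    multiplied by that fold (1.5 models a trisomic chromosome in a diploid).
    Counts are negative binomial with the given dispersion alpha
    (var = mu + alpha mu^2); alpha = 0 degenerates to Poisson. The default
    replicate structure is 3 parent cultures vs a single evolved culture.

    Returns ``(counts, annotation)``: counts is genes x samples with columns
    ``parent_1..parent_m, evolved_1..evolved_k``; annotation maps gene to
    chromosome.
    """
    genome = genome or GenomeSpec()
    if n_reps[0] < 1 or n_reps[1] < 1:
        raise ValueError("n_reps must be >= (1, 1)")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = _rng(seed, 5)
    if gene_chromosomes is None:
        lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
        probs = lengths / lengths.sum()
        chrom_idx = rng.choice(len(probs), size=n_genes, p=probs)
        genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
        chroms = [genome.names[i] for i in chrom_idx]
    else:
        genes = list(gene_chromosomes)
        chroms = [gene_chromosomes[g] for g in genes]
        n_genes = len(genes)
    dosage = dosage or {}
    known = set(chroms) | set(genome.names)
    for chrom in dosage:
        if chrom not in known:
            raise ValueError(f"unknown chromosome in dosage map: {chrom!r}")

    base = 10 ** rng.uniform(1.0, 3.5, size=n_genes)
    fold = np.array([dosage.get(c, 1.0) for c in chroms])

    def _draw(mu: np.ndarray) -> np.ndarray:
        if dispersion == 0:
            return rng.poisson(mu)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        return rng.poisson(lam)

    data = {}
    for r in range(n_reps[0]):
        data[f"parent_{r + 1}"] = _draw(base)
    for r in range(n_reps[1]):
        data[f"evolved_{r + 1}"] = _draw(base * fold)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    annotation = pd.DataFrame({"chrom": chroms}, index=counts.index)
    return counts, annotation


# ---------------------------------------------------------------------------
# plain-text writers


def write_bedgraph(windows: pd.DataFrame, path: str | Path) -> None:
    """Write coverage windows as 4-column bedGraph (0-based half-open)."""
    out = windows.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end", "mean_depth"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.4f"
    )


def write_expression_tsv(
    counts: pd.DataFrame, annotation: pd.DataFrame, path: str | Path
) -> None:
    """Write counts + chromosome annotation as one TSV (gene, chrom, samples...)."""
    merged = annotation.join(counts)
    merged.to_csv(path, sep="\t")


def write_truth(path: str | Path, **planted) -> None:
    """Record planted simulation truth (QTL, copy numbers, dosage) as JSON."""
    Path(path).write_text(json.dumps(planted, indent=2, default=str) + "\n")
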
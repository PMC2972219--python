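"""Synthetic study generator: drift-generated LD, multiallelic markers,
an additive causal variant, half-sib structure and tail selection.

The generator emulates the statistical structure the analysis assumes.
A small closed diploid population (effective size ``ne``) is evolved
forward under Wright-Fisher reproduction for ``n_generations`` with
recombination between adjacent loci at the Haldane rate
r = (1 - exp(-2d)) / 2 for map distance d Morgans; finite size builds
linkage disequilibrium that decays with distance, which is what the
Sved regression estimates Ne from.  Founder haplotypes are drawn in
linkage equilibrium with per-marker allele frequencies from a symmetric
Dirichlet; no mutation occurs during the simulated generations (allelic
diversity comes entirely from the founders).  A biallelic causal locus
is inserted at its map position and transmitted like a marker but is
not part of the emitted genotype matrix; it adds ``effect`` phenotype
units per minor-allele copy to a Gaussian baseline.

The study cohort is a single offspring generation bred from the final
Wright-Fisher generation, with each individual's father drawn from
``n_sires`` males to create the paternal half-sib families that the
per-sire cap in tail selection guards against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genio
from .genio import GeneticMap, GenotypeMatrix

logger = logging.getLogger("hapscan")


@dataclass(frozen=True)
class CausalConfig:
    """A single additive biallelic causal locus.

    ``effect`` is the phenotype change per minor-allele copy (the
    default -3 emulates a variant that removes three ova per copy);
    ``mean``/``sd`` are the baseline phenotype mean and residual noise.
    """

    chromosome: str = "3"
    position_cm: float = 25.0
    maf: float = 0.3
    effect: float = -3.0
    mean: float = 16.0
    sd: float = 7.0
    #: smallest acceptable cohort minor-allele frequency; the variant is a
    #: drifting locus like any marker and would fix in most long runs, but a
    #: mapping study presupposes a segregating variant at intermediate
    #: frequency (the mapped substitution ran at ~0.27), so realizations where
    #: it drifted below this floor are rejected and resimulated (0 disables
    #: conditioning)
    min_cohort_maf: float = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``chromosomes`` is a tuple of (name, length_cM, n_markers); markers
    are evenly spaced along each chromosome.  ``alleles_per_marker`` is
    an inclusive range; each marker draws its allele count uniformly
    from it and its founder allele frequencies from a symmetric
    Dirichlet with the given concentration.
    """

    ne: int = 30
    n_generations: int = 60
    chromosomes: tuple[tuple[str, float, int], ...] = (
        ("1", 50.0, 20),
        ("2", 50.0, 20),
        ("3", 50.0, 20),
        ("4", 50.0, 20),
        ("5", 50.0, 20),
    )
    alleles_per_marker: tuple[int, int] = (6, 10)
    founder_allele_dirichlet: float = 1.0
    causal: CausalConfig | None = field(default_factory=CausalConfig)
    n_individuals: int = 639
    n_sires: int = 15
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for name, length, n_markers in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
            if n_markers < 2:
                raise ValueError(f"chromosome {name}: need >= 2 markers")
        if self.alleles_per_marker[0] < 2 or (
            self.alleles_per_marker[0] > self.alleles_per_marker[1]
        ):
            raise ValueError("alleles_per_marker must be a range with min >= 2")
        if self.founder_allele_dirichlet <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        if self.causal is not None:
            c = self.causal
            if not 0 < c.maf < 0.5:
                raise ValueError("minor allele frequency must be in (0, 0.5)")
            if c.sd <= 0:
                raise ValueError("phenotype sd must be > 0")
            lengths = {name: length for name, length, _ in self.chromosomes}
            if c.chromosome not in lengths:
                raise ValueError(f"causal chromosome {c.chromosome!r} not simulated")
            if not 0 <= c.position_cm <= lengths[c.chromosome]:
                raise ValueError("causal position lies outside its chromosome")
        if not 1 <= self.n_sires <= self.ne:
            raise ValueError("n_sires must be between 1 and ne")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class StudyTruth:
    """Ground truth of a simulated study."""

    causal_chromosome: str | None
    causal_position_cm: float | None
    causal_genotypes: pd.Series | None       # minor-allele copies per individual
    phases: np.ndarray                       # (n, 2, n_markers) allele codes
    founder_freqs: dict[str, np.ndarray]     # realized founder allele freqs
    founder_alleles: dict[str, np.ndarray]   # allele codes, aligned with freqs


@dataclass
class SimulatedStudy:
    map: GeneticMap
    genotypes: GenotypeMatrix
    phenotypes: pd.Series
    sires: pd.Series
    truth: StudyTruth
    config: SimConfig


def _integer_counts(freqs: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of freqs * total to integers summing
    to total (the realized founder frequencies are what downstream
    invariants refer to)."""
    raw = freqs * total
    base = np.floor(raw).astype(int)
    shortfall = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:shortfall]] += 1
    return base


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for d centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


def _gametes(pop: np.ndarray, parents: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Draw one recombinant gamete per parent index.

    ``pop`` holds haplotypes (2 per individual, rows 2i and 2i+1);
    crossovers fall between adjacent loci independently with
    probabilities ``r`` and the starting strand is uniform.
    """
    g = len(parents)
    m = pop.shape[1]
    start = rng.integers(0, 2, size=g)
    strand = np.empty((g, m), dtype=np.int64)
    strand[:, 0] = start
    if m > 1:
        cross = rng.random((g, m - 1)) < r[None, :]
        strand[:, 1:] = (start[:, None] + np.cumsum(cross, axis=1)) % 2
    return pop[2 * parents[:, None] + strand, np.arange(m)[None, :]]


def simulate_population(config: SimConfig) -> SimulatedStudy:
    """Generate a synthetic study; bit-reproducible given the seed.

    When a causal locus is configured with ``min_cohort_maf > 0``,
    realizations in which the variant drifted to (near-)fixation are
    rejected and resimulated with a derived sub-seed until its cohort
    frequency lies in [min_cohort_maf, 1 - min_cohort_maf]; the
    rejection loop is part of the deterministic seed stream.
    """
    condition = config.causal is not None and config.causal.min_cohort_maf > 0
    for attempt in range(1000):
        rng = np.random.default_rng([config.seed, attempt])
        study = _simulate_once(config, rng)
        if not condition:
            return study
        cg = study.truth.causal_genotypes.to_numpy()
        freq = cg.sum() / (2.0 * len(cg))
        lo = config.causal.min_cohort_maf
        if lo <= freq <= 1.0 - lo:
            if attempt:
                logger.info(
                    "causal variant segregating after %d rejected realizations",
                    attempt,
                )
            return study
    raise RuntimeError(
        "causal variant failed to segregate in 1000 realizations; "
        "lower min_cohort_maf or n_generations"
    )


def _simulate_once(config: SimConfig, rng: np.random.Generator) -> SimulatedStudy:
    two_ne = 2 * config.ne

    # per-chromosome locus lattices; the causal locus is spliced into its
    # chromosome but excluded from the emitted marker set
    chrom_names: list[str] = []
    chrom_positions: list[np.ndarray] = []
    chrom_marker_names: list[list[str]] = []
    causal_site: tuple[int, int] | None = None  # (chromosome idx, locus idx)
    for ci, (name, length, n_markers) in enumerate(config.chromosomes):
        pos = np.linspace(0.0, length, n_markers)
        names = [f"C{name}M{i + 1:03d}" for i in range(n_markers)]
        if config.causal is not None and config.causal.chromosome == name:
            at = int(np.searchsorted(pos, config.causal.position_cm))
            pos = np.insert(pos, at, config.causal.position_cm)
            names = names[:at] + ["__causal__"] + names[at:]
            causal_site = (ci, at)
        chrom_names.append(name)
        chrom_positions.append(pos)
        chrom_marker_names.append(names)

    # founders in linkage equilibrium
    founder_freqs: dict[str, np.ndarray] = {}
    founder_alleles: dict[str, np.ndarray] = {}
    pops: list[np.ndarray] = []
    kmin, kmax = config.alleles_per_marker
    for ci in range(len(chrom_names)):
        m = len(chrom_positions[ci])
        pop = np.empty((two_ne, m), dtype=np.int64)
        for li, locus in enumerate(chrom_marker_names[ci]):
            if locus == "__causal__":
                codes = np.array([1, 2])
                freqs = np.array([1.0 - config.causal.maf, config.causal.maf])
            else:
                n_alleles = int(rng.integers(kmin, kmax + 1))
                codes = np.arange(1, n_alleles + 1)
                freqs = rng.dirichlet(
                    np.full(n_alleles, config.founder_allele_dirichlet)
                )
            counts = _integer_counts(freqs, two_ne)
            column = np.repeat(codes, counts)
            rng.shuffle(column)
            pop[:, li] = column
            founder_freqs[locus if locus != "__causal__" else f"__causal__{ci}"] = (
                counts / two_ne
            )
            founder_alleles[locus if locus != "__causal__" else f"__causal__{ci}"] = codes
        pops.append(pop)

    # Wright-Fisher generations with Haldane recombination
    rs = [_haldane_r(np.diff(p)) for p in chrom_positions]
    for _gen in range(config.n_generations):
        parents = rng.integers(0, config.ne, size=(config.ne, 2))
        for ci in range(len(pops)):
            pat = _gametes(pops[ci], parents[:, 0], rs[ci], rng)
            mat = _gametes(pops[ci], parents[:, 1], rs[ci], rng)
            nxt = np.empty_like(pops[ci])
            nxt[0::2] = pat
            nxt[1::2] = mat
            pops[ci] = nxt

    # study cohort: one offspring generation with half-sib paternal families
    n = config.n_individuals
    sire_pool = rng.choice(config.ne, size=config.n_sires, replace=False)
    sire_of = rng.integers(0, config.n_sires, size=n)
    fathers = sire_pool[sire_of]
    mothers = rng.integers(0, config.ne, size=n)
    phase_blocks: list[np.ndarray] = []   # each (n, 2, m_markers)
    causal_copies: np.ndarray | None = None
    map_rows = []
    for ci in range(len(pops)):
        pat = _gametes(pops[ci], fathers, rs[ci], rng)
        mat = _gametes(pops[ci], mothers, rs[ci], rng)
        block = np.stack([pat, mat], axis=1)           # (n, 2, m_all)
        keep = np.ones(block.shape[2], dtype=bool)
        if causal_site is not None and causal_site[0] == ci:
            li = causal_site[1]
            causal_copies = (block[:, :, li] == 2).sum(axis=1)
            keep[li] = False
        phase_blocks.append(block[:, :, keep])
        kept_names = [nm for nm, k in zip(chrom_marker_names[ci], keep) if k]
        kept_pos = chrom_positions[ci][keep]
        map_rows.extend(
            (nm, chrom_names[ci], float(p)) for nm, p in zip(kept_names, kept_pos)
        )

    phases = np.concatenate(phase_blocks, axis=2)
    ids = [f"I{i + 1:04d}" for i in range(n)]
    gmap = GeneticMap(
        pd.DataFrame(map_rows, columns=["marker", "chromosome", "position_cm"])
    )
    alleles = np.sort(np.swapaxes(phases, 1, 2), axis=2)  # (n, m, 2) canonical

    if config.missing_rate > 0:
        mask = rng.random((n, alleles.shape[1])) < config.missing_rate
        alleles = alleles.copy()
        alleles[mask] = genio.MISSING
        logger.info("injected %d missing genotypes", int(mask.sum()))

    genotypes = GenotypeMatrix(ids, gmap.markers, alleles)

    if config.causal is not None:
        c = config.causal
        pheno_values = c.mean + c.effect * causal_copies + rng.normal(0, c.sd, n)
        causal_series = pd.Series(causal_copies, index=pd.Index(ids, name="individual"),
                                  name="causal_genotype")
    else:
        pheno_values = 16.0 + rng.normal(0, 7.0, n)
        causal_series = None
    phenotypes = pd.Series(pheno_values, index=pd.Index(ids, name="individual"),
                           name="phenotype")
    sires = pd.Series([f"S{s + 1:02d}" for s in sire_of],
                      index=pd.Index(ids, name="individual"), name="sire")

    truth = StudyTruth(
        causal_chromosome=config.causal.chromosome if config.causal else None,
        causal_position_cm=config.causal.position_cm if config.causal else None,
        causal_genotypes=causal_series,
        phases=phases,
        founder_freqs=founder_freqs,
        founder_alleles=founder_alleles,
    )
    logger.info(
        "simulated %d individuals, %d markers on %d chromosomes (seed %d)",
        n, len(gmap), len(chrom_names), config.seed,
    )
    return SimulatedStudy(
        map=gmap, genotypes=genotypes, phenotypes=phenotypes, sires=sires,
        truth=truth, config=config,
    )


@dataclass
class TailSelection:
    """High/low tail groups with realized thresholds."""

    groups: pd.Series            # id -> 'high' | 'low' | 'unselected'
    high_threshold: float        # smallest phenotype admitted to 'high'
    low_threshold: float         # largest phenotype admitted to 'low'
    high_ids: list[str]
    low_ids: list[str]


def select_tails(
    phenotypes: pd.Series,
    sires: pd.Series,
    n_high: int,
    n_low: int,
    max_per_sire: int = 4,
) -> TailSelection:
    """Select phenotype extremes subject to a per-sire cap per group.

    Takes the ``n_high`` largest and ``n_low`` smallest phenotype
    individuals, skipping anyone whose sire already has
    ``max_per_sire`` members in that group (the cap limits paternal
    half-sib family influence).  Ties break deterministically by
    individual identifier.  Raises if the cap makes the requested group
    sizes unreachable.
    """
    if n_high + n_low > len(phenotypes):
        raise ValueError("n_high + n_low exceeds the population size")
    if phenotypes.index.has_duplicates:
        raise ValueError("duplicated individual ids")
    sires = sires.reindex(phenotypes.index)
    if phenotypes.nunique() == 1:
        logger.warning(
            "all phenotypes are equal; tail groups filled purely by "
            "identifier tie-break"
        )

    order = sorted(phenotypes.index, key=lambda i: (-phenotypes[i], str(i)))

    def take(candidates, count, label):
        chosen = []
        per_sire: dict = {}
        for ind in candidates:
            s = sires[ind]
            if per_sire.get(s, 0) >= max_per_sire:
                continue
            chosen.append(ind)
            per_sire[s] = per_sire.get(s, 0) + 1
            if len(chosen) == count:
                return chosen
        raise ValueError(
            f"sire cap {max_per_sire} makes the requested {label} group "
            f"size {count} unreachable"
        )

    high = take(order, n_high, "high")
    taken = set(high)
    low_order = [i for i in sorted(
        phenotypes.index, key=lambda i: (phenotypes[i], str(i))
    ) if i not in taken]
    low = take(low_order, n_low, "low")

    groups = pd.Series("unselected", index=phenotypes.index, name="group")
    groups[high] = "high"
    groups[low] = "low"
    logger.info(
        "tails: %d high (>= %.2f), %d low (<= %.2f), cap %d per sire",
        n_high, phenotypes[high].min(), n_low, phenotypes[low].max(), max_per_sire,
    )
    return TailSelection(
        groups=groups,
        high_threshold=float(phenotypes[high].min()),
        low_threshold=float(phenotypes[low].max()),
        high_ids=high,
        low_ids=low,
    )


def write_study(study: SimulatedStudy, prefix) -> dict[str, Path]:
    """Write a simulated study as TSV files ``<prefix>.<part>.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": prefix.with_suffix(".map.tsv"),
        "genotypes": prefix.with_suffix(".genotypes.tsv"),
        "phenotypes": prefix.with_suffix(".phenotypes.tsv"),
        "sires": prefix.with_suffix(".sires.tsv"),
        "truth": prefix.with_suffix(".truth.tsv"),
        "truth_meta": prefix.with_suffix(".truth_meta.tsv"),
    }
    genio.write_map(study.map, paths["map"])
    genio.write_genotypes(study.genotypes, paths["genotypes"])
    genio.write_phenotypes(study.phenotypes, paths["phenotypes"])
    genio.write_sires(study.sires, paths["sires"])
    if study.truth.causal_genotypes is not None:
        study.truth.causal_genotypes.rename_axis("individual").to_csv(
            paths["truth"], sep="\t"
        )
        pd.DataFrame(
            [
                ("causal_chromosome", study.truth.causal_chromosome),
                ("causal_position_cm", study.truth.causal_position_cm),
            ],
            columns=["key", "value"],
        ).to_csv(paths["truth_meta"], sep="\t", index=False)
    return paths
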
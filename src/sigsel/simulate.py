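"""Forward-time simulation of a replicated bidirectional selection experiment.

An inbred multi-founder pool is intercrossed into a recombinant base
population (small haplotype blocks from the start), split into independent
high/low line pairs per replicate, and driven by within-family truncation
selection on an additive polygenic trait with rotational mating, followed by
relaxed-selection generations.  Shallow sequencing of the final generation
produces read counts with a per-read error rate.

Randomness: a single master seed spawns deterministic, independent
per-replicate streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigsel.design import StudyDesign
from sigsel.genotypes import GenotypeMatrix, ReadCountMatrix


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic selection experiment."""

    n_founders: int = 8
    n_chromosomes: int = 2
    loci_per_chromosome: int = 500
    chromosome_length: int = 1_000_000          # bp
    recombination_rate: float = 1e-6            # Morgans per bp
    n_causal_loci: int = 5
    effect_sizes: np.ndarray | float | None = 1.0   # trait units per allele copy
    heritability: float = 0.5
    n_generations_selected: int = 40
    n_generations_total: int = 60
    families_per_line: int = 10
    offspring_per_family: int = 4
    n_replicates: int = 2
    n_sequenced_per_line: int = 10
    mean_depth: float = 5.0
    read_error_rate: float = 0.003
    n_generations_intercross: int = 3
    base_population_size: int | None = None     # default: 4 * families_per_line
    founder_four_gamete_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_chromosomes": self.n_chromosomes,
            "loci_per_chromosome": self.loci_per_chromosome,
            "chromosome_length": self.chromosome_length,
            "n_generations_total": self.n_generations_total,
            "families_per_line": self.families_per_line,
            "offspring_per_family": self.offspring_per_family,
            "n_replicates": self.n_replicates,
            "n_sequenced_per_line": self.n_sequenced_per_line,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"invalid config: {name} must be positive, got {value}")
        if self.n_causal_loci < 0:
            raise ValueError("invalid config: n_causal_loci must be >= 0")
        if self.n_causal_loci > self.n_loci:
            raise ValueError("invalid config: n_causal_loci exceeds the total locus count")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("invalid config: heritability must be in [0, 1]")
        if self.recombination_rate < 0:
            raise ValueError("invalid config: recombination_rate must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("invalid config: mean_depth must be >= 0")
        if not 0.0 <= self.read_error_rate < 1.0:
            raise ValueError("invalid config: read_error_rate must be in [0, 1)")
        if self.n_generations_selected > self.n_generations_total:
            raise ValueError(
                "invalid config: n_generations_selected exceeds n_generations_total"
            )
        if self.families_per_line < 2:
            raise ValueError("invalid config: families_per_line must be >= 2")
        if not 0.0 <= self.founder_four_gamete_fraction <= 1.0:
            raise ValueError(
                "invalid config: founder_four_gamete_fraction must be in [0, 1]"
            )
        if self.n_sequenced_per_line > self.families_per_line * self.offspring_per_family:
            raise ValueError(
                "invalid config: n_sequenced_per_line exceeds offspring per line"
            )

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def n_base(self) -> int:
        if self.base_population_size is not None:
            return self.base_population_size
        return max(4 * self.families_per_line, 2 * self.families_per_line)

    def effects(self) -> np.ndarray:
        if self.effect_sizes is None:
            return np.ones(self.n_causal_loci)
        e = np.asarray(self.effect_sizes, dtype=float)
        if e.ndim == 0:
            return np.full(self.n_causal_loci, float(e))
        if e.size != self.n_causal_loci:
            raise ValueError("invalid config: effect_sizes length != n_causal_loci")
        return e


# ---------------------------------------------------------------------------
# Founders and the intercrossed base
# ---------------------------------------------------------------------------

@dataclass
class FounderHaplotypes:
    """Fully inbred founders: one haplotype row per founder."""

    haplotypes: np.ndarray       # (n_founders, n_loci) 0/1
    chrom: np.ndarray            # per locus
    pos: np.ndarray              # bp, strictly increasing within chromosome

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class Population:
    """A diploid population as two phased haplotype matrices."""

    hap0: np.ndarray             # (n_individuals, n_loci)
    hap1: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n(self) -> int:
        return self.hap0.shape[0]

    def dosage(self) -> np.ndarray:
        return (self.hap0 + self.hap1).astype(np.int8)

    def allele_frequency(self) -> np.ndarray:
        return (self.hap0.sum(0) + self.hap1.sum(0)) / (2.0 * self.n)


@dataclass
class TruthSet:
    """Ground truth of the planted causal architecture."""

    causal_locus_ids: np.ndarray          # indices into the locus map
    effect_directions: np.ndarray         # +1 / -1 per causal locus
    effect_sizes: np.ndarray
    # (line, replicate, generation, causal locus) allele frequencies
    frequency_trajectories: np.ndarray
    line_labels: tuple[str, ...] = ("HIGH", "LOW")

    def to_frame(self) -> pd.DataFrame:
        n_line, n_rep, n_gen, n_loc = self.frequency_trajectories.shape
        rows = []
        for i in range(n_line):
            for j in range(n_rep):
                for g in range(n_gen):
                    for q in range(n_loc):
                        rows.append(
                            {
                                "line": self.line_labels[i],
                                "replicate": j + 1,
                                "generation": g,
                                "locus": int(self.causal_locus_ids[q]),
                                "direction": int(self.effect_directions[q]),
                                "effect": float(self.effect_sizes[q]),
                                "freq": float(
                                    self.frequency_trajectories[i, j, g, q]
                                ),
                            }
                        )
        return pd.DataFrame(rows)


def simulate_founders(config: SimConfig, rng=None) -> FounderHaplotypes:
    """Draw inbred founder haplotypes.

    Every locus is polymorphic across founders (minor-allele count of at
    least one founder).  A configurable fraction of adjacent locus pairs is
    forced to exhibit all four gametes across the founder pool, so
    four-gamete-rule blocks are small from the very start; the remaining
    pairs copy the previous locus pattern and show at most two gametes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nf, npl = config.n_founders, config.loci_per_chromosome
    chrom = np.repeat(
        [f"chr{c + 1}" for c in range(config.n_chromosomes)], npl
    ).astype(object)
    pos = np.concatenate(
        [
            np.sort(
                rng.choice(
                    np.arange(1, config.chromosome_length + 1), size=npl, replace=False
                )
            )
            for _ in range(config.n_chromosomes)
        ]
    )

    def random_pattern() -> np.ndarray:
        while True:
            k = rng.integers(1, nf) if nf > 1 else 1
            pat = np.zeros(nf, dtype=np.int8)
            pat[rng.choice(nf, size=k, replace=False)] = 1
            if 0 < pat.sum() < nf or nf == 1:
                return pat

    haps = np.zeros((nf, config.n_loci), dtype=np.int8)
    for c in range(config.n_chromosomes):
        lo = c * npl
        haps[:, lo] = random_pattern()
        for q in range(lo + 1, lo + npl):
            prev = haps[:, q - 1]
            if nf >= 3 and rng.random() < config.founder_four_gamete_fraction:
                for _ in range(200):
                    pat = random_pattern()
                    pairs = {(int(a), int(b)) for a, b in zip(prev, pat)}
                    if len(pairs) == 4:
                        break
                haps[:, q] = pat
            else:
                haps[:, q] = prev
    return FounderHaplotypes(haps, chrom, pos)


def _meiosis(hap_a, hap_b, chrom_bounds, chrom_lengths, pos, rec_rate, rng):
    """One recombinant gamete from a pair of parental haplotypes."""
    gamete = np.empty_like(hap_a)
    for (lo, hi), length in zip(chrom_bounds, chrom_lengths):
        k = rng.poisson(length * rec_rate)
        start = rng.integers(2)
        if k == 0:
            seg = np.full(hi - lo, start)
        else:
            xo = np.sort(rng.integers(1, length + 1, size=k))
            seg = (start + np.searchsorted(xo, pos[lo:hi], side="left")) % 2
        block = np.where(seg == 0, hap_a[lo:hi], hap_b[lo:hi])
        gamete[lo:hi] = block
    return gamete


def _chrom_structure(config: SimConfig):
    bounds = [
        (c * config.loci_per_chromosome, (c + 1) * config.loci_per_chromosome)
        for c in range(config.n_chromosomes)
    ]
    lengths = [config.chromosome_length] * config.n_chromosomes
    return bounds, lengths


def simulate_magic_base(
    founders: FounderHaplotypes, config: SimConfig, rng=None
) -> Population:
    """Intercross the founder pool into a recombinant diploid base population.

    Generation 0 pairs founder haplotypes so that every founder contributes;
    each subsequent intercross generation mates randomly chosen distinct
    parents with Poisson-distributed crossover counts in genetic length.
    With a zero recombination rate every base haplotype is an intact founder
    chromosome.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    bounds, lengths = _chrom_structure(config)
    n = config.n_base
    nf = founders.n_founders
    # ensure all founders contribute to generation 0
    picks0 = np.concatenate([np.arange(nf), rng.integers(0, nf, size=max(0, n - nf))])
    rng.shuffle(picks0)
    picks1 = rng.integers(0, nf, size=n)
    hap0 = founders.haplotypes[picks0].copy()
    hap1 = founders.haplotypes[picks1].copy()
    pop = Population(hap0, hap1, founders.chrom, founders.pos)
    for _ in range(config.n_generations_intercross):
        new0 = np.empty_like(pop.hap0)
        new1 = np.empty_like(pop.hap1)
        for i in range(n):
            pa, pb = rng.choice(n, size=2, replace=False)
            new0[i] = _meiosis(
                pop.hap0[pa], pop.hap1[pa], bounds, lengths, pop.pos,
                config.recombination_rate, rng,
            )
            new1[i] = _meiosis(
                pop.hap0[pb], pop.hap1[pb], bounds, lengths, pop.pos,
                config.recombination_rate, rng,
            )
        pop = Population(new0, new1, pop.chrom, pop.pos)
    return pop


# ---------------------------------------------------------------------------
# Selection experiment
# ---------------------------------------------------------------------------

@dataclass
class SelectionExperiment:
    """Final-generation sequenced individuals plus the causal truth set."""

    genotypes: GenotypeMatrix            # sequenced samples, design attached
    haplotypes: Population               # phased genomes of the same samples
    truth: TruthSet
    config: SimConfig

    @property
    def design(self) -> StudyDesign:
        return self.genotypes.design


def _line_generation(
    dams: Population,
    sires: Population,
    config: SimConfig,
    bounds,
    lengths,
    rng,
) -> Population:
    """Offspring of one line for one generation (rotational families).

    Family ``f`` crosses dam ``f`` with sire ``(f + 1) mod F`` so that every
    family contributes to the next generation.
    """
    f_count = config.families_per_line
    off = config.offspring_per_family
    n_off = f_count * off
    hap0 = np.empty((n_off, dams.hap0.shape[1]), dtype=np.int8)
    hap1 = np.empty_like(hap0)
    for f in range(f_count):
        s = (f + 1) % f_count
        for o in range(off):
            i = f * off + o
            hap0[i] = _meiosis(
                dams.hap0[f], dams.hap1[f], bounds, lengths, dams.pos,
                config.recombination_rate, rng,
            )
            hap1[i] = _meiosis(
                sires.hap0[s], sires.hap1[s], bounds, lengths, sires.pos,
                config.recombination_rate, rng,
            )
    return Population(hap0, hap1, dams.chrom, dams.pos)


def simulate_selection_experiment(
    base: Population, config: SimConfig
) -> SelectionExperiment:
    """Replicated bidirectional within-family selection plus drift.

    For each replicate an independent sample of the base population seeds a
    high and a low line.  Each generation every family produces
    ``offspring_per_family`` offspring; their additive trait (sum of causal
    effects plus Gaussian environmental noise scaled to the heritability) is
    truncation-selected within family -- the top two offspring per family in
    the line's direction -- during the selected generations, and replaced by
    random within-family picks during the relaxed generations.  Returns the
    sequenced final-generation samples and the causal truth set.
    """
    config.validate()
    if base.n < 2 * config.families_per_line:
        raise ValueError("base population smaller than 2 * families_per_line")
    master = np.random.SeedSequence(config.seed + 2)
    causal_ss, *rep_ss = master.spawn(config.n_replicates + 1)
    causal_rng = np.random.default_rng(causal_ss)
    n_loci = base.hap0.shape[1]
    causal = np.sort(
        causal_rng.choice(n_loci, size=config.n_causal_loci, replace=False)
    )
    directions = causal_rng.choice([-1, 1], size=config.n_causal_loci)
    effects = config.effects()
    signed = effects * directions
    bounds, lengths = _chrom_structure(config)

    # environmental variance from the base additive variance and h^2
    base_dosage = base.dosage()[:, causal].astype(float)
    genetic = base_dosage @ signed if config.n_causal_loci else np.zeros(base.n)
    va = float(np.var(genetic))
    h2 = config.heritability
    if h2 >= 1.0:
        ve = 0.0
    elif h2 <= 0.0 or va == 0.0:
        ve = 1.0
    else:
        ve = va * (1.0 - h2) / h2

    n_gen = config.n_generations_total
    traj = np.zeros((2, config.n_replicates, n_gen + 1, max(config.n_causal_loci, 1)))
    per_line_pops: dict[tuple[int, int], Population] = {}
    f_count = config.families_per_line

    for rep in range(config.n_replicates):
        rng = np.random.default_rng(rep_ss[rep])
        founders_idx = rng.choice(base.n, size=4 * f_count, replace=base.n < 4 * f_count)
        for line in range(2):  # 0 = high, 1 = low
            sel = founders_idx[line * 2 * f_count : (line + 1) * 2 * f_count]
            dams = Population(
                base.hap0[sel[:f_count]].copy(),
                base.hap1[sel[:f_count]].copy(),
                base.chrom,
                base.pos,
            )
            sires = Population(
                base.hap0[sel[f_count:]].copy(),
                base.hap1[sel[f_count:]].copy(),
                base.chrom,
                base.pos,
            )
            parents = np.vstack([dams.dosage(), sires.dosage()])
            if config.n_causal_loci:
                traj[line, rep, 0] = parents[:, causal].mean(0) / 2.0
            offspring = None
            for gen in range(1, n_gen + 1):
                offspring = _line_generation(dams, sires, config, bounds, lengths, rng)
                dose = offspring.dosage()[:, causal].astype(float)
                genetic = dose @ signed if config.n_causal_loci else np.zeros(offspring.n)
                trait = genetic + (
                    rng.normal(0.0, np.sqrt(ve), size=offspring.n) if ve > 0 else 0.0
                )
                if config.n_causal_loci:
                    traj[line, rep, gen] = offspring.allele_frequency()[causal]
                per_family = trait.reshape(f_count, config.offspring_per_family)
                if gen <= config.n_generations_selected:
                    order = np.argsort(per_family, axis=1)
                    if line == 0:  # high line: largest trait first
                        order = order[:, ::-1]
                else:  # relaxed selection: random within-family picks
                    order = np.argsort(
                        rng.random(per_family.shape), axis=1
                    )
                first = order[:, 0] + np.arange(f_count) * config.offspring_per_family
                second = (
                    order[:, min(1, config.offspring_per_family - 1)]
                    + np.arange(f_count) * config.offspring_per_family
                )
                dams = Population(
                    offspring.hap0[first], offspring.hap1[first], base.chrom, base.pos
                )
                sires = Population(
                    offspring.hap0[second], offspring.hap1[second], base.chrom, base.pos
                )
            seq = rng.choice(offspring.n, size=config.n_sequenced_per_line, replace=False)
            per_line_pops[(line, rep)] = Population(
                offspring.hap0[seq], offspring.hap1[seq], base.chrom, base.pos
            )

    # assemble the sequenced cohort
    hap0_rows, hap1_rows, names, line_codes, rep_codes = [], [], [], [], []
    labels = ("HIGH", "LOW")
    for line in range(2):
        for rep in range(config.n_replicates):
            pop = per_line_pops[(line, rep)]
            for k in range(pop.n):
                hap0_rows.append(pop.hap0[k])
                hap1_rows.append(pop.hap1[k])
                names.append(f"{labels[line]}_R{rep + 1}_S{k + 1:02d}")
                line_codes.append(line)
                rep_codes.append(rep)
    haps = Population(
        np.array(hap0_rows), np.array(hap1_rows), base.chrom, base.pos
    )
    design = StudyDesign(
        samples=tuple(names),
        line=np.array(line_codes),
        replicate=np.array(rep_codes),
        line_labels=labels,
        replicate_labels=tuple(f"R{j + 1}" for j in range(config.n_replicates)),
    )
    gen_matrix = GenotypeMatrix(
        haps.dosage(), base.chrom, base.pos, tuple(names), design=design
    )
    truth = TruthSet(
        causal_locus_ids=causal,
        effect_directions=directions,
        effect_sizes=effects,
        frequency_trajectories=traj[:, :, :, : max(config.n_causal_loci, 1)],
    )
    return SelectionExperiment(gen_matrix, haps, truth, config)


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------

def simulate_reads(
    genotypes: GenotypeMatrix,
    mean_depth: float = 5.0,
    read_error_rate: float = 0.003,
    seed=None,
) -> ReadCountMatrix:
    """Shallow-sequencing read counts for diploid dosages.

    Total reads per sample x locus are Poisson(``mean_depth``); each read
    reports the non-reference allele with probability
    ``dosage/2 * (1 - e) + (1 - dosage/2) * e`` for per-read flip probability
    ``e``.  Reads are conserved: nr + ref = total in every cell.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0.0 <= read_error_rate < 1.0:
        raise ValueError("read_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = genotypes.dosage
    if np.any(d < 0):
        raise ValueError("missing dosages cannot be sequenced")
    total = rng.poisson(mean_depth, size=d.shape)
    p_alt = (d / 2.0) * (1.0 - read_error_rate) + (1.0 - d / 2.0) * read_error_rate
    nr = rng.binomial(total, p_alt)
    return ReadCountMatrix(
        nr, total, genotypes.chrom, genotypes.pos, genotypes.samples,
        genotypes.ref, genotypes.alt,
    )


def simulate_experiment(config: SimConfig) -> tuple[SelectionExperiment, ReadCountMatrix]:
    """Founders -> intercrossed base -> selection -> shallow reads, one seed."""
    founders = simulate_founders(config)
    base = simulate_magic_base(founders, config)
    experiment = simulate_selection_experiment(base, config)
    reads = simulate_reads(
        experiment.genotypes,
        mean_depth=config.mean_depth,
        read_error_rate=config.read_error_rate,
        seed=np.random.SeedSequence(config.seed + 3),
    )
    return experiment, reads
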
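"""Pairwise LD via EM haplotype frequencies, LD-decay window calibration and
four-gamete-rule haplotype blocks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigsel.genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Two-locus EM
# ---------------------------------------------------------------------------

@dataclass
class GameteTable:
    """Estimated two-locus gamete frequencies for biallelic loci.

    ``freq[(x, y)]`` is the frequency of the gamete carrying allele ``x`` at
    the first locus and ``y`` at the second (1 = non-reference).
    """

    f11: float
    f10: float
    f01: float
    f00: float
    n_samples: int
    converged: bool = True

    @property
    def frequencies(self) -> dict[tuple[int, int], float]:
        return {(1, 1): self.f11, (1, 0): self.f10, (0, 1): self.f01, (0, 0): self.f00}

    @property
    def p1(self) -> float:
        return self.f11 + self.f10

    @property
    def p2(self) -> float:
        return self.f11 + self.f01

    @property
    def d(self) -> float:
        return self.f11 - self.p1 * self.p2

    @property
    def r_squared(self) -> float:
        """D^2 over the product of the four marginal frequencies; NaN if any
        marginal is zero (monomorphic locus)."""
        denom = self.p1 * (1 - self.p1) * self.p2 * (1 - self.p2)
        if denom <= 0:
            return float("nan")
        return self.d**2 / denom

    def n_gametes_observed(self, mgf: float) -> int:
        """Number of gamete classes with estimated frequency above ``mgf``."""
        return sum(f > mgf for f in (self.f11, self.f10, self.f01, self.f00))


def em_gamete_frequencies(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> GameteTable:
    """EM haplotype frequencies for a pair of loci from unphased dosages.

    Started from linkage equilibrium (product of the allele-frequency
    marginals) and iterated until the largest frequency change is below
    ``tol``.  Only the double-heterozygote class is phase-ambiguous; with no
    double heterozygotes the estimate equals direct gamete counting and the
    first iteration already converges.

    Missing dosages are dropped pairwise (complete cases).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok], g2[ok]
    n = g1.size
    if n == 0:
        raise ValueError("no samples with calls at both loci")
    # known haplotype contributions
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1, g2), 1)
    k11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    k10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    k01 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    k00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    dh = counts[1, 1]  # double heterozygotes: (1,1)+(0,0) or (1,0)+(0,1)
    m = 2.0 * n

    p1 = g1.mean() / 2.0
    p2 = g2.mean() / 2.0
    f = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    converged = False
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        x = 0.5 if cis + trans == 0 else cis / (cis + trans)
        new = (
            np.array(
                [k11 + dh * x, k10 + dh * (1 - x), k01 + dh * (1 - x), k00 + dh * x]
            )
            / m
        )
        if np.max(np.abs(new - f)) < tol:
            f = new
            converged = True
            break
        f = new
    return GameteTable(
        f11=float(f[0]),
        f10=float(f[1]),
        f01=float(f[2]),
        f00=float(f[3]),
        n_samples=int(n),
        converged=converged,
    )


def r_squared(table: GameteTable) -> float:
    """Squared correlation of the two-locus gamete table (see GameteTable)."""
    return table.r_squared


# ---------------------------------------------------------------------------
# LD-decay profile and window calibration
# ---------------------------------------------------------------------------

@dataclass
class LDProfile:
    """R^2 distributions at fixed SNP-rank separations, with the derived
    LD_25 distance and scan window size."""

    separations: list[int]
    r2_by_separation: dict[int, np.ndarray]
    bp_by_separation: dict[int, np.ndarray]
    ld25_separation: int | None
    ld25_bp: float | None
    window: int

    def median_r2(self, sep: int) -> float:
        v = self.r2_by_separation[sep]
        return float(np.median(v)) if v.size else float("nan")

    def fraction_below(self, sep: int, cutoff: float) -> float:
        v = self.r2_by_separation[sep]
        return float(np.mean(v < cutoff)) if v.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.separations:
            v = self.r2_by_separation[s]
            rows.append(
                {
                    "separation": s,
                    "n_pairs": v.size,
                    "median_r2": self.median_r2(s),
                    "frac_below_0.25": self.fraction_below(s, 0.25),
                    "frac_below_0.50": self.fraction_below(s, 0.50),
                    "median_bp": float(np.median(self.bp_by_separation[s]))
                    if v.size
                    else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def ld_decay_profile(
    gen: GenotypeMatrix,
    maf_min: float = 0.10,
    separations: list[int] | None = None,
    max_pairs_per_separation: int = 5000,
    r2_cutoff: float = 0.25,
    seed=None,
) -> LDProfile:
    """R^2 decay with SNP-rank separation and the implied scan window.

    Only loci with minor allele frequency above ``maf_min`` qualify.  For
    each separation ``d`` the profile holds R^2 of (bounded random subsample
    of) qualifying pairs ``d`` ranks apart on the same chromosome.  The
    recommended window is the smallest separation whose median R^2 drops
    below ``r2_cutoff`` (the LD_25 when the cutoff is 0.25), forced odd by
    rounding up and never below 3.
    """
    if separations is None:
        separations = list(range(1, 16))
    rng = np.random.default_rng(seed)
    maf = gen.minor_allele_frequency()
    qual = np.flatnonzero(maf > maf_min)
    if qual.size < 2:
        raise ValueError("fewer than two loci pass the MAF filter")
    r2_by: dict[int, list[float]] = {d: [] for d in separations}
    bp_by: dict[int, list[float]] = {d: [] for d in separations}
    for c in pd.unique(gen.chrom):
        on_c = qual[gen.chrom[qual] == c]
        for d in separations:
            if on_c.size <= d:
                continue
            starts = np.arange(on_c.size - d)
            if starts.size > max_pairs_per_separation:
                starts = rng.choice(starts, max_pairs_per_separation, replace=False)
            for s in starts:
                i, j = on_c[s], on_c[s + d]
                tab = em_gamete_frequencies(gen.dosage[:, i], gen.dosage[:, j])
                r2 = tab.r_squared
                if np.isfinite(r2):
                    r2_by[d].append(r2)
                    bp_by[d].append(float(gen.pos[j] - gen.pos[i]))
    if not any(r2_by[d] for d in separations):
        raise ValueError("no qualifying locus pairs for the LD profile")
    ld25_sep = None
    for d in separations:
        vals = r2_by[d]
        if vals and float(np.median(vals)) < r2_cutoff:
            ld25_sep = d
            break
    if ld25_sep is None:
        w = max(separations)
        ld25_bp = None
        warnings.warn(
            f"median R^2 never fell below {r2_cutoff}; using the largest "
            f"examined separation ({w}) for the window",
            stacklevel=2,
        )
    else:
        w = ld25_sep
        ld25_bp = float(np.median(bp_by[ld25_sep]))
    if w % 2 == 0:
        w += 1
    w = max(w, 3)
    return LDProfile(
        separations=separations,
        r2_by_separation={d: np.asarray(r2_by[d]) for d in separations},
        bp_by_separation={d: np.asarray(bp_by[d]) for d in separations},
        ld25_separation=ld25_sep,
        ld25_bp=ld25_bp,
        window=w,
    )


# ---------------------------------------------------------------------------
# Four-gamete-rule haplotype blocks
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    """Maximal run of loci without four-gamete recombination evidence."""

    chrom: str
    start: int              # bp of the first member SNP (1-based, inclusive)
    end: int                # bp of the last member SNP (1-based, inclusive)
    locus_indices: list[int]
    mgf: float

    @property
    def n_loci(self) -> int:
        return len(self.locus_indices)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def four_gamete_blocks(
    gen: GenotypeMatrix, mgf: float = 0.0, maf_min: float = 0.0
) -> list[HaplotypeBlock]:
    """Greedy left-to-right partition of each chromosome into blocks.

    Loci are appended to the open block until the incoming locus shows all
    four gametes (EM-estimated frequency > ``mgf`` for every class) against
    ANY member of the block -- evidence of at least one historical
    recombination -- at which point the incoming locus starts a new block.
    """
    if mgf < 0:
        raise ValueError("mgf must be non-negative")
    maf = gen.minor_allele_frequency()
    blocks: list[HaplotypeBlock] = []
    for c in pd.unique(gen.chrom):
        on_c = np.flatnonzero(
            (gen.chrom == c) & np.isfinite(maf) & (maf > maf_min) & (maf > 0)
        )
        if on_c.size == 0:
            continue
        members: list[int] = [int(on_c[0])]
        for i in on_c[1:]:
            recombined = False
            for j in reversed(members):
                tab = em_gamete_frequencies(gen.dosage[:, j], gen.dosage[:, i])
                if tab.n_gametes_observed(mgf) == 4:
                    recombined = True
                    break
            if recombined:
                blocks.append(
                    HaplotypeBlock(
                        chrom=str(c),
                        start=int(gen.pos[members[0]]),
                        end=int(gen.pos[members[-1]]),
                        locus_indices=members,
                        mgf=mgf,
                    )
                )
                members = [int(i)]
            else:
                members.append(int(i))
        blocks.append(
            HaplotypeBlock(
                chrom=str(c),
                start=int(gen.pos[members[0]]),
                end=int(gen.pos[members[-1]]),
                locus_indices=members,
                mgf=mgf,
            )
        )
    return blocks


def block_summary(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start": [b.start for b in blocks],
            "end": [b.end for b in blocks],
            "n_loci": [b.n_loci for b in blocks],
            "length_bp": [b.length_bp for b in blocks],
            "mgf": [b.mgf for b in blocks],
        }
    )


def median_block_length(blocks: list[HaplotypeBlock], min_loci: int = 2) -> float:
    lengths = [b.length_bp for b in blocks if b.n_loci >= min_loci]
    return float(np.median(lengths)) if lengths else float("nan")


def blocks_to_bed(blocks: list[HaplotypeBlock], path) -> None:
    """BED export: 0-based half-open intervals spanning the member SNPs."""
    with open(path, "w") as fh:
        for k, b in enumerate(blocks):
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\tblock_{k}\t{b.n_loci}\n")


def block_coverage(blocks: list[HaplotypeBlock], n_loci_total: int) -> float:
    """Fraction of qualifying SNPs inside multi-SNP blocks."""
    covered = sum(b.n_loci for b in blocks if b.n_loci >= 2)
    return covered / n_loci_total if n_loci_total else float("nan")


def spine_mgf_search(
    gen: GenotypeMatrix,
    coverage_target: float = 0.95,
    grid: np.ndarray | None = None,
    maf_min: float = 0.0,
) -> tuple[float, list[HaplotypeBlock]]:
    """Smallest MGF on the grid giving a near-continuous spine of blocks.

    Coverage is the fraction of qualifying SNPs contained in blocks of at
    least two SNPs.  Raising the MGF makes recombination evidence stricter
    and blocks larger, so coverage is non-decreasing along the grid; if the
    target is unreachable, the best-covering MGF is returned with a warning.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 0.2501, 0.01), 4)
    maf = gen.minor_allele_frequency()
    n_qual = int(np.sum(np.isfinite(maf) & (maf > maf_min) & (maf > 0)))
    if n_qual == 0:
        raise ValueError("no polymorphic loci")
    best: tuple[float, float, list[HaplotypeBlock]] | None = None
    for mgf in grid:
        blocks = four_gamete_blocks(gen, mgf=float(mgf), maf_min=maf_min)
        cov = block_coverage(blocks, n_qual)
        if cov >= coverage_target:
            return float(mgf), blocks
        if best is None or cov > best[0]:
            best = (cov, float(mgf), blocks)
    warnings.warn(
        f"spine coverage target {coverage_target} unreachable on the MGF grid; "
        f"best achieved {best[0]:.3f} at MGF {best[1]}",
        stacklevel=2,
    )
    return best[1], best[2]
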
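"""Windowed intra-class-correlation (theta) scan for signatures of selection.

Per locus, a 0/1 allele indicator per gamete is decomposed by a nested
random-effects model -- line, replicate within line, sample within
replicate x line, gamete within sample -- using method-of-moments estimates
that support unbalanced cells.  Theta over a window is the ratio of summed
between-line components to summed totals; genome-wide significance comes from
a max-statistic permutation of design labels over gametes or individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigsel.design import StudyDesign
from sigsel.genotypes import MISSING, FrequencyTable, GenotypeMatrix


# ---------------------------------------------------------------------------
# Gamete expansion
# ---------------------------------------------------------------------------

def gamete_indicators(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand sample dosages to per-gamete 0/1 indicators plus a valid mask.

    Gametes of an unphased heterozygote are ordered arbitrarily (row ``2k``
    carries the first copy); the scan statistic depends only on per-sample
    allele counts, so the order is immaterial.
    """
    n_samples, n_loci = dosage.shape
    y = np.zeros((2 * n_samples, n_loci), dtype=np.float64)
    y[0::2] = dosage >= 1
    y[1::2] = dosage == 2
    valid = np.empty((2 * n_samples, n_loci), dtype=np.float64)
    ok = dosage != MISSING
    valid[0::2] = ok
    valid[1::2] = ok
    y *= valid
    return y, valid


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass
class LocusComponents:
    """Per-locus method-of-moments variance components.

    Components may individually be negative (no truncation); a monomorphic
    locus has a zero denominator and is excluded from windows via ``usable``.
    """

    sigma_line: np.ndarray
    sigma_rep: np.ndarray
    sigma_sample: np.ndarray
    sigma_gamete: np.ndarray
    denominator: np.ndarray
    usable: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_loci(self) -> int:
        return self.sigma_line.size

    def theta_single(self) -> np.ndarray:
        """Per-locus theta; NaN where the denominator is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            t = self.sigma_line / self.denominator
        return np.where(self.denominator != 0, t, np.nan)


def _group_sum(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    out = np.zeros((n_groups,) + values.shape[1:], dtype=values.dtype)
    np.add.at(out, codes, values)
    return out


def _components_from_gametes(
    y: np.ndarray,
    valid: np.ndarray,
    design: StudyDesign,
) -> tuple[np.ndarray, ...]:
    """Vectorised nested ANOVA over all loci.

    Returns (sigma_line, sigma_rep, sigma_sample, sigma_gamete, usable).
    Coefficients of the expected sums of squares are the standard
    Henderson-type quantities for unbalanced nested designs, computed per
    locus from the observed (non-missing) gamete counts.
    """
    n_samples = design.n_samples
    n_loci = y.shape[1]
    use_rep = design.n_replicates > 1
    cell_of_sample = design.cell if use_rep else design.line
    n_cells = design.n_cells if use_rep else design.n_lines
    line_of_cell = np.zeros(n_cells, dtype=np.int64)
    line_of_cell[cell_of_sample] = design.line
    n_lines = design.n_lines

    # group sums of data and counts
    t_s = y.reshape(n_samples, 2, n_loci).sum(axis=1)
    n_s = valid.reshape(n_samples, 2, n_loci).sum(axis=1)
    t_c = _group_sum(t_s, cell_of_sample, n_cells)
    n_c = _group_sum(n_s, cell_of_sample, n_cells)
    s2_c = _group_sum(n_s**2, cell_of_sample, n_cells)
    t_l = _group_sum(t_c, line_of_cell, n_lines)
    n_l = _group_sum(n_c, line_of_cell, n_lines)
    s2_l = _group_sum(n_s**2, line_of_cell[cell_of_sample], n_lines)
    c2_l = _group_sum(n_c**2, line_of_cell, n_lines)
    t_tot = t_l.sum(0)
    n_tot = n_l.sum(0)

    with np.errstate(invalid="ignore", divide="ignore"):
        q_s = np.where(n_s > 0, t_s**2 / np.maximum(n_s, 1), 0.0).sum(0)
        q_c = np.where(n_c > 0, t_c**2 / np.maximum(n_c, 1), 0.0).sum(0)
        q_l = np.where(n_l > 0, t_l**2 / np.maximum(n_l, 1), 0.0).sum(0)
        q_g = np.where(n_tot > 0, t_tot**2 / np.maximum(n_tot, 1), 0.0)

        # sums of squares (y is 0/1 so sum(y^2) == sum(y))
        ss_gam = t_tot - q_s
        ss_sam = q_s - q_c
        ss_rep = q_c - q_l
        ss_lin = q_l - q_g

        # per-locus nonempty-group counts and EMS coefficients
        s_plus = (n_s > 0).sum(0)
        c_plus = (n_c > 0).sum(0)
        l_plus = (n_l > 0).sum(0)
        k_s_cell = np.where(n_c > 0, s2_c / np.maximum(n_c, 1), 0.0).sum(0)
        k_s_line = np.where(n_l > 0, s2_l / np.maximum(n_l, 1), 0.0).sum(0)
        k_s_grand = (n_s**2).sum(0) / np.maximum(n_tot, 1)
        k_r_line = np.where(n_l > 0, c2_l / np.maximum(n_l, 1), 0.0).sum(0)
        k_r_grand = (n_c**2).sum(0) / np.maximum(n_tot, 1)
        k_l_grand = (n_l**2).sum(0) / np.maximum(n_tot, 1)

        # back-substitute from the innermost stratum outwards
        c_g = n_tot - s_plus
        sigma_g = np.where(c_g > 0, ss_gam / np.maximum(c_g, 1), 0.0)
        c_s = n_tot - k_s_cell
        sigma_s = np.where(
            c_s > 0, (ss_sam - sigma_g * (s_plus - c_plus)) / np.where(c_s > 0, c_s, 1), 0.0
        )
        if use_rep:
            c_r = n_tot - k_r_line
            sigma_r = np.where(
                c_r > 0,
                (ss_rep - sigma_g * (c_plus - l_plus) - sigma_s * (k_s_cell - k_s_line))
                / np.where(c_r > 0, c_r, 1),
                0.0,
            )
        else:
            sigma_r = np.zeros(n_loci)
        c_l = n_tot - k_l_grand
        sigma_l = np.where(
            c_l > 0,
            (
                ss_lin
                - sigma_g * (l_plus - 1)
                - sigma_s * (k_s_line - k_s_grand)
                - sigma_r * (k_r_line - k_r_grand)
            )
            / np.where(c_l > 0, c_l, 1),
            0.0,
        )

    polymorphic = (t_tot > 0) & (t_tot < n_tot)
    usable = polymorphic & (n_c > 0).all(0) & (c_g > 0)
    return sigma_l, sigma_r, sigma_s, sigma_g, usable


def locus_variance_components(
    gen: GenotypeMatrix, design: StudyDesign | None = None
) -> LocusComponents:
    """Nested variance components of the per-gamete allele indicator.

    Loci with an empty line x replicate cell are flagged unusable, as are
    monomorphic loci (zero denominator).
    """
    if design is None:
        design = gen.design
    if design is None:
        raise ValueError("a StudyDesign is required")
    if design.n_samples != gen.n_samples:
        raise ValueError("design does not match genotype matrix")
    y, valid = gamete_indicators(gen.dosage)
    s_l, s_r, s_s, s_g, usable = _components_from_gametes(y, valid, design)
    return LocusComponents(
        sigma_line=s_l,
        sigma_rep=s_r,
        sigma_sample=s_s,
        sigma_gamete=s_g,
        denominator=s_l + s_r + s_s + s_g,
        usable=usable,
        chrom=gen.chrom,
        pos=gen.pos,
    )


# ---------------------------------------------------------------------------
# Windowed theta
# ---------------------------------------------------------------------------

@dataclass
class ThetaTrack:
    """Windowed theta at focal SNPs (ratio of window sums)."""

    chrom: np.ndarray
    pos: np.ndarray
    theta: np.ndarray
    locus_index: np.ndarray   # index of the focal locus in the source matrix
    window: int

    @property
    def n(self) -> int:
        return self.theta.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "theta": self.theta}
        )


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[w:] - c[:-w]


def windowed_theta(components: LocusComponents, w: int = 7) -> ThetaTrack:
    """Ratio-of-sums theta over sliding windows of ``w`` usable loci.

    The focal SNP is the centre of the window; focal SNPs within
    ``(w - 1) / 2`` usable loci of a chromosome end are not scored.  ``w = 1``
    degenerates to the per-locus theta.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("window size must be odd and >= 1")
    half = w // 2
    chroms, poss, thetas, idxs = [], [], [], []
    for c in pd.unique(components.chrom):
        on_chrom = np.flatnonzero((components.chrom == c) & components.usable)
        if on_chrom.size < w:
            continue
        num = _sliding_sum(components.sigma_line[on_chrom], w)
        den = _sliding_sum(components.denominator[on_chrom], w)
        with np.errstate(invalid="ignore", divide="ignore"):
            th = np.where(den != 0, num / np.where(den != 0, den, 1), np.nan)
        focal = on_chrom[half : on_chrom.size - half]
        chroms.append(np.full(focal.size, c, dtype=object))
        poss.append(components.pos[focal])
        thetas.append(th)
        idxs.append(focal)
    if not chroms:
        empty = np.array([])
        return ThetaTrack(
            np.array([], dtype=object), empty.astype(np.int64), empty, empty.astype(np.int64), w
        )
    return ThetaTrack(
        np.concatenate(chroms),
        np.concatenate(poss),
        np.concatenate(thetas),
        np.concatenate(idxs),
        w,
    )


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    n_permutations: int
    mode: str
    maxima: np.ndarray
    gwp: float
    critical_theta: float
    maxima_by_mode: dict | None = None

    def critical_at(self, gwp: float) -> float:
        """The ceil(gwp * n)-th largest recorded genome-wide maximum."""
        n = self.maxima.size
        k = max(1, min(n, math.ceil(gwp * n)))
        return float(np.sort(self.maxima)[::-1][k - 1])


def _max_theta(y, valid, design, chrom, pos, w):
    s_l, s_r, s_s, s_g, usable = _components_from_gametes(y, valid, design)
    comp = LocusComponents(
        s_l, s_r, s_s, s_g, s_l + s_r + s_s + s_g, usable, chrom, pos
    )
    track = windowed_theta(comp, w)
    if track.n == 0 or np.all(np.isnan(track.theta)):
        return np.nan
    return float(np.nanmax(track.theta))


def genome_permutation_threshold(
    gen: GenotypeMatrix,
    design: StudyDesign | None = None,
    w: int = 7,
    n_permutations: int = 1000,
    gwp: float = 0.01,
    mode: str = "both",
    seed=None,
) -> PermutationResult:
    """Genome-wide critical theta from max-statistic permutations.

    Per permutation, the (line, replicate) label tuples are shuffled once
    genome-wide -- in ``gamete`` mode independently over gametes, in
    ``individual`` mode over whole individuals with their two gametes kept
    together -- and the largest windowed theta across the genome is recorded.
    The critical value is the ceil(gwp * n)-th largest maximum; with
    ``mode='both'`` the larger critical value of the two modes is used.
    """
    if design is None:
        design = gen.design
    if design is None:
        raise ValueError("a StudyDesign is required")
    if not 0 < gwp <= 1:
        raise ValueError("gwp must be in (0, 1]")
    if mode not in {"gamete", "individual", "both"}:
        raise ValueError(f"unknown permutation mode: {mode}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if gwp < 1.0 / n_permutations:
        warnings.warn(
            f"gwp={gwp} finer than 1/{n_permutations} permutations; "
            "threshold is the maximum of the recorded maxima",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    y, valid = gamete_indicators(gen.dosage)
    n_g = y.shape[0]
    n_samples = design.n_samples
    modes = ["gamete", "individual"] if mode == "both" else [mode]
    maxima_by_mode: dict[str, np.ndarray] = {}
    for m in modes:
        maxima = np.empty(n_permutations)
        for b in range(n_permutations):
            if m == "gamete":
                order = rng.permutation(n_g)
            else:
                ps = rng.permutation(n_samples)
                order = np.empty(n_g, dtype=np.int64)
                order[0::2] = 2 * ps
                order[1::2] = 2 * ps + 1
            maxima[b] = _max_theta(
                y[order], valid[order], design, gen.chrom, gen.pos, w
            )
        maxima_by_mode[m] = maxima
    results = {
        m: PermutationResult(n_permutations, m, mx, gwp, 0.0)
        for m, mx in maxima_by_mode.items()
    }
    for r in results.values():
        r.critical_theta = r.critical_at(gwp)
    chosen = max(results.values(), key=lambda r: r.critical_theta)
    return PermutationResult(
        n_permutations=n_permutations,
        mode=mode,
        maxima=chosen.maxima,
        gwp=gwp,
        critical_theta=chosen.critical_theta,
        maxima_by_mode=maxima_by_mode,
    )


# ---------------------------------------------------------------------------
# Signature calls
# ---------------------------------------------------------------------------

@dataclass
class SignatureCall:
    chrom: str
    pos: int
    theta: float
    threshold: float
    locus_index: int
    gene: str | None = None
    region: str | None = None


def call_signatures(track: ThetaTrack, threshold: float) -> list[SignatureCall]:
    """Focal SNPs whose windowed theta strictly exceeds the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    hits = np.flatnonzero(track.theta > threshold)
    calls = [
        SignatureCall(
            chrom=str(track.chrom[i]),
            pos=int(track.pos[i]),
            theta=float(track.theta[i]),
            threshold=float(threshold),
            locus_index=int(track.locus_index[i]),
        )
        for i in hits
    ]
    calls.sort(key=lambda s: (s.chrom, s.pos))
    return calls


def signatures_to_frame(calls: list[SignatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "theta": [c.theta for c in calls],
            "threshold": [c.threshold for c in calls],
            "gene": [c.gene for c in calls],
            "region": [c.region for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Genome-wide pairwise Fst summaries
# ---------------------------------------------------------------------------

def _wc_pairwise_components(p1, p2, n1, n2):
    """Per-locus two-population Fst pieces from pooled-frequency estimates.

    Population-level (uncorrected) index: numerator is the read-weighted
    between-line variance of the frequency, denominator the pooled
    heterozygosity; theta = num / den aggregated as ratio of sums.  Identical
    frequency tables give exactly zero; divergent fixation gives one.
    """
    n_t = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n1 * p1 + n2 * p2) / n_t
        num = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / n_t
        den = pbar * (1 - pbar)
    return num, den - num


def pairwise_fst_summary(freqs: FrequencyTable) -> pd.DataFrame:
    """Genome-wide average pairwise Fst within and across replicates.

    Within each replicate, the two lines are compared directly.  Across
    replicates, SNP frequencies are first averaged over replicates within
    line (read totals summed), then compared -- signatures that drifted in
    opposite directions in the two replicates are averaged away before Fst is
    computed.  All averages are ratio-of-sums over loci.
    """
    lines = freqs.lines
    reps = freqs.replicates
    if len(lines) != 2:
        raise ValueError("pairwise Fst summary requires exactly two lines")
    rows = []
    for rep in reps:
        i1 = freqs.cell(lines[0], rep)
        i2 = freqs.cell(lines[1], rep)
        ok = (
            np.isfinite(freqs.freq[i1])
            & np.isfinite(freqs.freq[i2])
            & (freqs.total[i1] > 1)
            & (freqs.total[i2] > 1)
        )
        a, b = _wc_pairwise_components(
            freqs.freq[i1][ok], freqs.freq[i2][ok], freqs.total[i1][ok], freqs.total[i2][ok]
        )
        rows.append(
            {
                "scope": f"replicate_{rep}",
                "fst": float(a.sum() / (a.sum() + b.sum())),
                "n_loci": int(ok.sum()),
            }
        )
    if len(reps) > 1:
        p_line, n_line = [], []
        for line in lines:
            cells = [freqs.cell(line, rep) for rep in reps]
            f = np.nanmean(freqs.freq[cells], axis=0)
            n = freqs.total[cells].sum(0)
            p_line.append(f)
            n_line.append(n)
        ok = (
            np.isfinite(p_line[0])
            & np.isfinite(p_line[1])
            & (n_line[0] > 1)
            & (n_line[1] > 1)
        )
        a, b = _wc_pairwise_components(
            p_line[0][ok], p_line[1][ok], n_line[0][ok], n_line[1][ok]
        )
        rows.append(
            {
                "scope": "across_replicates",
                "fst": float(a.sum() / (a.sum() + b.sum())),
                "n_loci": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
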
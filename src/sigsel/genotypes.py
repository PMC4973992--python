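"""Genotype and read-count containers, allele-frequency estimation and locus filters.

Coordinates are 1-based inclusive in VCF files and kept 1-based on the
in-memory locus map (``pos``); interval-style outputs (BED) convert to
0-based half-open at write time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from sigsel.design import StudyDesign

MISSING = -1  # dosage code for a missing genotype call


def _as_locus_arrays(chrom, pos, ref=None, alt=None, n=None):
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    if n is None:
        n = pos.size
    if ref is None:
        ref = np.full(n, "A", dtype=object)
    if alt is None:
        alt = np.full(n, "T", dtype=object)
    return chrom, pos, np.asarray(ref, dtype=object), np.asarray(alt, dtype=object)


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on {c}")


@dataclass
class ReadCountMatrix:
    """Per sample x locus non-reference and total read counts."""

    nr: np.ndarray      # (n_samples, n_loci) non-reference reads
    total: np.ndarray   # (n_samples, n_loci) total reads
    chrom: np.ndarray
    pos: np.ndarray
    samples: tuple[str, ...]
    ref: np.ndarray = None
    alt: np.ndarray = None

    def __post_init__(self):
        self.nr = np.asarray(self.nr, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        self.chrom, self.pos, self.ref, self.alt = _as_locus_arrays(
            self.chrom, self.pos, self.ref, self.alt, self.nr.shape[1]
        )
        if self.nr.shape != self.total.shape:
            raise ValueError("nr and total shapes differ")
        if np.any(self.nr < 0) or np.any(self.nr > self.total):
            raise ValueError("need 0 <= nr_reads <= total_reads")
        _check_sorted(self.chrom, self.pos)

    @property
    def n_samples(self) -> int:
        return self.nr.shape[0]

    @property
    def n_loci(self) -> int:
        return self.nr.shape[1]

    def take_loci(self, idx) -> "ReadCountMatrix":
        return ReadCountMatrix(
            self.nr[:, idx],
            self.total[:, idx],
            self.chrom[idx],
            self.pos[idx],
            self.samples,
            self.ref[idx],
            self.alt[idx],
        )


@dataclass
class GenotypeMatrix:
    """Unphased diploid dosages (0/1/2 copies of the non-reference allele)."""

    dosage: np.ndarray  # (n_samples, n_loci) int8; -1 = missing
    chrom: np.ndarray
    pos: np.ndarray
    samples: tuple[str, ...]
    ref: np.ndarray = None
    alt: np.ndarray = None
    design: StudyDesign | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.chrom, self.pos, self.ref, self.alt = _as_locus_arrays(
            self.chrom, self.pos, self.ref, self.alt, self.dosage.shape[1]
        )
        if not np.all(np.isin(np.unique(self.dosage), [MISSING, 0, 1, 2])):
            raise ValueError("dosage values must be in {-1, 0, 1, 2}")
        _check_sorted(self.chrom, self.pos)
        if self.design is not None and self.design.n_samples != self.dosage.shape[0]:
            raise ValueError("design size does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Per-locus non-reference allele frequency over non-missing calls."""
        d = self.dosage
        ok = d >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ok, d, 0).sum(0) / (2.0 * ok.sum(0))

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def take_loci(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.chrom[idx],
            self.pos[idx],
            self.samples,
            self.ref[idx],
            self.alt[idx],
            self.design,
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[idx, :],
            self.chrom,
            self.pos,
            tuple(self.samples[i] for i in idx),
            self.ref,
            self.alt,
            self.design.subset(idx) if self.design is not None else None,
        )

    def attach_design(self, design: StudyDesign) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in design.samples if s not in order]
        if unknown:
            raise ValueError(f"design samples not present in genotypes: {unknown[:5]}")
        idx = np.array([order[s] for s in design.samples])
        out = self.take_samples(idx)
        out.design = design
        return out


@dataclass
class FrequencyTable:
    """Pooled non-reference allele frequency per (line, replicate) cell."""

    freq: np.ndarray     # (n_cells, n_loci); NaN where no reads
    nr: np.ndarray       # pooled non-reference reads per cell
    total: np.ndarray    # pooled total reads per cell
    cell_line: tuple[str, ...]
    cell_replicate: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.nr = np.asarray(self.nr, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        self.chrom, self.pos, _, _ = _as_locus_arrays(
            self.chrom, self.pos, None, None, self.freq.shape[1]
        )

    @property
    def n_cells(self) -> int:
        return self.freq.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freq.shape[1]

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.cell_line))

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.cell_replicate))

    def cell(self, line: str, replicate: str) -> int:
        for i, (l, r) in enumerate(zip(self.cell_line, self.cell_replicate)):
            if l == line and r == replicate:
                return i
        raise KeyError(f"no cell for line={line} replicate={replicate}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_cells):
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": self.chrom,
                        "pos": self.pos,
                        "line": self.cell_line[i],
                        "replicate": self.cell_replicate[i],
                        "nr_reads": self.nr[i],
                        "total_reads": self.total[i],
                        "freq": self.freq[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# VCF and read-count I/O
# ---------------------------------------------------------------------------

def write_vcf(gen: GenotypeMatrix, path) -> None:
    """Write unphased GT-only VCF v4.2."""
    codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(gen.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gen.samples)
            + "\n"
        )
        for j in range(gen.n_loci):
            gts = "\t".join(codes[int(d)] for d in gen.dosage[:, j])
            fh.write(
                f"{gen.chrom[j]}\t{gen.pos[j]}\t.\t{gen.ref[j]}\t{gen.alt[j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path, design: StudyDesign | None = None) -> GenotypeMatrix:
    """Read a VCF into dosages; optionally attach/reorder by a design sheet."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib raises varied types
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    samples = tuple(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt (gts012=False)
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) > 1:
            raise ValueError(f"multi-allelic record at VCF record {i} not supported")
        types = rec.gt_types
        d = np.full(len(samples), MISSING, dtype=np.int8)
        d[types == 0] = 0
        d[types == 1] = 1
        d[types == 3] = 2
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0] if rec.ALT else ".")
        rows.append(d)
    vcf.close()
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gen = GenotypeMatrix(dosage, chrom, pos, samples, ref, alt)
    if design is not None:
        gen = gen.attach_design(design)
    return gen


def write_readcounts(reads: ReadCountMatrix, path) -> None:
    recs = []
    for i, s in enumerate(reads.samples):
        recs.append(
            pd.DataFrame(
                {
                    "chrom": reads.chrom,
                    "pos": reads.pos,
                    "sample": s,
                    "nr_reads": reads.nr[i],
                    "total_reads": reads.total[i],
                }
            )
        )
    pd.concat(recs, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_readcounts(path) -> ReadCountMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "sample", "nr_reads", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"read-count table missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    loci = df[["chrom", "pos"]].drop_duplicates()
    loci = loci.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    key = pd.MultiIndex.from_frame(loci)
    samples = tuple(pd.unique(df["sample"].astype(str)))
    nr = df.pivot_table(
        index="sample", columns=["chrom", "pos"], values="nr_reads", fill_value=0
    ).reindex(index=list(samples), columns=key)
    total = df.pivot_table(
        index="sample", columns=["chrom", "pos"], values="total_reads", fill_value=0
    ).reindex(index=list(samples), columns=key)
    return ReadCountMatrix(
        nr.to_numpy(),
        total.to_numpy(),
        loci["chrom"].to_numpy(dtype=object),
        loci["pos"].to_numpy(),
        samples,
    )


# ---------------------------------------------------------------------------
# Estimators and filters
# ---------------------------------------------------------------------------

def estimate_allele_frequency(
    reads: ReadCountMatrix, design: StudyDesign
) -> FrequencyTable:
    """Pooled-read allele frequencies per line x replicate cell.

    The frequency in each cell is the ratio of summed non-reference reads to
    summed total reads across the cell's samples; cells with zero total reads
    are NaN.
    """
    if reads.n_loci == 0 or reads.n_samples == 0:
        raise ValueError("empty read-count matrix")
    if reads.n_samples != design.n_samples:
        raise ValueError("design does not match read-count matrix samples")
    cells = []
    nr_rows, tot_rows, lines, reps = [], [], [], []
    for i in range(design.n_lines):
        for j in range(design.n_replicates):
            members = (design.line == i) & (design.replicate == j)
            if not members.any():
                continue
            nr_rows.append(reads.nr[members].sum(0))
            tot_rows.append(reads.total[members].sum(0))
            lines.append(design.line_labels[i])
            reps.append(design.replicate_labels[j])
    nr = np.array(nr_rows, dtype=float)
    tot = np.array(tot_rows, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, nr / np.maximum(tot, 1), np.nan)
    return FrequencyTable(freq, nr, tot, tuple(lines), tuple(reps), reads.chrom, reads.pos)


def frequency_from_genotypes(
    gen: GenotypeMatrix, design: StudyDesign | None = None
) -> FrequencyTable:
    """Per-cell allele frequencies from called dosages (2 'reads' per sample).

    Equivalent to :func:`estimate_allele_frequency` on an error-free,
    depth-2 read matrix; useful when exact fixation (frequency 0/1) matters.
    """
    if design is None:
        design = gen.design
    if design is None:
        raise ValueError("a StudyDesign is required")
    d = gen.dosage
    reads = ReadCountMatrix(
        np.where(d > 0, d, 0).astype(np.int64),
        np.where(d >= 0, 2, 0).astype(np.int64),
        gen.chrom,
        gen.pos,
        gen.samples,
        gen.ref,
        gen.alt,
    )
    return estimate_allele_frequency(reads, design)


def call_genotypes(
    reads: ReadCountMatrix,
    min_reads_per_allele: int = 1,
    design: StudyDesign | None = None,
) -> GenotypeMatrix:
    """Naive dosage calls from allele presence.

    Dosage 1 requires both alleles seen at least ``min_reads_per_allele``
    times; otherwise the observed allele is called homozygous.  Sites with no
    reads are missing.  At low depth a true heterozygote is miscalled
    homozygous whenever one allele is unseen (see
    :func:`sigsel.drift.het_miscall_rate`).
    """
    ref_reads = reads.total - reads.nr
    dosage = np.full(reads.nr.shape, MISSING, dtype=np.int8)
    both = (reads.nr >= min_reads_per_allele) & (ref_reads >= min_reads_per_allele)
    dosage[(reads.total > 0) & (reads.nr == 0)] = 0
    dosage[(reads.total > 0) & (ref_reads == 0)] = 2
    dosage[both] = 1
    return GenotypeMatrix(
        dosage, reads.chrom, reads.pos, reads.samples, reads.ref, reads.alt, design
    )


@dataclass
class FilterReport:
    n_input: int
    n_depth_removed: int
    n_error_removed: int
    n_kept: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "depth_cap", "error_screen", "kept"],
                "loci": [
                    self.n_input,
                    self.n_depth_removed,
                    self.n_error_removed,
                    self.n_kept,
                ],
            }
        )


def filter_loci(
    reads: ReadCountMatrix,
    expected_depth: float,
    error_rate: float = 0.003,
    depth_cap_multiple: float = 4.0,
) -> tuple[ReadCountMatrix, FilterReport]:
    """Apply the two locus-level read filters.

    1. depth cap: drop loci whose reads summed over all samples exceed
       ``depth_cap_multiple`` times the expected total
       (``expected_depth * n_samples``) -- putative CNVs/duplications;
    2. error screen: drop loci whose pooled non-reference reads are below
       ``error_rate`` of the pooled total -- consistent with sequencing error.

    Idempotent: both rules depend only on per-locus pooled totals.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be positive")
    pooled_total = reads.total.sum(0)
    pooled_nr = reads.nr.sum(0)
    cap = depth_cap_multiple * expected_depth * reads.n_samples
    too_deep = pooled_total > cap
    erroneous = ~too_deep & (pooled_nr < error_rate * pooled_total)
    keep = ~(too_deep | erroneous)
    report = FilterReport(
        n_input=reads.n_loci,
        n_depth_removed=int(too_deep.sum()),
        n_error_removed=int(erroneous.sum()),
        n_kept=int(keep.sum()),
    )
    return reads.take_loci(np.flatnonzero(keep)), report


def pool_founder_lines(tables: list[FrequencyTable]) -> FrequencyTable:
    """Average per-line allele frequencies into one in-silico pooled line.

    Each input table must describe a single line (one cell) on the same locus
    map.  The pooled frequency is the unweighted mean over lines, matching an
    equal-contribution pool of the founder lines.
    """
    if not tables:
        raise ValueError("no founder tables given")
    first = tables[0]
    for t in tables[1:]:
        if t.n_loci != first.n_loci or np.any(t.pos != first.pos) or np.any(
            t.chrom != first.chrom
        ):
            raise ValueError("founder tables have mismatched locus maps")
    freqs = np.vstack([t.freq.mean(0) for t in tables])
    pooled = freqs.mean(0, keepdims=True)
    nr = np.vstack([t.nr.sum(0) for t in tables]).sum(0, keepdims=True)
    tot = np.vstack([t.total.sum(0) for t in tables]).sum(0, keepdims=True)
    return FrequencyTable(
        pooled, nr, tot, ("pooled",), ("pooled",), first.chrom, first.pos
    )


def min_gamete_frequency_resolution(n_lines: int) -> float:
    """Smallest nonzero gamete frequency in an equal pool of inbred lines.

    Pooling ``n_lines`` lines gives ``2 * n_lines`` gamete slots, so a variant
    present on a single pooled gamete (e.g. one still-segregating founder
    haplotype) has frequency ``1 / (2 * n_lines)``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    return 1.0 / (2.0 * n_lines)
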
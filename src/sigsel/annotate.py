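"""Gene-region partition of the genome and classification of signature calls.

Per gene, bases are partitioned into promoter (10 kb upstream of the TSS,
strand-aware), exon, UTR, intron-exon junction (within 150 bp of an exon
boundary; JR) and deep intron (INJR); everything outside gene bodies and
promoters is intergenic.  Intervals are 0-based half-open internally; GFF
input is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

PROMOTER_LENGTH = 10_000
JUNCTION_LENGTH = 150

REGION_CLASSES = ("promoter", "exon", "utr", "junction", "intron")
# within-gene precedence when classes could claim the same base
_PRECEDENCE = ("exon", "utr", "junction", "intron")


# ---------------------------------------------------------------------------
# Interval helpers (0-based half-open)
# ---------------------------------------------------------------------------

def merge_intervals(intervals):
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base, minus):
    """Bases of ``base`` not covered by ``minus`` (both merged lists)."""
    out = []
    minus = merge_intervals(minus)
    for s, e in merge_intervals(base):
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, min(ms, e)))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals) -> int:
    return sum(e - s for s, e in intervals)


def _contains(intervals, point: int) -> bool:
    return any(s <= point < e for s, e in intervals)


# ---------------------------------------------------------------------------
# Region index
# ---------------------------------------------------------------------------

@dataclass
class GeneRegions:
    gene_id: str
    chrom: str
    strand: str
    tss: int                       # 0-based position of the transcription start
    span: tuple[int, int]          # gene body, half-open
    regions: dict                  # class -> list of (start, end)


@dataclass
class RegionIndex:
    genes: dict
    chrom_sizes: dict | None = None

    def class_intervals(self, cls: str) -> dict:
        """Merged intervals of one class per chromosome, across genes."""
        per_chrom: dict[str, list] = {}
        for g in self.genes.values():
            per_chrom.setdefault(g.chrom, []).extend(g.regions.get(cls, []))
        return {c: merge_intervals(iv) for c, iv in per_chrom.items()}

    def class_sizes(self) -> dict:
        sizes = {}
        for cls in REGION_CLASSES:
            sizes[cls] = sum(total_length(iv) for iv in self.class_intervals(cls).values())
        if self.chrom_sizes:
            genic: dict[str, list] = {c: [] for c in self.chrom_sizes}
            for g in self.genes.values():
                if g.chrom in genic:
                    genic[g.chrom].append(g.span)
                    genic[g.chrom].extend(g.regions.get("promoter", []))
            sizes["intergenic"] = sum(
                size - total_length(merge_intervals(genic.get(c, [])))
                for c, size in self.chrom_sizes.items()
            )
        return sizes


def _gene_regions(gene_id, chrom, strand, gene_span, exons, utrs) -> GeneRegions:
    exons = merge_intervals(exons)
    utrs = merge_intervals(utrs)
    gs, ge = gene_span
    if strand == "+":
        tss = gs
        promoter = [(max(0, tss - PROMOTER_LENGTH), tss)]
    else:
        tss = ge - 1
        promoter = [(ge, ge + PROMOTER_LENGTH)]
    introns = subtract_intervals([gene_span], exons)
    junction, deep = [], []
    if len(exons) > 1:
        for s, e in introns:
            if e - s <= 2 * JUNCTION_LENGTH:
                junction.append((s, e))
            else:
                junction.append((s, s + JUNCTION_LENGTH))
                junction.append((e - JUNCTION_LENGTH, e))
                deep.append((s + JUNCTION_LENGTH, e - JUNCTION_LENGTH))
    else:
        deep = introns  # single-exon genes: no junctions; introns (if any) deep
    exon_only = subtract_intervals(exons, utrs)
    return GeneRegions(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        span=gene_span,
        regions={
            "promoter": merge_intervals(promoter),
            "exon": exon_only,
            "utr": utrs,
            "junction": merge_intervals(junction),
            "intron": merge_intervals(deep),
        },
    )


_UTR_TYPES = {"five_prime_utr", "three_prime_utr", "utr", "5'utr", "3'utr"}
_TRANSCRIPT_TYPES = {"mrna", "transcript"}


def build_region_index(gff_path, chrom_sizes: dict | None = None) -> RegionIndex:
    """Partition gene models from a GFF3/GTF file into region classes.

    Per gene, exons are unioned across transcripts and the TSS is the 5'-most
    transcript start on the coding strand.  Malformed genes are skipped with
    a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    genes: dict[str, GeneRegions] = {}
    for gene in db.features_of_type("gene"):
        try:
            exons, utrs = [], []
            for child in db.children(gene.id):
                iv = (child.start - 1, child.end)  # GFF is 1-based inclusive
                t = child.featuretype.lower()
                if t == "exon":
                    exons.append(iv)
                elif t in _UTR_TYPES:
                    utrs.append(iv)
            if not exons:
                exons = [(gene.start - 1, gene.end)]
            if gene.strand not in {"+", "-"}:
                raise ValueError(f"gene {gene.id} lacks a strand")
            genes[gene.id] = _gene_regions(
                gene.id,
                gene.seqid,
                gene.strand,
                (gene.start - 1, gene.end),
                exons,
                utrs,
            )
        except Exception as exc:
            warnings.warn(f"skipping malformed gene {gene.id}: {exc}", stacklevel=2)
    return RegionIndex(genes=genes, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# Assignment of signature calls
# ---------------------------------------------------------------------------

@dataclass
class RegionAssignment:
    """(call, gene, region) records plus per-gene per-region counts."""

    records: pd.DataFrame
    gene_region_counts: pd.DataFrame  # genes x region classes

    @property
    def n_intergenic(self) -> int:
        return int((self.records["region"] == "intergenic").sum())


def assign_ss_to_regions(calls, index: RegionIndex) -> RegionAssignment:
    """Map each signature call to every overlapping gene's region.

    ``calls`` is any iterable with ``chrom`` and ``pos`` attributes
    (1-based SNP positions).  Within a gene the precedence
    exon > UTR > junction > deep intron resolves a base's label; promoter
    hits are separate records; calls outside all genes and promoters are
    intergenic.  A call overlapping several genes yields one record per gene.
    """
    rows = []
    for call in calls:
        p0 = int(call.pos) - 1
        chrom = str(call.chrom)
        hit_any = False
        for g in index.genes.values():
            if g.chrom != chrom:
                continue
            label = None
            if g.span[0] <= p0 < g.span[1]:
                for cls in _PRECEDENCE:
                    if _contains(g.regions[cls], p0):
                        label = cls
                        break
            elif _contains(g.regions["promoter"], p0):
                label = "promoter"
            if label is not None:
                rows.append(
                    {"chrom": chrom, "pos": int(call.pos), "gene": g.gene_id, "region": label}
                )
                hit_any = True
        if not hit_any:
            rows.append(
                {"chrom": chrom, "pos": int(call.pos), "gene": None, "region": "intergenic"}
            )
    records = pd.DataFrame(rows, columns=["chrom", "pos", "gene", "region"])
    genic = records.dropna(subset=["gene"])
    if len(genic):
        counts = (
            genic.groupby(["gene", "region"]).size().unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame()
    counts = counts.reindex(columns=list(REGION_CLASSES), fill_value=0)
    return RegionAssignment(records=records, gene_region_counts=counts.fillna(0).astype(int))


def region_density(assignment: RegionAssignment, index: RegionIndex) -> pd.DataFrame:
    """Signature count per megabase for each region class.

    Density is the class-wide call count divided by the total merged length
    of the class across the genome; zero-length classes are flagged NaN.
    """
    sizes = index.class_sizes()
    counts = assignment.records["region"].value_counts()
    rows = []
    for cls, size in sizes.items():
        n = int(counts.get(cls, 0))
        density = n / (size / 1e6) if size > 0 else float("nan")
        rows.append({"region": cls, "n_ss": n, "bases": size, "ss_per_mb": density})
    return pd.DataFrame(rows)


def region_count_correlations(
    gene_region_counts: pd.DataFrame,
    n_permutations: int = 10_000,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of per-gene region counts, with permutation p-values.

    p-values are two-sided: the fraction of gene-label permutations whose
    absolute correlation reaches the observed one.  Constant count vectors
    give NaN correlations.
    """
    if len(gene_region_counts) < 3:
        raise ValueError("need counts for at least three genes")
    rng = np.random.default_rng(seed)
    cols = list(gene_region_counts.columns)
    x = gene_region_counts.to_numpy(dtype=float)
    k = len(cols)
    corr = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(corr, 1.0)
    for i, j in combinations(range(k), 2):
        a, b = x[:, i], x[:, j]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        perm_r = np.empty(n_permutations)
        for t in range(n_permutations):
            perm_r[t] = np.corrcoef(a, rng.permutation(b))[0, 1]
        p = float((np.sum(np.abs(perm_r) >= abs(r)) + 1) / (n_permutations + 1))
        corr[i, j] = corr[j, i] = r
        pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(corr, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def index_to_bed(index: RegionIndex, cls: str, path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in sorted(index.class_intervals(cls).items()):
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
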
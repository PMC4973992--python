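"""One-config orchestration: simulate/load -> filter -> calibrate -> scan ->
annotate -> drift FDR, with a checksummed output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sigsel import annotate as annotate_mod
from sigsel import drift as drift_mod
from sigsel import ld as ld_mod
from sigsel import scan as scan_mod
from sigsel.design import StudyDesign
from sigsel.genotypes import (
    call_genotypes,
    estimate_allele_frequency,
    filter_loci,
    read_readcounts,
    read_vcf,
    write_readcounts,
    write_vcf,
)
from sigsel.simulate import SimConfig, simulate_experiment

log = logging.getLogger("sigsel")


@dataclass
class PipelineConfig:
    outdir: str
    # input paths; when all None, a synthetic experiment is simulated
    vcf: str | None = None
    readcounts: str | None = None
    design: str | None = None
    gff: str | None = None
    sim: SimConfig | None = None
    # scan parameters
    window: int | None = None           # None: auto from the LD profile
    n_permutations: int = 1000
    gwp: float = 0.01
    permutation_mode: str = "both"
    # block parameters
    mgf: float | None = None            # None: spine search
    spine_coverage_target: float = 0.95
    # filter parameters
    expected_depth: float = 5.0
    error_rate: float = 0.003
    depth_cap_multiple: float = 4.0
    seed: int = 0
    overwrite: bool = False

    def validate(self) -> None:
        if not 0 < self.gwp < 1:
            raise ValueError("gwp must be in (0, 1)")
        if self.window is not None and self.window % 2 == 0:
            raise ValueError("window must be odd")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the manifest of outputs.

    Deterministic given ``config.seed``.  Any stage failure aborts with the
    stage name and cause.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not config.overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    if config.gwp < 1.0 / config.n_permutations:
        log.warning(
            "gwp=%s is finer than 1/%d permutations", config.gwp, config.n_permutations
        )

    stage = "inputs"
    try:
        if config.readcounts or config.vcf:
            design = StudyDesign.read(config.design) if config.design else None
            if config.readcounts:
                reads = read_readcounts(config.readcounts)
            else:
                gen_in = read_vcf(config.vcf, design)
                # exact counts from called genotypes (depth 2 per sample)
                from sigsel.genotypes import ReadCountMatrix

                d = gen_in.dosage
                reads = ReadCountMatrix(
                    np.where(d > 0, d, 0),
                    np.where(d >= 0, 2, 0),
                    gen_in.chrom,
                    gen_in.pos,
                    gen_in.samples,
                )
                design = gen_in.design
            truth = None
        else:
            sim = config.sim or SimConfig(seed=config.seed)
            experiment, reads = simulate_experiment(sim)
            design = experiment.design
            truth = experiment.truth
            write_vcf(experiment.genotypes, outdir / "simulated.vcf")
            manifest["outputs"]["simulated.vcf"] = _sha256(outdir / "simulated.vcf")
            write_readcounts(reads, outdir / "simulated_readcounts.tsv")
            manifest["outputs"]["simulated_readcounts.tsv"] = _sha256(
                outdir / "simulated_readcounts.tsv"
            )
            design.write(outdir / "design.tsv")
            manifest["outputs"]["design.tsv"] = _sha256(outdir / "design.tsv")
            _write(truth.to_frame(), outdir / "truth.tsv", manifest)
        if design is None:
            raise ValueError("a design sheet is required with read-count input")
        manifest["stages"].append(stage)

        stage = "filter"
        reads, report = filter_loci(
            reads,
            expected_depth=config.expected_depth,
            error_rate=config.error_rate,
            depth_cap_multiple=config.depth_cap_multiple,
        )
        log.info(
            "filter: %d in, %d depth-capped, %d error-screened, %d kept",
            report.n_input, report.n_depth_removed, report.n_error_removed, report.n_kept,
        )
        _write(report.to_frame(), outdir / "filter_report.tsv", manifest)
        manifest["stages"].append(stage)

        stage = "genotypes"
        gen = call_genotypes(reads, design=design)
        freqs = estimate_allele_frequency(reads, design)
        _write(freqs.to_frame(), outdir / "frequencies.tsv", manifest)
        manifest["stages"].append(stage)

        stage = "ld"
        if config.window is None:
            profile = ld_mod.ld_decay_profile(gen, seed=config.seed)
            window = profile.window
            _write(profile.to_frame(), outdir / "ld_profile.tsv", manifest)
        else:
            window = config.window
        log.info("window size: %d SNPs", window)
        manifest["window"] = window
        manifest["stages"].append(stage)

        stage = "blocks"
        if config.mgf is None:
            mgf, blocks = ld_mod.spine_mgf_search(
                gen, coverage_target=config.spine_coverage_target
            )
        else:
            mgf, blocks = config.mgf, ld_mod.four_gamete_blocks(gen, mgf=config.mgf)
        manifest["mgf"] = mgf
        _write(ld_mod.block_summary(blocks), outdir / "blocks.tsv", manifest)
        ld_mod.blocks_to_bed(blocks, outdir / "blocks.bed")
        manifest["outputs"]["blocks.bed"] = _sha256(outdir / "blocks.bed")
        manifest["stages"].append(stage)

        stage = "scan"
        components = scan_mod.locus_variance_components(gen, design)
        track = scan_mod.windowed_theta(components, w=window)
        perm = scan_mod.genome_permutation_threshold(
            gen,
            design,
            w=window,
            n_permutations=config.n_permutations,
            gwp=config.gwp,
            mode=config.permutation_mode,
            seed=config.seed,
        )
        manifest["critical_theta"] = perm.critical_theta
        calls = scan_mod.call_signatures(track, perm.critical_theta)
        _write(track.to_frame(), outdir / "theta_track.tsv", manifest)
        manifest["stages"].append(stage)

        stage = "annotate"
        if config.gff:
            index = annotate_mod.build_region_index(config.gff)
            assignment = annotate_mod.assign_ss_to_regions(calls, index)
            by_call = assignment.records.set_index(["chrom", "pos"])
            for c in calls:
                rows = assignment.records[
                    (assignment.records["chrom"] == c.chrom)
                    & (assignment.records["pos"] == c.pos)
                ]
                if len(rows):
                    c.gene = rows.iloc[0]["gene"]
                    c.region = rows.iloc[0]["region"]
            _write(assignment.records, outdir / "ss_regions.tsv", manifest)
            _write(
                annotate_mod.region_density(assignment, index),
                outdir / "region_density.tsv",
                manifest,
            )
        _write(scan_mod.signatures_to_frame(calls), outdir / "signatures.tsv", manifest)
        manifest["n_signatures"] = len(calls)
        manifest["stages"].append(stage)

        stage = "fdr"
        fst = scan_mod.pairwise_fst_summary(freqs)
        _write(fst, outdir / "fst_summary.tsv", manifest)
        counts = drift_mod.count_fixed_lost(freqs)
        _write(counts.table, outdir / "fixed_lost.tsv", manifest)
        try:
            _write(
                drift_mod.drift_fdr_report(counts), outdir / "drift_fdr.tsv", manifest
            )
        except ValueError as exc:
            log.warning("drift regression skipped: %s", exc)
        manifest["stages"].append(stage)

        stage = "manhattan"
        export_manhattan(track, perm.critical_theta, outdir / "manhattan.tsv")
        manifest["outputs"]["manhattan.tsv"] = _sha256(outdir / "manhattan.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def export_manhattan(track, threshold: float, path, figure_path=None) -> pd.DataFrame:
    """Per-SNP plot table with cumulative genome coordinates and a flag for
    focal SNPs above the threshold; optionally renders the figure."""
    if track.n == 0:
        raise ValueError("empty theta track")
    df = track.to_frame()
    offset = 0
    cum = np.empty(len(df))
    for c in pd.unique(df["chrom"]):
        on_c = df["chrom"] == c
        cum[on_c] = df.loc[on_c, "pos"] + offset
        offset = cum[on_c].max()
    df["genome_pos"] = cum
    df["above_threshold"] = df["theta"] > threshold
    df["threshold"] = threshold
    df.to_csv(path, sep="\t", index=False)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3.5))
        for i, c in enumerate(pd.unique(df["chrom"])):
            on_c = df["chrom"] == c
            ax.scatter(
                df.loc[on_c, "genome_pos"],
                df.loc[on_c, "theta"],
                s=4,
                color=f"C{i % 10}",
            )
        ax.axhline(threshold, color="red", lw=1)
        ax.set_xlabel("genome position")
        ax.set_ylabel(r"windowed $\theta$")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return df
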
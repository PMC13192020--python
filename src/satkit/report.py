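"""End-to-end orchestration and the per-family satellitome report.

Chromosomal organization classes mirror the patterns satDNA families show on
real assemblies: many interspersed arrays across most chromosomes, large
terminal blocks, block sets on a few chromosomes, families confined to a
single chromosome, or one single block. The class thresholds (5% chromosome-
end window, 50% majorities, 3-chromosome minimum for terminal blocks) are
package choices, config-exposed and printed in the report header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from satkit import __version__
from satkit.annotate import build_arrays, find_monomers
from satkit.config import PipelineConfig
from satkit.divergence import Peak, build_landscape, call_peaks, classify_landscape, hit_divergence_records
from satkit.io import write_bed, write_fasta, write_gff3
from satkit.records import GenomeSequence, SatArray
from satkit.simulate import FamilySimSpec, simulate_genome

logger = logging.getLogger("satkit")

DISTRIBUTION_CLASSES = (
    "interspersed",
    "terminal_blocks",
    "block_set",
    "restricted",
    "single_block",
    "absent",
)


def classify_distribution(
    arrays: list[SatArray],
    assembly: list[GenomeSequence],
    chromosomes: list[str] | None = None,
    end_window: float = 0.05,
    majority: float = 0.5,
    min_terminal_chromosomes: int = 3,
) -> str:
    """Distribution class of one family's arrays across an assembly."""
    if not arrays:
        return "absent"
    chrom_ids = chromosomes if chromosomes is not None else [g.seq_id for g in assembly]
    lengths = {g.seq_id: g.length for g in assembly}
    occupied = {a.seq_id for a in arrays}
    if len(occupied) == 1:
        return "single_block" if len(arrays) == 1 else "restricted"
    terminal = [
        a
        for a in arrays
        if min((a.start + a.end) / 2, lengths[a.seq_id] - (a.start + a.end) / 2)
        <= end_window * lengths[a.seq_id]
    ]
    terminal_chroms = {a.seq_id for a in terminal}
    if len(terminal) / len(arrays) >= majority and len(terminal_chroms) >= min_terminal_chromosomes:
        return "terminal_blocks"
    if len(occupied & set(chrom_ids)) / max(1, len(chrom_ids)) >= majority:
        return "interspersed"
    return "block_set"


def _peaks_str(peaks: list[Peak]) -> str:
    return ";".join(f"{p.start_bin}-{p.end_bin}@{p.apex_bin}" for p in peaks)


@dataclass
class PipelineResult:
    outdir: Path
    report: pd.DataFrame
    manifest: dict


def run_pipeline(
    specs: list[FamilySimSpec],
    chromosome_lengths: dict[str, int],
    config: PipelineConfig,
    outdir: str | Path,
    expression_profile: pd.DataFrame | None = None,
    ages: pd.DataFrame | None = None,
) -> PipelineResult:
    """simulate -> annotate -> landscape -> classify, under one run directory.

    Stage outputs (FASTA, truth tables, per-family BED/GFF3, landscape and
    report TSVs) land in ``outdir`` with a manifest recording inputs, resolved
    config, seed and version; a rerun with identical inputs and seed is
    byte-identical. Optional expression/age tables are merged into the report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.log_resolved()

    genome, truth = simulate_genome(specs, chromosome_lengths, config.rng_seed)
    write_fasta(genome, outdir / "genome.fasta")
    truth.write(outdir)

    rows = []
    landscape_rows = []
    for spec in specs:
        fam = spec.family
        hits = find_monomers(genome, fam, config.max_divergence)
        arrays = build_arrays(hits, config.gap_tolerance)
        write_bed(hits, outdir / f"{fam.family_id}.bed")
        write_gff3(hits, outdir / f"{fam.family_id}.gff3")
        records = hit_divergence_records(hits, genome, fam)
        landscape = build_landscape(
            records, config.bin_width, fam.family_id, lengths=[h.length for h in hits]
        )
        peaks = call_peaks(landscape, config.peak_factor, config.peak_rule)
        shape = classify_landscape(peaks)
        for k, v in enumerate(landscape.values):
            lo, hi = landscape.bin_range(k)
            landscape_rows.append(
                dict(family=fam.family_id, bin_low=lo, bin_high=hi, count=int(v),
                     bp=int(landscape.bp_values[k]))
            )
        row = dict(
            family=fam.family_id,
            n_monomers=len(hits),
            n_arrays=len(arrays),
            genome_fraction=sum(h.length for h in hits) / sum(g.length for g in genome),
            distribution_class=classify_distribution(arrays, genome),
            landscape_shape=shape,
            peaks=_peaks_str(peaks),
        )
        rows.append(row)

    report = pd.DataFrame(rows).set_index("family")
    if expression_profile is not None:
        argmax = (
            expression_profile.sort_values("mean_fpkm", ascending=False)
            .groupby("family")
            .first()[["stage", "sex"]]
            .rename(columns={"stage": "peak_stage", "sex": "peak_sex"})
        )
        report = report.join(argmax)
    if ages is not None:
        report = report.join(ages.set_index("family")[["minimal_age", "upper_bound"]])

    pd.DataFrame(landscape_rows).to_csv(outdir / "landscapes.tsv", sep="\t", index=False)
    report.to_csv(outdir / "report.tsv", sep="\t")

    fasta_hash = hashlib.sha256((outdir / "genome.fasta").read_bytes()).hexdigest()
    manifest = dict(
        version=__version__,
        seed=config.rng_seed,
        config=config.to_dict(),
        genome_sha256=fasta_hash,
        families=[s.family.family_id for s in specs],
        chromosomes=chromosome_lengths,
        class_thresholds=dict(end_window=0.05, majority=0.5, min_terminal_chromosomes=3),
    )
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(outdir=outdir, report=report, manifest=manifest)


def regenerate_report(outdir: str | Path) -> pd.DataFrame:
    """Reload the pipeline report from stage TSVs without recomputation."""
    return pd.read_csv(Path(outdir) / "report.tsv", sep="\t").set_index("family")
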
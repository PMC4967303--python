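"""End-to-end orchestration: filter -> ingest -> cluster -> calibrate ->
classify -> de novo -> annotate, with a machine-readable summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .annotate import annotate_genic, chromatin_abundance, genic_summary
from .calibrate import (
    CutoffChoice,
    SensitivityGrid,
    compute_sensitivity_grid,
    fixed_locus_set,
    select_all_cutoffs,
)
from .classify import (
    LocusCall,
    Pedigree,
    allele_frequency_spectrum,
    call_genotypes,
    calls_to_presence_matrix,
    classify_loci,
    de_novo_candidates,
    write_vcf,
)
from .loci import (
    LocusCluster,
    cluster_positions,
    clusters_to_frame,
    compute_support,
    ingest_alignments,
    write_cluster_bed,
)
from .model import SVAConsensusModel, SVAElementAnnotation, load_repeatmasker
from .readfilter import (
    RELAXED_CUTOFF,
    STRINGENT_CUTOFF,
    ScoredReadPair,
    ScoringScheme,
    filter_read_pairs,
    score_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters for one pipeline run."""

    bitscore_cutoff: float = RELAXED_CUTOFF
    relaxed_cutoff: float = RELAXED_CUTOFF
    stringent_cutoff: float = STRINGENT_CUTOFF
    mapq_cutoff: int = 29
    window: int = 500
    target_sensitivity: float = 0.90
    tpm_axis: tuple[float, ...] = tuple(range(0, 21))
    ur_axis: tuple[float, ...] = tuple(range(0, 21))
    selection_order: str = "ur_major"
    seed: int = 0


@dataclass
class PipelineResult:
    config: RunConfig
    pass_fractions: pd.DataFrame
    mapq_fractions: pd.DataFrame
    totals: dict[str, int]
    clusters: list[LocusCluster]
    fixed_loci: list[LocusCluster]
    grid: Optional[SensitivityGrid]
    cutoffs: dict[str, CutoffChoice]
    calls: list[LocusCall]
    spectrum: pd.DataFrame
    de_novo: dict[str, list[dict]]
    summary: dict

    def locus_ids(self) -> set[str]:
        return {c.locus_id for c in self.calls}


def run_stages(
    reads1: Mapping[str, Sequence[tuple[str, str]]],
    sam_path: str | Path,
    annotations: Sequence[SVAElementAnnotation],
    known_catalog: Sequence[tuple[str, int, int]],
    pedigree: Optional[Pedigree],
    model: SVAConsensusModel,
    config: RunConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> PipelineResult:
    """Run every analysis stage on in-memory reads plus a flanking-alignment
    SAM/BAM.  Deterministic: identical inputs and config give an identical
    summary."""
    # stage 1: element-side read scoring and filtering
    scored: list[ScoredReadPair] = []
    for ind in sorted(reads1):
        scored.extend(score_reads(list(reads1[ind]), ind, model, scheme))
    kept, pass_fractions = filter_read_pairs(scored, config.bitscore_cutoff)
    keep_ids = {p.read_id for p in kept}

    # stage 2: flanking-read ingestion (MAPQ filter, TPM totals)
    flanks, totals, mapq_fractions = ingest_alignments(
        sam_path, mapq_cutoff=config.mapq_cutoff, keep_read_ids=keep_ids
    )

    # stage 3: clustering and support
    clusters = compute_support(
        cluster_positions(flanks, window=config.window), totals
    )

    # stage 4: calibration on presumed fixed loci
    individuals = sorted(totals)
    fixed = fixed_locus_set(
        clusters, annotations, known_catalog, model, window=config.window
    )
    grid: Optional[SensitivityGrid] = None
    if fixed:
        grid = compute_sensitivity_grid(
            fixed, individuals, config.tpm_axis, config.ur_axis, totals=totals
        )
        cutoffs = select_all_cutoffs(
            grid, target=config.target_sensitivity, order=config.selection_order
        )
    else:
        cutoffs = {
            ind: CutoffChoice(
                tpm=config.tpm_axis[0], ur=config.ur_axis[0],
                achieved_sensitivity=float("nan"), met_target=False,
            )
            for ind in individuals
        }

    # stage 5: typing and presence genotyping
    calls = classify_loci(
        clusters, annotations, known_catalog, model, window=config.window
    )
    call_genotypes(calls, cutoffs, individuals=individuals)
    spectrum = allele_frequency_spectrum(calls, n_individuals=len(individuals))

    # stage 6: trio de novo filtering
    de_novo = (
        de_novo_candidates(calls, pedigree, repeat_annotations=annotations)
        if pedigree
        else {}
    )

    n_reads_in = sum(len(v) for v in reads1.values())
    type_counts: dict[str, int] = {}
    for c in calls:
        type_counts[c.locus_type] = type_counts.get(c.locus_type, 0) + 1
    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "bitscore_cutoff": config.bitscore_cutoff,
            "mapq_cutoff": config.mapq_cutoff,
            "window": config.window,
            "target_sensitivity": config.target_sensitivity,
            "selection_order": config.selection_order,
        },
        "reads": {
            "input_pairs": n_reads_in,
            "passed_bitscore": len(kept),
            "mapped_flanks_retained": len(flanks),
        },
        "loci": {
            "clusters": len(clusters),
            "presumed_fixed": len(fixed),
            "types": type_counts,
        },
        "cutoffs": {
            ind: {
                "tpm": c.tpm,
                "ur": c.ur,
                "achieved_sensitivity": c.achieved_sensitivity,
                "met_target": c.met_target,
            }
            for ind, c in sorted(cutoffs.items())
        },
        "per_individual_locus_counts": _per_individual_counts(calls, individuals),
        "de_novo_candidates": {k: len(v) for k, v in sorted(de_novo.items())},
    }
    return PipelineResult(
        config=config,
        pass_fractions=pass_fractions,
        mapq_fractions=mapq_fractions,
        totals=totals,
        clusters=clusters,
        fixed_loci=fixed,
        grid=grid,
        cutoffs=cutoffs,
        calls=calls,
        spectrum=spectrum,
        de_novo=de_novo,
        summary=summary,
    )


def _per_individual_counts(
    calls: Sequence[LocusCall], individuals: Sequence[str]
) -> dict[str, dict[str, int]]:
    """Table-1-shaped per-individual counts: all / polymorphic / novel loci
    called present."""
    out = {}
    for ind in individuals:
        present = [c for c in calls if c.presence.get(ind, False)]
        out[ind] = {
            "all": len(present),
            "polymorphic": sum(
                1 for c in present if c.locus_type != "reference_fixed"
            ),
            "novel": sum(
                1 for c in present if c.locus_type == "novel_polymorphic"
            ),
        }
    return out


def run_from_dataset(
    dataset,
    config: Optional[RunConfig] = None,
    workdir: str | Path = ".",
    model: Optional[SVAConsensusModel] = None,
) -> PipelineResult:
    """Convenience wrapper: run the pipeline on a
    :class:`~svascan.simulate.SimulatedDataset`, using its truth SAM as the
    flanking alignments."""
    from .simulate import write_truth_sam

    config = config or RunConfig(seed=dataset.config.seed)
    model = model or SVAConsensusModel.default()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sam_path = workdir / "flanks.sam"
    write_truth_sam(dataset.sam_records, dataset.genome, sam_path)
    return run_stages(
        reads1=dataset.reads1,
        sam_path=sam_path,
        annotations=dataset.annotations,
        known_catalog=dataset.known_polymorphic_catalog(),
        pedigree=dataset.config.pedigree,
        model=model,
        config=config,
    )


def load_catalog(path: str | Path) -> list[tuple[str, int, int]]:
    """Known-polymorphic catalog: BED (contig, start, end) or 2-column TSV
    (contig, position)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) >= 3 and f[2].isdigit():
                out.append((f[0], int(f[1]), int(f[2])))
            else:
                pos = int(f[1])
                out.append((f[0], pos, pos + 1))
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Emit the per-stage report bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.pass_fractions.to_csv(outdir / "read_filter_fractions.tsv", sep="\t", index=False)
    result.mapq_fractions.to_csv(outdir / "mapq_fractions.tsv", sep="\t", index=False)
    clusters_to_frame(result.clusters).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    write_cluster_bed(result.clusters, outdir / "clusters.bed")
    if result.grid is not None:
        result.grid.to_frame().to_csv(outdir / "sensitivity_grid.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "individual": ind,
                "tpm_cutoff": c.tpm,
                "ur_cutoff": c.ur,
                "achieved_sensitivity": c.achieved_sensitivity,
                "met_target": c.met_target,
            }
            for ind, c in sorted(result.cutoffs.items())
        ]
    ).to_csv(outdir / "cutoffs.tsv", sep="\t", index=False)
    calls_to_presence_matrix(result.calls).to_csv(outdir / "call_matrix.tsv", sep="\t")
    write_vcf(result.calls, outdir / "calls.vcf")
    result.spectrum.to_csv(outdir / "allele_frequency_spectrum.tsv", sep="\t")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    fastq_by_individual: Mapping[str, str | Path],
    sam_path: str | Path,
    annotations_path: str | Path,
    catalog_path: Optional[str | Path],
    outdir: str | Path,
    pedigree_path: Optional[str | Path] = None,
    gtf_path: Optional[str | Path] = None,
    chromatin_path: Optional[str | Path] = None,
    config: Optional[RunConfig] = None,
    consensus_fasta: Optional[str | Path] = None,
) -> PipelineResult:
    """File-based end-to-end run; writes the report bundle to ``outdir``."""
    from Bio import SeqIO

    config = config or RunConfig()
    model = (
        SVAConsensusModel.from_fasta(consensus_fasta)
        if consensus_fasta
        else SVAConsensusModel.default()
    )
    annotations = load_repeatmasker(annotations_path, model)
    catalog = load_catalog(catalog_path) if catalog_path else []
    pedigree = Pedigree.from_tsv(pedigree_path) if pedigree_path else None
    reads1 = {
        ind: [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(p), "fastq")]
        for ind, p in fastq_by_individual.items()
    }
    result = run_stages(
        reads1, sam_path, annotations, catalog, pedigree, model, config
    )
    outdir = Path(outdir)
    write_outputs(result, outdir)
    if gtf_path:
        contexts = annotate_genic(result.calls, gtf_path)
        genic_summary(contexts).to_csv(outdir / "genic_annotation.tsv", sep="\t", index=False)
    if chromatin_path:
        chromatin_abundance(result.calls, chromatin_path).to_csv(
            outdir / "chromatin_abundance.tsv", sep="\t", index=False
        )
    return result
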
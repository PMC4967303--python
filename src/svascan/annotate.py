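"""Genic context and chromatin-state abundance of insertion loci.

Each locus is treated as a 1-bp point at its representative position (the
assay localises an insertion junction, not an interval).  Genic categories
are assigned against a GTF with the precedence CDS > UTR > undefined exonic >
intron > intergenic, across all overlapping transcripts, so the categories
partition the loci.  Chromatin-state abundance assigns each locus to the
segmentation interval containing it and normalises insertion counts by the
number of genomic segments in each state (a base-pair denominator is
available as an option).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("CDS", "UTR", "exonic_undefined", "intron", "intergenic")


@dataclass
class GenicContext:
    category: str
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_ORDER:
            raise ValueError(f"unknown genic category {self.category}")


def _load_gtf_trees(gtf_path: str | Path) -> dict[str, dict[str, IntervalTree]]:
    """Per-contig interval trees for gene, exon, CDS and UTR features.

    Records are parsed with gffutils; malformed lines are screened out first
    and skipped with a warning.  GTF coordinates (1-based closed) become
    0-based half-open here.
    """
    import warnings

    import gffutils

    clean_lines: list[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or not (f[3].isdigit() and f[4].isdigit()):
                warnings.warn(f"{gtf_path}:{lineno}: malformed GTF record; skipped")
                continue
            clean_lines.append(line)
    db = gffutils.create_db(
        "".join(clean_lines),
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    trees: dict[str, dict[str, IntervalTree]] = {
        k: defaultdict(IntervalTree) for k in ("gene", "exon", "CDS", "UTR")
    }
    wanted = {
        "gene": "gene",
        "exon": "exon",
        "cds": "CDS",
        "utr": "UTR",
        "five_prime_utr": "UTR",
        "three_prime_utr": "UTR",
    }
    for feat in db.all_features():
        kind = wanted.get(feat.featuretype.lower())
        if kind is None:
            continue
        start, end = feat.start - 1, feat.end
        if end <= start:
            continue
        gene_id = (feat.attributes.get("gene_id") or [""])[0]
        trees[kind][feat.seqid].addi(start, end, gene_id)
    return trees


def annotate_genic(
    loci: Sequence[tuple[str, int, str]] | Sequence,
    gtf_path: str | Path,
) -> dict[str, GenicContext]:
    """Genic category per locus.

    ``loci`` may be (contig, position, locus_id) tuples or objects with
    ``contig``, ``representative`` and ``locus_id`` attributes (clusters or
    calls).  Returns locus_id -> GenicContext.
    """
    trees = _load_gtf_trees(gtf_path)
    out: dict[str, GenicContext] = {}
    for locus in loci:
        contig, pos, locus_id = _as_point(locus)
        point = lambda feat: trees[feat][contig][pos] if contig in trees[feat] else set()
        cds = point("CDS")
        utr = point("UTR")
        exon = point("exon")
        gene = point("gene")
        if cds:
            cat, hits = "CDS", cds
        elif utr:
            cat, hits = "UTR", utr
        elif exon:
            cat, hits = "exonic_undefined", exon
        elif gene:
            cat, hits = "intron", gene
        else:
            cat, hits = "intergenic", set()
        out[locus_id] = GenicContext(
            category=cat,
            gene_ids=tuple(sorted({iv.data for iv in hits if iv.data})),
        )
    return out


def _as_point(locus) -> tuple[str, int, str]:
    if isinstance(locus, tuple):
        return locus
    cluster = getattr(locus, "cluster", locus)
    return (cluster.contig, cluster.representative, cluster.locus_id)


def genic_summary(contexts: Mapping[str, GenicContext]) -> pd.DataFrame:
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for ctx in contexts.values():
        counts[ctx.category] += 1
    return pd.DataFrame(
        {"category": list(counts), "n_loci": list(counts.values())}
    )


def read_segmentation(path: str | Path) -> pd.DataFrame:
    """ChromHMM-style BED4: chrom, start, end, state label."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["contig", "start", "end", "state"],
        dtype={"contig": str, "start": int, "end": int, "state": str},
    )
    return frame


def chromatin_abundance(
    loci: Sequence,
    segmentation: pd.DataFrame | str | Path,
    basis: str = "segments",
) -> pd.DataFrame:
    """Normalised insertion abundance per chromatin state.

    Each locus point is assigned to the segment containing it; abundance is
    insertion count divided by the total number of segments in the state
    (``basis='bp'`` divides by the state's base-pair total instead).  Loci
    outside every segment are tallied under an ``unsegmented`` state with no
    normalisation.
    """
    if not isinstance(segmentation, pd.DataFrame):
        segmentation = read_segmentation(segmentation)
    if basis not in ("segments", "bp"):
        raise ValueError("basis must be 'segments' or 'bp'")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in segmentation.itertuples(index=False):
        trees[row.contig].addi(row.start, row.end, row.state)
    counts: dict[str, int] = defaultdict(int)
    for locus in loci:
        contig, pos, _ = _as_point(locus)
        hits = trees[contig][pos] if contig in trees else set()
        if hits:
            # deterministic tie-break on overlapping segments: first by label
            state = sorted(iv.data for iv in hits)[0]
            counts[state] += 1
        else:
            counts["unsegmented"] += 1
    denom = (
        segmentation.groupby("state").size()
        if basis == "segments"
        else (segmentation["end"] - segmentation["start"]).groupby(segmentation["state"]).sum()
    )
    states = sorted(set(denom.index) | set(counts))
    rows = []
    for state in states:
        n_ins = counts.get(state, 0)
        n_seg = int(denom.get(state, 0))
        rows.append(
            {
                "state": state,
                "n_insertions": n_ins,
                "n_segments" if basis == "segments" else "n_bp": n_seg,
                "normalized_abundance": (n_ins / n_seg) if n_seg else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def chromatin_abundance_by_cell_line(
    loci: Sequence,
    segmentations: Mapping[str, pd.DataFrame | str | Path],
    basis: str = "segments",
) -> dict[str, pd.DataFrame]:
    """One abundance table per cell line."""
    return {
        cell: chromatin_abundance(loci, seg, basis=basis)
        for cell, seg in segmentations.items()
    }
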
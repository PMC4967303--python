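"""Flanking-read ingestion, 500-bp clustering and per-locus support.

The genome-side mate of each retained read pair (the "Flanking Read") is
mapped by an external aligner (or emitted pre-aligned by the simulator's
truth writer).  Alignments are filtered at MAPQ >= 29 to exclude multi-mapping
reads, sorted, and chained into candidate insertion loci: consecutive
same-contig, same-strand insertion-proximal coordinates join one cluster when
they differ by at most the 500-bp window.  Within a cluster the member
coordinate closest to the element junction is the representative insertion
position (maximal on the plus strand, minimal on the minus strand, because
the sequenced flank lies 5' of the element).

Per-locus, per-individual support:

* depth - member read count;
* UR    - "unique reads", distinct (contig, 5'-most aligned coordinate,
          strand) keys, a PCR-duplicate surrogate;
* TPM   - tags per million, depth / individual's total mapped reads * 1e6.

The TPM denominator is the individual's total mapped-read count before MAPQ
filtering (switchable to post-filter totals).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_CUTOFF = 29
DEFAULT_WINDOW = 500


@dataclass(frozen=True)
class MappedFlank:
    """One filtered flanking-read alignment (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str
    mapq: int
    individual: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: empty alignment interval")
        if self.mapq < 0:
            raise ValueError(f"{self.read_id}: negative MAPQ")

    @property
    def proximal(self) -> int:
        """Alignment endpoint nearest the inferred element junction: the end
        for plus-strand flanks (element to the right), the start for minus."""
        return self.end if self.strand == "+" else self.start

    @property
    def dedup_key(self) -> tuple[str, int, str]:
        """(contig, 5'-most aligned coordinate, strand)."""
        five_prime = self.start if self.strand == "+" else self.end
        return (self.contig, five_prime, self.strand)


@dataclass
class LocusCluster:
    """A candidate insertion locus with per-individual support."""

    contig: str
    strand: str
    representative: int
    members: list[MappedFlank] = field(default_factory=list)
    support: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.representative}:{self.strand}"

    def individuals(self) -> list[str]:
        return sorted({m.individual for m in self.members})


def ingest_alignments(
    path: str | Path,
    mapq_cutoff: int = DEFAULT_MAPQ_CUTOFF,
    individual: Optional[str] = None,
    keep_read_ids: Optional[set[str]] = None,
) -> tuple[list[MappedFlank], dict[str, int], pd.DataFrame]:
    """Read a SAM/BAM of flanking-read alignments.

    Individuals come from each record's read group (``RG`` -> header ``SM``),
    falling back to ``individual`` when given; a record with neither is an
    error.  Unmapped, secondary and supplementary records are dropped; the
    per-individual mapped-read totals (pre-MAPQ, for TPM denominators) are
    counted before the MAPQ cutoff is applied.  ``keep_read_ids`` optionally
    restricts to reads whose mate passed the bit-score filter.

    Returns (flanks, totals, per-individual retained-fraction table).
    """
    totals: dict[str, int] = defaultdict(int)
    passed: dict[str, int] = defaultdict(int)
    flanks: list[MappedFlank] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        rg_to_sample = {
            rg.get("ID"): rg.get("SM", rg.get("ID"))
            for rg in af.header.to_dict().get("RG", [])
        }
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("RG"):
                ind = rg_to_sample.get(rec.get_tag("RG"), rec.get_tag("RG"))
            elif individual is not None:
                ind = individual
            else:
                raise ValueError(
                    f"record {rec.query_name}: no read group and no individual given"
                )
            totals[ind] += 1
            if rec.mapping_quality < mapq_cutoff:
                continue
            if keep_read_ids is not None and rec.query_name not in keep_read_ids:
                continue
            passed[ind] += 1
            flanks.append(
                MappedFlank(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    individual=ind,
                    read_id=rec.query_name,
                )
            )
    frac = pd.DataFrame(
        [
            {
                "individual": ind,
                "n_mapped": totals[ind],
                "n_retained": passed.get(ind, 0),
                "fraction": passed.get(ind, 0) / totals[ind] if totals[ind] else 0.0,
            }
            for ind in sorted(totals)
        ]
    )
    return flanks, dict(totals), frac


def cluster_positions(
    flanks: Sequence[MappedFlank], window: int = DEFAULT_WINDOW
) -> list[LocusCluster]:
    """Single-linkage chaining of insertion-proximal coordinates.

    Flanks are sorted by (contig, strand, proximal coordinate); consecutive
    coordinates on one contig and strand join a cluster iff they differ by at
    most ``window``.  Output is invariant to input order.
    """
    ordered = sorted(flanks, key=lambda f: (f.contig, f.strand, f.proximal))
    clusters: list[LocusCluster] = []
    current: list[MappedFlank] = []

    def _flush() -> None:
        if not current:
            return
        coords = [m.proximal for m in current]
        rep = max(coords) if current[0].strand == "+" else min(coords)
        clusters.append(
            LocusCluster(
                contig=current[0].contig,
                strand=current[0].strand,
                representative=rep,
                members=list(current),
            )
        )

    for f in ordered:
        if (
            current
            and f.contig == current[-1].contig
            and f.strand == current[-1].strand
            and f.proximal - current[-1].proximal <= window
        ):
            current.append(f)
        else:
            _flush()
            current = [f]
    _flush()
    return clusters


def compute_support(
    clusters: Iterable[LocusCluster], totals: Mapping[str, int]
) -> list[LocusCluster]:
    """Fill per-individual depth / UR / TPM on each cluster (in place).

    ``totals`` maps individual -> total mapped reads (the TPM denominator);
    an individual present in a cluster with a zero or missing total is an
    error.  TPM is rounded to 2 decimals.
    """
    clusters = list(clusters)
    for cl in clusters:
        support: dict[str, dict[str, float]] = {}
        by_ind: dict[str, list[MappedFlank]] = defaultdict(list)
        for m in cl.members:
            by_ind[m.individual].append(m)
        for ind, members in by_ind.items():
            total = totals.get(ind, 0)
            if total <= 0:
                raise ValueError(
                    f"individual {ind} has zero total mapped reads; cannot compute TPM"
                )
            depth = len(members)
            ur = len({m.dedup_key for m in members})
            support[ind] = {
                "depth": depth,
                "ur": ur,
                "tpm": round(depth / total * 1e6, 2),
            }
        cl.support = support
    return clusters


def clusters_to_frame(clusters: Sequence[LocusCluster]) -> pd.DataFrame:
    """Long-format support table: one row per (locus, individual)."""
    rows = []
    for cl in clusters:
        for ind, sup in sorted(cl.support.items()):
            rows.append(
                {
                    "locus_id": cl.locus_id,
                    "contig": cl.contig,
                    "position": cl.representative,
                    "strand": cl.strand,
                    "individual": ind,
                    "depth": int(sup["depth"]),
                    "ur": int(sup["ur"]),
                    "tpm": sup["tpm"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "contig",
            "position",
            "strand",
            "individual",
            "depth",
            "ur",
            "tpm",
        ],
    )


def write_cluster_bed(clusters: Sequence[LocusCluster], path: str | Path) -> None:
    """Representative positions as 1-bp BED6 intervals."""
    with open(path, "w") as fh:
        for cl in sorted(clusters, key=lambda c: (c.contig, c.representative)):
            fh.write(
                f"{cl.contig}\t{cl.representative}\t{cl.representative + 1}"
                f"\t{cl.locus_id}\t{len(cl.members)}\t{cl.strand}\n"
            )
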
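"""Locus typing, presence genotyping, frequency spectra and trio filtering.

Candidate loci fall into three disjoint types: reference fixed (on an
amplifiable reference-genome element not reported polymorphic), known
polymorphic (matching a user-supplied catalog of previously reported
insertions), or novel polymorphic (matching neither).  Presence genotypes are
binary -- the single-sided assay cannot separate heterozygous from homozygous
carriers -- and an individual is called a carrier at a locus when its TPM and
UR support both meet that individual's calibrated cutoffs.

Trio de novo candidates in an offspring are loci absent from both parents and
from every unrelated individual in the cohort (shared loci are background).
Because the germline retrotransposition rate is on the order of one event in
~916 births, the chance of a true de novo insertion among six offspring is
below 1%, so surviving candidates deserve suspicion: those sitting inside
annotated repeats are flagged as the typical false-positive mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .calibrate import CutoffChoice
from .loci import LocusCluster
from .model import SVAConsensusModel, SVAElementAnnotation, is_amplifiable

logger = logging.getLogger(__name__)

REFERENCE_FIXED = "reference_fixed"
KNOWN_POLYMORPHIC = "known_polymorphic"
NOVEL_POLYMORPHIC = "novel_polymorphic"
LOCUS_TYPES = (REFERENCE_FIXED, KNOWN_POLYMORPHIC, NOVEL_POLYMORPHIC)


@dataclass
class LocusCall:
    """One typed candidate locus with per-individual presence calls."""

    cluster: LocusCluster
    locus_type: str
    presence: dict[str, bool] = field(default_factory=dict)

    @property
    def locus_id(self) -> str:
        return self.cluster.locus_id

    @property
    def carrier_count(self) -> int:
        return sum(self.presence.values())

    def carriers(self) -> set[str]:
        return {ind for ind, p in self.presence.items() if p}


@dataclass
class Pedigree:
    """Trios (father, mother, offspring) plus unrelated singletons."""

    trios: list[tuple[str, str, str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set(self.individuals())
        for father, mother, child in self.trios:
            if father == child or mother == child:
                raise ValueError(f"pedigree cycle at offspring {child}")

    def individuals(self) -> list[str]:
        out: list[str] = []
        for f, m, c in self.trios:
            out.extend([f, m, c])
        out.extend(self.singletons)
        return sorted(set(out))

    def offspring(self) -> list[str]:
        return [c for _, _, c in self.trios]

    def parents_of(self, child: str) -> Optional[tuple[str, str]]:
        for f, m, c in self.trios:
            if c == child:
                return (f, m)
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        """TSV columns: individual, father, mother, population ('.' or empty
        for founders/singletons)."""
        frame = pd.read_csv(
            path, sep="\t", dtype=str, comment="#",
            names=["individual", "father", "mother", "population"],
        ).fillna(".")
        trios, singles, pops = [], [], {}
        declared = set(frame["individual"])
        for _, row in frame.iterrows():
            pops[row["individual"]] = row["population"]
            f, m = row["father"], row["mother"]
            if f not in (".", "") and m not in (".", ""):
                if f not in declared or m not in declared:
                    raise ValueError(
                        f"{row['individual']}: parent not declared in pedigree"
                    )
                trios.append((f, m, row["individual"]))
        children = {c for _, _, c in trios}
        parents = {p for f, m, _ in trios for p in (f, m)}
        singles = [
            i for i in declared if i not in children and i not in parents
        ]
        return cls(trios=trios, singletons=sorted(singles), populations=pops)


def classify_loci(
    clusters: Sequence[LocusCluster],
    annotations: Sequence[SVAElementAnnotation],
    known_polymorphic: Sequence[tuple[str, int, int]],
    model: SVAConsensusModel,
    window: int = 500,
) -> list[LocusCall]:
    """Assign exactly one type to every cluster.

    Catalog matches win over reference matches (a reference element that is
    also in the known-polymorphic catalog types as known polymorphic); a
    cluster near an amplifiable reference element and not in the catalog is
    reference fixed; everything else is novel polymorphic.
    """
    amp = [a for a in annotations if is_amplifiable(a, model)]
    calls = []
    for cl in clusters:
        near_poly = any(
            contig == cl.contig
            and s - window <= cl.representative <= e + window
            for contig, s, e in known_polymorphic
        )
        if near_poly:
            ltype = KNOWN_POLYMORPHIC
        else:
            near_ref = any(
                a.contig == cl.contig
                and a.start - window <= cl.representative <= a.end + window
                for a in amp
            )
            ltype = REFERENCE_FIXED if near_ref else NOVEL_POLYMORPHIC
        calls.append(LocusCall(cluster=cl, locus_type=ltype))
    return calls


def call_genotypes(
    calls: Sequence[LocusCall],
    cutoffs: Mapping[str, CutoffChoice],
    individuals: Optional[Sequence[str]] = None,
) -> list[LocusCall]:
    """Binary presence calls: present iff TPM >= the individual's TPM cutoff
    AND UR >= its UR cutoff (filled in place, returned for chaining)."""
    if individuals is None:
        individuals = sorted(k for k in cutoffs if k != "pooled")
    for call in calls:
        presence = {}
        for ind in individuals:
            cut = cutoffs[ind]
            sup = call.cluster.support.get(ind, {})
            presence[ind] = (
                sup.get("tpm", 0.0) >= cut.tpm and sup.get("ur", 0.0) >= cut.ur
            )
        call.presence = presence
    return list(calls)


def allele_frequency_spectrum(
    calls: Sequence[LocusCall], n_individuals: Optional[int] = None
) -> pd.DataFrame:
    """Carrier-count spectrum of polymorphic loci.

    Returns a DataFrame indexed by carrier count 1..N with, per category
    (known polymorphic / novel polymorphic / their union), the fraction of
    that category's loci carried by exactly that many individuals.
    """
    poly = [c for c in calls if c.locus_type != REFERENCE_FIXED]
    if n_individuals is None:
        n_individuals = max((len(c.presence) for c in calls), default=0)
    idx = pd.Index(range(1, n_individuals + 1), name="carrier_count")
    cats = {
        KNOWN_POLYMORPHIC: [c for c in poly if c.locus_type == KNOWN_POLYMORPHIC],
        NOVEL_POLYMORPHIC: [c for c in poly if c.locus_type == NOVEL_POLYMORPHIC],
        "all_polymorphic": poly,
    }
    out = {}
    for name, group in cats.items():
        counts = pd.Series(0, index=idx, dtype=float)
        carried = [c.carrier_count for c in group if c.carrier_count > 0]
        for k in carried:
            counts.loc[k] += 1
        out[name] = counts / len(carried) if carried else counts
    return pd.DataFrame(out)


def de_novo_candidates(
    calls: Sequence[LocusCall],
    pedigree: Pedigree,
    repeat_annotations: Sequence[SVAElementAnnotation] = (),
    min_evidence_depth: int = 1,
) -> dict[str, list[dict]]:
    """Per-offspring de novo candidate loci.

    A locus called present in an offspring is removed when any other
    individual of the cohort -- parent or unrelated background -- shows the
    insertion.  "Shows" is deliberately weaker than the discovery call:
    either a presence call at the calibrated cutoffs or raw read support of
    at least ``min_evidence_depth`` removes the candidate, because discarding
    a candidate needs far less evidence than asserting a novel insertion.
    Surviving candidates carry an ``in_repeat`` flag when the representative
    position falls inside an annotated repeat, the characteristic
    false-positive mode.  Offspring missing a parent in the call matrix are
    skipped with a warning.
    """
    out: dict[str, list[dict]] = {}
    for father, mother, child in pedigree.trios:
        sample_inds = set(calls[0].presence) if calls else set()
        if calls and (father not in sample_inds or mother not in sample_inds):
            warnings.warn(f"offspring {child}: missing parent calls; skipped")
            continue
        cands = []
        for call in calls:
            if not call.presence.get(child, False):
                continue
            others = {
                ind
                for ind in call.presence
                if ind != child
                and (
                    call.presence[ind]
                    or call.cluster.support.get(ind, {}).get("depth", 0)
                    >= min_evidence_depth
                )
            }
            if others:
                continue  # in a parent or shared with background
            in_repeat = any(
                a.contig == call.cluster.contig
                and a.start <= call.cluster.representative < a.end
                for a in repeat_annotations
            )
            cands.append(
                {
                    "locus_id": call.locus_id,
                    "locus_type": call.locus_type,
                    "in_repeat": in_repeat,
                }
            )
        out[child] = cands
    return out


def de_novo_probability(rate_per_birth: float, n_offspring: int) -> float:
    """Chance of observing at least one germline insertion among
    ``n_offspring`` births at a per-birth rate: 1 - (1 - rate)^n."""
    if not (0.0 < rate_per_birth <= 1.0):
        raise ValueError("rate must be in (0, 1]")
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    return 1.0 - (1.0 - rate_per_birth) ** n_offspring


def concordance_report(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> pd.DataFrame:
    """Genotype-concordance bookkeeping between two presence matrices
    (loci x individuals, boolean).  Compares the shared loci/individuals and
    reports per-locus and overall agreement fractions."""
    loci = calls_a.index.intersection(calls_b.index)
    inds = calls_a.columns.intersection(calls_b.columns)
    if len(loci) == 0 or len(inds) == 0:
        raise ValueError("no shared loci or individuals to compare")
    a = calls_a.loc[loci, inds].astype(bool)
    b = calls_b.loc[loci, inds].astype(bool)
    agree = a.eq(b)
    rows = [
        {
            "locus_id": locus,
            "n_compared": len(inds),
            "n_agree": int(agree.loc[locus].sum()),
            "concordance": float(agree.loc[locus].mean()),
        }
        for locus in loci
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["overall_concordance"] = float(agree.to_numpy().mean())
    return frame


def calls_to_presence_matrix(calls: Sequence[LocusCall]) -> pd.DataFrame:
    inds = sorted({i for c in calls for i in c.presence})
    return pd.DataFrame(
        {ind: [c.presence.get(ind, False) for c in calls] for ind in inds},
        index=pd.Index([c.locus_id for c in calls], name="locus_id"),
    )


def write_vcf(
    calls: Sequence[LocusCall],
    path: str | Path,
    individuals: Optional[Sequence[str]] = None,
) -> None:
    """VCF-like output with symbolic <INS:ME:SVA> alleles and per-sample
    presence genotypes (1 = insertion present, 0 = absent)."""
    if individuals is None:
        individuals = sorted({i for c in calls for i in c.presence})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS:ME:SVA,Description="SVA insertion">\n')
        fh.write(
            '##INFO=<ID=LTYPE,Number=1,Type=String,Description="Locus type">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Presence call">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for c in sorted(calls, key=lambda c: (c.cluster.contig, c.cluster.representative)):
            gts = "\t".join(
                "1" if c.presence.get(ind, False) else "0" for ind in individuals
            )
            fh.write(
                f"{c.cluster.contig}\t{c.cluster.representative + 1}\t{c.locus_id}"
                f"\tN\t<INS:ME:SVA>\t.\tPASS\tLTYPE={c.locus_type}\tGT\t{gts}\n"
            )
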
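"""Synthetic genomes, cohorts and targeted-sequencing libraries with truth.

The generator emulates the data the targeted SVA assay produces, end to end,
at desk scale:

* a toy reference genome carrying annotated fixed SVA elements of
  subfamilies SVA_D/E/F with subfamily-specific divergence from the
  consensus, variable hexamer-run length and optional 5' truncation;
* polymorphic insertions absent from the reference (known-catalog and novel),
  with founder genotypes drawn from Hardy-Weinberg at per-locus allele
  frequencies and offspring genotypes transmitted Mendelianly through trios;
  optional planted de novo insertions in named offspring;
* a library of read pairs: read 1 (the element-side "SVA Read") is the
  element-proximal end of each fragment, carrying (part of) the hexamer run
  and the 40-bp Alu-like region; read 2 (the "Flanking Read") samples the
  element's 5' genomic flank.  Uniform per-base sequencing error is applied;
  a configurable fraction of off-target noise pairs is mixed in.
* complete truth: planted-insertion table, genotype matrix, per-read
  provenance, and an error-free flanking-read alignment SAM (MAPQ 60) that
  can stand in for an external mapper's output.

Elements that lost either nested primer-binding site to truncation are not
amplifiable and emit no on-target pairs, exactly as the wet protocol would
drop them.  All randomness flows from one seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import Pedigree
from .model import (
    SVAConsensusModel,
    SVAElementAnnotation,
    is_amplifiable,
)
from .readfilter import revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

FIXED = "fixed"
KNOWN = "known_polymorphic"
NOVEL = "novel_polymorphic"
DE_NOVO = "de_novo"


def default_pedigree() -> Pedigree:
    """Two parent-offspring trios (six individuals)."""
    return Pedigree(
        trios=[("F1", "M1", "C1"), ("F2", "M2", "C2")],
        populations={i: "POP1" for i in ("F1", "M1", "C1", "F2", "M2", "C2")},
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator.

    Defaults are chosen to mirror the assay's study conditions at desk scale:
    100-bp paired reads, ~370 bp of biological sequence per size-selected
    fragment, 30x mean on-target depth per diploid locus, a subfamily mix
    dominated by the older SVA_D lineage with divergence falling toward the
    young SVA_F, and a cohort of two trios.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 400_000
    n_fixed_elements: int = 200
    n_known_polymorphic: int = 20
    n_novel_polymorphic: int = 20
    allele_frequency_range: tuple[float, float] = (0.05, 0.5)
    pedigree: Pedigree = field(default_factory=default_pedigree)
    subfamily_mix: dict[str, float] = field(
        default_factory=lambda: {"SVA_D": 0.6, "SVA_E": 0.2, "SVA_F": 0.2}
    )
    divergence_per_subfamily: dict[str, float] = field(
        default_factory=lambda: {"SVA_D": 0.05, "SVA_E": 0.02, "SVA_F": 0.005}
    )
    hexamer_copies_range: tuple[int, int] = (5, 30)
    truncation_probability: float = 0.2
    truncation_max: int = 400
    read_length: int = 100
    error_rate: float = 0.005
    mean_depth: float = 30.0
    noise_fraction: float = 0.05
    fragment_mean: float = 370.0
    fragment_sd: float = 30.0
    adapter_total: int = 132
    planted_de_novo: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if abs(sum(self.subfamily_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subfamily_mix proportions must sum to 1")
        for name, val in [
            ("truncation_probability", self.truncation_probability),
            ("error_rate", self.error_rate),
            ("noise_fraction", self.noise_fraction),
            *((f"divergence[{k}]", v) for k, v in self.divergence_per_subfamily.items()),
        ]:
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.allele_frequency_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("allele_frequency_range must be within [0, 1]")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        unknown = set(self.planted_de_novo) - set(self.pedigree.offspring())
        if unknown:
            raise ValueError(f"planted_de_novo names non-offspring: {unknown}")

    def individuals(self) -> list[str]:
        return self.pedigree.individuals()


@dataclass
class PlantedElement:
    """One element instance: its full sequence plus assay-relevant geometry."""

    name: str
    contig: str
    junction: int  # element-5'-flank junction in final genome coordinates
    strand: str
    subfamily: str
    kind: str
    hexamer_copies: int
    truncation: int  # bases removed from the element 5' end (0 = full length)
    sequence: str  # element sequence after truncation
    fragment_portion: str  # element part of a library fragment (to Alu query end)
    consensus_span: tuple[int, int]
    amplifiable: bool
    allele_frequency: float = 1.0


@dataclass
class TruthSet:
    """Simulator-side record of what was planted, for recovery scoring."""

    insertions: pd.DataFrame  # one row per planted locus
    genotypes: pd.DataFrame  # individuals x loci, insertion-allele copies
    provenance: pd.DataFrame  # one row per on-target read pair

    def loci_of_kind(self, *kinds: str) -> pd.DataFrame:
        return self.insertions[self.insertions["kind"].isin(kinds)]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    annotations: list[SVAElementAnnotation]
    elements: list[PlantedElement]
    truth: TruthSet
    reads1: dict[str, list[tuple[str, str]]]  # individual -> [(qname, seq)]
    reads2: dict[str, list[tuple[str, str]]]
    sam_records: list[dict]

    def known_polymorphic_catalog(self) -> list[tuple[str, int, int]]:
        rows = self.truth.loci_of_kind(KNOWN)
        return [
            (r.contig, int(r.position), int(r.position) + 1)
            for r in rows.itertuples(index=False)
        ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _make_element(
    rng: np.random.Generator,
    config: SimulationConfig,
    model: SVAConsensusModel,
    name: str,
    kind: str,
) -> dict:
    """Draw subfamily, hexamer copies, divergence and truncation; build the
    element sequence and the fragment portion ending at the Alu-query end."""
    fams = sorted(config.subfamily_mix)
    probs = np.array([config.subfamily_mix[f] for f in fams])
    fam = fams[rng.choice(len(fams), p=probs / probs.sum())]
    h = int(rng.integers(config.hexamer_copies_range[0], config.hexamer_copies_range[1] + 1))
    div = config.divergence_per_subfamily.get(fam, 0.0)
    qs, qe = model.alu_query_span  # 1-based closed; body starts at qs
    body = _mutate(rng, model.consensus_sequence[qs - 1 :], div)
    full = model.hexamer_unit * h + body
    d = 0
    if rng.random() < config.truncation_probability:
        d = int(rng.integers(1, config.truncation_max + 1))
        d = min(d, len(full) - 50)
    seq = full[d:]
    hex_len = 6 * h
    d_body = max(0, d - hex_len)
    span_start = 1 if d_body == 0 else qs + d_body
    span = (span_start, qe + len(body) - 40)  # consensus end carried
    portion = full[d : hex_len + 40]  # through the Alu-like query end
    return {
        "name": name,
        "subfamily": fam,
        "kind": kind,
        "hexamer_copies": h,
        "truncation": d,
        "sequence": seq,
        "fragment_portion": portion,
        "consensus_span": span,
    }


def simulate_genome(
    config: SimulationConfig, model: Optional[SVAConsensusModel] = None
) -> tuple[dict[str, str], list[SVAElementAnnotation], list[PlantedElement]]:
    """Random genome with the fixed elements spliced in and annotated.

    Deterministic given the config seed.  Raises when a contig is too short
    to host its share of elements at safe spacing.
    """
    config.validate()
    model = model or SVAConsensusModel.default()
    rng = np.random.default_rng(config.seed)
    per_contig = _split_count(config.n_fixed_elements, config.n_contigs)
    genome: dict[str, str] = {}
    annotations: list[SVAElementAnnotation] = []
    elements: list[PlantedElement] = []
    idx = 0
    for c in range(config.n_contigs):
        contig = f"contig{c + 1}"
        background = _random_seq(rng, config.contig_length)
        n_here = per_contig[c]
        if n_here:
            usable = config.contig_length - 2000
            slot = usable // n_here
            if slot < 3000:
                raise ValueError(
                    f"{contig}: too short to host {n_here} elements "
                    "(need >= 3 kb spacing)"
                )
            sites = [
                1000 + i * slot + int(rng.integers(0, slot - 2000))
                for i in range(n_here)
            ]
        else:
            sites = []
        pieces: list[str] = []
        prev = 0
        shift = 0
        for site in sites:
            spec = _make_element(rng, config, model, f"fixed_{idx:04d}", FIXED)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = spec["sequence"] if strand == "+" else revcomp(spec["sequence"])
            pieces.append(background[prev:site])
            start = site + shift
            end = start + len(seq)
            pieces.append(seq)
            prev = site
            shift += len(seq)
            ann = SVAElementAnnotation(
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                subfamily=spec["subfamily"],
                consensus_span=spec["consensus_span"],
                name=spec["name"],
            )
            annotations.append(ann)
            elements.append(
                PlantedElement(
                    name=spec["name"],
                    contig=contig,
                    junction=start if strand == "+" else end,
                    strand=strand,
                    subfamily=spec["subfamily"],
                    kind=FIXED,
                    hexamer_copies=spec["hexamer_copies"],
                    truncation=spec["truncation"],
                    sequence=spec["sequence"],
                    fragment_portion=spec["fragment_portion"],
                    consensus_span=spec["consensus_span"],
                    amplifiable=is_amplifiable(ann, model),
                )
            )
            idx += 1
        pieces.append(background[prev:])
        genome[contig] = "".join(pieces)
    return genome, annotations, elements


def _split_count(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _place_polymorphic(
    rng: np.random.Generator,
    config: SimulationConfig,
    model: SVAConsensusModel,
    genome: dict[str, str],
    annotations: Sequence[SVAElementAnnotation],
) -> list[PlantedElement]:
    """Choose insertion points for non-reference loci, away from fixed
    elements and each other, and build their element instances."""
    contigs = sorted(genome)
    taken: list[tuple[str, int]] = [
        (a.contig, p) for a in annotations for p in (a.start, a.end)
    ]
    kinds = (
        [KNOWN] * config.n_known_polymorphic
        + [NOVEL] * config.n_novel_polymorphic
        + [DE_NOVO] * len(config.planted_de_novo)
    )
    out = []
    for i, kind in enumerate(kinds):
        for _ in range(1000):
            contig = contigs[int(rng.integers(0, len(contigs)))]
            pos = int(rng.integers(1000, len(genome[contig]) - 1000))
            if all(
                c != contig or abs(pos - p) > 1500 for c, p in taken
            ):
                break
        else:
            raise ValueError("could not place polymorphic loci; genome too crowded")
        taken.append((contig, pos))
        spec = _make_element(rng, config, model, f"{kind}_{i:04d}", kind)
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = config.allele_frequency_range
        af = 0.0 if kind == DE_NOVO else float(rng.uniform(lo, hi))
        span = spec["consensus_span"]
        amp = span[0] <= model.primer_window[0] and span[1] >= model.primer_window[1]
        out.append(
            PlantedElement(
                name=spec["name"],
                contig=contig,
                junction=pos,
                strand=strand,
                subfamily=spec["subfamily"],
                kind=kind,
                hexamer_copies=spec["hexamer_copies"],
                truncation=spec["truncation"],
                sequence=spec["sequence"],
                fragment_portion=spec["fragment_portion"],
                consensus_span=span,
                amplifiable=amp,
                allele_frequency=af,
            )
        )
    return out


def simulate_genotypes(
    config: SimulationConfig,
    elements: Sequence[PlantedElement],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Genotype matrix (individuals x loci, insertion-allele copies 0/1/2).

    Fixed loci are 2 in everyone.  Polymorphic founders draw from
    Hardy-Weinberg at the locus allele frequency; offspring receive one
    allele from each parent.  De novo loci get one copy in their named
    offspring only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ped = config.pedigree
    inds = ped.individuals()
    children = set(ped.offspring())
    founders = [i for i in inds if i not in children]
    geno = pd.DataFrame(0, index=pd.Index(inds, name="individual"),
                        columns=[e.name for e in elements], dtype=int)
    de_novo_iter = iter(config.planted_de_novo)
    for e in elements:
        if e.kind == FIXED:
            geno[e.name] = 2
            continue
        if e.kind == DE_NOVO:
            child = next(de_novo_iter)
            geno.loc[child, e.name] = 1
            continue
        for f in founders:
            geno.loc[f, e.name] = int(rng.binomial(2, e.allele_frequency))
        for father, mother, child in ped.trios:
            a = int(rng.random() < geno.loc[father, e.name] / 2.0)
            b = int(rng.random() < geno.loc[mother, e.name] / 2.0)
            geno.loc[child, e.name] = a + b
    return geno


def simulate_library(
    config: SimulationConfig,
    genome: dict[str, str],
    elements: Sequence[PlantedElement],
    genotypes: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, list[tuple[str, str]]], list[dict], pd.DataFrame]:
    """Sample read pairs for every carried, amplifiable insertion.

    Returns (reads1, reads2, sam_records, provenance).  Each fragment is
    ``flank + element-portion`` in element orientation; read 1 is the
    reverse complement of the fragment's element-proximal end, read 2 the
    flank-distal end.  SAM records hold the error-free flanking alignment at
    MAPQ 60; noise pairs get random sequence, position and MAPQ.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    inds = config.individuals()
    reads1: dict[str, list[tuple[str, str]]] = {i: [] for i in inds}
    reads2: dict[str, list[tuple[str, str]]] = {i: [] for i in inds}
    sam_records: list[dict] = []
    prov_rows: list[dict] = []
    rl = config.read_length
    for ind in inds:
        n_on_target = 0
        for e in elements:
            g = int(genotypes.loc[ind, e.name])
            if g == 0 or not e.amplifiable:
                continue
            n_pairs = int(rng.poisson(config.mean_depth * g / 2.0))
            for k in range(n_pairs):
                portion = e.fragment_portion
                frag_bio = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
                flank_len = int(np.clip(frag_bio - len(portion), rl, 600))
                if e.strand == "+":
                    lo = e.junction - flank_len
                    flank = genome[e.contig][lo : e.junction]
                    r2_start, r2_end, r2_strand = lo, lo + rl, "+"
                else:
                    hi = e.junction + flank_len
                    flank = revcomp(genome[e.contig][e.junction : hi])
                    r2_start, r2_end, r2_strand = hi - rl, hi, "-"
                fragment = flank + portion
                read1 = revcomp(fragment)[:rl]
                read2 = fragment[:rl]
                qname = f"{ind}|{e.name}|{k}"
                reads1[ind].append((qname, _mutate(rng, read1, config.error_rate)))
                reads2[ind].append((qname, _mutate(rng, read2, config.error_rate)))
                sam_records.append(
                    {
                        "qname": qname,
                        "individual": ind,
                        "contig": e.contig,
                        "start": r2_start,
                        "end": r2_end,
                        "strand": r2_strand,
                        "mapq": 60,
                        "seq": read2 if r2_strand == "+" else revcomp(read2),
                    }
                )
                prov_rows.append(
                    {
                        "qname": qname,
                        "individual": ind,
                        "locus": e.name,
                        "kind": e.kind,
                        "hexamer_copies": e.hexamer_copies,
                        "truncation": e.truncation,
                        "flank_length": flank_len,
                        "fragment_bio_length": len(fragment),
                    }
                )
                n_on_target += 1
        if config.noise_fraction > 0 and n_on_target:
            n_noise = int(round(
                config.noise_fraction / (1.0 - config.noise_fraction) * n_on_target
            ))
            contigs = sorted(genome)
            for k in range(n_noise):
                qname = f"{ind}|noise|{k}"
                reads1[ind].append((qname, _random_seq(rng, rl)))
                contig = contigs[int(rng.integers(0, len(contigs)))]
                pos = int(rng.integers(0, len(genome[contig]) - rl))
                strand = "+" if rng.random() < 0.5 else "-"
                seq = genome[contig][pos : pos + rl]
                reads2[ind].append((qname, seq if strand == "+" else revcomp(seq)))
                sam_records.append(
                    {
                        "qname": qname,
                        "individual": ind,
                        "contig": contig,
                        "start": pos,
                        "end": pos + rl,
                        "strand": strand,
                        "mapq": int(rng.integers(0, 61)),
                        "seq": seq,
                    }
                )
    provenance = pd.DataFrame(prov_rows)
    return reads1, reads2, sam_records, provenance


def simulate_dataset(
    config: SimulationConfig, model: Optional[SVAConsensusModel] = None
) -> SimulatedDataset:
    """Run the whole generator: genome, cohort genotypes, library, truth."""
    config.validate()
    model = model or SVAConsensusModel.default()
    genome, annotations, fixed = simulate_genome(config, model)
    rng = np.random.default_rng(config.seed + 17)
    poly = _place_polymorphic(rng, config, model, genome, annotations)
    elements = fixed + poly
    genotypes = simulate_genotypes(config, elements)
    reads1, reads2, sam_records, provenance = simulate_library(
        config, genome, elements, genotypes
    )
    insertions = pd.DataFrame(
        [
            {
                "name": e.name,
                "contig": e.contig,
                "position": e.junction,
                "strand": e.strand,
                "subfamily": e.subfamily,
                "kind": e.kind,
                "amplifiable": e.amplifiable,
                "hexamer_copies": e.hexamer_copies,
                "truncation": e.truncation,
                "allele_frequency": e.allele_frequency,
            }
            for e in elements
        ]
    )
    truth = TruthSet(insertions=insertions, genotypes=genotypes, provenance=provenance)
    return SimulatedDataset(
        config=config,
        genome=genome,
        annotations=annotations,
        elements=elements,
        truth=truth,
        reads1=reads1,
        reads2=reads2,
        sam_records=sam_records,
    )


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastqs(
    reads: dict[str, list[tuple[str, str]]], outdir: str | Path, mate: int
) -> dict[str, Path]:
    """One Phred+33 FASTQ per individual; returns individual -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ind in sorted(reads):
        path = outdir / f"{ind}_R{mate}.fastq"
        with open(path, "w") as fh:
            for qname, seq in reads[ind]:
                fh.write(f"@{qname}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[ind] = path
    return paths


def write_truth_sam(
    sam_records: Sequence[dict], genome: dict[str, str], path: str | Path
) -> None:
    """Error-free flanking alignments as a plain-text SAM with one read group
    per individual (SM = individual)."""
    import pysam

    contigs = sorted(genome)
    inds = sorted({r["individual"] for r in sam_records})
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in contigs],
        "RG": [{"ID": ind, "SM": ind} for ind in inds],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in sam_records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["qname"]
            a.flag = 16 if r["strand"] == "-" else 0
            a.reference_id = tid[r["contig"]]
            a.reference_start = r["start"]
            a.mapping_quality = r["mapq"]
            a.cigarstring = f"{r['end'] - r['start']}M"
            a.query_sequence = r["seq"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            a.set_tag("RG", r["individual"])
            out.write(a)


def write_truth_tables(truth: TruthSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.insertions.to_csv(outdir / "truth_insertions.tsv", sep="\t", index=False)
    truth.genotypes.to_csv(outdir / "truth_genotypes.tsv", sep="\t")
    truth.provenance.to_csv(outdir / "truth_provenance.tsv", sep="\t", index=False)
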
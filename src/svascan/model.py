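"""SVA consensus model, element annotations, and amplifiability rules.

SVA elements are composite hominid retrotransposons: a 5' (CCCTCT)n hexamer
simple repeat, an Alu-like region, a VNTR, a SINE-R and a poly-A tail.  The
targeted-amplification assay this package models enriches the 5' end of an
element through two nested primer-binding sites that sit at consensus
positions 78-137 (1-based, inside the Alu-like region).  An element is
amplifiable -- and therefore visible to the assay -- only if its retained
consensus span still contains that whole primer window.

Coordinate conventions: consensus coordinates are 1-based closed intervals
(matching how primer positions are usually quoted); genomic intervals are
0-based half-open (BED/SAM convention).  The loaders in this module are the
only place the two systems meet.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

HEXAMER_UNIT = "CCCTCT"

#: default primer window in 1-based closed consensus coordinates
DEFAULT_PRIMER_WINDOW = (78, 137)

#: default 40-nt Alu-like scoring query, 1-based closed consensus coordinates,
#: immediately 3' of the hexamer region of the bundled consensus
DEFAULT_ALU_QUERY_SPAN = (73, 112)

SVA_SUBFAMILIES = ("SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA_E", "SVA_F")


@dataclass(frozen=True)
class SVAConsensusModel:
    """The SVA consensus sequence plus the coordinates the assay cares about.

    Parameters
    ----------
    consensus_sequence :
        Full consensus, 5'->3', uppercase A/C/G/T.
    primer_window :
        1-based closed interval of consensus positions spanned by the two
        nested primer-binding sites.  An element must retain this whole
        window to be amplifiable.
    alu_query_span :
        1-based closed interval of the 40-nt Alu-like subsequence used as
        the read-scoring query.
    hexamer_unit :
        The simple-repeat unit at the element 5' end.
    """

    consensus_sequence: str
    primer_window: tuple[int, int] = DEFAULT_PRIMER_WINDOW
    alu_query_span: tuple[int, int] = DEFAULT_ALU_QUERY_SPAN
    hexamer_unit: str = HEXAMER_UNIT

    def __post_init__(self) -> None:
        n = len(self.consensus_sequence)
        ws, we = self.primer_window
        qs, qe = self.alu_query_span
        if not (1 <= ws <= we <= n):
            raise ValueError(
                f"primer window {self.primer_window} outside consensus 1..{n}"
            )
        if qe - qs + 1 != 40:
            raise ValueError("alu_like_query must be exactly 40 nt")
        if not (1 <= qs <= qe <= n):
            raise ValueError(
                f"alu query span {self.alu_query_span} outside consensus 1..{n}"
            )

    @property
    def alu_like_query(self) -> str:
        """The 40-nt Alu-like scoring query."""
        qs, qe = self.alu_query_span
        return self.consensus_sequence[qs - 1 : qe]

    @property
    def scoring_target(self) -> str:
        """Consensus subsequence covering the Alu-like query and the primer
        window; the local-alignment target for read scoring."""
        lo = min(self.alu_query_span[0], self.primer_window[0])
        hi = max(self.alu_query_span[1], self.primer_window[1])
        return self.consensus_sequence[lo - 1 : hi]

    @classmethod
    def default(cls) -> "SVAConsensusModel":
        """Bundled synthetic stand-in consensus (the published consensus is
        held externally); override with :meth:`from_fasta` for real work."""
        path = resources.files("svascan.data") / "synthetic_sva_consensus.fasta"
        seq = _read_single_fasta(str(path))
        return cls(consensus_sequence=seq)

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        primer_window: tuple[int, int] = DEFAULT_PRIMER_WINDOW,
        alu_query_span: tuple[int, int] = DEFAULT_ALU_QUERY_SPAN,
    ) -> "SVAConsensusModel":
        return cls(
            consensus_sequence=_read_single_fasta(str(path)),
            primer_window=primer_window,
            alu_query_span=alu_query_span,
        )


def _read_single_fasta(path: str) -> str:
    seq_parts: list[str] = []
    n_records = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                n_records += 1
                if n_records > 1:
                    raise ValueError(f"{path}: expected a single-record FASTA")
            else:
                seq_parts.append(line.upper())
    if n_records == 0:
        raise ValueError(f"{path}: no FASTA record found")
    return "".join(seq_parts)


@dataclass
class SVAElementAnnotation:
    """One annotated SVA element in a genome.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``consensus_span`` is the 1-based closed range of consensus positions the
    element still carries (None when the source annotation did not say, in
    which case loaders may impute it from the element length and set
    ``span_imputed``).
    """

    contig: str
    start: int
    end: int
    strand: str
    subfamily: str
    consensus_span: Optional[tuple[int, int]] = None
    known_polymorphic: bool = False
    span_imputed: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.contig}:{self.start}-{self.end}: empty genomic interval"
            )
        if self.consensus_span is not None:
            cs, ce = self.consensus_span
            if cs > ce:
                raise ValueError(f"consensus_span {self.consensus_span} inverted")

    @property
    def length(self) -> int:
        return self.end - self.start


def is_amplifiable(element: SVAElementAnnotation, model: SVAConsensusModel) -> bool:
    """True iff the element's retained consensus span contains the whole
    primer window, i.e. both nested primer-binding sites survive.

    Elements whose span was imputed from length (plain BED input) use the
    imputed span; elements with no span at all are rejected.
    """
    if element.consensus_span is None:
        raise ValueError(
            f"element {element.name or element.contig + ':' + str(element.start)} "
            "has no consensus_span; cannot decide amplifiability"
        )
    ws, we = model.primer_window
    cs, ce = element.consensus_span
    return cs <= ws and ce >= we


def expected_fragment_length(
    hexamer_copies: int, flank_length: int, adapter_total: int
) -> int:
    """Expected library-fragment size: adapters + genomic flank + the
    (CCCTCT)n hexamer run + the 40-bp Alu-like region."""
    if hexamer_copies < 0 or flank_length < 0 or adapter_total < 0:
        raise ValueError("fragment-length arguments must be non-negative")
    return adapter_total + flank_length + 6 * hexamer_copies + 40


def load_repeatmasker(
    path: str | Path, model: Optional[SVAConsensusModel] = None
) -> list[SVAElementAnnotation]:
    """Load SVA annotations from a RepeatMasker ``.out`` file or a BED6 file.

    Non-SVA records are dropped.  RepeatMasker repeat-begin/end columns
    populate ``consensus_span``; for BED input the span is imputed as
    ``(1, element length)`` and flagged ``span_imputed`` so that length >= the
    primer-window end acts as the amplifiability proxy.  Unparseable lines
    are skipped with a warning carrying the line number; a file with no SVA
    records is an error.
    """
    path = str(path)
    records: list[SVAElementAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    is_out = _looks_like_rm_out(lines)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        try:
            ann = (
                _parse_rm_out_line(line) if is_out else _parse_bed6_line(line)
            )
        except (ValueError, IndexError) as exc:
            warnings.warn(f"{path}:{lineno}: skipping unparseable line ({exc})")
            continue
        if ann is not None:
            records.append(ann)
    if not records:
        raise ValueError(f"{path}: no SVA annotations found")
    return records


def _looks_like_rm_out(lines: Sequence[str]) -> bool:
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.lower().startswith(("sw", "score", "there were no")):
            return True
        fields = s.split()
        # RM .out data rows have >= 14 columns and a numeric SW score first
        return len(fields) >= 14 and fields[0].isdigit()
    return False


def _parse_rm_out_line(line: str) -> Optional[SVAElementAnnotation]:
    s = line.strip()
    if s.lower().startswith(("sw", "score")) or not s:
        return None  # header
    f = s.split()
    if not f[0].replace(".", "").isdigit():
        return None
    name = f[9]
    if not name.upper().startswith("SVA"):
        return None
    contig = f[4]
    start = int(f[5]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(f[6])
    rm_strand = f[8]
    strand = "+" if rm_strand == "+" else "-"
    # repeat coordinates: plus rows are (begin, end, left); C rows (left, end, begin)
    if rm_strand == "+":
        rbeg, rend = int(f[11]), int(f[12])
    else:
        rend, rbeg = int(f[12]), int(_strip_parens(f[13]))
    return SVAElementAnnotation(
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        subfamily=_normalise_subfamily(name),
        consensus_span=(min(rbeg, rend), max(rbeg, rend)),
        name=name,
    )


def _strip_parens(tok: str) -> str:
    return tok.strip("()")


def _parse_bed6_line(line: str) -> Optional[SVAElementAnnotation]:
    f = line.split("\t") if "\t" in line else line.split()
    if len(f) < 4:
        raise ValueError("fewer than 4 BED columns")
    name = f[3]
    if not name.upper().startswith("SVA"):
        return None
    start, end = int(f[1]), int(f[2])
    strand = f[5] if len(f) >= 6 else "+"
    return SVAElementAnnotation(
        contig=f[0],
        start=start,
        end=end,
        strand=strand,
        subfamily=_normalise_subfamily(name),
        consensus_span=(1, end - start),
        span_imputed=True,
        name=name,
    )


def _normalise_subfamily(name: str) -> str:
    up = name.upper()
    for fam in SVA_SUBFAMILIES:
        if up.startswith(fam):
            return fam
    return "other"


def write_bed(
    annotations: Iterable[SVAElementAnnotation], path: str | Path
) -> None:
    """Serialize annotations as BED6 (score column carries 0)."""
    with open(path, "w") as fh:
        for a in annotations:
            # the name field must identify the record as SVA for reloading
            if a.name.upper().startswith("SVA"):
                name = a.name
            elif a.name:
                name = f"{a.subfamily}|{a.name}"
            else:
                name = a.subfamily
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{name}\t0\t{a.strand}\n")
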
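"""Local-alignment bit-score filtering of element-side reads.

Each read pair's first mate (the "SVA Read") is expected to carry the 40-bp
Alu-like region of an SVA element.  We decide whether a pair derives from an
SVA locus by locally aligning the read against the consensus scoring target
(the Alu-like query plus the primer window) with a Smith-Waterman DP under a
+1 match / -2 mismatch / 2.5-per-gapped-position scheme, and converting the
raw score S to a Karlin-Altschul bit score

    bits = (lambda * S - ln K) / ln 2,   lambda = 1.28, K = 0.46,

the documented defaults for this match/mismatch pair.  A perfect 40-nt match
scores raw 40 -> 75.0 bits.  Reads are kept at a relaxed cutoff of 48 bits
(keeps older, more diverged subfamilies) or a stringent cutoff of 65 bits
(enriches near-consensus young elements).

Exact DP is used rather than a seeded heuristic: at read scale it is fast and
never scores lower than a heuristic would.  Both read strands are scored and
the maximum taken.  ``N`` bases always score as mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import SVAConsensusModel, SVAElementAnnotation

RELAXED_CUTOFF = 48.0
STRINGENT_CUTOFF = 65.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> small int; N gets a code that never equals a target code
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring constants.

    Raw scores use +``match`` / ``mismatch`` per aligned pair and a linear
    ``gap_per_position`` cost; the final raw score is floored to an integer
    before the Karlin-Altschul conversion.
    """

    match: int = 1
    mismatch: int = -2
    gap_per_position: float = 2.5
    lam: float = 1.28
    k: float = 0.46

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2.0)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class ScoredReadPair:
    read_id: str
    individual: str
    bit_score: float
    passed_relaxed: bool = False
    passed_stringent: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (_BASE_CODE.get(b, 4) for b in seq.upper()), dtype=np.int8, count=len(seq)
    )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sw_batch_scaled(reads: np.ndarray, target: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    """Best local-alignment score, doubled to keep half-integer gap costs
    integral, for a batch of equal-length encoded reads vs one target.

    Linear gap costs make the within-row dependence a running maximum, so the
    whole batch advances one read position per iteration with vectorised ops.
    """
    n, L = reads.shape
    m = target.shape[0]
    match2 = np.int32(2 * scheme.match)
    mismatch2 = np.int32(2 * scheme.mismatch)
    gap2 = np.int32(round(2 * scheme.gap_per_position))
    tgt = target[np.newaxis, :]  # (1, m)
    H = np.zeros((n, m + 1), dtype=np.int32)
    best = np.zeros(n, dtype=np.int32)
    jj = gap2 * np.arange(1, m + 1, dtype=np.int32)
    for i in range(L):
        sub = np.where(reads[:, i : i + 1] == tgt, match2, mismatch2)
        diag = H[:, :-1] + sub
        up = H[:, 1:] - gap2
        tmp = np.maximum(np.maximum(diag, up), 0)
        # close left gaps: newH_j = max_{k<=j} (tmp_k - gap2*(j-k))
        run = np.maximum.accumulate(tmp + jj, axis=1) - jj
        H[:, 1:] = np.maximum(tmp, run)
        best = np.maximum(best, H[:, 1:].max(axis=1))
    return best


def _raw_scores(
    seqs: Sequence[str], target: str, scheme: ScoringScheme, both_strands: bool = True
) -> np.ndarray:
    """Floored raw Smith-Waterman scores of each sequence vs the target,
    maximised over strands."""
    out = np.zeros(len(seqs), dtype=np.int32)
    targets = [_encode(target)]
    if both_strands:
        targets.append(_encode(revcomp(target)))
    by_len: dict[int, list[int]] = {}
    for idx, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(idx)
    for length, idxs in by_len.items():
        if length == 0:
            raise ValueError("empty read sequence")
        block = np.stack([_encode(seqs[i]) for i in idxs])
        scaled = np.zeros(len(idxs), dtype=np.int32)
        for tgt in targets:
            scaled = np.maximum(scaled, _sw_batch_scaled(block, tgt, scheme))
        out[idxs] = scaled // 2  # floor of the half-integer raw score
    return out


def local_bitscore(
    read_sequence: str,
    model: SVAConsensusModel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Maximum local-alignment bit score of a read against the consensus
    scoring target, reported to 1 decimal bit."""
    if not read_sequence:
        raise ValueError("empty read sequence")
    raw = int(_raw_scores([read_sequence], model.scoring_target, scheme)[0])
    return round(scheme.bit_score(raw), 1)


def score_reads(
    reads: Mapping[str, str] | Sequence[tuple[str, str]],
    individual: str,
    model: SVAConsensusModel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    relaxed: float = RELAXED_CUTOFF,
    stringent: float = STRINGENT_CUTOFF,
) -> list[ScoredReadPair]:
    """Score many reads at once (vectorised); returns one record per read."""
    items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    if not items:
        return []
    ids = [rid for rid, _ in items]
    seqs = [s for _, s in items]
    raws = _raw_scores(seqs, model.scoring_target, scheme)
    out = []
    for rid, raw in zip(ids, raws):
        bits = round(scheme.bit_score(int(raw)), 1)
        out.append(
            ScoredReadPair(
                read_id=rid,
                individual=individual,
                bit_score=bits,
                passed_relaxed=bits >= relaxed,
                passed_stringent=bits >= stringent,
            )
        )
    return out


def score_fastq(
    path: str | Path,
    individual: str,
    model: SVAConsensusModel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    relaxed: float = RELAXED_CUTOFF,
    stringent: float = STRINGENT_CUTOFF,
) -> list[ScoredReadPair]:
    """Score every read-1 record in a FASTQ file."""
    from Bio import SeqIO

    reads = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
    return score_reads(reads, individual, model, scheme, relaxed, stringent)


def filter_read_pairs(
    pairs: Iterable[ScoredReadPair], cutoff: float
) -> tuple[list[ScoredReadPair], pd.DataFrame]:
    """Retain pairs with bit score >= cutoff; also report per-individual pass
    fractions as a DataFrame (individual, n_total, n_passed, fraction)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pairs = list(pairs)
    kept = [p for p in pairs if p.bit_score >= cutoff]
    rows = {}
    for p in pairs:
        tot, ok = rows.get(p.individual, (0, 0))
        rows[p.individual] = (tot + 1, ok + (1 if p.bit_score >= cutoff else 0))
    frame = pd.DataFrame(
        [
            {
                "individual": ind,
                "n_total": tot,
                "n_passed": ok,
                "fraction": (ok / tot) if tot else float("nan"),
            }
            for ind, (tot, ok) in sorted(rows.items())
        ]
    )
    return kept, frame


def bitscore_distribution(
    annotations: Sequence[SVAElementAnnotation],
    genome: Mapping[str, str],
    model: SVAConsensusModel,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    bin_width: float = 5.0,
    max_element_prefix: int = 600,
) -> pd.DataFrame:
    """Score each annotated element's 5'-end genomic sequence against the
    consensus target and histogram the bit scores by subfamily.

    Elements whose retained consensus span does not cover the Alu-like query
    are tallied in an ``unscorable`` column.  Returns a DataFrame indexed by
    bin lower edge with one column per subfamily plus ``unscorable``.
    """
    qs, qe = model.alu_query_span
    per_fam_scores: dict[str, list[float]] = {}
    unscorable: dict[str, int] = {}
    seqs: list[str] = []
    fams: list[str] = []
    for a in annotations:
        cs, ce = a.consensus_span if a.consensus_span else (None, None)
        if cs is None or cs > qs or ce < qe:
            unscorable[a.subfamily] = unscorable.get(a.subfamily, 0) + 1
            continue
        seq = genome[a.contig][a.start : a.end]
        if a.strand == "-":
            seq = revcomp(seq)
        seqs.append(seq[:max_element_prefix])
        fams.append(a.subfamily)
    if seqs:
        raws = _raw_scores(seqs, model.scoring_target, scheme)
        for fam, raw in zip(fams, raws):
            per_fam_scores.setdefault(fam, []).append(
                round(scheme.bit_score(int(raw)), 1)
            )
    all_fams = sorted(set(per_fam_scores) | set(unscorable))
    if not all_fams:
        return pd.DataFrame()
    all_scores = [s for v in per_fam_scores.values() for s in v]
    hi = max(all_scores) if all_scores else 0.0
    edges = np.arange(0.0, hi + bin_width, bin_width)
    table = {}
    for fam in all_fams:
        counts, _ = np.histogram(
            per_fam_scores.get(fam, []), bins=np.append(edges, edges[-1] + bin_width)
        )
        table[fam] = counts
    frame = pd.DataFrame(table, index=pd.Index(edges, name="bit_score_bin"))
    frame["unscorable"] = [0] * len(frame)
    if len(frame) and unscorable:
        for fam, n in unscorable.items():
            # unscorable elements are counted once, in the lowest bin row
            frame.loc[frame.index[0], "unscorable"] += n
    return frame
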
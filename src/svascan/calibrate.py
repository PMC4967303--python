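"""Sensitivity calibration over TPM/UR cutoff grids.

Presumed fixed loci -- insertions present in the reference genome and not
reported polymorphic -- serve as an internal truth set: the assay should see
every one of them in every individual.  For a grid of (TPM, UR) cutoff pairs
we measure, per individual and pooled, the fraction of fixed loci whose
support meets both cutoffs, then pick the most stringent pair still reaching
the target sensitivity (default 90%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .loci import LocusCluster
from .model import SVAConsensusModel, SVAElementAnnotation, is_amplifiable

logger = logging.getLogger(__name__)

DEFAULT_TPM_AXIS = tuple(range(0, 21))
DEFAULT_UR_AXIS = tuple(range(0, 21))
POOLED = "pooled"


def _within(pos: int, start: int, end: int, window: int) -> bool:
    return start - window <= pos <= end + window


def fixed_locus_set(
    clusters: Sequence[LocusCluster],
    annotations: Sequence[SVAElementAnnotation],
    known_polymorphic: Sequence[tuple[str, int, int]],
    model: SVAConsensusModel,
    window: int = 500,
) -> list[LocusCluster]:
    """Clusters that land on an amplifiable reference element not listed in
    the known-polymorphic catalog.

    ``known_polymorphic`` is a list of (contig, start, end) intervals.  An
    empty result triggers a warning (calibration is then impossible).
    """
    amp = [
        a
        for a in annotations
        if is_amplifiable(a, model) and not a.known_polymorphic
    ]
    out = []
    for cl in clusters:
        near_ref = any(
            a.contig == cl.contig
            and _within(cl.representative, a.start, a.end, window)
            for a in amp
        )
        if not near_ref:
            continue
        near_poly = any(
            contig == cl.contig and _within(cl.representative, s, e, window)
            for contig, s, e in known_polymorphic
        )
        if not near_poly:
            out.append(cl)
    if not out:
        warnings.warn("no presumed fixed loci found; calibration impossible")
    return out


@dataclass
class SensitivityGrid:
    """Fixed-locus recovery fraction as a function of (TPM, UR) cutoffs.

    ``matrices[ind][i, j]`` is the fraction of fixed loci whose support for
    ``ind`` has TPM >= tpm_axis[i] and UR >= ur_axis[j].  The ``pooled``
    entry sums each locus's support over individuals first.
    """

    tpm_axis: tuple[float, ...]
    ur_axis: tuple[float, ...]
    matrices: dict[str, np.ndarray]
    n_fixed_loci: int

    def sensitivity(self, individual: str, tpm: float, ur: float) -> float:
        i = self.tpm_axis.index(tpm)
        j = self.ur_axis.index(ur)
        return float(self.matrices[individual][i, j])

    def individuals(self) -> list[str]:
        return [k for k in self.matrices if k != POOLED]

    def check_monotone(self) -> None:
        """Sensitivity must be non-increasing along each cutoff axis."""
        for ind, m in self.matrices.items():
            if np.any(np.diff(m, axis=0) > 1e-12) or np.any(
                np.diff(m, axis=1) > 1e-12
            ):
                raise AssertionError(f"sensitivity grid not monotone for {ind}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind, m in self.matrices.items():
            for i, t in enumerate(self.tpm_axis):
                for j, u in enumerate(self.ur_axis):
                    rows.append(
                        {
                            "individual": ind,
                            "tpm_cutoff": t,
                            "ur_cutoff": u,
                            "sensitivity": float(m[i, j]),
                        }
                    )
        return pd.DataFrame(rows)


def compute_sensitivity_grid(
    fixed_loci: Sequence[LocusCluster],
    individuals: Sequence[str],
    tpm_axis: Sequence[float] = DEFAULT_TPM_AXIS,
    ur_axis: Sequence[float] = DEFAULT_UR_AXIS,
    totals: Optional[Mapping[str, int]] = None,
) -> SensitivityGrid:
    """Build the per-individual and pooled sensitivity grids.

    A fixed locus with no support for an individual counts against that
    individual's sensitivity at every non-zero cutoff.  Pooled support sums
    depth and UR over individuals; pooled TPM is recomputed from summed depth
    over summed totals when ``totals`` is given, else TPM values are summed.
    """
    n = len(fixed_loci)
    if n == 0:
        raise ValueError("empty fixed-locus set")
    t = np.asarray(tpm_axis, dtype=float)
    u = np.asarray(ur_axis, dtype=float)
    matrices: dict[str, np.ndarray] = {}

    def grid_for(tpm_vals: np.ndarray, ur_vals: np.ndarray) -> np.ndarray:
        ok_t = tpm_vals[np.newaxis, :] >= t[:, np.newaxis]  # (T, n)
        ok_u = ur_vals[np.newaxis, :] >= u[:, np.newaxis]  # (U, n)
        return (
            ok_t[:, np.newaxis, :] & ok_u[np.newaxis, :, :]
        ).mean(axis=2)

    for ind in individuals:
        tpm_vals = np.array(
            [cl.support.get(ind, {}).get("tpm", 0.0) for cl in fixed_loci]
        )
        ur_vals = np.array(
            [cl.support.get(ind, {}).get("ur", 0.0) for cl in fixed_loci]
        )
        matrices[ind] = grid_for(tpm_vals, ur_vals)

    depth_sum = np.array(
        [
            sum(s.get("depth", 0.0) for s in cl.support.values())
            for cl in fixed_loci
        ]
    )
    ur_sum = np.array(
        [sum(s.get("ur", 0.0) for s in cl.support.values()) for cl in fixed_loci]
    )
    if totals:
        grand_total = sum(totals.values())
        pooled_tpm = depth_sum / grand_total * 1e6
    else:
        pooled_tpm = np.array(
            [
                sum(s.get("tpm", 0.0) for s in cl.support.values())
                for cl in fixed_loci
            ]
        )
    matrices[POOLED] = grid_for(pooled_tpm, ur_sum)
    grid = SensitivityGrid(
        tpm_axis=tuple(tpm_axis),
        ur_axis=tuple(ur_axis),
        matrices=matrices,
        n_fixed_loci=n,
    )
    grid.check_monotone()
    return grid


@dataclass(frozen=True)
class CutoffChoice:
    tpm: float
    ur: float
    achieved_sensitivity: float
    met_target: bool


def select_cutoffs(
    grid: SensitivityGrid,
    individual: str,
    target: float = 0.90,
    order: str = "ur_major",
) -> CutoffChoice:
    """Most stringent (TPM, UR) pair whose sensitivity still meets the target.

    Among grid cells with sensitivity >= target, maximise UR first, then TPM
    (``order='tpm_major'`` swaps the priority).  If no cell meets the target,
    the minimal axis values are returned with a warning.
    """
    m = grid.matrices[individual]
    candidates = [
        (t, uu, m[i, j])
        for i, t in enumerate(grid.tpm_axis)
        for j, uu in enumerate(grid.ur_axis)
        if m[i, j] >= target
    ]
    if not candidates:
        warnings.warn(
            f"{individual}: no cutoff pair reaches sensitivity {target}; "
            "falling back to the minimal cutoffs"
        )
        return CutoffChoice(
            tpm=grid.tpm_axis[0],
            ur=grid.ur_axis[0],
            achieved_sensitivity=float(m[0, 0]),
            met_target=False,
        )
    if order == "ur_major":
        key = lambda c: (c[1], c[0])
    elif order == "tpm_major":
        key = lambda c: (c[0], c[1])
    else:
        raise ValueError(f"unknown selection order {order!r}")
    t, uu, sens = max(candidates, key=key)
    return CutoffChoice(tpm=t, ur=uu, achieved_sensitivity=float(sens), met_target=True)


def select_all_cutoffs(
    grid: SensitivityGrid, target: float = 0.90, order: str = "ur_major"
) -> dict[str, CutoffChoice]:
    """Per-individual cutoff selection (pooled entry included)."""
    return {
        ind: select_cutoffs(grid, ind, target=target, order=order)
        for ind in grid.matrices
    }
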
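import pytest

from svascan.model import SVAConsensusModel
from svascan.pipeline import run_from_dataset
from svascan.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def model():
    return SVAConsensusModel.default()


def _clean_overrides():
    """Error-free control regime: no sequencing error, no off-target noise,
    no divergence from consensus, and saturating coverage, so every
    amplifiable carried insertion is guaranteed recoverable and logical
    checks are not confounded by borderline support."""
    return dict(
        error_rate=0.0,
        noise_fraction=0.0,
        divergence_per_subfamily={"SVA_D": 0.0, "SVA_E": 0.0, "SVA_F": 0.0},
        mean_depth=60.0,
    )


@pytest.fixture(scope="session")
def ds_small():
    """Modest dataset with the default (noisy) study conditions."""
    cfg = SimulationConfig(
        seed=11,
        n_fixed_elements=40,
        n_known_polymorphic=8,
        n_novel_polymorphic=8,
        contig_length=150_000,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def ds_clean():
    """Error-free dataset with a planted de novo insertion in offspring C1."""
    cfg = SimulationConfig(
        seed=23,
        n_fixed_elements=30,
        n_known_polymorphic=6,
        n_novel_polymorphic=6,
        contig_length=130_000,
        planted_de_novo=["C1"],
        **_clean_overrides(),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def ds_cohort():
    """Calibration-scale cohort: six individuals (two trios), >=150
    amplifiable fixed loci, 30x mean on-target depth, default noise/error."""
    cfg = SimulationConfig(seed=42)  # defaults are the study conditions
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def result_small(ds_small, tmp_path_factory):
    return run_from_dataset(
        ds_small, workdir=tmp_path_factory.mktemp("run_small")
    )


@pytest.fixture(scope="session")
def result_clean(ds_clean, tmp_path_factory):
    return run_from_dataset(
        ds_clean, workdir=tmp_path_factory.mktemp("run_clean")
    )


@pytest.fixture(scope="session")
def result_cohort(ds_cohort, tmp_path_factory):
    return run_from_dataset(
        ds_cohort, workdir=tmp_path_factory.mktemp("run_cohort")
    )


# ---------------------------------------------------------------------------
# independent oracles

def sw_bitscore_oracle(read: str, target: str, scheme) -> float:
    """Brute-force local alignment via Biopython's PairwiseAligner (an
    implementation independent of svascan's DP), with the same doubling /
    floor convention, maximised over read strands."""
    from Bio import Align

    from svascan.readfilter import revcomp

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=2 * scheme.match,
        mismatch_score=2 * scheme.mismatch,
        open_gap_score=-round(2 * scheme.gap_per_position),
        extend_gap_score=-round(2 * scheme.gap_per_position),
    )
    best = 0
    for seq in (read, revcomp(read)):
        best = max(best, int(aligner.score(target, seq)))
    return round(scheme.bit_score(best // 2), 1)


def clusters_nest_within(inner, outer, window=500):
    """True iff every cluster in `inner` has a same-contig, same-strand
    counterpart in `outer` within `window` bp (representative positions can
    shift when membership changes, so identity is positional)."""
    outer_keys = [(c.contig, c.strand, c.representative) for c in outer]
    for c in inner:
        if not any(
            contig == c.contig and strand == c.strand
            and abs(pos - c.representative) <= window
            for contig, strand, pos in outer_keys
        ):
            return False
    return True


def transitive_closure_clusters(positions, window):
    """Quadratic union-find over all pairs within `window`; returns sorted
    tuples of member positions."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(g)) for g in groups.values())
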
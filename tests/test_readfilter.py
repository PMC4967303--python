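import numpy as np
import pytest

from svascan.readfilter import (
    DEFAULT_SCHEME,
    RELAXED_CUTOFF,
    STRINGENT_CUTOFF,
    bitscore_distribution,
    filter_read_pairs,
    local_bitscore,
    revcomp,
    score_reads,
)

from conftest import sw_bitscore_oracle


def _substitute(seq, *positions):
    out = list(seq)
    for p in positions:
        out[p] = "A" if out[p] != "A" else "C"
    return "".join(out)


class TestLocalBitscore:
    def test_perfect_40nt_match_scores_75_bits(self, model):
        assert local_bitscore(model.alu_like_query, model) == 75.0

    def test_reverse_complement_scores_identically(self, model):
        assert local_bitscore(revcomp(model.alu_like_query), model) == 75.0

    def test_two_substitutions_score_63_9_bits(self, model):
        read = _substitute(model.alu_like_query, 5, 20)
        assert local_bitscore(read, model) == 63.9

    def test_homopolymer_read_scores_below_relaxed_cutoff(self, model):
        assert local_bitscore("A" * 100, model) < RELAXED_CUTOFF

    def test_empty_read_rejected(self, model):
        with pytest.raises(ValueError):
            local_bitscore("", model)

    def test_n_bases_score_as_mismatch(self, model):
        read = list(model.alu_like_query)
        read[10] = "N"
        # one interior mismatch: raw 37 under +1/-2
        expected = round(DEFAULT_SCHEME.bit_score(37), 1)
        assert local_bitscore("".join(read), model) == expected

    def test_padding_outside_alignment_does_not_change_score(self, model):
        """Bases 5' of the aligned query cannot extend the local alignment
        (the target begins at the query start), so they never alter the
        score; 3' padding may only extend it, never reduce it."""
        rng = np.random.default_rng(1)
        pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        assert local_bitscore(pad(30) + model.alu_like_query, model) == 75.0
        assert local_bitscore(pad(30) + model.alu_like_query + pad(30), model) >= 75.0


class TestOracleEquivalence:
    def test_matches_smith_waterman_oracle_on_random_reads(self, model):
        """Exact agreement with an independent local-alignment oracle over
        random reads (uniform and consensus-derived) up to 120 nt."""
        rng = np.random.default_rng(12345)
        target = model.scoring_target
        reads = []
        for _ in range(150):
            n = int(rng.integers(20, 121))
            reads.append("".join(rng.choice(list("ACGT"), size=n)))
        # consensus-derived reads exercise the high-score regime
        cons = model.consensus_sequence
        for _ in range(150):
            start = int(rng.integers(0, 200))
            n = int(rng.integers(50, 121))
            read = cons[start : start + n]
            k = int(rng.integers(0, 6))
            if k:
                read = _substitute(read, *rng.integers(0, len(read), size=k))
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        for read in reads:
            mine = local_bitscore(read, model)
            oracle = sw_bitscore_oracle(read, target, DEFAULT_SCHEME)
            assert mine == oracle, f"disagreement on {read}"


class TestFilterReadPairs:
    def _pairs(self, model, rng, n_good=20, n_bad=20):
        good = [
            (f"good{i}", model.alu_like_query) for i in range(n_good)
        ]
        bad = [
            (f"bad{i}", "".join(rng.choice(list("ACGT"), size=100)))
            for i in range(n_bad)
        ]
        return score_reads(good + bad, "ind1", model)

    def test_relaxed_cutoff_separates_on_target_from_random(self, model):
        rng = np.random.default_rng(7)
        scored = self._pairs(model, rng)
        kept, frac = filter_read_pairs(scored, RELAXED_CUTOFF)
        ids = {p.read_id for p in kept}
        assert ids == {f"good{i}" for i in range(20)}
        assert frac.loc[0, "fraction"] == 0.5

    def test_stringent_set_is_subset_of_relaxed(self, model):
        rng = np.random.default_rng(8)
        scored = self._pairs(model, rng)
        relaxed, _ = filter_read_pairs(scored, RELAXED_CUTOFF)
        stringent, _ = filter_read_pairs(scored, STRINGENT_CUTOFF)
        assert {p.read_id for p in stringent} <= {p.read_id for p in relaxed}

    def test_stringent_pass_implies_relaxed_pass(self, model):
        scored = score_reads([("r", model.alu_like_query)], "i", model)
        assert scored[0].passed_stringent and scored[0].passed_relaxed

    def test_empty_input(self):
        kept, frac = filter_read_pairs([], 48.0)
        assert kept == [] and frac.empty

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_read_pairs([], 0.0)


class TestBitscoreDistribution:
    def test_zero_divergence_elements_fill_the_top_bin(self, model, ds_clean):
        genome = ds_clean.genome
        anns = [a for a in ds_clean.annotations if a.consensus_span[0] == 1]
        hist = bitscore_distribution(anns, genome, model)
        scored_cols = [c for c in hist.columns if c != "unscorable"]
        total = hist[scored_cols].to_numpy().sum()
        top = hist.loc[hist.index >= 74.0, scored_cols].to_numpy().sum()
        assert total > 0 and top == total

    def test_diverged_subfamily_scores_below_young_one(self, model, ds_small):
        hist = bitscore_distribution(ds_small.annotations, ds_small.genome, model)
        assert {"SVA_D", "SVA_F"} <= set(hist.columns)

        def median_bin(col):
            c = hist[col].to_numpy().astype(float)
            cum = np.cumsum(c)
            return hist.index[np.searchsorted(cum, cum[-1] / 2)]

        assert median_bin("SVA_D") <= median_bin("SVA_F")

    def test_element_not_covering_query_is_unscorable(self, model, ds_clean):
        from svascan.model import SVAElementAnnotation

        stub = SVAElementAnnotation(
            contig="contig1", start=0, end=200, strand="+",
            subfamily="SVA_D", consensus_span=(200, 1316),
        )
        hist = bitscore_distribution([stub], ds_clean.genome, model)
        assert hist["unscorable"].sum() == 1

    def test_empty_annotation_list(self, model):
        assert bitscore_distribution([], {}, model).empty
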
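import numpy as np
import pandas as pd
import pytest

from svascan.calibrate import CutoffChoice
from svascan.classify import (
    KNOWN_POLYMORPHIC,
    NOVEL_POLYMORPHIC,
    REFERENCE_FIXED,
    LocusCall,
    Pedigree,
    allele_frequency_spectrum,
    call_genotypes,
    classify_loci,
    concordance_report,
    de_novo_candidates,
    de_novo_probability,
)
from svascan.loci import LocusCluster
from svascan.model import SVAElementAnnotation


def _cluster(pos, support=None, contig="chr1", strand="+"):
    cl = LocusCluster(contig=contig, strand=strand, representative=pos)
    cl.support = support or {}
    return cl


def _ref(start):
    return SVAElementAnnotation(
        contig="chr1", start=start, end=start + 1300, strand="+",
        subfamily="SVA_D", consensus_span=(1, 1316),
    )


class TestClassifyLoci:
    def test_type_assignment_and_partition(self, model):
        annotations = [_ref(10_000), _ref(50_000)]
        catalog = [("chr1", 50_500, 50_501), ("chr1", 70_000, 70_001)]
        clusters = [
            _cluster(10_100),  # near reference only -> fixed
            _cluster(50_600),  # reference AND catalog -> known wins
            _cluster(70_100),  # catalog only -> known
            _cluster(90_000),  # nothing -> novel
        ]
        calls = classify_loci(clusters, annotations, catalog, model)
        types = [c.locus_type for c in calls]
        assert types == [
            REFERENCE_FIXED,
            KNOWN_POLYMORPHIC,
            KNOWN_POLYMORPHIC,
            NOVEL_POLYMORPHIC,
        ]
        assert len(calls) == len(clusters)  # exactly one type per cluster

    def test_window_tolerance(self, model):
        calls = classify_loci(
            [_cluster(10_000 - 500), _cluster(10_000 - 501)],
            [_ref(10_000)], [], model, window=500,
        )
        assert [c.locus_type for c in calls] == [REFERENCE_FIXED, NOVEL_POLYMORPHIC]


class TestCallGenotypes:
    CUT = {
        "a": CutoffChoice(tpm=5, ur=10, achieved_sensitivity=0.95, met_target=True),
    }

    @pytest.mark.parametrize(
        "tpm,ur,expected",
        [(12.0, 12, True), (4.0, 12, False), (5.0, 10, True), (12.0, 9, False)],
    )
    def test_presence_requires_both_cutoffs(self, tpm, ur, expected):
        call = LocusCall(
            cluster=_cluster(100, {"a": {"tpm": tpm, "ur": ur, "depth": ur}}),
            locus_type=NOVEL_POLYMORPHIC,
        )
        call_genotypes([call], self.CUT, individuals=["a"])
        assert call.presence["a"] is expected

    def test_raising_support_never_flips_present_to_absent(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            tpm, ur = rng.uniform(0, 20), rng.integers(0, 20)
            call = LocusCall(
                cluster=_cluster(100, {"a": {"tpm": tpm, "ur": int(ur), "depth": int(ur)}}),
                locus_type=NOVEL_POLYMORPHIC,
            )
            boosted = LocusCall(
                cluster=_cluster(100, {"a": {"tpm": tpm + 1, "ur": int(ur) + 1, "depth": int(ur) + 1}}),
                locus_type=NOVEL_POLYMORPHIC,
            )
            call_genotypes([call, boosted], self.CUT, individuals=["a"])
            assert boosted.presence["a"] or not call.presence["a"]


class TestSpectrum:
    def _calls(self, carrier_sets, ltype=NOVEL_POLYMORPHIC, inds=("a", "b", "c")):
        calls = []
        for i, carriers in enumerate(carrier_sets):
            call = LocusCall(cluster=_cluster(1000 * (i + 1)), locus_type=ltype)
            call.presence = {ind: ind in carriers for ind in inds}
            calls.append(call)
        return calls

    def test_all_carried_by_everyone(self):
        calls = self._calls([{"a", "b", "c"}, {"a", "b", "c"}])
        spec = allele_frequency_spectrum(calls, n_individuals=3)
        assert spec.loc[3, "novel_polymorphic"] == 1.0

    def test_singleton_loci_mass_at_one(self):
        calls = self._calls([{"a"}, {"b"}, {"c"}])
        spec = allele_frequency_spectrum(calls, n_individuals=3)
        assert spec.loc[1, "novel_polymorphic"] == 1.0

    def test_reference_fixed_excluded(self):
        calls = self._calls([{"a"}], ltype=REFERENCE_FIXED)
        spec = allele_frequency_spectrum(calls, n_individuals=3)
        assert spec["all_polymorphic"].sum() == 0

    def test_founder_spectrum_matches_binomial_expectation(self):
        """Carrier counts of HWE founders follow Binomial(n, 1-(1-p)^2)."""
        rng = np.random.default_rng(10)
        p, n_ind, n_loci = 0.3, 6, 400
        inds = [f"i{k}" for k in range(n_ind)]
        carrier_p = 1 - (1 - p) ** 2
        calls = []
        for i in range(n_loci):
            geno = rng.binomial(2, p, size=n_ind)
            call = LocusCall(cluster=_cluster(1000 * (i + 1)), locus_type=NOVEL_POLYMORPHIC)
            call.presence = {ind: bool(g > 0) for ind, g in zip(inds, geno)}
            calls.append(call)
        counts = np.array([c.carrier_count for c in calls])
        observed_mean = counts.mean()
        expected_mean = n_ind * carrier_p
        sd = np.sqrt(n_ind * carrier_p * (1 - carrier_p) / n_loci)
        assert abs(observed_mean - expected_mean) < 5 * sd


class TestDeNovo:
    PED = Pedigree(trios=[("F1", "M1", "C1")], singletons=["S1"])

    def _call(self, carriers, pos=1000):
        call = LocusCall(cluster=_cluster(pos), locus_type=NOVEL_POLYMORPHIC)
        call.presence = {
            ind: ind in carriers for ind in ("F1", "M1", "C1", "S1")
        }
        return call

    def test_parental_locus_removed(self):
        out = de_novo_candidates([self._call({"C1", "F1"})], self.PED)
        assert out["C1"] == []

    def test_background_shared_locus_removed(self):
        out = de_novo_candidates([self._call({"C1", "S1"})], self.PED)
        assert out["C1"] == []

    def test_offspring_private_locus_retained(self):
        out = de_novo_candidates([self._call({"C1"})], self.PED)
        assert [c["locus_id"] for c in out["C1"]] == ["chr1:1000:+"]

    def test_repeat_context_flag(self):
        ann = SVAElementAnnotation(
            contig="chr1", start=900, end=1300, strand="+",
            subfamily="SVA_D", consensus_span=(1, 1316),
        )
        out = de_novo_candidates([self._call({"C1"})], self.PED, [ann])
        assert out["C1"][0]["in_repeat"] is True

    def test_offspring_missing_parent_calls_skipped(self):
        call = LocusCall(cluster=_cluster(1000), locus_type=NOVEL_POLYMORPHIC)
        call.presence = {"C1": True, "M1": False}  # father absent
        with pytest.warns(UserWarning, match="C1"):
            out = de_novo_candidates([call], self.PED)
        assert "C1" not in out


class TestDeNovoProbability:
    def test_six_trios_bound(self):
        p = de_novo_probability(1 / 916, 6)
        assert p == pytest.approx(0.00653, abs=5e-5)
        assert p < 0.01

    @pytest.mark.parametrize("rate,n,expected", [(0.5, 0, 0.0), (1.0, 1, 1.0)])
    def test_degenerate_cases(self, rate, n, expected):
        assert de_novo_probability(rate, n) == expected

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            de_novo_probability(0.0, 3)
        with pytest.raises(ValueError):
            de_novo_probability(1.5, 3)


class TestPedigree:
    def test_from_tsv_round_trip(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text(
            "F1\t.\t.\tCEU\nM1\t.\t.\tCEU\nC1\tF1\tM1\tCEU\nS1\t.\t.\tYRI\n"
        )
        ped = Pedigree.from_tsv(path)
        assert ped.trios == [("F1", "M1", "C1")]
        assert ped.singletons == ["S1"]
        assert ped.populations["S1"] == "YRI"

    def test_undeclared_parent_rejected(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text("C1\tF1\tM1\tCEU\n")
        with pytest.raises(ValueError, match="parent"):
            Pedigree.from_tsv(path)


class TestConcordance:
    def test_agreement_bookkeeping(self):
        a = pd.DataFrame(
            {"x": [True, True], "y": [False, True]},
            index=pd.Index(["l1", "l2"], name="locus_id"),
        )
        b = pd.DataFrame(
            {"x": [True, False], "y": [False, True]},
            index=pd.Index(["l1", "l2"], name="locus_id"),
        )
        rep = concordance_report(a, b)
        assert rep.set_index("locus_id").loc["l1", "concordance"] == 1.0
        assert rep.set_index("locus_id").loc["l2", "concordance"] == 0.5
        assert rep.attrs["overall_concordance"] == pytest.approx(0.75)

    def test_no_overlap_is_an_error(self):
        a = pd.DataFrame({"x": [True]}, index=["l1"])
        b = pd.DataFrame({"x": [True]}, index=["l2"])
        with pytest.raises(ValueError):
            concordance_report(a, b)
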
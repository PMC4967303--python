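import numpy as np
import pytest

from svascan.classify import Pedigree
from svascan.model import expected_fragment_length
from svascan.readfilter import local_bitscore
from svascan.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_genome,
    write_fasta,
)


def _small_cfg(**kw):
    defaults = dict(
        seed=1, n_fixed_elements=12, n_known_polymorphic=4,
        n_novel_polymorphic=4, contig_length=80_000, n_contigs=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_subfamily_mix_must_sum_to_one(self):
        cfg = _small_cfg(subfamily_mix={"SVA_D": 0.5, "SVA_F": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            _small_cfg(error_rate=1.5).validate()

    def test_read_length_floor(self):
        with pytest.raises(ValueError, match="read_length"):
            _small_cfg(read_length=30).validate()

    def test_contig_too_short_for_elements(self):
        cfg = _small_cfg(n_fixed_elements=100, contig_length=50_000)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(cfg)


class TestSimulateGenome:
    def test_same_seed_gives_identical_fasta(self, tmp_path):
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(simulate_genome(_small_cfg())[0], a)
        write_fasta(simulate_genome(_small_cfg())[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_no_fixed_elements_gives_empty_annotations(self):
        _, anns, elements = simulate_genome(_small_cfg(n_fixed_elements=0))
        assert anns == [] and elements == []

    def test_pure_subfamily_mix(self):
        cfg = _small_cfg(
            subfamily_mix={"SVA_F": 1.0},
            divergence_per_subfamily={"SVA_F": 0.0},
        )
        _, anns, _ = simulate_genome(cfg)
        assert {a.subfamily for a in anns} == {"SVA_F"}

    def test_annotation_sequence_matches_element(self, model):
        genome, anns, elements = simulate_genome(_small_cfg())
        from svascan.readfilter import revcomp

        for ann, elem in zip(anns, elements):
            seq = genome[ann.contig][ann.start : ann.end]
            if ann.strand == "-":
                seq = revcomp(seq)
            assert seq == elem.sequence


class TestSimulateGenotypes:
    PED = Pedigree(trios=[("F1", "M1", "C1"), ("F2", "M2", "C2")])

    def test_frequency_one_gives_all_founders_homozygous(self):
        cfg = _small_cfg(
            pedigree=self.PED, allele_frequency_range=(1.0, 1.0),
            n_fixed_elements=0,
        )
        ds = simulate_dataset(cfg)
        poly = ds.truth.insertions["name"]
        assert (ds.truth.genotypes[list(poly)] == 2).all().all()

    def test_planted_de_novo_has_exactly_one_carrier(self):
        cfg = _small_cfg(pedigree=self.PED, planted_de_novo=["C1"])
        ds = simulate_dataset(cfg)
        dn = ds.truth.loci_of_kind("de_novo")["name"].iloc[0]
        geno = ds.truth.genotypes[dn]
        assert geno["C1"] == 1 and (geno.drop("C1") == 0).all()

    def test_mendelian_consistency_everywhere(self, ds_small):
        """Exhaustive: each offspring genotype is reachable from its parents
        at every non-de-novo locus."""
        geno = ds_small.truth.genotypes
        for father, mother, child in ds_small.config.pedigree.trios:
            for locus in geno.columns:
                f, m, c = geno.loc[father, locus], geno.loc[mother, locus], geno.loc[child, locus]
                lo = (f // 2) + (m // 2)  # forced alleles from homozygotes
                hi = min(1, (f + 1) // 2) + min(1, (m + 1) // 2)
                assert lo <= c <= hi, (locus, f, m, c)

    def test_hwe_carrier_fraction(self):
        """Founder carrier fraction over many loci ~ 1 - (1-p)^2."""
        p = 0.3
        cfg = _small_cfg(
            seed=9, n_fixed_elements=0, n_known_polymorphic=150,
            n_novel_polymorphic=150, allele_frequency_range=(p, p),
            contig_length=1_200_000, mean_depth=0.01,
        )
        ds = simulate_dataset(cfg)
        founders = [
            i for i in cfg.pedigree.individuals()
            if i not in cfg.pedigree.offspring()
        ]
        geno = ds.truth.genotypes.loc[founders]
        frac = float((geno > 0).to_numpy().mean())
        expected = 1 - (1 - p) ** 2
        n = geno.size
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / n)


class TestSimulateLibrary:
    def test_fixed_seed_gives_identical_fastq(self, tmp_path):
        from svascan.simulate import write_fastqs

        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_fastqs(simulate_dataset(_small_cfg()).reads1, d1, mate=1)
        p2 = write_fastqs(simulate_dataset(_small_cfg()).reads1, d2, mate=1)
        for ind in p1:
            assert p1[ind].read_bytes() == p2[ind].read_bytes()

    def test_truncated_past_primer_site_emits_no_pairs(self, ds_small):
        prov = ds_small.truth.provenance
        non_amp = set(
            ds_small.truth.insertions.query("not amplifiable")["name"]
        )
        assert non_amp, "expect some non-amplifiable elements at these settings"
        assert set(prov["locus"]) & non_amp == set()

    def test_every_carried_amplifiable_locus_gets_reads(self, ds_cohort):
        """At 30x mean depth the chance of zero pairs is ~e^-15 per carrier;
        assert none occurred in this cohort."""
        truth = ds_cohort.truth
        prov = truth.provenance
        seen = set(zip(prov["individual"], prov["locus"]))
        amp = set(truth.insertions.query("amplifiable")["name"])
        for locus in amp:
            for ind, g in truth.genotypes[locus].items():
                if g > 0:
                    assert (ind, locus) in seen

    def test_error_free_read1_matches_consensus_query(self, model, ds_clean):
        """With no divergence/error, every on-target read 1 carries the
        Alu-like region and scores as a (near-)perfect match."""
        for ind, reads in ds_clean.reads1.items():
            for qname, seq in reads[:40]:
                assert local_bitscore(seq, model) >= 65.0

    def test_read1_composition_matches_fragment_arithmetic(self, ds_clean):
        """Biological fragment length equals flank + 6*hexamer + 40 for
        untruncated elements (adapters excluded by construction)."""
        prov = ds_clean.truth.provenance
        full = prov[prov["truncation"] == 0]
        assert len(full) > 0
        for row in full.itertuples(index=False):
            assert row.fragment_bio_length == expected_fragment_length(
                row.hexamer_copies, row.flank_length, 0
            )

    def test_truth_sam_round_trips_through_ingest(self, ds_clean, tmp_path):
        from svascan.loci import ingest_alignments
        from svascan.simulate import write_truth_sam

        sam = tmp_path / "truth.sam"
        write_truth_sam(ds_clean.sam_records, ds_clean.genome, sam)
        flanks, totals, _ = ingest_alignments(sam, mapq_cutoff=0)
        assert len(flanks) == len(ds_clean.sam_records)
        by_id = {r["qname"]: r for r in ds_clean.sam_records}
        for f in flanks[:200]:
            rec = by_id[f.read_id]
            assert (f.contig, f.start, f.end, f.strand) == (
                rec["contig"], rec["start"], rec["end"], rec["strand"]
            )
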
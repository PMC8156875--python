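"""Generator contracts: determinism, clock calibration, recombination rules."""

import numpy as np
import pytest

from ervscribe import synthetic_data as sd
from ervscribe.structural_annotation import composition


class TestAncestralProvirus:
    def test_layout_and_identical_ltrs(self, ancestor):
        assert len(ancestor) == 9546
        assert ancestor.ltr_length("LTR5") == 897
        assert ancestor.feature_sequence("LTR5") == ancestor.feature_sequence("LTR3")

    def test_at_fraction_near_target(self, ancestor):
        at = composition(ancestor.sequence)["AT_percent"] / 100.0
        assert abs(at - 0.60) < 0.02

    def test_deterministic_under_seed(self):
        a = sd.build_ancestral_provirus(seed=7).sequence
        b = sd.build_ancestral_provirus(seed=7).sequence
        assert a == b
        assert a != sd.build_ancestral_provirus(seed=8).sequence

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_at_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.build_ancestral_provirus(target_at_fraction=bad, seed=1)

    def test_cpg_depleted_relative_to_iid(self):
        def cpg_frac(s):
            return sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG") / len(s)

        dep = sd.build_ancestral_provirus(seed=3, cpg_depletion=0.25).sequence
        iid = sd.build_ancestral_provirus(seed=3, cpg_depletion=1.0).sequence
        assert cpg_frac(dep) < 0.5 * cpg_frac(iid)


class TestEvolveSequence:
    def test_age_zero_is_identity(self, ancestor):
        cfg = sd.SimulationConfig(seed=1)
        assert sd.evolve_sequence(ancestor.sequence, 0.0, cfg) == ancestor.sequence

    def test_negative_age_rejected(self, ancestor):
        with pytest.raises(ValueError):
            sd.evolve_sequence(ancestor.sequence, -1.0, sd.SimulationConfig(seed=1))

    def test_substitution_count_matches_closed_form(self):
        # CpG-free sequence: every site mutates with q = 1 - exp(-r*t)
        seq = "AT" * 5000
        cfg = sd.SimulationConfig(substitution_rate=0.002, seed=5)
        rng = np.random.default_rng(5)
        out = sd.evolve_sequence(seq, 25.0, cfg, rng)
        q = 1.0 - np.exp(-0.002 * 25.0)
        expected = len(seq) * q
        sd3 = 3.0 * np.sqrt(len(seq) * q * (1 - q))
        hamming = sum(a != b for a, b in zip(seq, out))
        assert abs(hamming - expected) < sd3

    def test_cpg_sites_mutate_at_multiplier_rate(self):
        # alternating AACG blocks: half the sites sit in a CpG
        seq = "AACG" * 2500
        cpg = {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG" for i in (i, i + 1)}
        non = [i for i in range(len(seq)) if i not in cpg]
        cfg = sd.SimulationConfig(substitution_rate=0.002, cpg_multiplier=10.0, seed=6)
        rng = np.random.default_rng(6)
        hits_cpg = hits_non = 0
        for _ in range(100):
            out = sd.evolve_sequence(seq, 1.0, cfg, rng)
            hits_cpg += sum(seq[i] != out[i] for i in cpg)
            hits_non += sum(seq[i] != out[i] for i in non)
        ratio = (hits_cpg / len(cpg)) / (hits_non / len(non))
        # closed form: (1-exp(-10rt)) / (1-exp(-rt)) ~ 9.9 at rt = 0.002
        assert 8.0 < ratio < 12.0

    def test_length_preserved_and_only_acgt_touched(self, ancestor):
        seq = ancestor.sequence[:100] + "N" * 10 + ancestor.sequence[100:200]
        out = sd.evolve_sequence(seq, 30.0, sd.SimulationConfig(seed=2))
        assert len(out) == len(seq)
        assert out[100:110] == "N" * 10


class TestSoloLtr:
    def test_identical_ltrs_give_either_copy(self, ancestor):
        solo = sd.make_solo_ltr(ancestor.sequence, ancestor.features, breakpoint=450)
        assert solo == ancestor.feature_sequence("LTR5")

    def test_breakpoint_zero_returns_three_prime_copy(self, ancestor):
        cfg = sd.SimulationConfig(seed=3)
        evolved = sd.evolve_sequence(ancestor.sequence, 20.0, cfg)
        solo = sd.make_solo_ltr(evolved, ancestor.features, breakpoint=0)
        l3s, l3e = ancestor.features["LTR3"]
        assert solo == evolved[l3s - 1 : l3e]

    def test_uniform_breakpoint_reproducible_and_ltr_length(self, ancestor):
        cfg = sd.SimulationConfig(seed=3)
        evolved = sd.evolve_sequence(ancestor.sequence, 20.0, cfg)
        a = sd.make_solo_ltr(evolved, ancestor.features, rng=np.random.default_rng(9))
        b = sd.make_solo_ltr(evolved, ancestor.features, rng=np.random.default_rng(9))
        assert a == b
        assert len(a) == 897

    def test_missing_ltr_rejected(self, ancestor):
        with pytest.raises(ValueError):
            sd.make_solo_ltr(ancestor.sequence, {"LTR5": (1, 897)})


class TestPlantLoci:
    def test_cohort_of_183_elements_across_24_chromosomes(self):
        lengths = {f"chr{i}": 400_000 for i in list(range(1, 23)) + ["X", "Y"]}
        cfg = sd.SimulationConfig(
            locus_ages=[20.0] * 183,
            solo_fraction=160 / 183,
            chromosome_lengths=lengths,
            seed=42,
        )
        _, truth, _ = sd.plant_loci(cfg)
        assert len(truth) == 183
        assert sum(1 for t in truth if t.category == "provirus") == 23
        assert sum(1 for t in truth if t.category == "solo_ltr") == 160

    def test_solo_fraction_one_gives_no_proviruses(self):
        cfg = sd.SimulationConfig(
            locus_ages=[10.0] * 5, solo_fraction=1.0,
            chromosome_lengths={"chr1": 50_000}, seed=4,
        )
        _, truth, _ = sd.plant_loci(cfg)
        assert all(t.category == "solo_ltr" for t in truth)

    def test_planted_intervals_non_overlapping(self, planted_age0):
        _, truth, _ = planted_age0
        by_chrom = {}
        for t in truth:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_bed_intervals_delimit_planted_sequence(self, planted_age0):
        genome, truth, reference = planted_age0
        for t in truth:
            planted = genome[t.chrom][t.start : t.end]
            if t.strand == "-":
                planted = sd.revcomp(planted)
            if t.category == "provirus":
                assert planted == reference.sequence
            else:
                assert len(planted) == reference.ltr_length()

    def test_fixed_seed_identical_genome_bytes(self):
        cfg = dict(
            locus_ages=[10.0, 20.0, 30.0], solo_fraction=0.34,
            chromosome_lengths={"chr1": 60_000}, seed=17,
        )
        g1, t1, _ = sd.plant_loci(sd.SimulationConfig(**cfg))
        g2, t2, _ = sd.plant_loci(sd.SimulationConfig(**cfg))
        assert g1 == g2
        assert [(t.chrom, t.start, t.end, t.strand) for t in t1] == [
            (t.chrom, t.start, t.end, t.strand) for t in t2
        ]

    def test_truth_tsv_roundtrip(self, planted_age0, tmp_path):
        _, truth, _ = planted_age0
        path = tmp_path / "truth.tsv"
        sd.write_truth_tsv(truth, path)
        back = sd.read_truth_tsv(path)
        assert [(t.locus_name, t.chrom, t.start, t.end) for t in back] == [
            (t.locus_name, t.chrom, t.start, t.end) for t in truth
        ]


class TestOrthologMatrix:
    PANEL = {"chimp": 6, "gorilla": 9, "orangutan": 16, "gibbon": 20, "rhesus": 30}

    def _record(self, age):
        return sd.TruthRecord("L0", age, "provirus", "chr1", 0, 100, "+")

    def test_age_25_present_through_gibbon_absent_rhesus(self):
        m = sd.simulate_ortholog_matrix([self._record(25.0)], self.PANEL)
        row = m.loc["L0"]
        assert row[["chimp", "gorilla", "orangutan", "gibbon"]].all()
        assert not row["rhesus"]

    def test_age_zero_present_only_in_human(self):
        m = sd.simulate_ortholog_matrix([self._record(0.0)], self.PANEL)
        row = m.loc["L0"]
        assert row["human"] and not row.drop("human").any()

    def test_zero_loss_matrix_is_monotone(self):
        rng = np.random.default_rng(11)
        records = [
            sd.TruthRecord(f"L{i}", a, "provirus", "chr1", i, i + 1, "+")
            for i, a in enumerate(rng.uniform(0, 40, 30))
        ]
        m = sd.simulate_ortholog_matrix(records, self.PANEL, loss_probability=0.0)
        ordered = sorted(self.PANEL, key=self.PANEL.get)
        for _, row in m.iterrows():
            vals = [row[s] for s in ordered]
            # once absent along the lineage, absent in all older species
            assert all(a or not b for a, b in zip(vals, vals[1:]))
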
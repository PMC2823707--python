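import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybtherm import hybmodel as hm
from hybtherm import nn_thermo as nt
from hybtherm import seqs
from hybtherm.errors import (
    BoundsError,
    ConsistencyError,
    DegenerateInputError,
    InputError,
)
from hybtherm.fold_engine import Region

from oracle_helpers import dimer_enum, nn_sum, RT37, z_enum


def _probe_for(target: str, start: int, length: int, pid: str = "p1") -> hm.Probe:
    return hm.Probe(id=pid, seq=seqs.revcomp_dna(target[start : start + length]))


class TestMapProbes:
    TARGETS = {
        "T1": "ATGCATGGCCTTAAGCGTACGTTTACGGATCCATGCAATT",
        "T2": "GGGGCCCCATATATATGCGCGCATTTTAAACCCGGGTACG",
    }

    def test_unique_match_maps_with_half_open_site(self):
        probe = _probe_for(self.TARGETS["T1"], 5, 12)
        pmap = hm.map_probes([probe], self.TARGETS)
        tid, site = pmap.entries["p1"]
        assert tid == "T1" and (site.start, site.end) == (5, 17)

    def test_multi_target_excluded(self):
        targets = {"A": "ATGCATGCATTTACGATCGATC", "B": "CCATGCATGCATTTACGTT"}
        probe = hm.Probe(id="p1", seq=seqs.revcomp_dna("ATGCATTTACG"))
        pmap = hm.map_probes([probe], targets)
        assert pmap.excluded["p1"] == "multi_target"

    def test_multi_locus_excluded(self):
        targets = {"A": "ATGCATTTACGGGGGGGATGCATTTACG"}
        probe = hm.Probe(id="p1", seq=seqs.revcomp_dna("ATGCATTTACG"))
        pmap = hm.map_probes([probe], targets)
        assert pmap.excluded["p1"] == "multi_locus"

    def test_no_match_excluded(self):
        probe = hm.Probe(id="p1", seq="T" * 20 + "GCGCG")
        pmap = hm.map_probes([probe], self.TARGETS)
        assert pmap.excluded["p1"] == "no_match"

    def test_duplicate_ids_rejected(self):
        p = _probe_for(self.TARGETS["T1"], 0, 10)
        with pytest.raises(InputError, match="duplicate"):
            hm.map_probes([p, p], self.TARGETS)

    def test_rna_targets_matched_through_u(self):
        rna = {"R1": "AUGGCUUAAGCGUACGUUUACGGAUCC"}
        probe = hm.Probe(id="p1", seq=seqs.revcomp_dna("ATGGCTTAAGCGT"))
        pmap = hm.map_probes([probe], rna)
        assert "p1" in pmap.entries


class TestExtractFragment:
    def test_interior_site_gets_full_flanks(self, rng):
        target = "".join(rng.choice(list("ACGT"), 2000))
        frag = hm.extract_fragment(target, Region(1000, 1060), flank=200)
        assert frag.seq == target[800:1260]
        assert (frag.binding_site.start, frag.binding_site.end) == (200, 260)
        assert frag.left_flank == frag.right_flank == 200

    def test_left_flank_truncated_at_origin(self, rng):
        target = "".join(rng.choice(list("ACGT"), 500))
        frag = hm.extract_fragment(target, Region(10, 70), flank=200)
        assert frag.seq == target[0:270]
        assert frag.binding_site.start == 10 and frag.left_flank == 10

    def test_site_covering_whole_target(self):
        target = "ACGTACGTACGTACGTACGT"
        frag = hm.extract_fragment(target, Region(0, 20), flank=200)
        assert frag.seq == target
        assert frag.left_flank == frag.right_flank == 0

    def test_out_of_bounds_site(self):
        with pytest.raises(BoundsError):
            hm.extract_fragment("ACGTACGT", Region(4, 12))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 400), st.integers(1, 80), st.integers(0, 300))
    def test_fragment_is_verbatim_substring(self, start, length, flank):
        rng = np.random.default_rng(start * 1000 + length)
        target = "".join(rng.choice(list("ACGT"), 500))
        end = min(500, start + length)
        if end <= start:
            return
        frag = hm.extract_fragment(target, Region(start, end), flank=flank)
        assert frag.seq in target
        site = frag.binding_site
        assert frag.seq[site.start : site.end] == target[start:end]


class TestEnergyProfile:
    def test_unstructured_system_reduces_to_duplex_energy(self):
        # poly-A target and poly-T probe: no competing structure anywhere
        target = "A" * 30
        probe = _probe_for(target, 8, 12)
        assert probe.seq == "T" * 12
        frag = hm.extract_fragment(target, Region(8, 20))
        prof = hm.energy_profile(probe, frag, "DNA")
        assert prof.dG_p == 0.0 and prof.dG_t == 0.0 and prof.dG_pp == 0.0
        assert prof.dG == prof.dG_h

    def test_combination_arithmetic(self):
        # dG_h=-66, dG_p=-10, dG_t=-8, dG_pp=-2 -> dG=-46
        assert -66 - (-10) - (-8) - (-2) == -46

    def test_mismatching_probe_reports_first_position(self):
        target = "ATGCATGGCCTTAAGCGTACG"
        frag = hm.extract_fragment(target, Region(2, 14))
        good = _probe_for(target, 2, 12)
        bad_seq = good.seq[:4] + ("A" if good.seq[4] != "A" else "C") + good.seq[5:]
        with pytest.raises(ConsistencyError, match="offset"):
            hm.energy_profile(hm.Probe(id="bad", seq=bad_seq), frag, "DNA")

    def test_pipeline_matches_all_oracle_recomputation(self, dna_params):
        # toy scale: every component recomputable by exhaustive enumeration
        target = "GGCATGCAAAGCATGCCTTT"  # 20 nt, hairpin-prone
        site = Region(4, 14)
        probe = _probe_for(target, 4, 10, "toy")
        frag = hm.extract_fragment(target, site, flank=200)
        assert frag.seq == target  # short target: fragment is everything
        prof = hm.energy_profile(probe, frag, "DNA")
        # oracle: duplex by hand-sum, folding by enumeration, dimer by recursion
        _, _, dg_dup = nn_sum(probe.seq, "stacks_dna_dna.tsv")
        dg_h = min(0.0, dg_dup)
        dg_p = -RT37 * math.log(z_enum(probe.seq, dna_params))
        z = z_enum(target, dna_params)
        zc = z_enum(target, dna_params, blocked=(4, 14))
        dg_t = -RT37 * math.log(z / zc)
        dg_pp = dimer_enum(probe.seq, probe.seq, dna_params)
        assert prof.dG_h == pytest.approx(dg_h, abs=1e-6)
        assert prof.dG_p == pytest.approx(dg_p, abs=1e-6)
        assert prof.dG_t == pytest.approx(dg_t, abs=1e-6)
        assert prof.dG_pp == pytest.approx(dg_pp, abs=1e-6)
        assert prof.dG == pytest.approx(dg_h - dg_p - dg_t - dg_pp, abs=1e-6)

    def test_profiles_satisfy_model_identities(self, small_benchmark):
        df = small_benchmark["profiles"]
        lhs = df["dG"]
        rhs = df["dG_h"] - df["dG_p"] - df["dG_t"] - df["dG_pp"]
        assert (lhs - rhs).abs().max() <= 1e-12
        assert (df["dG"] >= df["dG_h"] - 1e-12).all()
        for col in ("dG_h", "dG_p", "dG_t", "dG_pp"):
            assert (df[col] <= 1e-12).all()

    def test_rna_target_uses_hybrid_duplex(self):
        target = "AUGGCUUAAGCGUACGUUUACGGAUCCAAUGG"
        probe = hm.Probe(id="p", seq=seqs.revcomp_dna(seqs.to_dna(target[4:18])))
        frag = hm.extract_fragment(target, Region(4, 18))
        prof_rna = hm.energy_profile(probe, frag, "RNA")
        prof_dna = hm.energy_profile(
            probe,
            hm.extract_fragment(seqs.to_dna(target), Region(4, 18)),
            "DNA",
        )
        assert prof_rna.dG_h != prof_dna.dG_h  # Sugimoto vs SantaLucia tables


class TestTruncation:
    PROBE60 = hm.Probe(id="p", seq="ACGTTGCAAGCTTGGATCCGGAATTCCGTACGTAGCTAGCATCGATCGGCCTTAAGGCAT")

    def test_tethered_truncation_keeps_solution_end(self):
        t = hm.truncate_probe(self.PROBE60, hm.TETHERED_END, 5)
        assert t.seq == self.PROBE60.seq[:55]
        assert t.id.endswith("3p-5")

    def test_solution_truncation_keeps_tethered_end(self):
        p45 = hm.Probe(id="q", seq=self.PROBE60.seq[:45])
        t = hm.truncate_probe(p45, hm.SOLUTION_END, 20)
        assert t.seq == p45.seq[20:]
        assert len(t) == 25

    def test_truncation_nesting(self):
        twice = hm.truncate_probe(hm.truncate_probe(self.PROBE60, "3prime", 5), "3prime", 5)
        once = hm.truncate_probe(self.PROBE60, "3prime", 10)
        assert twice.seq == once.seq

    def test_truncation_beyond_length_rejected(self):
        with pytest.raises(DegenerateInputError):
            hm.truncate_probe(self.PROBE60, hm.SOLUTION_END, 60)

    def test_duplex_energy_magnitude_shrinks(self, rng):
        # a truncated duplex keeps a subset of the stacks
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), 60))
            p = hm.Probe(id="r", seq=seq)
            full = abs(nt.duplex_thermo(p.seq, "DNA/DNA").dG_at_T)
            for end in (hm.SOLUTION_END, hm.TETHERED_END):
                for n in (5, 10, 20):
                    t = hm.truncate_probe(p, end, n)
                    assert abs(nt.duplex_thermo(t.seq, "DNA/DNA").dG_at_T) <= full + 1e-9


class TestFilters:
    def _pmap(self):
        entries = {
            f"t{t}_p{i}": (f"T{t}", Region(i * 30, i * 30 + 25))
            for t in range(4)
            for i in range(3)
        }
        return hm.ProbeTargetMap(entries=entries, excluded={})

    def test_equal_intensities_express_nothing(self):
        pmap = self._pmap()
        ser = pd.Series(100.0, index=list(pmap.entries))
        res = hm.expression_filter(ser, pmap)
        assert res.expressed == frozenset()
        assert res.threshold == 100.0

    def test_bright_target_detected(self):
        pmap = self._pmap()
        ser = pd.Series(100.0, index=list(pmap.entries))
        ser.loc["t2_p1"] = 1000.0
        res = hm.expression_filter(ser, pmap)
        assert res.expressed == frozenset({"T2"})

    def test_two_population_mixture_recovered(self, rng):
        entries = {}
        values = {}
        truth = set()
        for t in range(30):
            tid = f"T{t}"
            on = t % 2 == 0
            if on:
                truth.add(tid)
            for i in range(6):
                pid = f"{tid}_p{i}"
                entries[pid] = (tid, Region(i, i + 25))
                base = 5000.0 if on else 100.0
                values[pid] = base * math.exp(0.3 * rng.standard_normal())
        pmap = hm.ProbeTargetMap(entries=entries, excluded={})
        res = hm.expression_filter(pd.Series(values), pmap)
        assert res.expressed == frozenset(truth)

    def test_variation_ratio(self):
        pmap = hm.ProbeTargetMap(
            entries={"a": ("T", Region(0, 25)), "b": ("T", Region(30, 55))}, excluded={}
        )
        per, mean = hm.variation_stats(pd.Series({"a": 100.0, "b": 1800.0}), pmap)
        assert per["T"] == pytest.approx(math.log2(18.0))
        assert mean == pytest.approx(math.log2(18.0))

    def test_variation_zero_for_equal_probes(self):
        pmap = hm.ProbeTargetMap(
            entries={"a": ("T", Region(0, 25)), "b": ("T", Region(30, 55))}, excluded={}
        )
        per, mean = hm.variation_stats(pd.Series({"a": 7.0, "b": 7.0}), pmap)
        assert mean == 0.0

    def test_nonpositive_intensity_rejected(self):
        pmap = hm.ProbeTargetMap(
            entries={"a": ("T", Region(0, 25)), "b": ("T", Region(30, 55))}, excluded={}
        )
        with pytest.raises(InputError):
            hm.variation_stats(pd.Series({"a": 0.0, "b": 5.0}), pmap)


class TestSynthesisYield:
    def test_validation(self):
        with pytest.raises(InputError):
            hm.full_length_fraction(60, 0.0)
        with pytest.raises(InputError):
            hm.full_length_fraction(0, 0.98)

    def test_compounding(self):
        assert hm.full_length_fraction(10, 0.9) == pytest.approx(0.9**10)
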
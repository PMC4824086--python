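"""Nearest-neighbor engine: table fidelity, summation oracle, hairpins."""

import math
import random

import pytest
from Bio.SeqUtils import MeltingTemp as mt

from foldlock import (
    Strand,
    ThermoError,
    build_probe,
    duplex_thermo,
    hairpin_thermo,
    load_dna_dna_params,
    load_rna_dna_params,
    loop_penalty_dG37,
    reverse_complement,
    stack_dG,
    unlock_score,
    validate_sequence,
)
from foldlock.thermo import GAS_CONSTANT, T37_K, stack_params

from .test_seqcore import mk_target

MIR21 = "UAGCUUAUCAGACUGAUGUUGA"


def naive_duplex_dg(dna_seq: str, hybrid: bool) -> float:
    """Independent loop-over-stacks summation (the structural oracle)."""
    if hybrid:
        params = load_rna_dna_params()
        rna = reverse_complement(validate_sequence(dna_seq, Strand.DNA), Strand.RNA)
        ref = rna.residues
    else:
        params = load_dna_dna_params()
        ref = dna_seq
    total = params.initiation[2]
    for i in range(len(ref) - 1):
        total += stack_dG(ref[i : i + 2], params)
    return total


class TestParameterTables:
    @pytest.mark.parametrize("step, expected", [("CG", -2.8), ("GC", -2.3), ("GG", -2.1)])
    def test_strongest_dna_stacks(self, step, expected):
        assert stack_dG(step, load_dna_dna_params()) == expected

    def test_symmetric_lookup(self):
        params = load_dna_dna_params()
        assert stack_dG("CC", params) == stack_dG("GG", params)
        assert stack_dG("TT", params) == stack_dG("AA", params)
        assert stack_dG("AG", params) == stack_dG("CT", params)

    def test_hybrid_table_is_asymmetric_and_rna_keyed(self):
        params = load_rna_dna_params()
        assert stack_dG("UU", params) == -0.2
        assert stack_dG("AA", params) != stack_dG("UU", params)
        with pytest.raises(ThermoError):
            stack_dG("AT", params)  # T is not an RNA-strand step

    def test_unknown_step_rejected(self):
        with pytest.raises(ThermoError):
            stack_dG("AX", load_dna_dna_params())
        with pytest.raises(ThermoError):
            stack_dG("ACG", load_dna_dna_params())

    @pytest.mark.parametrize("loader", [load_dna_dna_params, load_rna_dna_params])
    def test_dH_dS_dG_self_consistency(self, loader):
        """Every tabulated ΔG°37 must equal ΔH − T·ΔS within 0.1 kcal/mol."""
        params = loader()
        entries = dict(params.stacks)
        entries["init"] = params.initiation
        for step, (dh, ds, dg) in entries.items():
            assert dg == pytest.approx(dh - T37_K * ds / 1000.0, abs=0.1), step


class TestDuplexThermo:
    def test_matches_naive_summation_on_random_duplexes(self):
        rng = random.Random(20_240_101)
        for _ in range(200):
            n = rng.randint(8, 22)
            s = "".join(rng.choice("ACGT") for _ in range(n))
            for hybrid in (False, True):
                partner = reverse_complement(
                    validate_sequence(s, Strand.DNA),
                    Strand.RNA if hybrid else Strand.DNA,
                )
                res = duplex_thermo(s, partner)
                assert res.dG37 == pytest.approx(naive_duplex_dg(s, hybrid), abs=1e-9)

    def test_duplicated_halves_algebra(self):
        """ΔG(s+s) = 2·ΔG(s) − init + junction stack."""
        params = load_dna_dna_params()
        s = "TCAACATCAG"
        whole = duplex_thermo(s + s, reverse_complement(validate_sequence(s + s, Strand.DNA))).dG37
        half = duplex_thermo(s, reverse_complement(validate_sequence(s, Strand.DNA))).dG37
        junction = stack_dG(s[-1] + s[0], params)
        assert whole == pytest.approx(2 * half - params.initiation[2] + junction, abs=1e-9)

    def test_strand_swap_leaves_dg_unchanged(self):
        """Reading the duplex from the other strand gives the same ΔG."""
        s = validate_sequence("GCATTCAGGA", Strand.DNA)
        rc = reverse_complement(s)
        fwd = duplex_thermo(s, rc)
        swapped = duplex_thermo(rc, s)
        assert fwd.dG37 == pytest.approx(swapped.dG37, abs=1e-9)
        assert fwd.tm_c == pytest.approx(swapped.tm_c, abs=1e-9)

    def test_tm_cross_checked_against_biopython(self):
        """Dual route: same conditions through Bio.SeqUtils.MeltingTemp."""
        for s in ("TCAACATCAG", "CTATCTGCACT", "GGGCGCATTA"):
            ours = duplex_thermo(s, reverse_complement(validate_sequence(s, Strand.DNA)))
            ref = mt.Tm_NN(s, nn_table=mt.DNA_NN2, Na=45, dnac1=750, dnac2=750,
                           saltcorr=5, selfcomp=False)
            assert ours.tm_c == pytest.approx(ref, abs=1e-6)
            rna = reverse_complement(validate_sequence(s, Strand.DNA), Strand.RNA)
            ours_h = duplex_thermo(s, rna)
            ref_h = mt.Tm_NN(rna.residues, nn_table=mt.R_DNA_NN1, Na=45,
                             dnac1=750, dnac2=750, saltcorr=5, selfcomp=False)
            assert ours_h.tm_c == pytest.approx(ref_h, abs=1e-6)

    def test_rejects_mismatched_or_short_input(self):
        with pytest.raises(ThermoError, match="complementary"):
            duplex_thermo("ACGT", "AAAA")
        with pytest.raises(ThermoError):
            duplex_thermo("A", "T")

    def test_hybrid_vs_homoduplex_both_reported(self):
        """The engine reports ΔG°37 for both duplex classes per sequence."""
        s = "TCAACATCAGTCTGATAAGCTA"
        dna = duplex_thermo(s, reverse_complement(validate_sequence(s, Strand.DNA)))
        hyb = duplex_thermo(s, reverse_complement(validate_sequence(s, Strand.DNA), Strand.RNA))
        assert math.isfinite(dna.dG37) and math.isfinite(hyb.dG37)
        assert dna.dG37 != hyb.dG37  # sequence-dependent, no universal sign


class TestHairpin:
    def test_hairpin_is_stem_plus_loop_exactly(self):
        probe = build_probe(mk_target(), 10)
        hp = hairpin_thermo(probe)
        assert hp.dG_hairpin == hp.dG_stem + hp.dG_loop
        assert hp.dG_loop >= 0
        assert hp.dG_stem <= 0

    def test_longer_anchor_more_stable(self):
        hp22 = hairpin_thermo(build_probe(mk_target(), 22))
        hp10 = hairpin_thermo(build_probe(mk_target(), 10))
        assert hp22.dG_hairpin < hp10.dG_hairpin

    def test_series_monotonicity_tm_and_stem(self):
        for end in ("five_prime", "three_prime"):
            hps = [hairpin_thermo(build_probe(mk_target(), k, pairing_end=end))
                   for k in (6, 7, 8, 9, 10, 11, 22)]
            tms = [h.tm_stem_c for h in hps]
            mags = [abs(h.dG_stem) for h in hps]
            assert tms == sorted(tms)
            assert mags == sorted(mags)

    def test_degenerate_stems_rejected(self):
        with pytest.raises(Exception):
            build_probe(mk_target(), 0)  # loop-only probe cannot be built
        probe = build_probe(mk_target(), 1)
        with pytest.raises(ThermoError, match="too short"):
            hairpin_thermo(probe)

    def test_loop_penalty_table_and_extrapolation(self):
        assert loop_penalty_dG37(6) == 4.0
        assert loop_penalty_dG37(12) > loop_penalty_dG37(10)
        expected = loop_penalty_dG37(10) + 1.75 * GAS_CONSTANT / 1000 * T37_K * math.log(1.2)
        assert loop_penalty_dG37(12) == pytest.approx(expected)
        with pytest.raises(ThermoError):
            loop_penalty_dG37(2)


class TestUnlockScore:
    def test_full_anchor_identical_tables_leaves_init_minus_loop(self):
        """With one table for both duplex classes the stacks cancel and
        ddG_unlock reduces to the duplex initiation minus the loop penalty."""
        params = load_dna_dna_params()
        target = mk_target()
        probe = build_probe(target, len(MIR21))
        # same DNA table for the hybrid route: score the sensing homoduplex
        us = unlock_score(probe, target, params_dna=params, params_hybrid=None)
        dna_stem = hairpin_thermo(probe, paramset=params)
        sensing = probe.sensing
        same_table_duplex = duplex_thermo(
            sensing, reverse_complement(sensing, Strand.DNA), paramset=params
        )
        ddg_same = same_table_duplex.dG37 - dna_stem.dG_hairpin
        assert ddg_same == pytest.approx(params.initiation[2] - dna_stem.dG_loop, abs=1e-9)
        assert us.ddG_unlock == us.dG_target_duplex - us.dG_hairpin

    def test_single_bp_finite_difference(self):
        """Shortening the anchor by one bp shifts ddG by the removed stack."""
        params = load_dna_dna_params()
        target = mk_target()
        for end in ("five_prime", "three_prime"):
            p10 = build_probe(target, 10, pairing_end=end)
            p9 = build_probe(target, 9, pairing_end=end)
            stem10 = p10.stem_segment
            removed = (
                stem10[-2:] if end == "five_prime" else stem10[:2]
            )
            d = unlock_score(p10, target).ddG_unlock - unlock_score(p9, target).ddG_unlock
            assert d == pytest.approx(-stack_dG(removed, params), abs=1e-9)

    def test_monotone_in_anchor_length(self):
        target = mk_target()
        scores = [unlock_score(build_probe(target, k), target).ddG_unlock
                  for k in (6, 7, 8, 9, 10, 11, 22)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_probe_target_mismatch_rejected(self):
        other = mk_target("UAAGGUGCAUCUAGUGCAGAUAG", "miR-18a")
        probe = build_probe(mk_target(), 10)
        with pytest.raises(ThermoError, match="not built from"):
            unlock_score(probe, other)
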
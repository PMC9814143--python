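"""In-silico OAD fragmentation: neutral losses, reference spectra, special cases."""

import pytest
from hypothesis import given, settings, strategies as st

from oadlipid.chem import ELEMENT_MASSES
from oadlipid.enumeration import enumerate_positions
from oadlipid.nomenclature import AcylChain, parse_lipid_name, precursor_mz
from oadlipid.rules import (
    RuleError,
    bond_context,
    default_rules,
    diagnostic_pair,
    export_msp,
    fragment_neutral_loss,
    generate_reference_spectrum,
    load_rules,
    rules_for_context,
    special_case_rules,
)

_CH2 = ELEMENT_MASSES["C"] + 2 * ELEMENT_MASSES["H"]


def _rule(rule_id, rules=None):
    return next(r for r in (rules or default_rules()) if r.rule_id == rule_id)


def _hydrocarbon_mass(c, h):
    """Independent oracle: assemble the lost-fragment mass atom by atom."""
    return c * 12.0 + h * 1.00782503207


class TestRuleTable:
    def test_twenty_acyl_rule_types(self):
        acyl = rules_for_context("acyl")
        assert len(acyl) == 20
        assert sum(1 for r in acyl if r.diagnostic) == 2

    def test_diagnostic_pair_identities(self):
        oad03, oad16 = _rule("OAD03"), _rule("OAD16")
        assert (oad03.bond_site, oad03.oxygen_delta) == (-1, 1)
        assert (oad16.bond_site, oad16.oxygen_delta) == (1, 0)


class TestFragmentNeutralLoss:
    def test_oleoyl_oxygen_retaining_loss(self):
        """n-8_n-9 cleavage of 18:1(n-9): NL = C8H17 - O = 97.1381 Da."""
        chain = AcylChain(18, 1, positions=(9,))
        _, nl = fragment_neutral_loss(chain, 0, _rule("OAD03"))
        assert nl == pytest.approx(97.1381, abs=0.0005)

    def test_oleoyl_radical_loss(self):
        """n-10_n-11 cleavage of 18:1(n-9): NL = C10H19 = 139.1487 Da."""
        chain = AcylChain(18, 1, positions=(9,))
        _, nl = fragment_neutral_loss(chain, 0, _rule("OAD16"))
        assert nl == pytest.approx(139.1487, abs=0.0005)

    def test_arachidonoyl_first_bond_radical_loss(self):
        """n-7_n-8 cleavage of 20:4(n-6,...): loses C7H13 (one C=C on board)."""
        chain = AcylChain(20, 4, positions=(6, 9, 12, 15))
        delta, nl = fragment_neutral_loss(chain, 0, _rule("OAD16"))
        assert dict(delta.counts)["C"] == 7
        assert nl == pytest.approx(_hydrocarbon_mass(7, 13), abs=1e-9)

    def test_rule_not_applicable_to_context_raises(self):
        base = AcylChain(18, 1, hydroxyls=2, linkage="sphingoid",
                         positions=(14,))  # Δ4
        with pytest.raises(RuleError, match="not applicable"):
            fragment_neutral_loss(base, 0, _rule("OAD03"))

    def test_unassigned_double_bond_index_raises(self):
        with pytest.raises(RuleError):
            fragment_neutral_loss(AcylChain(18, 1), 0, _rule("OAD03"))

    @given(st.integers(3, 16))
    @settings(max_examples=30, derandomize=True)
    def test_pair_losses_shift_by_ch2_per_position(self, x):
        """Moving the double bond one carbon outward adds CH2 to both pair
        neutral losses; values agree with brute-force formula assembly."""
        chain = AcylChain(20, 1, positions=(x,))
        _, nl03 = fragment_neutral_loss(chain, 0, _rule("OAD03"))
        _, nl16 = fragment_neutral_loss(chain, 0, _rule("OAD16"))
        assert nl03 == pytest.approx(
            _hydrocarbon_mass(x - 1, 2 * x - 1) - 15.9949146196, abs=1e-9
        )
        assert nl16 == pytest.approx(
            _hydrocarbon_mass(x + 1, 2 * x + 1), abs=1e-9
        )
        if x < 16:
            nxt = AcylChain(20, 1, positions=(x + 1,))
            _, nl03b = fragment_neutral_loss(nxt, 0, _rule("OAD03"))
            _, nl16b = fragment_neutral_loss(nxt, 0, _rule("OAD16"))
            assert nl03b - nl03 == pytest.approx(_CH2, abs=1e-9)
            assert nl16b - nl16 == pytest.approx(_CH2, abs=1e-9)


class TestReferenceSpectrum:
    def test_pc_contains_pair_and_head_ion(self):
        sp = parse_lipid_name("PC 18:0/18:1(n-9)")
        ref = generate_reference_spectrum(sp)
        prec = ref.precursor_mz
        mzs = ref.mzs
        for expected in (prec - 97.1381, prec - 139.1487, 184.0734):
            assert min(abs(m - expected) for m in mzs) < 0.0005

    def test_mixed_pufa_pair_resolution(self):
        """The C20:4 n-7_n-8 and C18:1 n-8_n-9 fragments of the N-acyl PE
        standard differ by 0.0364 m/z, requiring high mass resolution."""
        sp = parse_lipid_name("PE-N(FA 20:4(n-6,9,12,15)) 18:1(n-9)/18:1(n-9)")
        ref = generate_reference_spectrum(sp)
        frag_204 = ref.peak_for("OAD16@chain0:n-6").mz
        frag_181 = ref.peak_for("OAD03@chain1:n-9").mz
        assert frag_204 == pytest.approx(933.6816, abs=0.001)
        assert frag_181 == pytest.approx(933.6452, abs=0.001)
        assert frag_204 - frag_181 == pytest.approx(0.0364, abs=0.0005)

    def test_saturated_species_has_no_double_bond_peaks(self):
        ref = generate_reference_spectrum(parse_lipid_name("PC 16:0_18:0"))
        assert all(
            p.annotation.startswith(("head:", "precursor"))
            for p in ref.peaks
        )

    def test_unresolved_chain_is_an_error(self):
        with pytest.raises(RuleError, match="unresolved"):
            generate_reference_spectrum(parse_lipid_name("PC 18:1_22:6"))

    def test_generation_is_pure(self):
        sp = parse_lipid_name("PG 22:6(n-3,6,9,12,15,18)_22:6(n-3,6,9,12,15,18)")
        assert generate_reference_spectrum(sp) == generate_reference_spectrum(sp)

    def test_peaks_sorted_and_positive(self):
        sp = parse_lipid_name("TG 16:0_18:1(n-9)_18:3(n-3,6,9)")
        ref = generate_reference_spectrum(sp)
        assert ref.mzs == sorted(ref.mzs)
        assert all(p.mz > 0 and 0 < p.rel_intensity <= 1 for p in ref.peaks)

    def test_mass_conservation_on_every_generated_peak(self):
        """fragment m/z + neutral-loss mass = precursor m/z (to 1e-6 Da)."""
        for name in (
            "PC 18:1(n-9)_22:6(n-3,6,9,12,15,18)",
            "TG 16:0_18:1(n-9)_18:3(n-3,6,9)",
            "SM 18:1(Δ4);O2/18:1(n-9)",
        ):
            sp = parse_lipid_name(name)
            prec = precursor_mz(sp)
            ref = generate_reference_spectrum(sp)
            for ci, chain in enumerate(sp.chains):
                for di in range(len(chain.positions)):
                    ctx = bond_context(chain, chain.positions[di])
                    for rule in rules_for_context(ctx):
                        _, nl = fragment_neutral_loss(chain, di, rule)
                        frag = prec - nl
                        if frag <= 0:
                            continue
                        assert min(abs(m - frag) for m in ref.mzs) < 1e-6


class TestSpecialCases:
    def test_sphingoid_delta4_uses_low_abundance_subset(self):
        sp = parse_lipid_name("SM 18:1(Δ4);O2/18:1(n-9)")
        base = sp.chains[0]
        assert bond_context(base, 14) == "sphingoid_delta4"
        pair = diagnostic_pair(base, 0)
        assert all(rule.rel_intensity <= 0.01 for rule, _ in pair)

    def test_sphingoid_delta8_and_beyond_use_standard_rules(self):
        sp = parse_lipid_name("Cer 18:2(Δ4,8);O2/24:1(n-9)")
        base = sp.chains[0]
        assert bond_context(base, 10) == "acyl"  # Δ8 on C18
        assert special_case_rules("sphingoid_delta_ge8") == rules_for_context("acyl")

    def test_vinyl_ether_entries_near_printed_values(self):
        sp = parse_lipid_name("PE P-18:0/18:1(n-9)")
        ref = generate_reference_spectrum(sp)
        ve = [p.mz for p in ref.peaks if "vinyl-ether" in p.annotation]
        assert any(abs(m - 521.3148) < 0.005 for m in ve)
        assert any(abs(m - 522.3122) < 0.010 for m in ve)

    def test_unknown_context_rejected(self):
        with pytest.raises(RuleError):
            special_case_rules("weird")


def test_msp_export_roundtrippable_text(tmp_path):
    spectra = [generate_reference_spectrum(parse_lipid_name("PC 18:0/18:1(n-9)"))]
    path = tmp_path / "ref.msp"
    export_msp(spectra, path)
    text = path.read_text()
    assert "NAME: PC 18:0/18:1(n-9)" in text
    assert f"Num Peaks: {len(spectra[0].peaks)}" in text


def test_loaded_rules_equal_default(tmp_path):
    import importlib.resources as res

    src = res.files("oadlipid.data").joinpath("oad_rules.tsv").read_text()
    p = tmp_path / "rules.tsv"
    p.write_text(src)
    assert load_rules(p) == default_rules()
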
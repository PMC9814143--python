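"""Peak matching, diagnostic-pair verification, scoring and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oadlipid.config import Config, MatchingConfig
from oadlipid.matching import (
    MeasuredSpectrum,
    annotate_species,
    match_peaks,
    rank_candidates,
    reverse_dot_product,
    verify_essential_pair,
)
from oadlipid.nomenclature import parse_lipid_name, precursor_mz
from oadlipid.rules import (
    TheoreticalPeak,
    TheoreticalSpectrum,
    generate_reference_spectrum,
)
from oadlipid.simulate import SimulationConfig, simulate_spectrum


def _spec(mz, inten, prec=900.0, rt=5.0):
    return MeasuredSpectrum(prec, rt, np.asarray(mz, float),
                            np.asarray(inten, float))


def _ref(peaks, prec=900.0):
    return TheoreticalSpectrum(
        species_name="toy", precursor_mz=prec, adduct="[M+H]+",
        peaks=tuple(TheoreticalPeak(m, i, f"p{k}")
                    for k, (m, i) in enumerate(peaks)),
    )


class TestMatchPeaks:
    def test_match_within_half_ppm(self):
        ref = _ref([(933.6816, 0.1)])
        meas = _spec([933.6820], [10.0])
        (ri, mi, ppm), = match_peaks(meas, ref, tol_ppm=15.0)
        assert mi == 0
        assert ppm == pytest.approx(0.43, abs=0.05)

    def test_39_ppm_apart_is_unmatched(self):
        ref = _ref([(933.6816, 0.1)])
        meas = _spec([933.6452], [10.0])
        (ri, mi, ppm), = match_peaks(meas, ref, tol_ppm=15.0)
        assert mi is None and ppm is None

    def test_empty_measured_spectrum(self):
        ref = _ref([(500.0, 0.5)])
        meas = _spec([], [])
        assert match_peaks(meas, ref, 15.0) == [(0, None, None)]

    def test_nearest_of_two_in_window_wins(self):
        ref = _ref([(500.0, 0.5)])
        meas = _spec([499.9990, 500.0020], [1.0, 1.0])
        (_, mi, _), = match_peaks(meas, ref, tol_ppm=15.0)
        assert mi == 0  # 2 ppm beats 4 ppm


class TestVerifyEssentialPair:
    def _oleoyl_pc(self):
        return parse_lipid_name("PC 18:0/18:1(n-9)")

    def _pair_mzs(self, sp):
        prec = precursor_mz(sp)
        return prec - 97.13811, prec - 139.14868

    def test_both_pair_ions_present_passes(self):
        sp = self._oleoyl_pc()
        a, b = self._pair_mzs(sp)
        meas = _spec([184.0733, a, b], [1e5, 20.0, 20.0])  # 0.02 % each
        ver = verify_essential_pair(meas, sp)
        assert ver.per_bond == (True,)
        assert len(ver.evidence) == 2

    def test_one_missing_pair_ion_fails(self):
        sp = self._oleoyl_pc()
        a, _ = self._pair_mzs(sp)
        meas = _spec([184.0733, a], [1e5, 20.0])
        assert verify_essential_pair(meas, sp).per_bond == (False,)

    def test_below_intensity_threshold_fails(self):
        sp = self._oleoyl_pc()
        a, b = self._pair_mzs(sp)
        meas = _spec([184.0733, a, b], [1e5, 5.0, 20.0])  # 0.005 % < 0.01 %
        assert verify_essential_pair(meas, sp).per_bond == (False,)

    def test_delta4_threshold_is_laxer_than_acyl(self):
        """An ion at 0.007 % passes the Δ4 threshold but not the acyl one."""
        sm = parse_lipid_name("SM 18:1(Δ4);O2/18:0")
        prec = precursor_mz(sm)
        from oadlipid.rules import diagnostic_pair

        pair = [prec - nl for _, nl in diagnostic_pair(sm.chains[0], 0)]
        meas = _spec([184.0733] + pair, [1e5, 7.0, 7.0])
        assert verify_essential_pair(meas, sm).per_bond == (True,)
        strict = MatchingConfig(min_rel_intensity_delta4=0.0001)
        assert verify_essential_pair(meas, sm, config=strict).per_bond == (False,)


class TestReverseDotProduct:
    def test_exact_copy_scores_one(self):
        ref = _ref([(200.0, 0.2), (300.0, 1.0), (400.0, 0.05)])
        meas = _spec([200.0, 300.0, 400.0], [0.2, 1.0, 0.05])
        assert reverse_dot_product(meas, ref, 15.0) == pytest.approx(1.0)

    def test_nothing_matched_scores_zero(self):
        ref = _ref([(200.0, 0.2)])
        meas = _spec([500.0], [1.0])
        assert reverse_dot_product(meas, ref, 15.0) == 0.0

    def test_three_peak_toy_vectors_match_hand_value(self):
        """Intensities (4,1,0) vs reference (1,1,1):
        score = (2*1 + 1*1)^2 / ((4+1) * 3) = 9/15 = 0.6 by hand."""
        ref = _ref([(200.0, 1.0), (300.0, 1.0), (400.0, 1.0)])
        meas = _spec([200.0, 300.0], [4.0, 1.0])
        assert reverse_dot_product(meas, ref, 15.0) == pytest.approx(0.6)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            reverse_dot_product(_spec([100.0], [1.0]), _ref([]), 15.0)

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_uniform_intensity_scaling(self, factor):
        ref = _ref([(200.0, 0.2), (300.0, 1.0), (400.0, 0.05)])
        meas1 = _spec([200.0, 300.0, 410.0], [3.0, 8.0, 1.0])
        meas2 = _spec([200.0, 300.0, 410.0],
                      [3.0 * factor, 8.0 * factor, 1.0 * factor])
        s1 = reverse_dot_product(meas1, ref, 15.0)
        s2 = reverse_dot_product(meas2, ref, 15.0)
        assert 0.0 <= s1 <= 1.0
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestRanking:
    def test_single_survivor_is_unambiguous(self, noise_free):
        truth = parse_lipid_name("LPC 18:1(n-9)")
        meas = simulate_spectrum(truth, noise_free, 0)
        out = annotate_species(parse_lipid_name("LPC 18:1"), meas)
        assert out.status == "resolved"
        assert out.resolved_name == "LPC 18:1(n-9)"
        assert out.score == pytest.approx(1.0, abs=1e-9)

    def test_no_survivors_is_unresolved(self):
        meas = _spec([184.0733], [1e5], prec=precursor_mz(
            parse_lipid_name("PC 18:0/18:1")
        ))
        out = annotate_species(parse_lipid_name("PC 18:0/18:1"), meas)
        assert out.status == "unresolved"
        assert out.species is None

    def test_equal_score_candidates_reported_with_ampersand(self, noise_free):
        """Assignments whose reference spectra coincide peak for peak
        (swapping n-7/n-6 between a 16:1 and an 18:2 chain reproduces the
        same fragment families) tie exactly and surface as an '&'
        ambiguity over the differing first positions."""
        truth = parse_lipid_name("PC 16:1(n-7)_18:2(n-6,9)")
        meas = simulate_spectrum(truth, noise_free, 0)
        out = annotate_species(parse_lipid_name("PC 16:1_18:2"), meas)
        assert out.status == "ambiguous"
        assert out.ambiguous_label == "18:2(n-6&7)"
        assert set(out.tied_names) == {
            "PC 16:1(n-6)_18:2(n-7,9)", "PC 16:1(n-7)_18:2(n-6,9)",
        }

    def test_removing_pair_ion_never_gains_verifications(self, noise_free):
        """Monotonicity: deleting a diagnostic ion can only shrink the set of
        candidates passing verification."""
        truth = parse_lipid_name("LPC 18:2(n-6,9)")
        meas = simulate_spectrum(truth, noise_free, 0)
        sp = parse_lipid_name("LPC 18:2")
        chain = sp.chains[0]
        from oadlipid.enumeration import enumerate_positions

        cands = [sp.with_chain(0, chain.with_positions(t))
                 for t in enumerate_positions(18, 2)]
        full = {
            tuple(c.species.chains[0].positions)
            for c in rank_candidates(meas, cands)
        }
        # delete the oxygen-retaining pair ion of the n-6 bond
        drop = precursor_mz(truth) - 55.09116  # C5H11 - O
        keep = np.abs(meas.mz - drop) > 0.001
        pruned_meas = MeasuredSpectrum(
            meas.precursor_mz, meas.retention_time,
            meas.mz[keep], meas.intensity[keep],
        )
        pruned = {
            tuple(c.species.chains[0].positions)
            for c in rank_candidates(pruned_meas, cands)
        }
        assert pruned <= full

    def test_chain_unresolved_flag_for_equal_dbe_swaps(self, noise_free):
        truth = parse_lipid_name("PC 16:1(n-7)_18:1(n-9)")
        meas = simulate_spectrum(truth, noise_free, 0)
        out = annotate_species(parse_lipid_name("PC 16:1_18:1"), meas)
        assert out.status in ("chain-unresolved", "ambiguous")

    def test_roundtrip_identity_on_noise_free_spectrum(self, noise_free):
        truth = parse_lipid_name("PC 18:1(n-9)_22:6(n-3,6,9,12,15,18)")
        meas = simulate_spectrum(truth, noise_free, 0)
        out = annotate_species(parse_lipid_name("PC 18:1_22:6"), meas)
        assert out.status == "resolved"
        assert out.resolved_name == "PC 18:1(n-9)_22:6(n-3,6,9,12,15,18)"
        assert out.n_candidates == 14 + 1716
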
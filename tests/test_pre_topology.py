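"""Accessibility ratios, TM boundary calling, and profile comparison."""

import numpy as np
import pandas as pd
import pytest

from bicellefit.pre_topology import (
    HYDROPHILIC,
    LIPOPHILIC,
    AccessibilityProfile,
    TopologyParams,
    call_tm_boundaries,
    compare_profiles,
    intensity_ratio_profile,
)
from bicellefit.synthetic_data import (
    BETA1_TMCT,
    BETA3_TMCT,
    TopologyFixture,
    simulate_pre_profiles,
)


def peak_table(residues, intensities):
    return pd.DataFrame({"residue": residues, "intensity": intensities})


class TestIntensityRatioProfile:
    def test_identical_tables_all_ones(self):
        tab = peak_table(range(700, 720), np.full(20, 100.0))
        prof = intensity_ratio_profile(tab, tab, noise=1.0)
        assert np.allclose(prof.ratio, 1.0)

    def test_missing_paramagnetic_peak_is_broadened_out(self):
        dia = peak_table([700, 701, 702], [100.0, 80.0, 120.0])
        para = peak_table([700, 702], [90.0, 60.0])
        prof = intensity_ratio_profile(para, dia, noise=4.0)
        i = list(prof.residues).index(701)
        assert prof.ratio[i] == 0.0
        assert prof.error[i] == pytest.approx(4.0 / 80.0)

    def test_five_percent_error_floor(self):
        dia = peak_table([700], [100.0])
        para = peak_table([700], [80.0])
        # tiny noise: propagated error ~0.0018 < 5% of 0.8 = 0.04
        prof = intensity_ratio_profile(para, dia, noise=0.1)
        assert prof.ratio[0] == pytest.approx(0.8)
        assert prof.error[0] == pytest.approx(0.04)

    def test_noise_error_used_when_larger(self):
        dia = peak_table([700], [100.0])
        para = peak_table([700], [80.0])
        prof = intensity_ratio_profile(para, dia, noise=20.0)
        expected = 0.8 * np.hypot(20 / 80, 20 / 100)
        assert prof.error[0] == pytest.approx(expected)
        assert prof.error[0] > 0.05 * 0.8

    def test_no_matches_or_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            intensity_ratio_profile(peak_table([1], [1.0]), peak_table([], []), noise=0)
        with pytest.raises(ValueError):
            intensity_ratio_profile(
                peak_table([1], [-1.0]), peak_table([1], [1.0]), noise=0)


class TestCallTmBoundaries:
    @pytest.mark.parametrize("fixture", [BETA1_TMCT, BETA3_TMCT], ids=lambda f: f.name)
    def test_noise_free_fixture_recovers_annotated_span(self, fixture):
        hyd, lip = simulate_pre_profiles(fixture)
        call = call_tm_boundaries(hyd, lip)
        assert (call.tm_start, call.tm_end) == fixture.tm_span

    def test_relocated_tm_followed(self):
        fx = TopologyFixture("relocated", (685, 762), (700, 725), (700, 730))
        hyd, lip = simulate_pre_profiles(fx)
        call = call_tm_boundaries(hyd, lip)
        assert (call.tm_start, call.tm_end) == (700, 725)

    def test_uniformly_exposed_profile_gives_empty_call(self):
        res = np.arange(700, 760)
        hyd = AccessibilityProfile(res, np.full(res.size, 0.2), np.zeros(res.size), HYDROPHILIC)
        lip = AccessibilityProfile(res, np.full(res.size, 0.9), np.zeros(res.size), LIPOPHILIC)
        call = call_tm_boundaries(hyd, lip)
        assert not call.has_tm
        assert call.evidence["flag"] == "no membrane-embedded span"

    def test_scaling_invariance_of_boundaries(self):
        hyd, lip = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=12)
        call = call_tm_boundaries(hyd, lip)
        scale = lambda p: AccessibilityProfile(  # noqa: E731 - ratios unchanged
            p.residues, p.ratio, p.error, p.probe)
        rescaled = call_tm_boundaries(scale(hyd), scale(lip))
        assert (rescaled.tm_start, rescaled.tm_end) == (call.tm_start, call.tm_end)
        assert rescaled.protected_segments == call.protected_segments
        assert rescaled.exposed_segments == call.exposed_segments

    def test_noisy_boundary_recovery_rate(self):
        """5% noise: boundaries within +-2 residues of truth in >=90/100 seeds."""
        hits = 0
        for seed in range(100):
            hyd, lip = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=seed)
            call = call_tm_boundaries(hyd, lip)
            if call.has_tm and abs(call.tm_start - 732) <= 2 and abs(call.tm_end - 757) <= 2:
                hits += 1
        assert hits >= 90

    def test_insufficient_overlap_rejected(self):
        res = np.arange(700, 706)
        hyd = AccessibilityProfile(res, np.ones(6), np.zeros(6), HYDROPHILIC)
        lip = AccessibilityProfile(res, np.ones(6), np.zeros(6), LIPOPHILIC)
        with pytest.raises(ValueError):
            call_tm_boundaries(hyd, lip)

    def test_min_run_configurable(self):
        fx = TopologyFixture("short_tm", (700, 760), (725, 733), (725, 736))
        hyd, lip = simulate_pre_profiles(fx)
        assert not call_tm_boundaries(hyd, lip).has_tm  # 9 < default 12
        call = call_tm_boundaries(hyd, lip, TopologyParams(min_run=8))
        assert (call.tm_start, call.tm_end) == (725, 733)


class TestCompareProfiles:
    def test_identical_profiles_unchanged(self):
        hyd, _ = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=1)
        cmp = compare_profiles(hyd, hyd)
        assert cmp.n_significant == 0
        assert cmp.verdict == "unchanged"

    def test_symmetry(self):
        a, _ = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=2)
        b, _ = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=3)
        ab, ba = compare_profiles(a, b), compare_profiles(b, a)
        assert np.allclose(ab.per_residue_delta, -ba.per_residue_delta)
        assert ab.verdict == ba.verdict

    def test_independent_realizations_mostly_unchanged(self):
        """Two same-truth noisy profiles read as unchanged in >=90/100 seeds."""
        unchanged = 0
        for seed in range(100):
            a, _ = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=seed)
            b, _ = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=10_000 + seed)
            if compare_profiles(a, b).verdict == "unchanged":
                unchanged += 1
        assert unchanged >= 90

    def test_shifted_tm_reads_as_changed(self):
        shifted = TopologyFixture("shifted", (719, 798), (742, 767), (742, 775))
        a, _ = simulate_pre_profiles(BETA1_TMCT, noise_sd=0.05, seed=4)
        b, _ = simulate_pre_profiles(shifted, noise_sd=0.05, seed=5)
        assert compare_profiles(a, b).verdict == "changed"

    def test_chelate_artifact_changes_hydrophilic_only(self):
        h0, l0 = simulate_pre_profiles(BETA3_TMCT, seed=6)
        h1, l1 = simulate_pre_profiles(BETA3_TMCT, seed=6, artifact_site=716)
        assert compare_profiles(h0, h1).verdict == "changed"
        assert compare_profiles(l0, l1).verdict == "unchanged"

    def test_probe_class_mismatch_rejected(self):
        hyd, lip = simulate_pre_profiles(BETA1_TMCT)
        with pytest.raises(ValueError):
            compare_profiles(hyd, lip)


def test_profile_validation():
    with pytest.raises(ValueError):
        AccessibilityProfile(np.array([1, 2]), np.array([-0.1, 0.5]),
                             np.zeros(2), HYDROPHILIC)
    with pytest.raises(ValueError):
        AccessibilityProfile(np.array([1, 1]), np.array([0.5, 0.5]),
                             np.zeros(2), HYDROPHILIC)
    # error floor applied on construction
    p = AccessibilityProfile(np.array([1]), np.array([0.8]), np.array([0.01]), LIPOPHILIC)
    assert p.error[0] == pytest.approx(0.04)
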
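"""LKB model: EUD reduction, effective volume, probit response."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungntcp import (
    DoseVolumeHistogram,
    LKBParameters,
    effective_volume,
    eud,
    list_presets,
    load_preset,
    max_dose,
    mean_dose,
    ntcp_for_patient,
    ntcp_from_eud,
    standard_normal_cdf,
)
from lungntcp.errors import ParameterError

from conftest import make_record, random_differential_dvh, uniform_dvh

BREAST_FIT = LKBParameters(n=0.912, m=0.437, td50_1_gy=17.211)


def two_mass_dvh():
    return DoseVolumeHistogram(
        np.array([10.0, 50.0]), np.array([0.5, 0.5]), "differential"
    )


class TestParameters:
    def test_positivity_enforced(self):
        for bad in [(0, 0.4, 17), (0.9, -1, 17), (0.9, 0.4, 0)]:
            with pytest.raises(ParameterError):
                LKBParameters(*bad)

    def test_sanity_bounds(self):
        with pytest.raises(ParameterError):
            LKBParameters(6.0, 0.4, 17.0)

    def test_json_roundtrip(self):
        p = LKBParameters.from_json(BREAST_FIT.to_json())
        assert p == BREAST_FIT

    def test_presets(self):
        assert set(list_presets()) == {"breast_imrt_lung", "emami_burman_lung"}
        assert load_preset("breast_imrt_lung") == BREAST_FIT
        hist = load_preset("emami_burman_lung")
        assert (hist.n, hist.m, hist.td50_1_gy) == (0.87, 0.18, 24.5)


class TestEud:
    def test_n_one_is_mean_dose(self):
        assert eud(two_mass_dvh(), 1.0) == pytest.approx(30.0, abs=1e-9)

    def test_power_mean_hand_value(self):
        # (0.5*10^2 + 0.5*50^2)^0.5
        assert eud(two_mass_dvh(), 0.5) == pytest.approx(np.sqrt(1300.0), abs=1e-9)

    def test_uniform_identity_all_n(self):
        for n in (0.05, 0.3, 1.0, 3.0):
            assert eud(uniform_dvh(17.211), n) == pytest.approx(17.211, rel=1e-12)

    def test_invalid_n(self):
        with pytest.raises(ParameterError):
            eud(two_mass_dvh(), 0.0)

    def test_all_mass_at_zero_dose(self):
        h = DoseVolumeHistogram(np.array([0.0]), np.array([1.0]), "differential")
        assert eud(h, 0.9) == 0.0

    def test_small_n_does_not_overflow(self):
        # 1/n = 50 on doses up to 60 Gy would overflow in linear space
        val = eud(two_mass_dvh(), 0.02)
        assert 49.0 < val <= 50.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mean_dose_equivalence_and_bounds(self, seed):
        h = random_differential_dvh(np.random.default_rng(seed))
        assert abs(eud(h, 1.0) - mean_dose(h)) <= 1e-9
        for n in (0.2, 0.912, 2.5):
            e = eud(h, n)
            assert h.doses_gy.min() - 1e-9 <= e <= h.doses_gy.max() + 1e-9


class TestEffectiveVolume:
    def test_hand_value(self):
        h = two_mass_dvh()
        assert effective_volume(h, 0.5, 50.0) == pytest.approx(0.52, abs=1e-12)

    def test_uniform_whole_organ(self):
        assert effective_volume(uniform_dvh(50.0), 0.7, 50.0) == pytest.approx(1.0)

    def test_bad_reference(self):
        with pytest.raises(ParameterError):
            effective_volume(two_mass_dvh(), 0.5, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([0.3, 0.912, 1.7]))
    def test_eud_identity(self, seed, n):
        """D_ref * v_eff^n == EUD: the KB reduction and the power mean agree."""
        h = random_differential_dvh(np.random.default_rng(seed))
        dref = max_dose(h)
        v = effective_volume(h, n, dref)
        assert dref * v**n == pytest.approx(eud(h, n), abs=1e-9)
        assert 0.0 <= v <= 1.0 + 1e-12


class TestProbitResponse:
    def test_phi_basics(self):
        assert standard_normal_cdf(0.0) == 0.5
        assert standard_normal_cdf(1.0356) == pytest.approx(0.8498, abs=5e-5)
        for t in np.linspace(-6, 6, 25):
            assert standard_normal_cdf(t) + standard_normal_cdf(-t) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_half_probability_at_td50(self):
        for params in (BREAST_FIT, LKBParameters(0.3, 1.2, 40.0)):
            assert ntcp_from_eud(params.td50_1_gy, params) == 0.5

    def test_published_triple_evaluation(self):
        assert ntcp_from_eud(25.0, BREAST_FIT) == pytest.approx(0.8498, abs=5e-5)

    def test_zero_eud_limit(self):
        assert ntcp_from_eud(0.0, BREAST_FIT) == pytest.approx(
            standard_normal_cdf(-1.0 / 0.437), rel=1e-12
        )
        assert ntcp_from_eud(0.0, BREAST_FIT) == pytest.approx(0.0111, abs=5e-5)

    def test_monotone_in_eud_and_td50(self):
        es = np.linspace(0, 60, 50)
        vals = [ntcp_from_eud(e, BREAST_FIT) for e in es]
        assert np.all(np.diff(vals) > 0)
        tds = np.linspace(5, 60, 40)
        at_fixed_eud = [
            ntcp_from_eud(25.0, LKBParameters(0.912, 0.437, td)) for td in tds
        ]
        assert np.all(np.diff(at_fixed_eud) < 0)


class TestPatientNtcp:
    def test_uniform_at_td50(self):
        rec = make_record("p1", uniform_dvh(17.211))
        assert ntcp_for_patient(rec, BREAST_FIT) == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_patient(self):
        rec = make_record(
            "p2", DoseVolumeHistogram(np.array([0.0]), np.array([1.0]), "differential")
        )
        assert ntcp_for_patient(rec, BREAST_FIT) == pytest.approx(
            standard_normal_cdf(-1.0 / BREAST_FIT.m), rel=1e-12
        )

    def test_strictly_increasing_under_dose_scaling(self):
        rng = np.random.default_rng(3)
        h = random_differential_dvh(rng)
        scales = np.linspace(0.2, 1.8, 25)
        vals = []
        for s in scales:
            hs = DoseVolumeHistogram(h.doses_gy * s, h.volumes, "differential")
            vals.append(ntcp_for_patient(make_record("x", hs), BREAST_FIT))
        assert np.all(np.diff(vals) > 0)
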
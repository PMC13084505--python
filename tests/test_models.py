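"""Unit and property tests for the multilayer model and classical family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sorbfit as sf
from sorbfit.errors import DomainError, RangeOverflowError, ValidationError

from conftest import brute_force_uptake


class TestCondensationTerm:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (0.0, 1.0),
            (1.0, 5.0**1.5),
            (0.5, 1.9375**1.5),  # 1 + .5 + .25 + .125 + .0625 = 1.9375
        ],
    )
    def test_values(self, z, expected):
        assert sf.condensation_term(z) == pytest.approx(expected, rel=1e-14)

    def test_strictly_increasing(self):
        z = np.linspace(0.0, 5.0, 200)
        ct = sf.condensation_term(z)
        assert np.all(np.diff(ct) > 0)
        assert np.all(ct >= 1.0)

    @pytest.mark.parametrize("bad", [-0.1, math.nan, math.inf])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            sf.condensation_term(bad)


class TestUptakeSingle:
    def test_zero_activity_is_zero_uptake(self):
        # including the m = 0 case where a 0**0 subterm appears (times zero)
        for sg in [
            sf.Sitegroup(1.0, 1.0, 1.0, 0.0, 1.0),
            sf.Sitegroup(0.5, 100.0, 2.0, 3.5, 2.0),
            sf.Sitegroup(2.0, 10.0, 0.5, math.inf, 1.0),
        ]:
            assert sf.uptake_single(sg, 0.0) == 0.0

    def test_langmuir_half_saturation(self):
        sg = sf.Sitegroup(alpha=1.0, K1=1.0, K2=0.0, m=0.0, N=1.0)
        assert sf.uptake_single(sg, 1.0) == pytest.approx(0.5, abs=1e-15)

    def test_condensation_enhanced_point(self):
        # alpha=1, K1=2, K2=1, m=1, N=1 at x=1 sits exactly on K2*x = 1:
        # explicit summation gives 2*(3 + (CT-1)) / (1 + 2*(2 + (CT-1)/2))
        ct = 5.0**1.5
        expected = 2.0 * (3.0 + (ct - 1.0)) / (1.0 + 2.0 * (2.0 + 0.5 * (ct - 1.0)))
        sg = sf.Sitegroup(1.0, 2.0, 1.0, 1.0, 1.0)
        assert sf.uptake_single(sg, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_null_isotherm_for_zero_K1(self):
        sg = sf.Sitegroup(alpha=1.0, K1=0.0, K2=2.0, m=3.0, N=5.0)
        x = np.linspace(0, 2, 17)
        assert np.all(np.asarray(sf.uptake_single(sg, x)) == 0.0)

    def test_infinite_layers_domain(self):
        sg = sf.Sitegroup(1.0, 10.0, 2.0, math.inf, 1.0)
        with pytest.raises(DomainError):
            sf.uptake_single(sg, 0.5)  # K2*x = 1
        assert sf.uptake_single(sg, 0.25) > 0

    def test_nonfinite_input_rejected(self):
        sg = sf.Sitegroup(1.0, 1.0, 1.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            sf.uptake_single(sg, math.nan)
        with pytest.raises(DomainError):
            sf.uptake_single(sg, -0.5)

    def test_overflow_guarded(self):
        sg = sf.Sitegroup(1.0, 1.0, 10.0, 1e5, 1.0)
        with pytest.raises(RangeOverflowError):
            sf.uptake_single(sg, 10.0)

    @pytest.mark.parametrize("m", [0, 1, 2, 3, 4])
    def test_explicit_summation_oracle(self, m, rng):
        for _ in range(40):
            alpha = rng.uniform(0.3, 3.0)
            K1 = 10.0 ** rng.uniform(-1, 3)
            K2 = 10.0 ** rng.uniform(-1, 1)
            N = rng.uniform(0.1, 5.0)
            x = rng.uniform(1e-4, 1.0)
            sg = sf.Sitegroup(alpha, K1, K2, float(m), N)
            expected = brute_force_uptake(alpha, K1, K2, m, N, x)
            assert sf.uptake_single(sg, x) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("eps", [1e-3, 1e-6, 1e-9, 0.0, -1e-9, -1e-6, -1e-3])
    def test_oracle_near_condensation_point(self, eps):
        # approach K2*x = 1 from both sides; the limit replacements must agree
        # with the explicit summation to full precision
        sg = sf.Sitegroup(1.3, 2.0, 1.0, 3.0, 1.0)
        x = 1.0 - eps
        expected = brute_force_uptake(1.3, 2.0, 1.0, 3, 1.0, x)
        assert sf.uptake_single(sg, x) == pytest.approx(expected, rel=1e-10)

    def test_continuity_in_m_toward_sips(self):
        sips = sf.ClassicalModel("sips", {"N": 2.0, "K1": 5.0, "alpha": 0.7})
        x = np.linspace(0.01, 1.0, 30)
        tiny_m = sf.Sitegroup(0.7, 5.0, 1.5, 1e-9, 2.0)
        assert np.allclose(
            sf.uptake_single(tiny_m, x), sf.classical_uptake(sips, x), rtol=1e-7
        )


class TestPlateau:
    @pytest.mark.parametrize(
        "m, N, expected", [(1.0, 1.0, 2.0), (0.5, 2.0, 3.0), (4.0, 0.25, 1.25)]
    )
    def test_values(self, m, N, expected):
        assert sf.plateau(sf.Sitegroup(1.0, 1.0, 1.0, m, N)) == expected

    @pytest.mark.parametrize("m", [0.0, math.inf])
    def test_rejects_degenerate_m(self, m):
        with pytest.raises(DomainError):
            sf.plateau(sf.Sitegroup(1.0, 1.0, 1.0, m, 1.0))

    def test_approached_from_below(self):
        sg = sf.Sitegroup(0.5, 700.0, 1.3, 2.0, 1.2)
        q = sf.uptake_single(sg, 1e6 / sg.K2)
        assert q <= sf.plateau(sg) * (1.0 + 1e-12)  # below, up to rounding
        assert q == pytest.approx(sf.plateau(sg), rel=1e-4)
        # strictly below at a point farther from the limit
        assert sf.uptake_single(sg, 10.0 / sg.K2) < sf.plateau(sg)


class TestLowCoverageAsymptote:
    def test_examples(self):
        sg = sf.Sitegroup(1.0, 10.0, 1.0, 1.0, 1.0)
        assert sf.low_coverage_asymptote(sg, 0.0) == 0.0
        assert sf.low_coverage_asymptote(sg, 0.001) == pytest.approx(0.01 / 1.01, rel=1e-12)

    def test_ratio_tends_to_one(self):
        sg = sf.Sitegroup(1.0, 1.0, 1.0, 3.0, 1.0)
        x = 1e-6
        ratio = sf.uptake_single(sg, x) / sf.low_coverage_asymptote(sg, x)
        assert ratio == pytest.approx(1.0, abs=1e-4)


class TestMultilayerModel:
    def test_single_sum_identity(self):
        sg = sf.Sitegroup(0.8, 3.0, 1.1, 2.0, 1.5)
        model = sf.MultilayerModel((sg,))
        x = np.linspace(0, 1, 11)
        assert np.array_equal(sf.uptake(model, x), sf.uptake_single(sg, x))

    def test_two_identical_sitegroups_double(self):
        sg = sf.Sitegroup(0.8, 3.0, 1.1, 2.0, 1.5)
        model = sf.MultilayerModel((sg, sg))
        x = np.linspace(0, 1, 11)
        assert np.allclose(sf.uptake(model, x), 2.0 * np.asarray(sf.uptake_single(sg, x)), rtol=0)

    def test_zero_capacity_null(self):
        model = sf.MultilayerModel(
            (sf.Sitegroup(1.0, 5.0, 1.0, 1.0, 0.0), sf.Sitegroup(2.0, 1.0, 0.5, 2.0, 0.0))
        )
        assert np.all(np.asarray(sf.uptake(model, np.linspace(0, 1, 9))) == 0.0)

    def test_empty_model_invalid(self):
        with pytest.raises(ValidationError):
            sf.MultilayerModel(())

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alpha=0.0, K1=1, K2=1, m=1, N=1),
            dict(alpha=1.0, K1=-1, K2=1, m=1, N=1),
            dict(alpha=1.0, K1=1, K2=1, m=-0.5, N=1),
            dict(alpha=math.inf, K1=1, K2=1, m=1, N=1),
            dict(alpha=1.0, K1=1, K2=1, m=1, N=math.nan),
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValidationError):
            sf.Sitegroup(**kwargs)


# --- limiting-case equivalences ---------------------------------------------

X_GRID = np.linspace(0.05, 0.85, 17)  # avoids x = 0/1 and K2*x = 1 singular points


class TestLimitingCases:
    def test_reduces_to_langmuir(self):
        md = sf.Sitegroup(1.0, 7.0, 0.0, 0.0, 2.0)
        ref = sf.ClassicalModel("langmuir", {"N": 2.0, "K1": 7.0})
        assert np.max(np.abs(sf.uptake_single(md, X_GRID) - sf.classical_uptake(ref, X_GRID))) < 1e-8

    def test_reduces_to_sips(self):
        md = sf.Sitegroup(0.6, 7.0, 3.0, 0.0, 2.0)  # m=0 tunes K2 out
        ref = sf.ClassicalModel("sips", {"N": 2.0, "K1": 7.0, "alpha": 0.6})
        assert np.max(np.abs(sf.uptake_single(md, X_GRID) - sf.classical_uptake(ref, X_GRID))) < 1e-8

    def test_reduces_to_bet(self):
        md = sf.Sitegroup(1.0, 100.0, 1.0, math.inf, 1.5)
        ref = sf.ClassicalModel("bet", {"N": 1.5, "K1": 100.0})
        assert np.max(np.abs(sf.uptake_single(md, X_GRID) - sf.classical_uptake(ref, X_GRID))) < 1e-8

    def test_reduces_to_anderson(self):
        md = sf.Sitegroup(1.0, 50.0, 0.8, math.inf, 1.5)
        ref = sf.ClassicalModel("anderson", {"N": 1.5, "K1": 50.0, "K2": 0.8})
        assert np.max(np.abs(sf.uptake_single(md, X_GRID) - sf.classical_uptake(ref, X_GRID))) < 1e-8

    def test_reduces_to_gab(self):
        md = sf.Sitegroup(1.0, 8.0, 0.8, math.inf, 1.0)  # K1 = c_G*k with c_G=10, k=0.8
        ref = sf.ClassicalModel("gab", {"Q_monolayer": 1.0, "c_G": 10.0, "k": 0.8})
        assert np.max(np.abs(sf.uptake_single(md, X_GRID) - sf.classical_uptake(ref, X_GRID))) < 1e-8


# --- classical forms and mappings -------------------------------------------


class TestClassicalUptake:
    @pytest.mark.parametrize(
        "kind, params, x, expected",
        [
            ("langmuir", {"N": 1, "K1": 1}, 1.0, 0.5),
            ("henry", {"N": 2, "K1": 3}, 0.1, 0.6),
            ("bet", {"N": 1, "K1": 100}, 0.5, 50.0 / 25.25),
            ("freundlich", {"N": 2, "K1": 4, "alpha": 0.5}, 0.25, 2.0),
            ("two_site_langmuir", {"N1": 1, "K1": 1, "N2": 2, "K2": 3}, 1.0, 0.5 + 1.5),
        ],
    )
    def test_closed_forms(self, kind, params, x, expected):
        model = sf.ClassicalModel(kind, params)
        assert sf.classical_uptake(model, x) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "kind, params, x, fragment",
        [
            ("bet", {"N": 1, "K1": 10}, 1.0, "(1 - x)"),
            ("anderson", {"N": 1, "K1": 10, "K2": 2.0}, 0.5, "K2*x < 1"),
            ("gab", {"Q_monolayer": 1, "c_G": 10, "k": 2.0}, 0.6, "k*a_w < 1"),
            ("pickett", {"N": 1, "K1": 10, "eta": 3}, 1.2, "(1 - x)"),
        ],
    )
    def test_domain_errors_name_denominator(self, kind, params, x, fragment):
        model = sf.ClassicalModel(kind, params)
        with pytest.raises(DomainError, match=r".+"):
            sf.classical_uptake(model, x)
        try:
            sf.classical_uptake(model, x)
        except DomainError as exc:
            assert fragment in str(exc)

    def test_eta_below_one_rejected(self):
        with pytest.raises(ValidationError):
            sf.ClassicalModel("eta_bet", {"N": 1, "K1": 10, "eta": 0.5})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            sf.ClassicalModel("toth", {"N": 1})


def _anderson_capacity_fraction_form(V, c, f, x):
    return V * c * x / ((1.0 - f * x) * (1.0 + (c - 1.0) * x))


def _anderson_layer_constant_form(Vm, c, k, j, x):
    return Vm * c * k * x / ((1.0 - j * k * x) * (1.0 + (c - j) * k * x))


def _gab_form(Qm, cG, k, a):
    return Qm * cG * k * a / ((1.0 - k * a) * (1.0 + (cG - 1.0) * k * a))


def _zeta_2007_form(M, aZ, c, zeta, x):
    t = aZ * x
    num = 1.0 - (1.0 + zeta) * t**zeta + zeta * t ** (1.0 + zeta)
    den = (1.0 - t) * (1.0 + (c - 1.0) * t - c * t ** (1.0 + zeta))
    return M * c * t * num / den


class TestMappings:
    def test_anderson_from_capacity_fraction_values(self):
        m = sf.anderson_from_capacity_fraction(2.0, 0.5, 1.0)
        assert m.params == {"N": pytest.approx(4.0 / 3.0), "K1": 1.5, "K2": 0.5}
        m2 = sf.anderson_from_capacity_fraction(1.0, 0.5, 1.0)
        assert m2.params == {"N": 2.0, "K1": 0.5, "K2": 0.5}

    def test_anderson_capacity_fraction_equivalence(self):
        c, f, V = 3.0, 0.4, 1.7
        mapped = sf.anderson_from_capacity_fraction(c, f, V)
        x = np.arange(0.1, 1.0, 0.1)
        diff = np.abs(
            sf.classical_uptake(mapped, x) - _anderson_capacity_fraction_form(V, c, f, x)
        )
        assert np.max(diff) < 1e-12

    def test_anderson_capacity_fraction_infeasible(self):
        with pytest.raises(DomainError):
            sf.anderson_from_capacity_fraction(0.5, 0.2, 1.0)  # c - 1 + f <= 0

    def test_anderson_layer_constant_equivalence(self):
        Vm, c, k, j = 1.3, 5.0, 0.6, 0.9
        mapped = sf.anderson_from_layer_constants(Vm, c, k, j)
        x = np.arange(0.1, 1.0, 0.1)
        diff = np.abs(
            sf.classical_uptake(mapped, x) - _anderson_layer_constant_form(Vm, c, k, j, x)
        )
        assert np.max(diff) < 1e-12

    def test_gab_mapping(self):
        m = sf.gab_to_anderson(10.0, 0.8, 1.0)
        assert m.params == {"N": 1.0, "K1": 8.0, "K2": 0.8}
        null = sf.gab_to_anderson(10.0, 0.0, 1.0)
        assert null.params["K1"] == 0.0 and null.params["K2"] == 0.0
        a = np.arange(0.1, 1.0, 0.1)
        diff = np.abs(sf.classical_uptake(m, a) - _gab_form(1.0, 10.0, 0.8, a))
        assert np.max(diff) < 1e-12

    def test_zeta_mapping_and_equivalence(self):
        mapped = sf.zeta_from_2007(M=1.0, alpha_Z=0.9, c=100.0, zeta=5.0)
        assert mapped.params == {"N": 1.0, "K2": 0.9, "K1": 90.0, "eta": 5.0}
        x = np.arange(0.1, 1.0, 0.1)
        diff = np.abs(
            sf.classical_uptake(mapped, x) - _zeta_2007_form(1.0, 0.9, 100.0, 5.0, x)
        )
        assert np.max(diff) < 1e-10

    def test_zeta_single_layer_is_langmuir(self):
        zeta1 = sf.ClassicalModel("zeta", {"N": 2.0, "K1": 5.0, "K2": 0.9, "eta": 1.0})
        lang = sf.ClassicalModel("langmuir", {"N": 2.0, "K1": 5.0})
        x = np.arange(0.1, 1.0, 0.1)
        assert np.allclose(sf.classical_uptake(zeta1, x), sf.classical_uptake(lang, x), atol=1e-12)


# --- property tests ----------------------------------------------------------

sitegroup_strategy = st.builds(
    sf.Sitegroup,
    alpha=st.floats(0.1, 5.0),
    K1=st.floats(0.0, 1e4),
    K2=st.floats(0.0, 5.0),
    m=st.floats(0.0, 50.0),
    N=st.floats(0.0, 10.0),
)


@given(sg=sitegroup_strategy)
def test_uptake_nonnegative_and_monotone(sg):
    x = np.linspace(0.0, 1.0, 101)
    q = np.asarray(sf.uptake_single(sg, x))
    assert np.all(q >= 0.0)
    assert np.all(np.diff(q) >= -1e-12 * max(q[-1], 1.0))


@given(sg=sitegroup_strategy, scale=st.floats(0.1, 10.0))
def test_uptake_homogeneous_in_capacity(sg, scale):
    x = np.linspace(0.0, 1.0, 21)
    scaled = sf.Sitegroup(sg.alpha, sg.K1, sg.K2, sg.m, sg.N * scale)
    assert np.allclose(
        np.asarray(sf.uptake_single(scaled, x)),
        scale * np.asarray(sf.uptake_single(sg, x)),
        rtol=1e-12,
        atol=1e-12,
    )
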
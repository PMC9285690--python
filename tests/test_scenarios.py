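"""Calibration closure, forcing modes, regimes, config files, sensitivity."""

import numpy as np
import pytest
import yaml

import forageweb as fw
from forageweb import ValidationError
from forageweb.scenarios import OPTIMIZATION_REGIMES, REGIME_NAMES


class TestDefaultParameters:
    def test_pelican_index_starts_at_100(self, params):
        assert params.pelican.N0 == 100

    def test_hcr_allocation_share(self, params):
        assert params.policy.hcr_share == 0.87

    def test_diet_fractions_sum_to_one(self, params):
        p = params.pelican
        assert p.Gamma_a + p.Gamma_s + p.Gamma_other == pytest.approx(1.0)

    def test_validates(self, params):
        params.validate()

    def test_unfished_equilibrium_is_fixed_point(self, params, nofish_200):
        # the closure pins r_bar = M + P* etc., so the constant-forcing
        # unfished system must sit exactly at its initial state
        y0, yT = nofish_200.states[0], nofish_200.states[-1]
        assert np.allclose(yT, y0, rtol=1e-6)

    def test_weak_top_down_control(self, params):
        from forageweb import predation_mortality
        Pa, Ps = predation_mortality(params.anchovy.X0, params.sardine.X0,
                                     params.halibut.X0, params.halibut)
        assert Pa < 0.5 * params.anchovy.M
        assert Ps < 0.5 * params.sardine.M

    def test_pelican_diet_sardine_dominant(self, params):
        p = params.pelican
        assert p.Gamma_s > p.Gamma_a


class TestForcing:
    def grid(self, p):
        return np.linspace(0, p, 2001)

    def test_constant_mode_flat(self, params):
        fo = fw.make_recruitment_forcing("constant", params)
        ra, rs = fo.rates(self.grid(25.0), params)
        assert np.allclose(ra, params.anchovy.r_bar)
        assert np.allclose(rs, params.sardine.r_bar)

    def test_synchronous_perfectly_correlated(self, params):
        fo = fw.make_recruitment_forcing("synchronous", params)
        ra, rs = fo.rates(self.grid(fo.anchovy[1]), params)
        corr = np.corrcoef(ra, rs)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_anti_synchronous_opposed(self, params):
        fo = fw.make_recruitment_forcing("anti_synchronous", params)
        assert fo.sardine[2] - fo.anchovy[2] == pytest.approx(180.0)
        ra, rs = fo.rates(self.grid(fo.anchovy[1]), params)
        # log-rates are exactly anti-correlated; the exponentiated rates
        # remain strongly opposed
        assert np.corrcoef(np.log(ra), np.log(rs))[0, 1] == pytest.approx(-1.0)
        assert np.corrcoef(ra, rs)[0, 1] < -0.95

    def test_long_sardine_period(self, params):
        fo = fw.make_recruitment_forcing("anti_synchronous_long_sardine", params)
        assert fo.sardine[1] > fo.anchovy[1]

    def test_unknown_mode_rejected(self, params):
        with pytest.raises(ValidationError):
            fw.make_recruitment_forcing("chaotic", params)

    def test_forcing_deterministic(self, params):
        fo1 = fw.make_recruitment_forcing("synchronous", params)
        fo2 = fw.make_recruitment_forcing("synchronous", params)
        t = self.grid(25.0)
        assert np.array_equal(fo1.rates(t, params)[0], fo2.rates(t, params)[0])


class TestRegimes:
    def test_seven_optimization_regimes(self):
        assert len(OPTIMIZATION_REGIMES) == 7
        for name in OPTIMIZATION_REGIMES:
            reg = fw.get_regime(name)
            assert len(reg.optimized) >= 1

    def test_registry_includes_oa_and_moratorium(self):
        assert "OA_all" in REGIME_NAMES
        assert "Moratorium_all" in REGIME_NAMES

    def test_regimes_partition_species(self):
        for name in REGIME_NAMES:
            reg = fw.get_regime(name)
            members = sorted(reg.optimized + reg.open_access + reg.closed)
            assert members == sorted(fw.SPECIES)

    def test_moratorium_subset(self):
        reg = fw.get_regime("Moratorium:A+S")
        assert set(reg.closed) == {"anchovy", "sardine"}
        assert reg.open_access == ("halibut",)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValidationError):
            fw.get_regime("X+Y")

    def test_scenario_registry_name(self):
        sc = fw.get_scenario("A+S/constant", T=50, close_baselines=False)
        assert sc.regime.name == "A+S"
        assert sc.forcing.mode == "constant"


class TestConfig:
    def test_empty_config_equals_defaults(self, tmp_path, params):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        assert fw.load_config(p) == params

    def test_delta_override_only(self, tmp_path, params):
        p = tmp_path / "c.yaml"
        p.write_text("delta: 0.10\n")
        ps = fw.load_config(p)
        assert ps.delta == 0.10
        ps.delta = params.delta
        assert ps == params

    def test_bad_diet_fractions_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(yaml.safe_dump(
            {"pelican": {"Gamma_a": 0.9, "Gamma_s": 0.9}}))
        with pytest.raises(ValidationError, match="diet fractions"):
            fw.load_config(p)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("sardine:\n  swim_speed: 3\n")
        with pytest.raises(ValidationError, match="swim_speed"):
            fw.load_config(p)

    def test_unknown_section_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("tuna:\n  M: 0.2\n")
        with pytest.raises(ValidationError, match="tuna"):
            fw.load_config(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            fw.load_config(tmp_path / "nope.yaml")


@pytest.fixture(scope="module")
def suite():
    base = fw.make_scenario("A+S+H", "anti_synchronous", T=50)
    return base, fw.sensitivity_suite(base)


class TestSensitivitySuite:
    def test_six_named_variants(self, suite):
        _, variants = suite
        assert len(variants) == 6
        assert len({v.name for v in variants}) == 6

    def test_discount_and_price_variants(self, suite):
        base, variants = suite
        by = {v.name.split("#")[1]: v for v in variants}
        assert by["high_discount"].params.delta == 0.10
        assert by["high_forage_price"].params.econ_sardine.p_tilde == \
            pytest.approx(1.25 * base.params.econ_sardine.p_tilde)

    def test_decoupling_variants(self, suite):
        _, variants = suite
        by = {v.name.split("#")[1]: v for v in variants}
        assert by["decoupled_survival"].params.pelican.theta_s[1] == 0
        assert by["decoupled_recruitment"].params.pelican.theta_r[1] == 0

    def test_half_initial_stocks(self, suite):
        base, variants = suite
        by = {v.name.split("#")[1]: v for v in variants}
        assert by["half_initial"].params.anchovy.X0 == \
            pytest.approx(0.5 * base.params.anchovy.X0)

    def test_long_sardine_variant_forcing(self, suite):
        _, variants = suite
        by = {v.name.split("#")[1]: v for v in variants}
        v = by["long_sardine_anti_synchronous"]
        assert v.params.sardine.p > v.params.anchovy.p

    def test_all_variants_validate(self, suite):
        _, variants = suite
        for v in variants:
            v.params.validate()
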
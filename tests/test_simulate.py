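"""Data-generating process: parameter derivation, randomization, admissibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rdgee
from rdgee.simulate import BLOCK_SIZE, ScenarioSpec, block_randomize, derive_params
from rdgee.exceptions import ConfigError


class TestDeriveParams:
    def test_identity_with_covariate(self):
        spec = ScenarioSpec(true_link="identity", pi_c=0.10, true_rd=0.05,
                            icc=0.05, covariate_effect="fifty_percent")
        p = derive_params(spec)
        assert p.alpha == pytest.approx(0.10)
        assert p.beta == pytest.approx(0.05)
        assert p.gamma == pytest.approx(0.05)
        assert p.pi_bar == pytest.approx(0.14)
        assert p.sigma2 == pytest.approx(0.05 * 0.14 * 0.86)  # 0.00602

    def test_log_null_effect(self):
        spec = ScenarioSpec(true_link="log", pi_c=0.25, true_rd=0.0, icc=0.07)
        p = derive_params(spec)
        assert p.beta == 0.0
        assert p.pi_bar == pytest.approx(0.25)
        assert p.sigma2 == pytest.approx(0.07 * 3.0)

    def test_log_beta_back_calculation(self):
        spec = ScenarioSpec(true_link="log", pi_c=0.10, true_rd=0.15, icc=0.01,
                            covariate_effect="fifty_percent")
        p = derive_params(spec)
        # at nu=0 and covariate prevalence 0.3 the marginal RD equals the target
        rd = np.exp(p.alpha + 0.3 * p.gamma) * (np.exp(p.beta) - 1)
        assert rd == pytest.approx(0.15)

    def test_sigma2_ranges_over_full_grid(self):
        """Center variance spans ~[0.001, 0.025] (identity), ~[0.006, 0.90] (log)."""
        values = {"identity": [], "log": []}
        for spec in rdgee.factorial_grid():
            values[spec.true_link].append(derive_params(spec).sigma2)
        lo_i, hi_i = min(values["identity"]), max(values["identity"])
        lo_l, hi_l = min(values["log"]), max(values["log"])
        assert lo_i == pytest.approx(0.001, abs=3e-4)
        assert hi_i == pytest.approx(0.025, abs=2e-3)
        assert lo_l == pytest.approx(0.006, abs=3e-3)
        assert hi_l == pytest.approx(0.90, abs=0.02)

    def test_inadmissible_cell_rejected(self):
        with pytest.raises(ConfigError, match="treatment=1, z=1"):
            ScenarioSpec(true_link="log", pi_c=0.60, true_rd=0.15, icc=0.01,
                         covariate_effect="fifty_percent")
        with pytest.raises(ConfigError):
            ScenarioSpec(true_link="identity", pi_c=0.60, true_rd=0.15, icc=0.01,
                         covariate_effect="fifty_percent")

    @pytest.mark.parametrize(
        "kw", [dict(icc=-0.1), dict(pi_c=0.0), dict(true_link="probit"),
               dict(covariate_effect="double"), dict(n_per_center=1)]
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ConfigError):
            ScenarioSpec(**kw)


class TestBlockRandomize:
    def test_complete_blocks_exactly_balanced(self):
        rng = np.random.default_rng(0)
        x = block_randomize(8, rng)
        assert x.size == 8 and x.sum() == 4

    def test_remainder_two_splits_evenly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert block_randomize(10, rng).sum() == 5

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=2, max_value=57), st.integers(0, 2**31 - 1))
    def test_imbalance_never_exceeds_one(self, n_j, seed):
        x = block_randomize(n_j, np.random.default_rng(seed))
        assert abs(int(x.sum()) - (n_j - int(x.sum()))) <= 1

    def test_within_block_arrangements_uniform(self):
        """All C(4,2)=6 arrangements of a complete block occur ~equally often."""
        rng = np.random.default_rng(12345)
        draws = 6000
        counts = {}
        for _ in range(draws):
            key = tuple(block_randomize(BLOCK_SIZE, rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        expected = draws / 6
        chi2 = sum((c - expected) ** 2 / expected for c in counts.values())
        assert chi2 < 20.5  # chi-square(5), far beyond the 0.999 quantile


class TestSimulateTrial:
    def test_reproducible_from_seed(self):
        spec = ScenarioSpec(seed=11, scenario_index=3)
        a = rdgee.simulate_trial(spec)
        b = rdgee.simulate_trial(spec)
        np.testing.assert_array_equal(a.outcome, b.outcome)
        np.testing.assert_array_equal(a.treatment, b.treatment)

    def test_structure_matches_spec(self):
        spec = ScenarioSpec(n_centers=18, n_per_center=10,
                            covariate_effect="fifty_percent", seed=1)
        data = rdgee.simulate_trial(spec)
        assert data.n == 180 and data.n_centers == 18
        assert set(data.cluster_sizes) == {10}
        assert data.has_covariate
        # per-center arm totals differ by at most 1
        for j in range(18):
            t = data.treatment[data.center_codes == j]
            assert abs(int(t.sum()) - (t.size - int(t.sum()))) <= 1

    def test_no_covariate_scenarios_omit_z(self):
        data = rdgee.simulate_trial(ScenarioSpec(seed=2))
        assert data.covariate is None

    def test_zero_icc_recovers_control_rate(self):
        """With rho=0 there is no center effect: control-arm rate ~ pi_c."""
        spec = ScenarioSpec(true_link="identity", pi_c=0.25, true_rd=0.10,
                            icc=0.0, n_per_center=100, seed=4)
        rates = []
        for r in range(60):
            data = rdgee.simulate_trial(spec, np.random.default_rng([4, r]))
            rates.append(data.outcome[data.treatment == 0].mean())
        assert np.mean(rates) == pytest.approx(0.25, abs=0.01)

    def test_unequal_center_sizes_accepted(self):
        spec = ScenarioSpec(n_centers=3, n_per_center=(5, 9, 14), seed=6)
        data = rdgee.simulate_trial(spec)
        assert sorted(data.cluster_sizes) == [5, 9, 14]
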
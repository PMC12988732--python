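"""Monte Carlo engine: spec validation, default assignment, degeneracy,
seeded reproducibility, quantile oracles, and convergence behaviour."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from eggrisk.data_io import ConcentrationRecord, ExposureProfile, ToxicityReference
from eggrisk.deterministic_risk import DomainError, assess, thq
from eggrisk.probabilistic_risk import (
    DistributionSpec,
    SpecSet,
    build_default_specs,
    convergence_check,
    percentile_threshold_report,
    run_mcs,
    simulate_cell,
)
from eggrisk.synthetic_data import GeneratorConfig, generate

RNG = lambda: np.random.default_rng(0)


class TestDistributionSpec:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("point", (1.0, 2.0)),
            ("normal", (1.0, 0.0)),
            ("lognormal", (0.0, -1.0)),
            ("uniform", (2.0, 1.0)),
            ("triangular", (-1.0, 0.0, 1.0)),
            ("triangular", (0.0, 2.0, 1.0)),
            ("empirical", ()),
            ("beta", (1.0, 1.0)),
        ],
    )
    def test_improper_parameters_rejected(self, family, params):
        with pytest.raises(DomainError):
            DistributionSpec(family, params)

    def test_point_draws_are_constant(self):
        x = DistributionSpec.point(0.3).sample(RNG(), 100)
        assert (x == 0.3).all()

    def test_degenerate_uniform_behaves_as_point(self):
        x = DistributionSpec("uniform", (0.5, 0.5)).sample(RNG(), 50)
        assert (x == 0.5).all()

    def test_truncated_normal_never_negative(self):
        x = DistributionSpec("normal", (0.5, 2.0)).sample(RNG(), 2000)
        assert (x >= 0).all()

    def test_empirical_resamples_observed_values(self):
        vals = (0.1, 0.2, 0.4)
        x = DistributionSpec("empirical", vals).sample(RNG(), 500)
        assert set(np.unique(x)) <= set(vals)

    def test_lognormal_moment_match(self):
        """Fitted log-parameters reproduce the hand-computed log-moments."""
        mean, cv = 0.2, 0.4
        spec = DistributionSpec.lognormal_from_moments(mean, cv)
        mu, sigma = spec.params
        assert sigma**2 == pytest.approx(np.log(1 + cv**2), rel=1e-12)
        assert mu == pytest.approx(np.log(mean) - sigma**2 / 2, rel=1e-12)
        x = spec.sample(RNG(), 200000)
        assert x.mean() == pytest.approx(mean, rel=0.01)
        assert x.std() / x.mean() == pytest.approx(cv, rel=0.03)


class TestBuildDefaultSpecs:
    def test_default_families(self, default_records, profiles):
        specs = build_default_specs(default_records, profiles)
        assert len(specs.concentration) == 90
        spec = specs.concentration[("GY", "Cr")]
        assert spec.family == "empirical" and len(spec.params) == 10
        assert specs.bw["male"].family == "normal"
        assert specs.fir["child"].family == "triangular"

    def test_all_point_override_gives_constant_draws(self, default_records, profiles):
        specs = build_default_specs(
            default_records, profiles,
            overrides={"concentration": "point", "bw": "point", "fir": "point"},
        )
        for spec in list(specs.concentration.values()) + list(specs.bw.values()):
            assert spec.family == "point"

    def test_lognormal_override_moment_matches_each_cell(self, default_records, profiles):
        specs = build_default_specs(default_records, profiles, overrides={"concentration": "lognormal"})
        vals = np.array(
            [r.concentration for r in default_records if r.area == "GY" and r.metal == "Cr"]
        )
        mu, sigma = specs.concentration[("GY", "Cr")].params
        cv = vals.std(ddof=1) / vals.mean()
        assert sigma == pytest.approx(np.sqrt(np.log(1 + cv**2)), rel=1e-12)
        assert mu == pytest.approx(np.log(vals.mean()) - np.log(1 + cv**2) / 2, rel=1e-12)

    def test_singleton_empirical_falls_back_to_point(self, profiles):
        rec = [ConcentrationRecord("s", "A", "free_range", "non_mining", "Cr", 0.1)]
        with pytest.warns(UserWarning, match="singleton"):
            specs = build_default_specs(rec, profiles)
        assert specs.concentration[("A", "Cr")] == DistributionSpec.point(0.1)


@pytest.fixture(scope="module")
def small_setup(profiles, toxicity):
    cfg = GeneratorConfig(seed=9, metals=("Cr", "Cd", "Pb", "Se"))
    records = generate(cfg)
    return records, profiles, toxicity


class TestRunMcs:
    def test_point_mass_degeneracy_reproduces_deterministic(self, small_setup):
        """All-point specs collapse the simulation onto the deterministic
        assessment: every percentile is bit-identical, the mean agrees to
        a few ulp (floating summation of a constant array)."""
        records, profiles, toxicity = small_setup
        specs = build_default_specs(
            records, profiles,
            overrides={"concentration": "point", "bw": "point", "fir": "point"},
        )
        sims = run_mcs(specs, profiles, toxicity, n_iter=500, seed=3)
        det = {(d.area, d.group): d for d in assess(records, profiles, toxicity)}
        assert len(sims) == 9 * 3 * 5
        for s in sims:
            d = det[(s.area, s.group)]
            want = {"HI": d.hi, "TCR": d.tcr}.get(s.metric, d.cr_by_metal.get(s.metric[3:]))
            assert s.p5 == want and s.p50 == want and s.p95 == want
            assert s.mean == pytest.approx(want, rel=1e-14)
            assert s.exceedance_prob in (0.0, 1.0)

    def test_same_seed_is_bit_identical(self, small_setup):
        records, profiles, toxicity = small_setup
        specs = build_default_specs(records, profiles)
        a = run_mcs(specs, profiles, toxicity, n_iter=2000, seed=11)
        b = run_mcs(specs, profiles, toxicity, n_iter=2000, seed=11)
        assert a == b  # dataclass equality over every summary field
        c = run_mcs(specs, profiles, toxicity, n_iter=2000, seed=12)
        assert a != c

    def test_missing_toxicity_input_named(self, small_setup, profiles):
        records, _, _ = small_setup
        specs = build_default_specs(records, profiles)
        with pytest.raises(DomainError, match="Se"):
            run_mcs(specs, profiles, [ToxicityReference("Cr", 0.003, 0.5)], n_iter=10, seed=0)

    def test_percentiles_are_ordered(self, small_setup):
        records, profiles, toxicity = small_setup
        specs = build_default_specs(records, profiles)
        for s in run_mcs(specs, profiles, toxicity, n_iter=1000, seed=5):
            assert s.p5 <= s.p50 <= s.p95


class TestQuantileOracle:
    def _single_input_specs(self, profile, mean=0.1, cv=0.5):
        conc = {("A", "Cr"): DistributionSpec.lognormal_from_moments(mean, cv)}
        return SpecSet(
            concentration=conc,
            bw={profile.group: DistributionSpec.point(profile.bw)},
            fir={profile.group: DistributionSpec.point(profile.fir)},
        )

    def test_p95_of_thq_matches_closed_form_lognormal_quantile(self, profile_map, toxicity):
        """THQ is monotone in the single uncertain concentration, so its p95
        equals thq(q95 of the lognormal); Monte Carlo at 1e5 draws agrees
        within 2%."""
        profile = profile_map["male"]
        specs = self._single_input_specs(profile)
        rfd = {t.metal: t.rfd for t in toxicity}["Cr"]
        draws = simulate_cell(specs, profile, list(toxicity), "A", 100000, seed=7)
        mu, sigma = specs.concentration[("A", "Cr")].params
        c95 = float(sps.lognorm.ppf(0.95, s=sigma, scale=np.exp(mu)))
        expected = thq(c95, profile, rfd)
        got = np.percentile(draws["THQ_Cr"], 95)
        assert got == pytest.approx(expected, rel=0.02)

    def test_mean_hi_equals_sum_of_mean_thqs(self, small_setup):
        """With draws shared per iteration, HI is the per-draw sum of the
        THQs, so the means agree to floating precision."""
        records, profiles, toxicity = small_setup
        specs = build_default_specs(records, profiles)
        draws = simulate_cell(specs, profiles[0], toxicity, "GY", 5000, seed=1)
        thq_means = sum(v.mean() for k, v in draws.items() if k.startswith("THQ_"))
        assert draws["HI"].mean() == pytest.approx(thq_means, rel=1e-12)

    def test_p95_spread_shrinks_like_inverse_sqrt_n(self, profile_map, toxicity):
        """Across seeds, the sd of the p95 estimator scales ~ n^-1/2:
        log-log slope within +-0.2 of -0.5."""
        profile = profile_map["male"]
        specs = self._single_input_specs(profile)
        sizes = (1000, 10000, 100000)
        sds = []
        for n in sizes:
            p95s = [
                np.percentile(
                    simulate_cell(specs, profile, list(toxicity), "A", n, seed=s)["HI"], 95
                )
                for s in range(25)
            ]
            sds.append(np.std(p95s))
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert -0.7 <= slope <= -0.3


class TestReporting:
    def test_threshold_report_classifies_p95(self, small_setup):
        records, profiles, toxicity = small_setup
        specs = build_default_specs(records, profiles)
        sims = run_mcs(specs, profiles, toxicity, n_iter=2000, seed=2)
        rep = percentile_threshold_report(sims)
        assert set(rep.columns) >= {"area", "group", "metric", "p95", "classification", "flagged"}
        hi = rep[rep.metric == "HI"]
        assert set(hi["classification"]) <= {"no_concern", "potential_adverse"}
        for _, row in rep.iterrows():
            if row.metric != "HI":
                assert row.flagged == (row.p95 >= 1e-4)

    def test_empty_results_rejected(self):
        with pytest.raises(DomainError):
            percentile_threshold_report([])


class TestConvergence:
    def test_point_specs_converge_immediately(self, small_setup, profile_map):
        records, profiles, toxicity = small_setup
        specs = build_default_specs(
            records, profiles,
            overrides={"concentration": "point", "bw": "point", "fir": "point"},
        )
        out = convergence_check(
            specs, profile_map["male"], toxicity, "GY", metric="HI", seed=0,
            sizes=(100, 500, 1000),
        )
        assert out["passed"]
        assert all(c == 0.0 for c in out["relative_changes"])

    def test_empirical_specs_pass_at_default_sizes(self, small_setup, profile_map):
        records, profiles, toxicity = small_setup
        specs = build_default_specs(records, profiles)
        out = convergence_check(
            specs, profile_map["child"], toxicity, "DZ", metric="TCR", seed=1,
        )
        assert out["passed"]
        assert len(out["p95"]) == 4
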
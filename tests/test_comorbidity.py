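"""Tests for the pairwise logistic comorbidity scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from equicomorb.comorbidity import (
    DirectionalAssociation,
    combine_directions,
    count_shared_cases,
    fit_pairwise_logistic,
    phecode_universe,
    run_phenome_scan,
    scheduled_regressions,
)
from tests.conftest import make_status

NO_COVARIATES = ((), ())


def table_status(both, outcome_only, predictor_only, neither):
    """Status matrix realizing a 2x2 contingency table for phecodes O and P."""
    o = [1] * both + [1] * outcome_only + [0] * predictor_only + [0] * neither
    p = [1] * both + [0] * outcome_only + [1] * predictor_only + [0] * neither
    return make_status({"O": o, "P": p})


def empty_demo(status):
    return pd.DataFrame(index=status.patients)


class TestPairwiseFit:
    def test_matches_closed_form_log_odds_ratio(self):
        status = table_status(30, 20, 20, 30)
        res = fit_pairwise_logistic(
            status, empty_demo(status), "O", "P",
            covariates=NO_COVARIATES, min_cases=1,
        )
        expected_beta = np.log(30 * 30 / (20 * 20))
        expected_se = np.sqrt(1 / 30 + 1 / 20 + 1 / 20 + 1 / 30)
        assert res.converged
        assert res.beta == pytest.approx(expected_beta, abs=1e-6)
        assert res.se == pytest.approx(expected_se, abs=1e-6)

    def test_predictor_identical_to_outcome_separates(self):
        status = table_status(40, 0, 0, 40)
        res = fit_pairwise_logistic(
            status, empty_demo(status), "O", "O",
            covariates=NO_COVARIATES, min_cases=1,
        )
        assert not res.converged
        assert np.isnan(res.z)

    def test_min_case_count_skips(self):
        status = table_status(5, 5, 40, 40)
        res = fit_pairwise_logistic(
            status, empty_demo(status), "O", "P",
            covariates=NO_COVARIATES, min_cases=20,
        )
        assert not res.converged
        assert res.skip_reason == "min_cases"

    def test_missing_status_patients_dropped(self):
        status = make_status({"O": [1, 1, 0, 0, -1], "P": [1, 0, 1, 0, 1]})
        res = fit_pairwise_logistic(
            status, empty_demo(status), "O", "P",
            covariates=NO_COVARIATES, min_cases=1,
        )
        assert res.n_case + res.n_control == 4

    def test_null_scan_z_scores_standard_normal(self):
        """Independent phenotypes with active covariates give per-pair
        combined Zs consistent with N(0,1): KS at alpha=0.01, small mean."""
        # 1000 pairs put the 0.1 mean-z tolerance at ~3 Monte-Carlo SEs
        rng = np.random.default_rng(2024)
        n, n_pairs = 5000, 1000
        index = (rng.random(n) < 0.15).astype(np.int8)
        cols = {"IDX": index}
        for j in range(n_pairs):
            cols[f"X{j:03d}"] = (rng.random(n) < 0.12).astype(np.int8)
        status = make_status(cols)
        demo = pd.DataFrame(
            {
                "current_age": rng.uniform(20, 80, n),
                "ehr_age": rng.uniform(18, 80, n),
                "log_unique_phecodes": rng.normal(2.0, 0.5, n),
                "sex": rng.choice(["male", "female"], n),
                "race": rng.choice(["white", "black", "other"], n),
            },
            index=status.patients,
        )
        scan = run_phenome_scan(
            status, demo, "IDX",
            universe=[c for c in cols if c != "IDX"],
            min_cases=20, site="s",
        )
        z = scan["z_site"].to_numpy()
        assert np.isfinite(z).all()
        assert abs(z.mean()) < 0.1
        ks = stats.kstest(z, "norm")
        assert ks.pvalue > 0.01

    def test_burden_covariate_attenuates_confounded_association(self):
        """A phenotype driven purely by code burden loses |z| against a
        burden-correlated index when the total-illness covariate enters."""
        rng = np.random.default_rng(5)
        n = 6000
        u = rng.standard_normal(n)
        index = (rng.random(n) < 1 / (1 + np.exp(2.0 - 1.2 * u))).astype(np.int8)
        pheno = (rng.random(n) < 1 / (1 + np.exp(2.0 - 1.0 * u))).astype(np.int8)
        status = make_status({"IDX": index, "PH": pheno})
        demo = pd.DataFrame(
            {"log_unique_phecodes": np.log1p(rng.poisson(np.exp(1.5 + 0.8 * u)))},
            index=status.patients,
        )
        with_cov = fit_pairwise_logistic(
            status, demo, "PH", "IDX",
            covariates=(("log_unique_phecodes",), ()), min_cases=1,
        )
        without = fit_pairwise_logistic(
            status, demo, "PH", "IDX", covariates=NO_COVARIATES, min_cases=1
        )
        assert with_cov.converged and without.converged
        assert abs(with_cov.z) < abs(without.z)


def _assoc(z, converged=True):
    return DirectionalAssociation(
        "O", "P", "s", z, 1.0, z, 100, 100, converged
    )


class TestCombineDirections:
    def test_mean_rule(self):
        assert combine_directions(_assoc(3.0), _assoc(5.0)) == pytest.approx(4.0)

    def test_single_converged_direction_passes_through(self):
        res = combine_directions(_assoc(2.2), _assoc(np.nan, converged=False))
        assert res == pytest.approx(2.2)

    def test_neither_converged_is_missing(self):
        res = combine_directions(
            _assoc(np.nan, False), _assoc(np.nan, False), rule="mean"
        )
        assert np.isnan(res)

    def test_stouffer_and_forward_rules(self):
        assert combine_directions(_assoc(3.0), _assoc(5.0), "stouffer") == (
            pytest.approx(8.0 / np.sqrt(2))
        )
        assert combine_directions(
            _assoc(3.0), _assoc(5.0), "outcome_direction_only"
        ) == pytest.approx(3.0)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            combine_directions(_assoc(1.0), _assoc(1.0), "median")

    def test_exchangeable_pair_directions_agree(self):
        """For an exchangeable synthetic pair the two directional Zs are
        close, so the mean rule tracks either direction."""
        rng = np.random.default_rng(9)
        n = 8000
        latent = rng.standard_normal(n)
        a = (latent + rng.standard_normal(n) > 1.0).astype(np.int8)
        b = (latent + rng.standard_normal(n) > 1.0).astype(np.int8)
        status = make_status({"A": a, "B": b})
        demo = empty_demo(status)
        fwd = fit_pairwise_logistic(status, demo, "B", "A", NO_COVARIATES, 1)
        rev = fit_pairwise_logistic(status, demo, "A", "B", NO_COVARIATES, 1)
        assert abs(fwd.z - rev.z) < 0.5
        assert combine_directions(fwd, rev) == pytest.approx((fwd.z + rev.z) / 2)


class TestSharedCases:
    def test_disjoint_and_identical(self):
        status = make_status({"A": [1, 1, 0, 0], "B": [0, 0, 1, 1]})
        assert count_shared_cases(status, "A", "B") == 0
        assert count_shared_cases(status, "A", "A") == 2

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(1)
        status = make_status({
            "A": rng.integers(-1, 2, 300), "B": rng.integers(-1, 2, 300)
        })
        brute = len(
            set(status.cases("A")).intersection(status.cases("B"))
        )
        assert count_shared_cases(status, "A", "B") == brute


class TestScanScheduling:
    def test_index_mode_pair_and_fit_counts(self):
        jobs = list(scheduled_regressions(["a", "b", "c"], "IDX"))
        assert len(jobs) == 6  # 3 pairs, 2 directional fits each

    def test_full_grid_count_small(self):
        jobs = list(scheduled_regressions(["a", "b", "c"], "IDX", full_grid=True))
        assert len(jobs) == 9

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            scheduled_regressions([], "IDX")

    def test_universe_is_phecodes_seen_in_index_cases(self):
        status = make_status({
            "IDX": [1, 1, 0, 0],
            "A": [-1, 0, 1, 1],   # single instance in an index case: occurs
            "B": [0, 0, 1, 1],    # never occurs in index cases
        })
        assert phecode_universe(status, "IDX") == ["A"]

    def test_scan_deterministic(self):
        rng = np.random.default_rng(3)
        status = make_status({
            "IDX": (rng.random(800) < 0.3).astype(np.int8),
            "A": (rng.random(800) < 0.3).astype(np.int8),
            "B": (rng.random(800) < 0.3).astype(np.int8),
        })
        demo = empty_demo(status)
        first = run_phenome_scan(status, demo, "IDX", ["A", "B"],
                                 NO_COVARIATES, 1, site="s")
        second = run_phenome_scan(status, demo, "IDX", ["A", "B"],
                                  NO_COVARIATES, 1, site="s")
        pd.testing.assert_frame_equal(first, second)
        assert list(first["phecode_b"]) == ["A", "B"]
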
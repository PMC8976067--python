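"""Natural-abundance correction, differential statistics, and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phasortrack.metabolomics import (
    convolve_natural_abundance,
    differential_stats,
    fisher_combine,
    fractional_contribution,
    msea,
    na_correction,
    natural_abundance_matrix,
    oxidative_reductive_readout,
    tic_normalize,
)
from phasortrack.synthetic import MetabSimConfig, generate_isotopologue_table


class TestCorrectionMatrix:
    @pytest.mark.parametrize("n", range(1, 13))
    def test_columns_sum_to_one(self, n):
        C = natural_abundance_matrix(n, 0.0107)
        np.testing.assert_allclose(C.sum(axis=0), 1.0, atol=1e-12)

    def test_p_zero_is_identity(self):
        np.testing.assert_allclose(natural_abundance_matrix(5, 0.0), np.eye(6))

    def test_p_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            natural_abundance_matrix(5, 0.5)


class TestNaCorrection:
    def test_single_carbon_inversion(self):
        x, _ = na_correction(np.array([0.9893, 0.0107]), 1)
        np.testing.assert_allclose(x, [1.0, 0.0], atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 8))
    def test_convolve_then_correct_is_identity(self, seed, n):
        rng = np.random.default_rng(seed)
        truth = rng.dirichlet(np.ones(n + 1))
        measured = convolve_natural_abundance(truth)
        rec, resid = na_correction(measured, n)
        np.testing.assert_allclose(rec, truth, atol=1e-9)
        assert resid < 1e-9

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            na_correction(np.array([0.5, -0.1, 0.6]), 2)


class TestTicNormalize:
    def _table(self):
        return pd.DataFrame({
            "sample": ["a", "a", "b", "b"],
            "metabolite": ["x", "y", "x", "y"],
            "signal": [1.0, 1.0, 3.0, 1.0],
        })

    def test_sample_totals_become_one(self):
        out = tic_normalize(self._table())
        totals = out.groupby("sample")["signal"].sum()
        np.testing.assert_allclose(totals, 1.0)
        # sample b was divided by 4
        assert out.loc[2, "signal"] == pytest.approx(0.75)

    def test_idempotent(self):
        once = tic_normalize(self._table())
        twice = tic_normalize(once)
        np.testing.assert_allclose(once["signal"], twice["signal"])

    def test_zero_total_names_sample(self):
        t = self._table()
        t.loc[t["sample"] == "b", "signal"] = 0.0
        with pytest.raises(ValueError, match="b"):
            tic_normalize(t)


class TestFractionalContribution:
    @pytest.mark.parametrize(
        "dist, n, expected",
        [
            ([0, 0, 0, 0, 0, 0, 1], 6, 1.0),
            ([1, 0, 0, 0, 0, 0, 0], 6, 0.0),
            ([0.5, 0, 0, 0, 0.5, 0, 0], 6, 1 / 3),
        ],
    )
    def test_known_values(self, dist, n, expected):
        assert fractional_contribution(np.array(dist), n) == pytest.approx(expected)

    def test_invariant_under_tic_normalization(self):
        """FC depends only on the within-metabolite distribution, so TIC
        normalization cannot change it."""
        dist = np.array([0.2, 0.3, 0.5])
        assert fractional_contribution(dist, 2) == pytest.approx(
            fractional_contribution(dist * 17.0 / dist.sum() / 17.0, 2)
        )

    def test_zero_carbons_rejected(self):
        with pytest.raises(ValueError):
            fractional_contribution(np.array([1.0]), 0)


def make_tables(effect=0.2, noise=0.05, seeds=(1, 2, 3)):
    """Three independent experiments with higher M4 / lower M5 labeling of
    TCA intermediates in the SP-like condition."""
    base = np.array([0.25, 0.02, 0.08, 0.05, 0.30, 0.25, 0.05])
    sp = base.copy()
    sp[4] += effect
    sp[5] -= effect
    truth = {
        "SP": {"citrate/isocitrate": sp, "aconitate": sp,
               "lactate": np.array([0.6, 0.1, 0.2, 0.1])},
        "NSP": {"citrate/isocitrate": base, "aconitate": base,
                "lactate": np.array([0.6, 0.1, 0.2, 0.1])},
    }
    nc = {"citrate/isocitrate": 6, "aconitate": 6, "lactate": 3}
    return [
        generate_isotopologue_table(
            MetabSimConfig(truth=truth, n_carbons=nc, noise_sd=noise, seed=s)
        )[0]
        for s in seeds
    ]


class TestOxidativeReductiveReadout:
    def test_generated_effect_recovered_significantly(self):
        table = make_tables()[0]
        res = oxidative_reductive_readout(table)
        m4 = res[(res["metabolite"] == "citrate/isocitrate") & (res["M"] == 4)]
        assert m4["mean_SP"].iloc[0] > m4["mean_NSP"].iloc[0]
        assert m4["p"].iloc[0] < 0.05
        m5 = res[(res["metabolite"] == "citrate/isocitrate") & (res["M"] == 5)]
        assert m5["mean_SP"].iloc[0] < m5["mean_NSP"].iloc[0]

    def test_missing_metabolite_raises(self):
        table = make_tables()[0]
        with pytest.raises(ValueError, match="succinate"):
            oxidative_reductive_readout(table, metabolites=("succinate",))

    def test_pure_m4_distribution(self):
        """A species fully labeled at M4 reads out M4 = 1, M5 = 0."""
        rows = []
        for cond in ("SP", "NSP"):
            for rep in (1, 2):
                for m in range(6):
                    rows.append({
                        "sample": f"{cond}_{rep}", "condition": cond,
                        "replicate": rep, "metabolite": "aconitate",
                        "n_carbons": 5, "M": m,
                        "signal": 1.0 if m == 4 else 0.0,
                    })
        with pytest.warns(UserWarning, match="zero-variance"):
            res = oxidative_reductive_readout(
                pd.DataFrame(rows), metabolites=("aconitate",), correct=False
            )
        m4 = res[res["M"] == 4].iloc[0]
        m5 = res[res["M"] == 5].iloc[0]
        assert m4["mean_SP"] == pytest.approx(1.0)
        assert m5["mean_SP"] == pytest.approx(0.0)


class TestDifferentialStats:
    def test_single_experiment_fisher_is_identity(self):
        tables = make_tables(seeds=(1,))
        res = differential_stats(tables)
        # recompute the single-experiment p directly
        t = tic_normalize(tables[0])
        pools = t.groupby(["condition", "replicate", "metabolite"],
                          as_index=False)["signal"].sum()
        sub = pools[pools["metabolite"] == "lactate"]
        a = sub.loc[sub["condition"] == "SP", "signal"]
        b = sub.loc[sub["condition"] == "NSP", "signal"]
        p_direct = stats.ttest_ind(a, b, equal_var=True).pvalue
        p_fisher = res.loc[res["metabolite"] == "lactate", "p_fisher"].iloc[0]
        assert p_fisher == pytest.approx(p_direct, rel=1e-9)

    def test_fisher_half_half_chi_square_oracle(self):
        """X^2 = -2(ln 0.5 + ln 0.5) = 2.7726 on 4 df gives p = 0.5966."""
        assert fisher_combine([0.5, 0.5]) == pytest.approx(
            stats.chi2.sf(-2 * np.log(0.25), 4), rel=1e-12
        )
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=5e-5)

    def test_signed_q_sign_matches_fold_change(self):
        res = differential_stats(make_tables())
        for _, row in res.iterrows():
            if row["log2fc"] != 0:
                assert np.sign(row["signed_log10_q"]) == np.sign(row["log2fc"])

    def test_bh_equals_brute_force_step_up(self):
        """BH via the library matches the brute-force step-up definition
        q_(i) = min_{j >= i} m p_(j) / j for every ordering of 5 p-values."""
        base = [0.01, 0.02, 0.03, 0.04, 0.2]
        for perm in itertools.permutations(base):
            p = np.array(perm)
            q_lib = multipletests(p, method="fdr_bh")[1]
            order = np.argsort(p)
            m = len(p)
            q_brute = np.empty(m)
            prev = np.inf
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                prev = min(prev, m * p[idx] / rank)
                q_brute[idx] = prev
            np.testing.assert_allclose(q_lib, q_brute, atol=1e-12)

    def test_bh_sorted_example(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10))
    def test_bh_preserves_p_ordering(self, ps):
        q = multipletests(ps, method="fdr_bh")[1]
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_type_one_error_calibrated(self):
        """Classic two-sample t-test at n = 3 per group: empirical
        rejection rate at alpha 0.05 over 1000 null replicates is within
        3 percentage points of nominal."""
        rng = np.random.default_rng(77)
        a = rng.normal(size=(1000, 3))
        b = rng.normal(size=(1000, 3))
        p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
        rate = np.mean(p < 0.05)
        assert abs(rate - 0.05) <= 0.03


class TestMsea:
    def _scores(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"m{i:02d}" for i in range(n)]
        return pd.Series(rng.normal(size=n), index=names)

    def test_set_at_top_scores_plus_one(self):
        s = pd.Series(
            np.arange(10, 0, -1, dtype=float), index=[f"m{i}" for i in range(10)]
        )
        res = msea(s, {"top": ["m0", "m1", "m2"]}, n_permutations=50, seed=1)
        assert res[0].es == pytest.approx(1.0)

    def test_set_at_bottom_scores_minus_one(self):
        s = pd.Series(
            np.arange(10, 0, -1, dtype=float), index=[f"m{i}" for i in range(10)]
        )
        res = msea(s, {"bottom": ["m7", "m8", "m9"]}, n_permutations=50, seed=1)
        assert res[0].es == pytest.approx(-1.0)

    def test_es_invariant_under_monotone_score_transform(self):
        s = self._scores()
        sets = {"set": list(s.index[3:8])}
        r1 = msea(s, sets, n_permutations=10, seed=0)[0]
        r2 = msea(np.exp(s) * 3 + 1, sets, n_permutations=10, seed=0)[0]
        assert r1.es == pytest.approx(r2.es)

    def test_disjoint_set_excluded_from_bh(self):
        s = self._scores()
        res = msea(
            s, {"absent": ["zz1", "zz2"], "real": list(s.index[:4])},
            n_permutations=50, seed=0,
        )
        absent = next(r for r in res if r.pathway == "absent")
        real = next(r for r in res if r.pathway == "real")
        assert np.isnan(absent.es)
        assert np.isfinite(real.q)

    def test_null_permutation_p_uniform(self):
        """Under a random ranking the permutation p-value is uniform
        (KS test over 200 independent repetitions)."""
        rng = np.random.default_rng(123)
        names = [f"m{i:02d}" for i in range(25)]
        ps = []
        for rep in range(200):
            scores = pd.Series(rng.normal(size=25), index=names)
            members = list(rng.choice(names, size=6, replace=False))
            r = msea(scores, {"s": members}, n_permutations=99,
                     seed=int(rng.integers(2**31)))
            ps.append(r[0].p)
        d, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_enriched_tca_set_has_smallest_p(self):
        """On synthetic experiments generated with enriched TCA pool sizes
        in the SP-like condition, ranking by signed log10 q puts the TCA set
        at the smallest permutation p among candidate sets."""
        rng = np.random.default_rng(5)
        tca = ["citrate/isocitrate", "aconitate", "malate", "fumarate"]
        others = [f"aa{i}" for i in range(12)]
        rows = []
        for exp in range(3):
            for cond, lift in (("SP", 2.0), ("NSP", 1.0)):
                for rep in range(1, 4):
                    for m in tca + others:
                        mult = lift if m in tca else 1.0
                        rows.append({
                            "sample": f"{cond}_{exp}_{rep}",
                            "condition": cond, "replicate": rep,
                            "metabolite": m,
                            "signal": mult * rng.lognormal(2.0, 0.1),
                        })
        df = pd.DataFrame(rows)
        tables = [df[df["sample"].str.contains(f"_{e}_")] for e in range(3)]
        res = differential_stats(tables)
        scores = pd.Series(
            res["signed_log10_q"].to_numpy(), index=res["metabolite"]
        )
        sets = {
            "TCA": tca,
            "other_a": others[:5],
            "other_b": others[5:10],
        }
        results = msea(scores, sets, n_permutations=500, seed=9)
        best = min(results, key=lambda r: r.p)
        assert best.pathway == "TCA"
        assert best.es > 0
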
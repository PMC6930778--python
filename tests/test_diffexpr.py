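import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from megscreen.diffexpr import (
    EBayesHyperparams,
    benjamini_hochberg,
    estimate_ebayes_hyperparams,
    fit_moderated_t,
    moderate_variances,
    select_degs,
    trigamma_inverse,
)
from megscreen.errors import InputError
from megscreen.simulate import SimulationConfig, generate_cross_sectional


# ---------------------------------------------------------------------------
# independent straight-line oracle: closed-form moderated t with a
# bisection trigamma inverse, no shared code with the implementation
# ---------------------------------------------------------------------------

def _bisect_trigamma_inverse(y, lo=1e-6, hi=1e8):
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_moderated_t(x1, x2):
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    diff, s2 = [], []
    for g in range(x1.shape[0]):
        m1 = sum(x1[g]) / n1
        m2 = sum(x2[g]) / n2
        diff.append(m1 - m2)
        ss = sum((v - m1) ** 2 for v in x1[g]) + sum((v - m2) ** 2 for v in x2[g])
        s2.append(ss / d)
    z = [math.log(v) for v in s2 if v > 0]
    mean_z = sum(z) / len(z)
    var_z = sum((v - mean_z) ** 2 for v in z) / (len(z) - 1)
    excess = var_z - special.polygamma(1, d / 2)
    e_mean = mean_z - special.digamma(d / 2) + math.log(d / 2)
    if excess <= 0:
        d0, log_s02 = math.inf, e_mean
    else:
        d0 = 2 * _bisect_trigamma_inverse(excess)
        log_s02 = e_mean + special.digamma(d0 / 2) - math.log(d0 / 2)
    s02 = math.exp(log_s02)
    t_vals, s2_mod = [], []
    for g in range(x1.shape[0]):
        sm = s02 if math.isinf(d0) else (d0 * s02 + d * s2[g]) / (d0 + d)
        s2_mod.append(sm)
        t_vals.append(diff[g] / math.sqrt(sm * (1 / n1 + 1 / n2)))
    return np.array(t_vals), np.array(s2_mod), d0, s02


def _frame(x1, x2):
    genes = [f"g{i}" for i in range(x1.shape[0])]
    cols1 = [f"a{i}" for i in range(x1.shape[1])]
    cols2 = [f"b{i}" for i in range(x2.shape[1])]
    expr = pd.DataFrame(np.hstack([x1, x2]), index=genes, columns=cols1 + cols2)
    meta = pd.DataFrame(
        {"patient_id": cols1 + cols2, "group": ["case"] * len(cols1) + ["control"] * len(cols2)},
        index=pd.Index(cols1 + cols2, name="sample_id"),
    )
    return expr, meta


class TestModeratedT:
    def test_matches_straightline_oracle(self, rng):
        x1 = 8 + rng.normal(0, rng.uniform(0.2, 1.5, size=(10, 1)), size=(10, 4))
        x2 = 8 + rng.normal(0, rng.uniform(0.2, 1.5, size=(10, 1)), size=(10, 4))
        expr, meta = _frame(x1, x2)
        res = fit_moderated_t(expr, meta)
        t_exp, s2m_exp, d0_exp, s02_exp = oracle_moderated_t(x1, x2)
        hyper = res.attrs["ebayes"]
        assert hyper.prior_df == pytest.approx(d0_exp, abs=1e-6)
        assert hyper.prior_var == pytest.approx(s02_exp, rel=1e-8)
        np.testing.assert_allclose(res["s2_mod"], s2m_exp, atol=1e-8)
        np.testing.assert_allclose(res["t"], t_exp, atol=1e-8)
        p_exp = 2 * stats.t.sf(np.abs(t_exp), df=d0_exp + 6)
        np.testing.assert_allclose(res["p"], p_exp, atol=1e-8)

    def test_identical_groups_give_zero_t(self):
        x1 = np.column_stack([np.array([5.0, 6.0, 7.0])] * 3)  # constant per gene
        expr, meta = _frame(x1, x1.copy())
        res = fit_moderated_t(expr, meta)
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_homoscedastic_collapse_gives_constant_moderated_variance(self):
        s2 = np.full(50, 0.7)
        hyper = estimate_ebayes_hyperparams(s2, df_resid=6)
        assert math.isinf(hyper.prior_df)
        mod = moderate_variances(np.linspace(0.1, 2.0, 50), 6, hyper)
        assert np.allclose(mod, mod[0])

    def test_moderated_t_approaches_ordinary_t_for_small_prior_df(self, rng):
        x1 = 8 + rng.normal(0, 1, size=(8, 5))
        x2 = 8 + rng.normal(0, 1, size=(8, 5))
        expr, meta = _frame(x1, x2)
        tiny = EBayesHyperparams(prior_df=1e-9, prior_var=1.0)
        res = fit_moderated_t(expr, meta, hyper=tiny)
        plain = fit_moderated_t(expr, meta, moderate=False)
        np.testing.assert_allclose(res["t"], plain["t"], rtol=1e-6)

    def test_contrast_antisymmetry(self, rng):
        x1 = 8 + rng.normal(0, 1, size=(12, 4))
        x2 = 8 + rng.normal(0, 1, size=(12, 6))
        expr, meta = _frame(x1, x2)
        fwd = fit_moderated_t(expr, meta, ("case", "control"))
        rev = fit_moderated_t(expr, meta, ("control", "case"))
        np.testing.assert_allclose(fwd["mean_diff"], -rev["mean_diff"], atol=1e-12)
        np.testing.assert_allclose(fwd["t"], -rev["t"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_zero_variance_gene_gets_positive_moderated_variance(self, rng):
        x1 = 8 + rng.normal(0, 1, size=(10, 4))
        x2 = 8 + rng.normal(0, 1, size=(10, 4))
        x1[0] = 5.0
        x2[0] = 5.0
        expr, meta = _frame(x1, x2)
        res = fit_moderated_t(expr, meta)
        assert res["s2"].iloc[0] == 0.0
        assert res["s2_mod"].iloc[0] > 0.0
        assert np.isfinite(res["t"]).all()

    def test_missing_group_rejected(self, rng):
        expr, meta = _frame(8 + rng.normal(size=(4, 3)), 8 + rng.normal(size=(4, 3)))
        with pytest.raises(InputError):
            fit_moderated_t(expr, meta, ("case", "treated"))

    def test_null_raw_p_calibration(self):
        """Under a pure-noise simulation, raw p-values are roughly uniform."""
        hits, total = 0, 0
        for seed in range(20):
            cfg = SimulationConfig(n_genes=50, de_fraction=0.0, seed=seed)
            expr, meta, _ = generate_cross_sectional(cfg)
            res = fit_moderated_t(expr, meta)
            hits += int((res["p"] < 0.05).sum())
            total += len(res)
        assert 0.03 <= hits / total <= 0.07


def oracle_bh(p):
    """Direct step-up enumeration: adj_(i) = min(1, min_{j>=i} m p_(j) / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.05], [0.05]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_worked_examples(self, raw, expected):
        np.testing.assert_allclose(benjamini_hochberg(raw), expected, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_matches_enumeration_oracle(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), oracle_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=12))
    def test_monotone_and_bounded(self, p):
        adj = benjamini_hochberg(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            benjamini_hochberg([0.5, 1.5])


class TestSelectDegs:
    def test_nothing_selected_when_all_adjusted_one(self):
        res = pd.DataFrame({"mean_diff": [1.0, -1.0], "adj_p": [1.0, 1.0], "direction": ["up", "down"]}, index=["a", "b"])
        assert select_degs(res).empty

    def test_alpha_monotone_superset(self, cross_dataset):
        expr, meta, _ = cross_dataset
        res = fit_moderated_t(expr, meta)
        small = set(select_degs(res, 0.1).index)
        large = set(select_degs(res, 0.2).index)
        assert small <= large

    def test_planted_recovery_is_perfect_at_high_effect(self):
        """Strong, low-noise planted effects are all recovered with the
        planted direction; false discoveries stay within the FDR-0.1
        guarantee (controlling the rate, not forbidding every one)."""
        false_positives = 0
        for seed in range(1, 6):
            cfg = SimulationConfig(
                n_genes=60, n_cases=20, n_controls=20, noise_sd=0.1, de_effect=3.0, seed=seed
            )
            expr, meta, truth = generate_cross_sectional(cfg)
            degs = select_degs(fit_moderated_t(expr, meta), 0.1)
            planted = truth.de_up | truth.de_down
            assert planted <= set(degs.index)  # sensitivity 1.0
            assert set(degs.index[degs["direction"] == "up"]) >= truth.de_up
            assert truth.de_up <= set(degs.index[degs["direction"] == "up"])
            assert truth.de_down <= set(degs.index[degs["direction"] == "down"])
            false_positives += len(set(degs.index) - planted)
        assert false_positives <= 5  # ~0.1 of discoveries over 5 seeds, loosely

    def test_bad_alpha_rejected(self, cross_dataset):
        expr, meta, _ = cross_dataset
        res = fit_moderated_t(expr, meta)
        with pytest.raises(InputError):
            select_degs(res, 1.0)


def test_trigamma_inverse_round_trip():
    for x in [0.01, 0.5, 1.0, 5.0, 50.0]:
        y = float(special.polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-8)
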
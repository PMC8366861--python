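"""Cluster-number selection, representative populations, and the
environment-genetics association stage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ssrphylo.cluster_env import (AssociationModel, best_k,
                                  category_count_test, evanno_delta_k,
                                  forward_stepwise_bic, local_fdr,
                                  pearson_screen,
                                  select_representative_populations, vif)
from ssrphylo.synthetic import generate_cluster_runs


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def runs_from_means(means, sd=10.0, reps=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = [{"K": k, "replicate": r, "L": m + rng.normal(0, sd)}
            for k, m in means.items() for r in range(reps)]
    return pd.DataFrame(rows)


def test_delta_k_zero_for_linear_likelihood():
    runs = runs_from_means({k: 1000.0 * k for k in range(1, 7)}, sd=5.0)
    tab = evanno_delta_k(runs)
    assert tab["delta_k"].dropna().max() < 3  # second differences ~ noise only


def test_delta_k_peaks_at_elbow():
    means = {1: -9000, 2: -6000, 3: -3000, 4: -2900, 5: -2850, 6: -2840}
    runs = runs_from_means(means, sd=20.0, seed=1)
    assert best_k(runs) == 3


def test_delta_k_invariant_to_constant_shift():
    runs = runs_from_means({1: -500, 2: -300, 3: -100, 4: -90, 5: -85}, seed=2)
    shifted = runs.assign(L=runs["L"] + 12345.0)
    a = evanno_delta_k(runs)["delta_k"]
    b = evanno_delta_k(shifted)["delta_k"]
    pd.testing.assert_series_equal(a, b)


def test_delta_k_flags_zero_sd():
    runs = runs_from_means({1: 0, 2: 10, 3: 20}, sd=0.0)
    tab = evanno_delta_k(runs)
    assert tab.loc[2, "sd_zero"]
    assert np.isnan(tab.loc[2, "delta_k"])


def test_synthetic_cluster_runs_recover_true_k():
    runs = generate_cluster_runs(true_k=3, seed=5)
    assert best_k(runs) == 3
    flat = generate_cluster_runs(true_k=3, signal=0.0, noise_sd=50.0, seed=6)
    tab = evanno_delta_k(flat)
    assert tab["delta_k"].dropna().max() < 5  # no pronounced peak
    assert (runs.groupby("K")["replicate"].count() == 10).all()


# ---------------------------------------------------------------------------
# Representative populations
# ---------------------------------------------------------------------------

STUDY_Q = pd.DataFrame(
    {"west": [0.91, 0.92, 0.05, 0.06, 0.44, 0.25, 0.04, 0.05],
     "east": [0.05, 0.04, 0.88, 0.87, 0.36, 0.60, 0.06, 0.04],
     "alps": [0.04, 0.04, 0.07, 0.07, 0.20, 0.15, 0.93, 0.91]},
    index=["Borc", "Issa", "Lesp", "Bele", "Stla", "Sigu", "Vent", "Punt"])
# Issa deliberately carries the higher western Q; exclusion lists drive the
# replicate analysis.


def test_representative_selection_with_exclusions():
    picks = select_representative_populations(STUDY_Q, exclude=["Issa"])
    assert picks == {"west": "Borc", "east": "Lesp", "alps": "Vent",
                     "admixed": "Stla"}
    second = select_representative_populations(
        STUDY_Q, exclude=["Borc", "Lesp", "Vent", "Stla"])
    assert second == {"west": "Issa", "east": "Bele", "alps": "Punt",
                      "admixed": "Sigu"}


def test_representative_tie_breaks_alphabetically():
    q = pd.DataFrame({"a": [0.9, 0.9, 0.1], "b": [0.1, 0.1, 0.9]},
                     index=["zeta", "alpha", "mid"])
    picks = select_representative_populations(q)
    assert picks["a"] == "alpha"


def test_representative_empty_cluster_errors():
    q = pd.DataFrame({"a": [0.9], "b": [0.1]}, index=["only"])
    with pytest.raises(ValueError):
        select_representative_populations(q)


# ---------------------------------------------------------------------------
# Pearson screen
# ---------------------------------------------------------------------------

def test_pearson_screen_identity_and_antisymmetry():
    rng = np.random.default_rng(0)
    g = pd.DataFrame({"he": rng.normal(0, 1, 30)})
    env = pd.DataFrame({"same": g["he"], "neg": -g["he"],
                        "noise": rng.normal(0, 1, 30)}, index=g.index)
    out = pearson_screen(g, env).set_index("env")
    assert out.loc["same", "r"] == pytest.approx(1.0, abs=1e-6)
    assert out.loc["neg", "r"] == pytest.approx(-out.loc["same", "r"], abs=1e-6)
    assert abs(out.loc["noise", "r"]) < 0.5


def test_pearson_screen_null_rarely_large():
    rng = np.random.default_rng(1)
    n = 45
    g = pd.DataFrame({f"g{i}": rng.normal(0, 1, n) for i in range(4)})
    env = pd.DataFrame({f"e{j}": rng.normal(0, 1, n) for j in range(25)},
                       index=g.index)
    out = pearson_screen(g, env)
    assert (out["r"].abs() < 0.3).mean() > 0.9  # |r|<0.3 for ~95% of null pairs


def test_pearson_screen_skips_constant():
    g = pd.DataFrame({"he": [1.0] * 10})
    env = pd.DataFrame({"x": np.arange(10.0)}, index=g.index)
    out = pearson_screen(g, env)
    assert out["skipped"].all()


# ---------------------------------------------------------------------------
# Local FDR
# ---------------------------------------------------------------------------

def test_lfdr_all_null():
    rng = np.random.default_rng(2)
    z = rng.normal(0, 1, 500)
    lf, method = local_fdr(z)
    assert method == "lfdr"
    assert np.median(lf) > 0.9
    assert (lf <= 0.05).mean() < 0.02  # essentially nothing called


def test_lfdr_mixture_matches_analytic():
    """80% null + 20% N(4,1): compare to the generating mixture's lfdr."""
    rng = np.random.default_rng(3)
    n = 2000
    is_alt = rng.random(n) < 0.2
    z = np.where(is_alt, rng.normal(4, 1, n), rng.normal(0, 1, n))
    lf, _ = local_fdr(z)
    f = 0.8 * sps.norm.pdf(z) + 0.2 * sps.norm.pdf(z, 4, 1)
    analytic = np.clip(0.8 * sps.norm.pdf(z) / f, 0, 1)
    assert np.mean(np.abs(lf - analytic)) < 0.1
    assert lf[np.abs(z) > 5].max() < 0.05


def test_lfdr_isotonic_monotone_in_abs_z():
    rng = np.random.default_rng(4)
    z = np.concatenate([rng.normal(0, 1, 400), rng.normal(3.5, 1, 100)])
    lf, _ = local_fdr(z, isotonic=True)
    order = np.argsort(np.abs(z))
    assert (np.diff(lf[order]) <= 1e-9).all()


def test_lfdr_few_tests_falls_back_to_bh():
    z = np.array([0.1, 0.5, 4.0, -0.3, 1.0])
    lf, method = local_fdr(z)
    assert method == "bh_fallback"
    assert lf[2] < 0.05  # |z|=4 clearly significant even under BH


def test_lfdr_empirical_fdr_control():
    """At the 0.05 lfdr cut the realised false-discovery proportion stays
    below 0.10 (mixture replicates, fixed seed)."""
    rng = np.random.default_rng(5)
    false_disc, total_disc = 0, 0
    for _ in range(40):
        n = 400
        is_alt = rng.random(n) < 0.2
        z = np.where(is_alt, rng.normal(4, 1, n), rng.normal(0, 1, n))
        lf, _ = local_fdr(z)
        called = lf <= 0.05
        false_disc += int((called & ~is_alt).sum())
        total_disc += int(called.sum())
    assert total_disc > 0
    assert false_disc / total_disc <= 0.10


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def test_vif_orthogonal_predictors():
    n = 40
    X = pd.DataFrame({"a": np.sin(np.arange(n)), "b": np.cos(np.arange(n))})
    v = vif(X)
    assert (v < 1.2).all()


def test_vif_closed_form_for_known_r2():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 2000)
    # construct y with exact sample correlation sqrt(0.99)
    e = rng.normal(0, 1, 2000)
    e -= e.mean() + x * np.dot(e - e.mean(), x - x.mean()) / np.dot(x - x.mean(), x - x.mean())
    xs = (x - x.mean()) / x.std()
    es = (e - e.mean()) / e.std()
    y = np.sqrt(0.99) * xs + np.sqrt(0.01) * es
    v = vif(pd.DataFrame({"x": xs, "y": y}))
    assert v["x"] == pytest.approx(100.0, rel=0.01)


def test_vif_scale_invariant_and_collinear():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
    v1 = vif(X)
    v2 = vif(X.assign(a=X["a"] * 1000))
    assert np.allclose(v1, v2)
    Xc = X.assign(d=X["a"] * 2)
    assert vif(Xc)["d"] == np.inf


# ---------------------------------------------------------------------------
# Forward stepwise BIC
# ---------------------------------------------------------------------------

def test_stepwise_null_selection_matches_bic_threshold():
    """Pure-noise candidates: the first-step false-selection rate follows the
    analytic BIC acceptance threshold (adding a variable wins when its
    chi-squared statistic exceeds about ln n), computed as an independent
    oracle."""
    rng = np.random.default_rng(8)
    n, p = 40, 20
    picked = 0
    n_rep = 80
    for _ in range(n_rep):
        y = pd.Series(rng.normal(0, 1, n))
        X = pd.DataFrame(rng.normal(0, 1, (n, p)),
                         columns=[f"x{i}" for i in range(p)])
        res = forward_stepwise_bic(y, X)
        if res.selected:
            picked += 1
    # adding one regressor lowers BIC iff n*ln(1 - r^2) + ln n < 0
    r2_crit = 1.0 - n ** (-1.0 / n)
    p_one = sps.chi2.sf(-n * np.log(1 - r2_crit), 1)
    expected = 1 - (1 - p_one) ** p
    assert picked / n_rep == pytest.approx(expected, abs=0.15)


def test_stepwise_recovers_single_signal():
    rng = np.random.default_rng(9)
    n = 60
    X = pd.DataFrame(rng.normal(0, 1, (n, 10)),
                     columns=[f"x{i}" for i in range(10)])
    y = 2.0 * X["x1"] + rng.normal(0, 0.1, n)
    res = forward_stepwise_bic(pd.Series(y), X)
    assert res.selected == ["x1"]
    assert res.coefficients["x1"] == pytest.approx(2.0, abs=0.1)
    assert res.adj_r2 > 0.99
    assert (np.diff(res.path["bic"]) < 0).all()  # strictly decreasing path


def test_stepwise_never_selects_duplicate_twice():
    rng = np.random.default_rng(10)
    n = 50
    x = rng.normal(0, 1, n)
    X = pd.DataFrame({"a": x, "dup": x.copy(), "noise": rng.normal(0, 1, n)})
    y = pd.Series(3 * x + rng.normal(0, 0.2, n))
    res = forward_stepwise_bic(y, X)
    assert len(res.selected) == len(set(res.selected))
    assert not {"a", "dup"} <= set(res.selected)


# ---------------------------------------------------------------------------
# Chi-squared on category counts
# ---------------------------------------------------------------------------

def test_category_count_temperature_vs_precipitation():
    chi2, p = category_count_test([21, 16])
    assert chi2 == pytest.approx(2 * 2.5 ** 2 / 18.5, abs=1e-9)  # 0.6757
    assert p > 0.05  # not significant
    assert p == pytest.approx(0.41, abs=0.01)


def test_category_count_edge_cases():
    chi2, p = category_count_test([10, 10])
    assert chi2 == 0.0 and p == 1.0
    rng = np.random.default_rng(11)
    counts = rng.integers(1, 30, size=4)
    chi2, _ = category_count_test(counts)
    e = counts.mean()
    assert chi2 == pytest.approx(sum((c - e) ** 2 / e for c in counts))
    with pytest.raises(ValueError):
        category_count_test([0, 0])


# ---------------------------------------------------------------------------
# Association Model/Results
# ---------------------------------------------------------------------------

def test_association_model_recovers_planted_effect():
    rng = np.random.default_rng(12)
    n = 45
    qw = pd.Series(rng.uniform(0, 1, n), index=[f"p{i}" for i in range(n)])
    env = pd.DataFrame(index=qw.index)
    env["longitude"] = -0.9 * (qw - qw.mean()) / qw.std() + rng.normal(0, 0.3, n)
    env["bio8_lig"] = -0.8 * (qw - qw.mean()) / qw.std() + rng.normal(0, 0.4, n)
    for j in range(60):
        env[f"noise{j}"] = rng.normal(0, 1, n)
    model = AssociationModel(pd.DataFrame({"q_west": qw}), env)
    res = model.fit()
    sw = res.models["q_west"]
    assert "longitude" in sw.selected
    assert sw.coefficients["longitude"] < 0
    if "bio8_lig" in sw.selected:
        assert sw.coefficients["bio8_lig"] < 0
    assert "q_west" in res.summary()
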
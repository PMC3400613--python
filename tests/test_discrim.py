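"""Canonical discriminant analysis, MANOVA tests and confidence circles."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from mitocohort.discrim import _sscp, confidence_circles, fit_cda
from mitocohort.discrim import test_groups as group_tests


def random_sample(seed=0, n_per=12, g=5, p=8, spread=1.0):
    rng = np.random.default_rng(seed)
    means = rng.normal(0, spread, (g, p))
    X = np.vstack([rng.normal(means[i], 1.0, (n_per, p)) for i in range(g)])
    groups = np.repeat([f"g{i}" for i in range(g)], n_per)
    return X, groups


def test_two_group_1d_single_axis():
    rng = np.random.default_rng(1)
    X = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])[:, None]
    groups = np.repeat(["a", "b"], 30)
    model = fit_cda(X, groups)
    assert model.eigenvalues.shape == (1,)
    assert model.variance_fraction[0] == pytest.approx(1.0)
    # scores standardized to unit pooled within-group variance
    s = model.scores
    within = np.concatenate([
        s.loc[s["group"] == g, "can1"] - s.loc[s["group"] == g, "can1"].mean()
        for g in ("a", "b")
    ])
    assert np.var(within, ddof=2) == pytest.approx(1.0, rel=0.01)


def test_relabeled_data_no_separation():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(80, 4))
    groups = np.tile(["a", "b", "c", "d"], 20)  # labels independent of X
    model = fit_cda(X, groups)
    comp = group_tests(model, X, groups)
    assert model.eigenvalues.max() < 0.5
    assert comp.wilks_lambda > 0.7
    assert comp.p_value > 0.1


def test_eigenvalues_match_dense_generalized_solve():
    """Canonical eigenvalues equal a brute-force dense eig of E^-1 H to 1e-8."""
    X, groups = random_sample(seed=3)
    model = fit_cda(X, groups)
    H, E, _ = _sscp(X, groups)
    ref = np.sort(np.real(linalg.eig(np.linalg.solve(E, H))[0]))[::-1]
    n_axes = len(model.eigenvalues)
    assert np.allclose(model.eigenvalues, ref[:n_axes], atol=1e-8)
    assert (np.diff(model.eigenvalues) <= 1e-12).all()
    assert model.variance_fraction.sum() == pytest.approx(1.0)


def test_two_group_wilks_equals_hotelling_t2():
    """For two groups, Wilks' Lambda is 1/(1 + T^2/(n-2)) and Rao's F equals the
    Hotelling F with df (p, n-p-1)."""
    rng = np.random.default_rng(4)
    n1, n2, p = 10, 10, 3
    X = np.vstack([rng.normal(0, 1, (n1, p)), rng.normal(0.8, 1, (n2, p))])
    groups = np.repeat(["a", "b"], [n1, n2])
    model = fit_cda(X, groups)
    comp = group_tests(model, X, groups)
    d = X[:n1].mean(0) - X[n1:].mean(0)
    S = (np.cov(X[:n1].T) * (n1 - 1) + np.cov(X[n1:].T) * (n2 - 1)) / (n1 + n2 - 2)
    t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(S, d)
    n = n1 + n2
    assert comp.wilks_lambda == pytest.approx(1 / (1 + t2 / (n - 2)), rel=1e-10)
    f_ref = t2 * (n - p - 1) / (p * (n - 2))
    assert comp.rao_F == pytest.approx(f_ref, rel=1e-10)
    p_ref = stats.f.sf(f_ref, p, n - p - 1)
    assert comp.p_value == pytest.approx(p_ref, rel=1e-10)


def test_matches_statsmodels_manova():
    """Wilks and Roy agree with an independent MANOVA implementation."""
    from statsmodels.multivariate.manova import MANOVA

    X, groups = random_sample(seed=5, n_per=10, g=3, p=4, spread=0.6)
    df = pd.DataFrame(X, columns=["v1", "v2", "v3", "v4"])
    df["g"] = groups
    res = MANOVA.from_formula("v1 + v2 + v3 + v4 ~ g", data=df).mv_test()
    tbl = res.results["g"]["stat"]
    model = fit_cda(X, groups)
    comp = group_tests(model, X, groups)
    assert comp.wilks_lambda == pytest.approx(tbl.loc["Wilks' lambda", "Value"], rel=1e-8)
    assert comp.rao_F == pytest.approx(tbl.loc["Wilks' lambda", "F Value"], rel=1e-6)
    assert comp.p_value == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], abs=1e-8)
    assert comp.roys_root == pytest.approx(tbl.loc["Roy's greatest root", "Value"], rel=1e-8)
    assert comp.roy_F == pytest.approx(tbl.loc["Roy's greatest root", "F Value"], rel=1e-6)


def test_widely_separated_groups():
    X, groups = random_sample(seed=6, spread=8.0)
    model = fit_cda(X, groups)
    comp = group_tests(model, X, groups)
    assert comp.wilks_lambda < 0.01
    assert comp.p_value < 1e-6
    assert comp.pairwise_significant.to_numpy()[~np.eye(5, dtype=bool)].all()


def test_affine_invariance():
    """An invertible linear map of the data leaves Lambda, F and the variance
    fractions unchanged."""
    X, groups = random_sample(seed=7, p=5)
    rng = np.random.default_rng(8)
    A = rng.normal(size=(5, 5)) + 5 * np.eye(5)
    Y = X @ A.T + rng.normal(size=5)
    m1, m2 = fit_cda(X, groups), fit_cda(Y, groups)
    c1, c2 = group_tests(m1, X, groups), group_tests(m2, Y, groups)
    assert c1.wilks_lambda == pytest.approx(c2.wilks_lambda, rel=1e-8)
    assert c1.rao_F == pytest.approx(c2.rao_F, rel=1e-8)
    assert np.allclose(m1.variance_fraction, m2.variance_fraction, atol=1e-8)


def test_pairwise_matrix_symmetric_bonferroni():
    X, groups = random_sample(seed=9, g=4, p=3, spread=1.5)
    model = fit_cda(X, groups)
    comp = group_tests(model, X, groups)
    P = comp.pairwise_p
    assert comp.n_pairs == 6
    assert np.allclose(P.to_numpy(), P.to_numpy().T, equal_nan=True)
    assert (P.to_numpy()[~np.eye(4, dtype=bool)] <= 1.0).all()


def test_confidence_circle_radius_formula_and_scaling():
    """radius = sqrt(chi2_2(0.95)/n); doubling n at fixed variance shrinks the
    radius by sqrt(2); n_g = 50 gives 0.346."""
    rng = np.random.default_rng(10)
    X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(2, 1, (25, 3)),
                   rng.normal(4, 1, (50, 3))])
    groups = np.repeat(["big", "small", "mid"], [100, 25, 50])
    model = fit_cda(X, groups)
    circles = {c.group: c for c in confidence_circles(model)}
    chi2 = stats.chi2.ppf(0.95, 2)
    assert circles["mid"].radius == pytest.approx(np.sqrt(chi2 / 50))
    assert circles["mid"].radius == pytest.approx(0.346, abs=0.001)
    assert circles["small"].radius / circles["big"].radius == pytest.approx(2.0)


def test_separated_groups_have_disjoint_circles():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(0, 1, (200, 2)), rng.normal(6, 1, (200, 2))])
    groups = np.repeat(["a", "b"], 200)
    model = fit_cda(X, groups)
    ca, cb = confidence_circles(model)
    dist = np.hypot(ca.center[0] - cb.center[0], ca.center[1] - cb.center[1])
    assert dist > ca.radius + cb.radius


def test_singleton_group_flagged():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(21, 2))
    groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"])
    with pytest.raises(ValueError):
        fit_cda(X, groups)


def test_singular_within_ridge_fallback():
    rng = np.random.default_rng(13)
    base = rng.normal(size=(20, 2))
    X = np.hstack([base, base[:, :1] * 2.0])  # exactly collinear third column
    groups = np.repeat(["a", "b"], 10)
    model = fit_cda(X, groups)
    assert model.ridged
    with pytest.raises(np.linalg.LinAlgError):
        fit_cda(X, groups, ridge=False)
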
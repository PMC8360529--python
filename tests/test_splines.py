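import numpy as np
import pytest

from mgam.splines import basis_from_knots, build_basis


def truncated_power_natural_basis(x, knots):
    """Independent natural cubic spline construction (truncated powers).

    ``knots`` are all knots including the two boundary ones.  Columns:
    x and d_k(x) − d_{K−1}(x) for k = 1..K−2 with
    d_k(x) = [(x−κ_k)₊³ − (x−κ_K)₊³] / (κ_K − κ_k).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k):
        return ((np.clip(x - knots[k], 0, None) ** 3
                 - np.clip(x - knots[K - 1], 0, None) ** 3)
                / (knots[K - 1] - knots[k]))

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def fitted_values(B, y):
    """Least-squares projection of y onto span{1, B}."""
    X = np.column_stack([np.ones(len(y)), B])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ beta


def test_df1_basis_is_affine_in_x():
    x = np.arange(1.0, 101.0)
    basis = build_basis(x, df=1)
    B = basis.design(x)
    assert B.shape == (100, 1)
    # exactly affine: second differences vanish
    assert np.allclose(np.diff(B[:, 0], 2), 0.0, atol=1e-10)


@pytest.mark.parametrize("df", [1, 2, 3, 5, 8])
def test_span_contains_affine_functions(df):
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0, 10, 120))
    y = 2.5 - 1.25 * x
    basis = build_basis(x, df=df)
    fit = fitted_values(basis.design(x), y)
    assert np.allclose(fit, y, atol=1e-9)


@pytest.mark.parametrize("df", [3, 5, 7])
def test_agrees_with_truncated_power_oracle(df):
    rng = np.random.default_rng(1)
    x = np.sort(rng.uniform(-3, 35, 400))
    basis = build_basis(x, df=df)
    knots = np.r_[basis.boundary_knots[0], basis.interior_knots,
                  basis.boundary_knots[1]]
    TP = truncated_power_natural_basis(x, knots)
    y = np.sin(x / 5.0) + 0.1 * x
    fit_b = fitted_values(basis.design(x), y)
    fit_tp = fitted_values(TP, y)
    # same function space -> identical projections
    probes = np.linspace(x[5], x[-5], 10)
    assert np.allclose(fit_b, fit_tp, atol=1e-8)
    # and identical smooths at probe points inside the range
    Xb = np.column_stack([np.ones(len(x)), basis.design(x)])
    bb, *_ = np.linalg.lstsq(Xb, y, rcond=None)
    Xtp = np.column_stack([np.ones(len(x)), TP])
    bt, *_ = np.linalg.lstsq(Xtp, y, rcond=None)
    pb = bb[0] + basis.design(probes) @ bb[1:]
    pt = np.column_stack([np.ones(10),
                          truncated_power_natural_basis(probes, knots)]) @ bt
    assert np.allclose(pb, pt, atol=1e-8)


def test_linear_extrapolation_beyond_boundary_knots():
    x = np.linspace(0, 10, 50)
    basis = build_basis(x, df=5)
    coef = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
    for grid in (np.linspace(10.5, 15.0, 20), np.linspace(-5.0, -0.5, 20)):
        vals = basis.evaluate(coef, grid)
        assert np.allclose(np.diff(vals, 2), 0.0, atol=1e-10)
    # second derivative is zero at the boundary itself (natural condition)
    assert np.allclose(basis.derivative(np.array([0.0, 10.0]), nu=2),
                       0.0, atol=1e-8)


def test_evaluate_zero_coef_and_training_reproduction():
    x = np.linspace(0, 10, 60)
    basis = build_basis(x, df=4)
    assert np.allclose(basis.evaluate(np.zeros(4), x), 0.0)
    y = np.cos(x)
    B = basis.design(x)
    beta, *_ = np.linalg.lstsq(B, y - y.mean(), rcond=None)
    assert np.allclose(basis.evaluate(beta, x), B @ beta)


def test_basis_reproducible_and_reconstructible():
    x = np.linspace(0, 5, 40)
    b1 = build_basis(x, df=4)
    b2 = build_basis(x, df=4)
    assert np.array_equal(b1.design(x), b2.design(x))
    b3 = basis_from_knots(b1.boundary_knots, b1.interior_knots,
                          center=b1._center)
    assert np.array_equal(b1.design(x), b3.design(x))


def test_df_too_large_for_distinct_values():
    with pytest.raises(ValueError, match="distinct"):
        build_basis(np.array([1.0, 1.0, 2.0, 3.0]), df=4)


def test_centering_does_not_change_fitted_values():
    rng = np.random.default_rng(2)
    x = np.sort(rng.uniform(0, 20, 150))
    y = rng.normal(size=150)
    basis = build_basis(x, df=5)
    raw = basis.design(x, center=False)
    centered = basis.design(x, center=True)
    assert np.allclose(fitted_values(raw, y), fitted_values(centered, y),
                       atol=1e-9)
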
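"""Preprocessing transforms: closed-form identities, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.special import binom, gamma

from hsq import SpectraSet
from hsq.preprocess import derivative_int, fod, gl_weights, lg, msc, snv


def make_set(values, tag="R"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    return SpectraSet(
        sample_ids=[f"s{i}" for i in range(n)],
        wavelengths=400.0 + np.arange(p),
        reflectance=values,
        transform_tag=tag,
    )


finite_rows = hnp.arrays(
    np.float64,
    st.tuples(st.integers(2, 6), st.integers(4, 12)),
    elements=st.floats(0.01, 1.0),
)


# ------------------------------------------------------------------- MSC

def test_msc_is_identity_on_identical_rows():
    s = np.linspace(0.2, 0.8, 10)
    out, model = msc(make_set(np.tile(s, (4, 1))))
    np.testing.assert_allclose(out.reflectance, np.tile(s, (4, 1)), atol=1e-12)
    np.testing.assert_allclose(model.slope, 1.0, atol=1e-12)
    np.testing.assert_allclose(model.offset, 0.0, atol=1e-12)


def test_msc_removes_exact_affine_scatter():
    rng = np.random.default_rng(0)
    shape = np.sin(np.linspace(0, 3, 50)) + 2.0
    a = rng.uniform(0.7, 1.3, size=6)
    b = rng.uniform(-0.1, 0.1, size=6)
    rows = a[:, None] * shape + b[:, None]
    out, _ = msc(make_set(rows))
    spread = out.reflectance.max(axis=0) - out.reflectance.min(axis=0)
    assert spread.max() < 1e-8


def test_msc_changes_spectra_least_among_the_five_transforms(trimmed):
    spectra, _ = trimmed
    raw = spectra.reflectance
    changes = {}
    for tag, out in [
        ("MSC", msc(spectra)[0]),
        ("SNV", snv(spectra)),
        ("Lg", lg(spectra)),
        ("FD", derivative_int(spectra, 1)),
        ("SD", derivative_int(spectra, 2)),
    ]:
        m = out.valid_mask & spectra.valid_mask
        changes[tag] = np.abs(out.reflectance[:, m] - raw[:, m]).mean()
    assert changes["MSC"] == min(changes.values())


def test_msc_rejects_sample_with_zero_variance():
    rows = np.vstack([np.linspace(0.2, 0.8, 8), np.linspace(0.3, 0.9, 8),
                      np.full(8, 0.5)])
    with pytest.raises(ValueError, match="s2"):
        msc(make_set(rows))


# ------------------------------------------------------------------- SNV

@settings(derandomize=True, max_examples=25, deadline=None)
@given(finite_rows)
def test_snv_rows_have_zero_mean_unit_sd(values):
    if np.any(values.std(axis=1) <= 1e-9 * np.abs(values).max()):
        return  # near-constant rows are rejected, covered separately
    out = snv(make_set(values))
    np.testing.assert_allclose(out.reflectance.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.reflectance.std(axis=1, ddof=0), 1.0, atol=1e-10)


def test_snv_population_sd_convention():
    out = snv(make_set([0.2, 0.4, 0.6]))
    np.testing.assert_allclose(
        out.reflectance[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
    )


def test_snv_preserves_row_shape():
    rng = np.random.default_rng(1)
    rows = rng.uniform(0.1, 0.9, size=(3, 30))
    out = snv(make_set(rows))
    for x, z in zip(rows, out.reflectance):
        assert np.corrcoef(x, z)[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_snv_global_mode_is_one_affine_map():
    rng = np.random.default_rng(2)
    rows = rng.uniform(0.1, 0.9, size=(5, 20))
    out = snv(make_set(rows), mode="global")
    assert out.reflectance.mean() == pytest.approx(0.0, abs=1e-10)
    assert out.reflectance.std(ddof=0) == pytest.approx(1.0, abs=1e-10)
    # single affine map: band-wise z-scores differ from per-spectrum output
    np.testing.assert_allclose(
        out.reflectance, (rows - rows.mean()) / rows.std(ddof=0), atol=1e-12
    )


def test_snv_rejects_constant_row():
    rows = np.vstack([np.full(6, 0.4), np.linspace(0.2, 0.7, 6)])
    with pytest.raises(ValueError, match="s0"):
        snv(make_set(rows))


# -------------------------------------------------------------------- Lg

def test_lg_log10_identities_and_roundtrip():
    out = lg(make_set([[0.1, 1.0]]))
    np.testing.assert_allclose(out.reflectance[0], [1.0, 0.0], atol=1e-12)
    a = np.linspace(0.0, 2.0, 40)
    round_trip = lg(make_set(10.0 ** (-a))).reflectance[0]
    np.testing.assert_allclose(round_trip, a, atol=1e-12)


def test_lg_rejects_non_positive_values():
    rows = np.array([[0.2, 0.0, 0.4]])
    with pytest.raises(ValueError, match="s0"):
        lg(make_set(rows))


# ----------------------------------------------------------- derivatives

def test_derivative_of_constant_is_zero():
    s = make_set(np.full((2, 10), 0.5))
    for order in (1, 2):
        out = derivative_int(s, order)
        np.testing.assert_allclose(out.valid_reflectance, 0.0, atol=1e-14)


def test_central_scheme_exact_for_quadratics():
    lam = np.arange(20.0)
    s = SpectraSet(["q"], lam, (lam**2)[None, :])
    fd = derivative_int(s, 1)
    sd = derivative_int(s, 2)
    np.testing.assert_array_equal(fd.valid_reflectance[0], 2 * lam[1:-1])
    np.testing.assert_array_equal(sd.valid_reflectance[0], np.full(18, 2.0))
    assert not fd.valid_mask[0] and not fd.valid_mask[-1]


def test_forward_scheme_is_literal_difference():
    rng = np.random.default_rng(3)
    row = rng.uniform(0.1, 0.9, 12)
    fd = derivative_int(make_set(row), 1, scheme="forward")
    np.testing.assert_allclose(fd.reflectance[0, :-1], np.diff(row), atol=0)
    sd = derivative_int(make_set(row), 2, scheme="forward")
    np.testing.assert_allclose(sd.reflectance[0, :-2], np.diff(row, 2), atol=0)


def test_derivative_needs_three_bands():
    with pytest.raises(ValueError):
        derivative_int(make_set([[0.1, 0.2]]), 1)


def test_second_derivative_alternates_sign_more_than_first(trimmed):
    spectra, _ = trimmed
    counts = {}
    for order in (1, 2):
        out = derivative_int(spectra, order)
        X = out.valid_reflectance
        counts[order] = np.mean([(np.diff(np.sign(r)) != 0).sum() for r in X])
    assert counts[2] > counts[1]


# ----------------------------------------------------------- G-L weights

@pytest.mark.parametrize(
    "alpha,t,expected",
    [
        (1.0, 3, [1.0, -1.0, 0.0, 0.0]),
        (2.0, 3, [1.0, -2.0, 1.0, 0.0]),
        (0.5, 3, [1.0, -0.5, -0.125, -0.0625]),
    ],
)
def test_gl_weight_examples(alpha, t, expected):
    np.testing.assert_allclose(gl_weights(alpha, t).weights, expected, atol=1e-12)


def test_gl_weights_reject_invalid_arguments():
    with pytest.raises(ValueError):
        gl_weights(-0.1, 10)
    with pytest.raises(ValueError):
        gl_weights(0.5, 0)


def test_gl_recurrence_matches_direct_gamma_evaluation():
    rng = np.random.default_rng(0)
    checked = 0
    while checked < 200:
        alpha = float(rng.uniform(0.01, 1.99))
        if abs(alpha - 1.0) < 1e-6:
            continue
        m = int(rng.integers(1, 41))
        w = gl_weights(alpha, 40).weights[m]
        direct = (-1) ** m * gamma(alpha + 1) / (gamma(m + 1) * gamma(alpha - m + 1))
        np.testing.assert_allclose(w, direct, rtol=1e-8, atol=1e-12)
        checked += 1


def test_gl_integer_orders_have_finite_support():
    for k in (1, 2):
        w = gl_weights(float(k), 40).weights
        assert np.all(w[k + 1 :] == 0.0)


def test_gl_partial_sums_follow_closed_form_and_shrink():
    # sum_{m<=t} w_m = (-1)^t binom(alpha-1, t) -> 0 as t grows (alpha > 0)
    for alpha in (0.5, 0.8, 1.3, 1.7, 2.0):
        s40 = gl_weights(alpha, 40).weights.sum()
        np.testing.assert_allclose(s40, (-1) ** 40 * binom(alpha - 1, 40), atol=1e-10)
        assert abs(s40) < 0.1
        assert abs(s40) <= abs(gl_weights(alpha, 10).weights.sum()) + 1e-12


# -------------------------------------------------------------------- FOD

def test_fod_order_zero_is_identity(trimmed):
    spectra, _ = trimmed
    out = fod(spectra, 0.0)
    np.testing.assert_array_equal(out.reflectance, spectra.reflectance)
    assert out.transform_tag == "FOD:0"


def test_fod_order_one_is_backward_difference(trimmed):
    spectra, _ = trimmed
    out = fod(spectra, 1.0)
    expected = spectra.reflectance[:, 1:] - spectra.reflectance[:, :-1]
    np.testing.assert_array_equal(out.reflectance[:, 1:], expected)
    assert not out.valid_mask[0] and out.valid_mask[1]


def test_fod_rejects_order_outside_sweep_range():
    with pytest.raises(ValueError):
        fod(make_set(np.linspace(0.1, 0.9, 50)[None, :]), 2.1)


def test_fod_is_linear_per_row():
    rng = np.random.default_rng(4)
    rows = rng.uniform(0.1, 0.9, size=(3, 60))
    a = fod(make_set(rows), 0.7, t=10)
    b = fod(make_set(2.5 * rows), 0.7, t=10)
    np.testing.assert_allclose(2.5 * a.valid_reflectance, b.valid_reflectance,
                               atol=1e-10)
    x, y = rows[0], rows[1]
    dsum = derivative_int(make_set(x + y), 1).valid_reflectance
    dx = derivative_int(make_set(x), 1).valid_reflectance
    dy = derivative_int(make_set(y), 1).valid_reflectance
    np.testing.assert_allclose(dsum, dx + dy, atol=1e-10)


def test_fod_order_two_equals_order_one_applied_twice(trimmed):
    spectra, _ = trimmed
    once = fod(spectra, 1.0)
    twice = fod(once, 1.0)
    direct = fod(spectra, 2.0)
    common = twice.valid_mask & direct.valid_mask
    np.testing.assert_allclose(
        twice.reflectance[:, common], direct.reflectance[:, common], atol=1e-8
    )


def test_fod_varies_continuously_with_order(trimmed):
    spectra, _ = trimmed
    eps = 1e-6
    hi = fod(spectra, 1.0 + eps)
    lo = fod(spectra, 1.0 - eps)
    m = hi.valid_mask & lo.valid_mask
    assert np.nanmax(np.abs(hi.reflectance[:, m] - lo.reflectance[:, m])) < 1e-4
    prev = None
    for k in range(21):
        alpha = round(0.1 * k, 1)
        out = fod(spectra, alpha) if alpha > 0 else spectra
        vals = out.reflectance[0, 45:]
        if prev is not None:
            assert np.nanmax(np.abs(vals - prev)) < 0.5
        prev = vals


# ----------------------------------------------------- structural props

def test_row_independent_transforms_ignore_other_samples():
    rng = np.random.default_rng(5)
    rows = rng.uniform(0.1, 0.9, size=(5, 50))
    full = make_set(rows)
    reduced = make_set(rows[:3])
    for op in (snv, lg, lambda s: derivative_int(s, 1), lambda s: fod(s, 0.6, t=10)):
        a = op(full).reflectance[:3]
        b = op(reduced).reflectance
        np.testing.assert_allclose(a, b, atol=1e-12, equal_nan=True)


def test_msc_commutes_with_sample_permutation():
    rng = np.random.default_rng(6)
    rows = rng.uniform(0.1, 0.9, size=(6, 40))
    perm = rng.permutation(6)
    out, _ = msc(make_set(rows))
    out_perm, _ = msc(make_set(rows[perm]))
    np.testing.assert_allclose(out.reflectance[perm], out_perm.reflectance, atol=1e-12)
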
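"""Wavelet registry, multilevel DWT/inverse, DCT baseline.

The multilevel DWT is checked against an independently written circular
convolve-then-decimate filterbank oracle, anchored to hand-computed Haar
values, so correctness does not rest on the library being tested.
"""

import numpy as np
import pytest

from tactsparse import (
    ValidationError,
    dct_forward,
    dct_inverse,
    dwt_forward,
    dwt_inverse,
    forward,
    inverse,
    max_decomposition_level,
    wavelet_registry,
)
from tactsparse.transforms import get_wavelet, registry_families, scaling_function

REGISTRY = wavelet_registry()
IMPLEMENTED = [s for s in REGISTRY if s.implemented]
PR_EXACT = [s for s in REGISTRY if s.implemented and s.pr_exact]


# ---------------------------------------------------------------- registry

def test_registry_has_75_wavelets_in_12_families():
    assert len(REGISTRY) == 75
    assert len({s.family for s in REGISTRY}) == 12
    assert len({s.name for s in REGISTRY}) == 75


def test_families_without_published_taps_are_reported_not_approximated():
    missing = sorted(s.name for s in REGISTRY if not s.implemented)
    assert missing == sorted([
        "fk4", "fk6", "fk8", "fk14", "fk18", "fk22",
        "bl7", "bl9", "bl10",
        "mb4.2", "mb8.2", "mb8.3", "mb8.4",
        "beyl", "vaid",
        "han2.3", "han3.3", "han4.5", "han5.5",
    ])
    for name in missing:
        with pytest.raises(ValidationError, match="no published filter taps"):
            get_wavelet(name).to_pywt()


def test_haar_support_length_is_two():
    assert get_wavelet("haar").support_length == 2
    assert get_wavelet("db1").support_length == 2


def test_biorthogonal_wavelets_are_flagged_non_orthogonal():
    assert not get_wavelet("bior4.4").orthogonal
    assert get_wavelet("sym4").orthogonal


def test_orthogonal_filters_are_time_reverses():
    for spec in PR_EXACT:
        if spec.orthogonal:
            assert np.allclose(spec.rec_lo, spec.dec_lo[::-1], atol=1e-12)
            assert np.allclose(spec.rec_hi, spec.dec_hi[::-1], atol=1e-12)


def test_registry_family_layout_is_stable():
    fams = registry_families()
    assert sum(len(v) for v in fams.values()) == 75
    assert set(fams["BiorSplines"]) == {f"bior{t}" for t in
        ["1.1", "1.3", "1.5", "2.2", "2.4", "2.6", "2.8",
         "3.1", "3.3", "3.5", "3.7", "3.9", "4.4", "5.5", "6.8"]}


# ------------------------------------------------------------ level rule

@pytest.mark.parametrize(
    "shape,dim,expected",
    [((8,), 1, 3), ((100,), 1, 6), ((500, 32, 32), 3, 5),
     ((256, 32, 32), 1, 8), ((64, 16, 16), 2, 4), ((16, 16), 2, 4)],
)
def test_max_decomposition_level_rule(shape, dim, expected):
    assert max_decomposition_level(shape, dim) == expected


def test_dimension_below_two_rejected():
    with pytest.raises(ValidationError):
        max_decomposition_level((1, 32, 32), 3)


def test_level_above_maximum_rejected(rng):
    with pytest.raises(ValidationError, match="level"):
        dwt_forward(rng.normal(size=16), "haar", 1, level=5)


# --------------------------------------------- filterbank oracle (1D DWT)

def _oracle_dwt_step(x, filt):
    """Periodized single-level analysis: circular convolution with the
    decomposition filter, decimated by 2, phase offset len(filt)/2."""
    n, L = len(x), len(filt)
    return np.array([
        sum(filt[m] * x[(2 * k + L // 2 - m) % n] for m in range(L))
        for k in range(n // 2)
    ])


def _oracle_wavedec(x, spec, level):
    lo, hi = np.asarray(spec.dec_lo), np.asarray(spec.dec_hi)
    a, details = np.asarray(x, float), []
    for _ in range(level):
        details.append(_oracle_dwt_step(a, hi))
        a = _oracle_dwt_step(a, lo)
    return a, details[::-1]  # coarsest first


def test_oracle_matches_hand_computed_haar_values():
    a, (d,) = _oracle_wavedec([1.0, 3.0, 5.0, 7.0], get_wavelet("haar"), 1)
    s = np.sqrt(2.0)
    assert np.allclose(a, [4 / s, 12 / s])
    assert np.allclose(d, [-2 / s, -2 / s])


@pytest.mark.parametrize("wname", ["haar", "db2", "sym4", "bior2.2"])
def test_multilevel_dwt_matches_filterbank_oracle(wname, rng):
    x = rng.normal(size=16)
    spec = get_wavelet(wname)
    coeffs = dwt_forward(x, spec, 1, level=2)
    a_or, d_or = _oracle_wavedec(x, spec, 2)
    got = dict(coeffs.subbands())
    assert np.allclose(got["a2"], a_or, atol=1e-10)
    assert np.allclose(got["d2"], d_or[0], atol=1e-10)
    assert np.allclose(got["d1"], d_or[1], atol=1e-10)


# -------------------------------------------------- perfect reconstruction

@pytest.mark.parametrize("spec", PR_EXACT, ids=lambda s: s.name)
@pytest.mark.parametrize("dim,shape", [(1, (64,)), (2, (16, 16)), (3, (8, 8, 8))])
def test_perfect_reconstruction_across_registry(spec, dim, shape, rng):
    x = rng.normal(size=shape)
    coeffs = dwt_forward(x, spec, dim, level="max")
    y = dwt_inverse(coeffs)
    assert np.linalg.norm(x - y) <= 1e-8 * np.linalg.norm(x)


def test_dmey_reconstruction_floor_is_documented():
    """The 62-tap discrete Meyer filter is a truncation of an ideal filter
    and only quasi-orthogonal: reconstruction error sits near 3e-3 in every
    extension mode, so exact-PR guarantees exclude it."""
    rng = np.random.default_rng(1)
    x = rng.normal(size=256)
    y = dwt_inverse(dwt_forward(x, "dmey", 1))
    rel = np.linalg.norm(x - y) / np.linalg.norm(x)
    assert 1e-9 < rel < 1e-2
    assert not get_wavelet("dmey").pr_exact


def test_coefficient_count_equals_input_size_with_periodization(rng):
    for dim, shape in [(1, (64,)), (2, (16, 16)), (3, (8, 8, 8)), (1, (64, 4, 4))]:
        coeffs = dwt_forward(rng.normal(size=shape), "db3", dim)
        assert coeffs.n_coefficients == int(np.prod(shape))


def test_parseval_for_orthogonal_wavelets(rng):
    x = rng.normal(size=64)
    for spec in PR_EXACT:
        if not spec.orthogonal:
            continue
        vec = dwt_forward(x, spec, 1, level="max").vector()
        assert np.sum(vec**2) == pytest.approx(np.sum(x**2), rel=1e-8)


def test_constant_input_kills_detail_bands():
    coeffs = dwt_forward(np.full(32, 3.0), "haar", 1, level=1)
    got = dict(coeffs.subbands())
    assert np.allclose(got["d1"], 0.0, atol=1e-12)


def test_haar_zeroed_details_give_blockwise_means():
    coeffs = dwt_forward(np.array([1.0, 3.0, 5.0, 7.0]), "haar", 1, level=1)
    coeffs.coeffs[1]["d"][:] = 0.0
    assert np.allclose(dwt_inverse(coeffs), [2.0, 2.0, 6.0, 6.0])


def test_all_zero_coefficients_invert_to_zero(rng):
    coeffs = dwt_forward(rng.normal(size=(16, 8, 8)), "sym4", 3)
    zero = coeffs.map(np.zeros_like)
    assert not dwt_inverse(zero).any()


def test_inverse_with_mismatched_wavelet_rejected(rng):
    coeffs = dwt_forward(rng.normal(size=32), "db2", 1)
    with pytest.raises(ValidationError, match="mismatch"):
        dwt_inverse(coeffs, "sym4")


def test_symmetric_extension_mode_round_trips(rng):
    x = rng.normal(size=(32, 8, 8))
    coeffs = dwt_forward(x, "bior4.4", 3, level=2, mode="symmetric")
    y = dwt_inverse(coeffs)
    assert np.allclose(x, y, atol=1e-10)
    assert coeffs.n_coefficients > x.size  # expansive mode


# ------------------------------------------------------------------- DCT

def test_dct_constant_input_has_single_nonzero_dc_coefficient():
    c = dct_forward(np.full(16, 2.0), 1)
    assert np.count_nonzero(np.abs(c) > 1e-12) == 1
    assert np.argmax(np.abs(c)) == 0


@pytest.mark.parametrize("dim,shape", [(1, (64,)), (2, (8, 8)), (3, (16, 8, 8)), (1, (32, 4, 4))])
def test_dct_round_trip_and_parseval(dim, shape, rng):
    x = rng.normal(size=shape)
    c = dct_forward(x, dim)
    assert np.allclose(dct_inverse(c, dim), x, atol=1e-10)
    assert np.sum(c**2) == pytest.approx(np.sum(x**2), rel=1e-10)


def test_uniform_forward_inverse_dispatch(rng):
    x = rng.normal(size=(32, 4, 4))
    for transform in ("dct", "sym4"):
        cs = forward(x, transform, 1)
        assert np.allclose(inverse(cs), x, atol=1e-8)


# ------------------------------------------------------- scaling function

def test_scaling_function_integrates_to_one_scale():
    # cascade approximations of orthogonal scaling functions sum to ~2^level/sqrt(2^level)
    x, phi = scaling_function("db2", iterations=5)
    assert phi.size == x.size
    assert np.trapezoid(phi, x) == pytest.approx(1.0, rel=0.05)
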
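"""Hilbert-Noda matrix and correlation-map algebra: hand-computed cases,
symmetry structure, variance identity, scaling and equivariance."""

import numpy as np
import pytest

from mircos.cos import (
    CosError,
    asynchronous_map,
    correlation_maps,
    dynamic_spectra,
    hilbert_noda_matrix,
    integrated_map,
    per_sample_maps,
    synchronous_map,
)
from mircos.simulate import SyntheticConfig, generate_spectra


def test_noda_matrix_m1():
    np.testing.assert_array_equal(hilbert_noda_matrix(1), [[0.0]])


def test_noda_matrix_m3_hand_values():
    expected = np.array(
        [
            [0.0, 1 / np.pi, 1 / (2 * np.pi)],
            [-1 / np.pi, 0.0, 1 / np.pi],
            [-1 / (2 * np.pi), -1 / np.pi, 0.0],
        ]
    )
    np.testing.assert_allclose(hilbert_noda_matrix(3), expected, atol=1e-15)


@pytest.mark.parametrize("m", [1, 2, 5, 12])
def test_noda_matrix_antisymmetry(m):
    N = hilbert_noda_matrix(m)
    np.testing.assert_allclose(N + N.T, 0.0, atol=1e-15)
    assert np.all(np.diag(N) == 0)


def test_noda_matrix_rejects_nonpositive_m():
    with pytest.raises(CosError):
        hilbert_noda_matrix(0)


# --------------------------- dynamic spectra --------------------------- #


def test_identical_records_center_to_zero():
    D = dynamic_spectra(np.array([[1.0, 2.0], [1.0, 2.0]]))
    np.testing.assert_array_equal(D.matrix, 0.0)


def test_mean_centering_hand_example():
    D = dynamic_spectra(np.array([[1.0, 3.0], [3.0, 1.0]]))
    np.testing.assert_array_equal(D.reference, [2.0, 2.0])
    np.testing.assert_array_equal(D.matrix, [[-1.0, 1.0], [1.0, -1.0]])


def test_supplied_reference_policy():
    mat = np.array([[1.0, 2.0], [3.0, 4.0]])
    r = np.array([1.0, 1.0])
    D = dynamic_spectra(mat, reference=r)
    np.testing.assert_array_equal(D.matrix, mat - r)
    assert not np.allclose(D.matrix.sum(axis=0), 0.0)


def test_column_sums_vanish_with_mean_reference(rng):
    D = dynamic_spectra(rng.normal(size=(7, 20)))
    np.testing.assert_allclose(D.matrix.sum(axis=0), 0.0, atol=1e-9)


def test_series_size_guard():
    with pytest.raises(CosError):
        dynamic_spectra(np.ones((1, 4)))


# ------------------------------- maps ---------------------------------- #

D3 = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])


def test_synchronous_hand_example():
    np.testing.assert_allclose(synchronous_map(D3), [[1.0, 0.5], [0.5, 1.0]])


def test_asynchronous_hand_example():
    a = 3 / (4 * np.pi)
    np.testing.assert_allclose(asynchronous_map(D3), [[0.0, a], [-a, 0.0]], atol=1e-14)


def test_integrated_hand_example():
    b = 3 / (8 * np.pi)
    I = integrated_map(synchronous_map(D3), asynchronous_map(D3))
    np.testing.assert_allclose(I, [[0.0, b], [-b, 0.0]], atol=1e-14)


def test_two_opposite_rows_cancel_asynchronously(rng):
    d = rng.normal(size=12)
    Psi = asynchronous_map(np.vstack([d, -d]))
    np.testing.assert_allclose(Psi, 0.0, atol=1e-12)


def test_zero_dynamic_spectra_give_zero_maps():
    Z = np.zeros((4, 6))
    np.testing.assert_array_equal(synchronous_map(Z), 0.0)
    np.testing.assert_array_equal(asynchronous_map(Z), 0.0)


def test_map_symmetry_structure(rng):
    D = rng.normal(size=(9, 15))
    Phi = synchronous_map(D)
    Psi = asynchronous_map(D)
    I = integrated_map(Phi, Psi)
    assert np.abs(Phi - Phi.T).max() < 1e-10
    assert np.all(np.diag(Phi) >= -1e-12)
    np.testing.assert_allclose(Psi + Psi.T, 0.0, atol=1e-10)
    np.testing.assert_allclose(np.diag(Psi), 0.0, atol=1e-12)
    np.testing.assert_allclose(I + I.T, 0.0, atol=1e-10)


def test_sync_diagonal_is_per_wavenumber_variance(rng):
    mat = rng.normal(size=(8, 10))
    Phi = synchronous_map(dynamic_spectra(mat))
    np.testing.assert_allclose(np.diag(Phi), mat.var(axis=0, ddof=1), atol=1e-10)


def test_quadratic_and_quartic_scaling(rng):
    D = rng.normal(size=(5, 8))
    c = 3.0
    np.testing.assert_allclose(
        synchronous_map(c * D), c**2 * synchronous_map(D), atol=1e-12
    )
    np.testing.assert_allclose(
        asynchronous_map(c * D), c**2 * asynchronous_map(D), atol=1e-12
    )
    I = integrated_map(synchronous_map(D), asynchronous_map(D))
    Ic = integrated_map(synchronous_map(c * D), asynchronous_map(c * D))
    np.testing.assert_allclose(Ic, c**4 * I, atol=1e-12)


def test_wavenumber_permutation_equivariance(rng):
    D = rng.normal(size=(6, 7))
    perm = rng.permutation(7)
    for f in (synchronous_map, asynchronous_map):
        np.testing.assert_allclose(f(D[:, perm]), f(D)[np.ix_(perm, perm)], atol=1e-12)


def test_integrated_shape_mismatch_rejected():
    with pytest.raises(CosError):
        integrated_map(np.ones((3, 3)), np.ones((4, 4)))


# --------------------------- per-sample maps --------------------------- #


def test_one_map_set_per_sample_study_scale():
    """172 samples x 3 categories = 516 images downstream."""
    cfg = SyntheticConfig(grid=(4000, 450, 40), seed=1)
    sp = generate_spectra(cfg)
    maps = per_sample_maps(sp, "replicate", downsample=1)
    assert len(maps) == 172
    assert 3 * len(maps) == 516


def test_identical_replicates_give_zero_maps():
    cfg = SyntheticConfig(
        n_per_class={"cultivated": 2, "wild": 2},
        grid=(4000, 450, 20),
        noise_sd=0.0,
        replicate_jitter_sd=0.0,
        scatter_range=(1.0, 1.0),
        scatter_model="iid",
        seed=0,
    )
    sp = generate_spectra(cfg)
    maps = per_sample_maps(sp, "replicate", 1)
    for cm in maps.values():
        np.testing.assert_allclose(cm.sync, 0.0, atol=1e-20)
        np.testing.assert_allclose(cm.asyn, 0.0, atol=1e-20)


def test_downsample_decimates_grid(small_spectra):
    n = small_spectra.n_wavenumbers
    maps = per_sample_maps(small_spectra, "replicate", downsample=4)
    expected = len(np.arange(n)[::4])
    cm = next(iter(maps.values()))
    assert cm.sync.shape == (expected, expected)


def test_downsample_arithmetic_1776_points():
    w = np.arange(1776)
    assert len(w[::4]) == 444  # 1776-point grid, factor 4 -> 444 x 444 maps


def test_replicate_mode_requires_replicates():
    cfg = SyntheticConfig(
        n_per_class={"cultivated": 3, "wild": 3},
        grid=(4000, 450, 20),
        replicates=1,
        seed=0,
    )
    sp = generate_spectra(cfg)
    with pytest.raises(CosError, match="replicate"):
        per_sample_maps(sp, "replicate", 1)
    maps = per_sample_maps(sp, "deviation", 1)  # fallback works without replicates
    assert len(maps) == 6
    for cm in maps.values():  # m=2 deviation series: async vanishes exactly
        np.testing.assert_allclose(cm.asyn, 0.0, atol=1e-12)
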
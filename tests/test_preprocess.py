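"""Preprocessing correctness: SNV/MSC algebra, Savitzky-Golay exactness,
chain composition and the frozen-reference (no-leakage) contract."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mircos.preprocess import (
    ChainTransformer,
    DegenerateRecordError,
    ParameterError,
    apply_chain,
    msc,
    parse_chain_name,
    savitzky_golay,
    snv,
    CHAIN_NAMES,
)
from mircos.simulate import SyntheticConfig, clean_class_spectrum, generate_spectra
from mircos.spectra import SpectraSet


def _set(mat, w=None):
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if w is None:
        w = 4000.0 - 2.0 * np.arange(mat.shape[1])
    ids = tuple(f"s{i}" for i in range(mat.shape[0]))
    return SpectraSet(w, mat, ids, ("wild",) * mat.shape[0])


# ------------------------------ SNV ----------------------------------- #


def test_snv_hand_example():
    out = snv(_set([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_snv_fixed_point():
    x = np.array([-1.0, 0.0, 1.0])  # already mean 0, sd (n-1) = 1
    out = snv(_set(x))
    np.testing.assert_allclose(out.absorbance[0], x, atol=1e-12)


def test_snv_constant_record_rejected():
    with pytest.raises(DegenerateRecordError, match="s0"):
        snv(_set([5.0, 5.0, 5.0]))


@settings(max_examples=30, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=5, max_size=30
    ).filter(lambda v: np.std(v) > 1e-6)
)
def test_snv_idempotent(values):
    s = _set(values)
    once = snv(s)
    twice = snv(once)
    np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)


# ------------------------------ MSC ----------------------------------- #


def test_msc_inverts_affine_distortion():
    ref = np.sin(np.linspace(0, 3, 40)) + 2
    distorted = 2.0 * ref + 1.0
    out = msc(_set(np.vstack([distorted]), w=4000 - 2.0 * np.arange(40)), reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)


def test_msc_reference_is_fixed_point():
    ref = np.cos(np.linspace(0, 2, 25)) + 3
    out = msc(_set(ref, w=4000 - 2.0 * np.arange(25)), reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-10)


def test_msc_recovers_clean_spectrum_from_generator_distortions():
    """Scatter gains + baseline offsets, zero noise: MSC against the clean
    class spectrum restores every record to that spectrum."""
    cfg = SyntheticConfig(
        n_per_class={"cultivated": 5, "wild": 1},
        grid=(4000, 450, 10),
        noise_sd=0.0,
        replicate_jitter_sd=0.0,
        replicates=1,
        scatter_range=(0.8, 1.2),
        baseline_offset_range=(-0.05, 0.05),
        baseline_slope_range=(0.0, 0.0),
        seed=11,
    )
    sp = generate_spectra(cfg)
    clean = clean_class_spectrum(cfg, "cultivated")
    cult = [i for i, lab in enumerate(sp.labels) if lab == "cultivated"]
    out = msc(sp.select(cult), reference=clean)
    for row in out.absorbance:
        np.testing.assert_allclose(row, clean, atol=1e-9)


def test_msc_zero_slope_rejected():
    ref = np.linspace(1, 2, 10)
    flat = np.full(10, 3.0)  # zero covariance with ref
    with pytest.raises(DegenerateRecordError):
        msc(_set(flat, w=4000 - 2.0 * np.arange(10)), reference=ref)


# --------------------------- Savitzky-Golay ---------------------------- #


def test_sg_smoothing_preserves_low_degree_polynomials():
    w = 4000.0 - 2.0 * np.arange(100)
    x = 1e-6 * w**3 - 2e-3 * w**2 + w - 5  # degree 3 = polyorder
    out = savitzky_golay(_set(x, w), window=15, polyorder=3, deriv_order=0)
    np.testing.assert_allclose(out.absorbance[0], x, rtol=1e-9)


@pytest.mark.parametrize("direction", ["descending", "ascending"])
def test_sg_first_derivative_of_quadratic(direction):
    """x(v) = v^2 differentiates to 2v in physical (per cm^-1) units."""
    w = np.arange(100.0, 300.0, 2.0)
    if direction == "descending":
        w = w[::-1]
    x = w**2
    out = savitzky_golay(_set(x, w.copy()), 15, 3, 1)
    interior = slice(8, -8)
    np.testing.assert_allclose(out.absorbance[0][interior], 2 * w[interior], rtol=1e-9)


def test_sg_second_derivative_of_line_is_zero():
    w = 4000.0 - 2.0 * np.arange(80)
    out = savitzky_golay(_set(0.5 * w + 3, w), 15, 3, 2)
    np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-9)


def test_sg_parameter_validation():
    s = _set(np.arange(30.0))
    with pytest.raises(ParameterError):
        savitzky_golay(s, window=14, polyorder=3)
    with pytest.raises(ParameterError):
        savitzky_golay(s, window=3, polyorder=3)
    with pytest.raises(ParameterError):
        savitzky_golay(s, window=15, polyorder=3, deriv_order=4)


# ------------------------------ chains --------------------------------- #


def test_all_printed_chain_names_parse():
    for name in CHAIN_NAMES:
        parse_chain_name(name)  # no exception
    with pytest.raises(ParameterError):
        parse_chain_name("OSC")


def test_single_step_chain_equals_direct_call(small_spectra):
    np.testing.assert_allclose(
        apply_chain(small_spectra, "SNV").absorbance,
        snv(small_spectra).absorbance,
    )


def test_chain_composition_snv_then_second_derivative(small_spectra):
    chained = apply_chain(small_spectra, "SNV+2D")
    manual = savitzky_golay(snv(small_spectra), 15, 3, 2)
    np.testing.assert_allclose(chained.absorbance, manual.absorbance, atol=1e-12)


def test_chain_preserves_record_count_order_and_labels(small_spectra):
    for name in ("1D", "2D", "SG", "MSC+2D"):
        out = ChainTransformer.from_name(name).fit_transform(small_spectra)
        assert out.sample_ids == small_spectra.sample_ids
        assert out.labels == small_spectra.labels
        assert out.absorbance.shape == small_spectra.absorbance.shape


def test_msc_reference_frozen_on_train_no_refit(small_spectra):
    train = small_spectra.select(list(range(0, 24)))  # 8 samples x 3 replicates
    held_out = small_spectra.select(list(range(24, 42)))
    tf = ChainTransformer.from_name("MSC").fit(train)
    ref_before = tf.msc_reference.copy()
    out_held = tf.transform(held_out)
    np.testing.assert_array_equal(tf.msc_reference, ref_before)
    # same operator: transforming a held-out record manually with the frozen
    # reference gives the same result
    manual = msc(held_out, reference=ref_before)
    np.testing.assert_allclose(out_held.absorbance, manual.absorbance, atol=1e-12)


def test_unfitted_msc_chain_refuses_transform(small_spectra):
    tf = ChainTransformer.from_name("MSC+2D")
    with pytest.raises(ParameterError, match="fitted"):
        tf.transform(small_spectra)
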
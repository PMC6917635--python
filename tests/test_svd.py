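"""Truncated-SVD compression: matrix level, model level, persistence."""

import numpy as np
import pytest

from tinyseg.archspec import build_model, count_parameters
from tinyseg.nn import init_params, predict
from tinyseg.svd import (
    CompressedArchive,
    SVDFactors,
    baseline_floats,
    compress_model,
    load_archive,
    load_weights,
    reconstruct,
    reconstruct_model,
    save_archive,
    save_weights,
    storage_report,
    svd_truncate,
)

# --- svd_truncate / reconstruct -----------------------------------------


def test_identity_matrix_full_rank_exact():
    w = np.eye(4)
    factors = svd_truncate(w, 4)
    np.testing.assert_allclose(factors.S_trunc, 1.0)
    np.testing.assert_allclose(reconstruct(factors), w, atol=1e-12)


def test_rank_one_outer_product_exact_at_k1():
    u = np.array([1.0, -2.0, 3.0])
    v = np.array([0.5, 4.0])
    w = np.outer(u, v)
    np.testing.assert_allclose(reconstruct(svd_truncate(w, 1)), w, atol=1e-12)


def test_zero_matrix_round_trips_to_zero():
    w = np.zeros((5, 3))
    np.testing.assert_allclose(reconstruct(svd_truncate(w, 2)), 0.0)


def test_frobenius_error_equals_discarded_spectrum():
    w = np.random.default_rng(0).standard_normal((8, 6))
    sigma = np.linalg.svd(w, compute_uv=False)
    err = np.linalg.norm(w - reconstruct(svd_truncate(w, 4)))
    np.testing.assert_allclose(err, np.sqrt((sigma[4:] ** 2).sum()), rtol=1e-10)


def test_full_rank_round_trip_identity():
    w = np.random.default_rng(1).standard_normal((9, 7))
    w2 = reconstruct(svd_truncate(w, 7))
    assert np.linalg.norm(w - w2) / np.linalg.norm(w) < 1e-6


def test_singular_values_match_eigendecomposition_oracle():
    # sigma_i = sqrt(eigvals of W^T W), on matrices <= 20x20
    rng = np.random.default_rng(2)
    for m, n in ((20, 20), (12, 20), (20, 5), (3, 3)):
        w = rng.standard_normal((m, n))
        k = min(m, n)
        factors = svd_truncate(w, k)
        eig = np.sort(np.linalg.eigvalsh(w.T @ w))[::-1]
        np.testing.assert_allclose(
            factors.S_trunc, np.sqrt(np.clip(eig[:k], 0, None)), atol=1e-8
        )


def test_eckart_young_beats_random_rank_k_probes():
    rng = np.random.default_rng(3)
    w = rng.standard_normal((10, 8))
    k = 3
    best = np.linalg.norm(w - reconstruct(svd_truncate(w, k)))
    for _ in range(50):
        b = rng.standard_normal((10, k)) @ rng.standard_normal((k, 8))
        # scale the probe optimally toward w to make it a fair candidate
        scale = np.tensordot(w, b, 2) / max(np.tensordot(b, b, 2), 1e-12)
        assert best <= np.linalg.norm(w - scale * b) + 1e-9


def test_reconstruction_error_monotone_in_k():
    w = np.random.default_rng(4).standard_normal((12, 9))
    errors = [np.linalg.norm(w - reconstruct(svd_truncate(w, k)))
              for k in range(1, 10)]
    assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))
    assert errors[-1] < 1e-9


def test_truncate_validates_inputs():
    w = np.ones((4, 4))
    with pytest.raises(ValueError, match="rank"):
        svd_truncate(w, 0)
    with pytest.raises(ValueError, match="rank"):
        svd_truncate(w, 5)
    with pytest.raises(ValueError, match="finite"):
        svd_truncate(np.full((3, 3), np.nan), 2)
    with pytest.raises(ValueError):
        svd_truncate(np.ones(4), 1)


def test_sign_convention_is_deterministic():
    w = np.random.default_rng(5).standard_normal((6, 6))
    a, b = svd_truncate(w, 3), svd_truncate(w.copy(), 3)
    np.testing.assert_array_equal(a.U_trunc, b.U_trunc)
    for f in (a, b):
        cols = np.abs(f.U_trunc).argmax(axis=0)
        assert (f.U_trunc[cols, np.arange(f.k)] >= 0).all()


def test_stored_floats_formula_for_random_shapes():
    rng = np.random.default_rng(6)
    for _ in range(10):
        m, n = int(rng.integers(2, 40)), int(rng.integers(2, 40))
        k = int(rng.integers(1, min(m, n) + 1))
        factors = svd_truncate(rng.standard_normal((m, n)), k)
        assert factors.stored_floats == m * k + k + k * n
        saving = 100.0 * (1 - factors.stored_floats / (m * n))
        assert np.isclose(saving, 100.0 * (1 - (m * k + k + k * n) / (m * n)))


# --- model-level policy -------------------------------------------------


@pytest.fixture(scope="module")
def tiny_fcn():
    spec = build_model("fcn", tiny=True, n_classes=3, input_size=32)
    return spec, init_params(spec, rng=0)


def test_block4_pointwise_factored_at_published_sizes(tiny_fcn):
    spec, params = tiny_fcn
    archive = compress_model(params, spec, k=4)
    for name, expected_m in (("enc4_conv2", 512), ("enc4_conv3", 512)):
        entry = archive.entries[name]["pointwise"]
        assert isinstance(entry, SVDFactors)
        assert entry.stored_floats == expected_m * 4 + 4 + 4 * 512 == 4100


def test_first_three_blocks_and_bn_stored_raw(tiny_fcn):
    spec, params = tiny_fcn
    archive = compress_model(params, spec, k=4)
    for lname, arrays in archive.entries.items():
        for key, arr in arrays.items():
            if lname.startswith(("enc1", "enc2", "enc3")) or key in (
                "bias", "depthwise", "gamma", "beta", "moving_mean", "moving_var"
            ):
                assert not isinstance(arr, SVDFactors), (lname, key)


def test_unworthwhile_matrices_fall_back_to_raw(tiny_fcn):
    spec, params = tiny_fcn
    archive = compress_model(params, spec, k=4)
    # score convs map 512->3 etc.; factoring a m x 3 matrix at rank 3
    # stores more floats than the matrix itself
    assert not isinstance(archive.entries["score_pool4"]["kernel"], SVDFactors)
    for lname, arrays in archive.entries.items():
        for key, arr in arrays.items():
            if isinstance(arr, SVDFactors):
                m, n = arr.shape
                assert m * arr.k + arr.k + arr.k * n < m * n


def test_reconstructed_model_keeps_parameter_count(tiny_fcn):
    spec, params = tiny_fcn
    restored = reconstruct_model(compress_model(params, spec, k=4), spec)
    size = sum(a.size for arrs in restored.values() for a in arrs.values())
    assert size == count_parameters(spec).total


def test_compression_idempotent(tiny_fcn):
    spec, params = tiny_fcn
    a1 = compress_model(params, spec, k=4)
    restored = reconstruct_model(a1, spec)
    a2 = compress_model(restored, spec, k=4)
    assert a1.manifest == a2.manifest
    r2 = reconstruct_model(a2, spec)
    for lname in restored:
        for key in restored[lname]:
            np.testing.assert_allclose(
                restored[lname][key], r2[lname][key], atol=1e-4
            )


def test_full_rank_compression_preserves_predictions(tiny_fcn):
    spec, params = tiny_fcn
    archive = compress_model(params, spec, k=10**9)
    restored = reconstruct_model(archive, spec)
    x = np.random.default_rng(7).uniform(0, 1, (32, 32, 3)).astype(np.float32)
    np.testing.assert_allclose(
        predict(spec, params, x), predict(spec, restored, x), atol=1e-5
    )


def test_savings_vs_dense_baseline_exceed_95_percent(tiny_fcn):
    spec, params = tiny_fcn
    archive = compress_model(params, spec, k=4)
    dense = build_model("fcn", tiny=False, n_classes=3, input_size=32)
    assert storage_report(archive, baseline_floats(dense)).savings_percent >= 95.0


def test_uncompressed_archive_saves_nothing(tiny_fcn):
    spec, params = tiny_fcn
    raw = CompressedArchive(entries={
        ln: {k: a for k, a in arrs.items()} for ln, arrs in params.items()
    })
    report = storage_report(raw, count_parameters(spec))
    assert report.savings_percent == 0.0


def test_compress_rejects_mismatched_weights(tiny_fcn):
    spec, params = tiny_fcn
    bad = {ln: dict(arrs) for ln, arrs in params.items()}
    bad["enc4_conv1"] = dict(bad["enc4_conv1"])
    bad["enc4_conv1"]["pointwise"] = np.zeros((8, 8), np.float32)
    with pytest.raises(ValueError, match="enc4_conv1"):
        compress_model(bad, spec, k=4)


# --- persistence --------------------------------------------------------


def test_weights_h5_round_trip(tmp_path, tiny_fcn):
    spec, params = tiny_fcn
    path = tmp_path / "w.h5"
    save_weights(path, params)
    loaded = load_weights(path)
    assert set(loaded) == set(params)
    for lname in params:
        for key in params[lname]:
            np.testing.assert_array_equal(loaded[lname][key], params[lname][key])


def test_archive_h5_round_trip(tmp_path, tiny_fcn):
    spec, params = tiny_fcn
    archive = compress_model(params, spec, k=4)
    path = tmp_path / "a.h5"
    save_archive(path, archive)
    loaded = load_archive(path)
    assert loaded.k_used == archive.k_used
    assert loaded.manifest == archive.manifest
    a, b = reconstruct_model(archive, spec), reconstruct_model(loaded, spec)
    for lname in a:
        for key in a[lname]:
            np.testing.assert_array_equal(a[lname][key], b[lname][key])
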
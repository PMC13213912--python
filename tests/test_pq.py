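import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from pqatlas.pq import (
    ProductQuantizer,
    build_sd_tables,
    load_codes,
    save_codes,
    sd_matrix,
    symmetric_distance,
)
from pqatlas.synthetic import BlobSpec, generate_mqn_blobs

from conftest import sd_bruteforce


class TestCodebookTraining:
    def test_default_geometry_on_42d(self, blobs):
        X, _, _ = blobs
        pq = ProductQuantizer(random_state=0).fit(X)
        assert pq.codebooks_.shape == (6, 256, 7)

    def test_rejects_indivisible_dimension(self):
        X = np.random.default_rng(0).integers(0, 5, (300, 41))
        with pytest.raises(ValueError, match="divisible"):
            ProductQuantizer().fit(X)

    def test_rejects_sample_smaller_than_codewords(self):
        X = np.zeros((10, 42))
        with pytest.raises(ValueError, match="smaller than n_codewords"):
            ProductQuantizer(n_codewords=256).fit(X)

    def test_zero_error_when_values_fit_codebook(self):
        # subvectors take exactly L distinct values -> k-means fixed point
        rng = np.random.default_rng(3)
        L = 4
        atoms = rng.integers(0, 30, (L, 7))
        X = atoms[rng.integers(0, L, 500)]
        X = np.tile(X, 6)[:, :42]
        pq = ProductQuantizer(n_codewords=L, random_state=0).fit(X)
        recon = pq.inverse_transform(pq.transform(X))
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_reconstruction_error_nonincreasing_in_codewords(self, blobs):
        X, _, _ = blobs
        errs = []
        for L in (2, 4, 8):
            pq = ProductQuantizer(n_codewords=L, random_state=0).fit(X)
            recon = pq.inverse_transform(pq.transform(X))
            errs.append(np.linalg.norm(X - recon, axis=1).mean())
        assert errs[0] >= errs[1] >= errs[2]

    def test_deterministic_for_fixed_seed(self, blobs):
        X, _, _ = blobs
        a = ProductQuantizer(n_codewords=16, random_state=9).fit(X)
        b = ProductQuantizer(n_codewords=16, random_state=9).fit(X)
        np.testing.assert_array_equal(a.codebooks_, b.codebooks_)

    def test_training_invariant_to_input_order(self, blobs):
        X, _, _ = blobs
        perm = np.random.default_rng(0).permutation(len(X))
        a = ProductQuantizer(n_codewords=16, random_state=9).fit(X)
        b = ProductQuantizer(n_codewords=16, random_state=9).fit(X[perm])
        np.testing.assert_array_equal(a.codebooks_, b.codebooks_)


class TestEncoding:
    def test_codeword_roundtrip(self, fitted_pq):
        rng = np.random.default_rng(4)
        m, L, d_sub = fitted_pq.codebooks_.shape
        target = rng.integers(0, L, size=m)
        vec = np.concatenate([fitted_pq.codebooks_[j][target[j]] for j in range(m)])
        code = fitted_pq.transform(vec[None, :])[0]
        np.testing.assert_array_equal(code, target)
        np.testing.assert_allclose(fitted_pq.inverse_transform(code[None, :])[0], vec)

    def test_codes_are_bytes_in_range(self, blob_codes, fitted_pq):
        assert blob_codes.dtype == np.uint8
        assert blob_codes.shape[1] == 6
        assert blob_codes.max() < fitted_pq.n_codewords

    def test_matches_bruteforce_scan(self, blobs, fitted_pq):
        """Encoding equals an exhaustive per-subspace nearest-codeword scan."""
        X, _, _ = blobs
        m, L, d_sub = fitted_pq.codebooks_.shape
        codes = fitted_pq.transform(X[:200])
        for i in range(200):
            for j in range(m):
                sub = X[i, j * d_sub : (j + 1) * d_sub]
                dists = np.linalg.norm(fitted_pq.codebooks_[j] - sub, axis=1)
                assert codes[i, j] == np.argmin(dists)

    def test_batched_equals_single_batch(self, blobs):
        X, _, _ = blobs
        pq1 = ProductQuantizer(n_codewords=16, batch_size=10**6, random_state=2).fit(X)
        codes_one = pq1.transform(X)
        pq1.batch_size = 37
        codes_batched = pq1.transform(X)
        np.testing.assert_array_equal(codes_one, codes_batched)

    def test_dimension_mismatch_raises(self, fitted_pq):
        with pytest.raises(ValueError, match="dimensional"):
            fitted_pq.transform(np.zeros((3, 41)))

    def test_decode_out_of_range_raises(self, fitted_pq):
        bad = np.full((1, 6), fitted_pq.n_codewords, dtype=np.int64)
        with pytest.raises(ValueError, match="indices"):
            fitted_pq.inverse_transform(bad)

    def test_decode_then_reencode_is_fixed_point(self, blob_codes, fitted_pq):
        recon = fitted_pq.inverse_transform(blob_codes[:100])
        np.testing.assert_array_equal(fitted_pq.transform(recon), blob_codes[:100])


class TestSymmetricDistance:
    def test_tables_symmetric_zero_diagonal(self, fitted_pq):
        tables = build_sd_tables(fitted_pq)
        for j in range(tables.shape[0]):
            np.testing.assert_allclose(tables[j], tables[j].T)
            np.testing.assert_allclose(np.diag(tables[j]), 0.0)
            assert (tables[j] >= 0).all()

    def test_spot_entries_match_direct_codeword_distance(self, fitted_pq):
        tables = fitted_pq.sd_tables_
        cb = fitted_pq.codebooks_
        rng = np.random.default_rng(0)
        for _ in range(20):
            j = rng.integers(cb.shape[0])
            a, b = rng.integers(cb.shape[1], size=2)
            expected = float(np.sum((cb[j][a] - cb[j][b]) ** 2))
            assert tables[j][a, b] == pytest.approx(expected)

    def test_identity_and_symmetry(self, blob_codes, fitted_pq):
        t = fitted_pq.sd_tables_
        a, b = blob_codes[0], blob_codes[1]
        assert symmetric_distance(a, a, t) == 0.0
        assert symmetric_distance(a, b, t) == pytest.approx(symmetric_distance(b, a, t))

    def test_matches_codeword_oracle(self, blob_codes, fitted_pq):
        t = fitted_pq.sd_tables_
        rng = np.random.default_rng(1)
        for _ in range(50):
            i, j = rng.integers(len(blob_codes), size=2)
            expected = sd_bruteforce(blob_codes[i], blob_codes[j], fitted_pq.codebooks_)
            assert symmetric_distance(blob_codes[i], blob_codes[j], t) == pytest.approx(expected)

    def test_sd_matrix_agrees_with_scalar(self, blob_codes, fitted_pq):
        t = fitted_pq.sd_tables_
        M = sd_matrix(blob_codes[:10], blob_codes[:7], t)
        for i in range(10):
            for j in range(7):
                assert M[i, j] == pytest.approx(
                    symmetric_distance(blob_codes[i], blob_codes[j], t)
                )

    def test_exact_for_codeword_exact_vectors(self, fitted_pq):
        """SD equals true Euclidean distance when quantization error is zero."""
        rng = np.random.default_rng(6)
        m, L, d_sub = fitted_pq.codebooks_.shape
        for _ in range(10):
            ca = rng.integers(0, L, m)
            cb_idx = rng.integers(0, L, m)
            va = np.concatenate([fitted_pq.codebooks_[j][ca[j]] for j in range(m)])
            vb = np.concatenate([fitted_pq.codebooks_[j][cb_idx[j]] for j in range(m)])
            sd = symmetric_distance(ca, cb_idx, fitted_pq.sd_tables_)
            assert sd == pytest.approx(np.linalg.norm(va - vb))

    def test_sd_euclidean_correlation_on_spread_vectors(self):
        """SD tracks true Euclidean distance strongly on well-spread counts."""
        X, _, _ = generate_mqn_blobs(BlobSpec(n=2000, k=12, spread=2.0, seed=8))
        pq = ProductQuantizer(random_state=0, n_codewords=64).fit(X)
        codes = pq.transform(X)
        ref = X[0]
        euclid = np.linalg.norm(X - ref, axis=1)
        sd = sd_matrix(codes, codes[:1], pq.sd_tables_)[:, 0]
        r = pearsonr(euclid[1:], sd[1:])[0]
        assert r >= 0.9


class TestPersistence:
    def test_codebook_roundtrip(self, fitted_pq, tmp_path):
        path = tmp_path / "cb.npz"
        fitted_pq.save(path)
        loaded = ProductQuantizer.load(path)
        np.testing.assert_array_equal(loaded.codebooks_, fitted_pq.codebooks_)
        assert loaded.n_codewords == fitted_pq.n_codewords

    def test_codes_roundtrip(self, blob_codes, fitted_pq, tmp_path):
        path = tmp_path / "codes.bin"
        save_codes(blob_codes, path, fitted_pq)
        loaded, manifest = load_codes(path)
        np.testing.assert_array_equal(loaded, blob_codes)
        assert manifest["m"] == 6
        # compression: 6 one-byte indices stand for 42 counts
        assert path.stat().st_size == blob_codes.shape[0] * 6


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_sd_is_a_premetric_on_random_codes(seed):
    """SD(a,a)=0, symmetry, and non-negativity for arbitrary valid codes."""
    rng = np.random.default_rng(seed)
    cb = rng.normal(size=(3, 8, 2))

    class Stub:
        codebooks_ = cb

    tables = build_sd_tables(Stub())
    a = rng.integers(0, 8, 3)
    b = rng.integers(0, 8, 3)
    assert symmetric_distance(a, a, tables) == 0.0
    ab = symmetric_distance(a, b, tables)
    assert ab >= 0.0
    assert ab == pytest.approx(symmetric_distance(b, a, tables))
    assert ab == pytest.approx(sd_bruteforce(a, b, cb))
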
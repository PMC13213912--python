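"""Product quantization of MQN vectors and the symmetric-distance lookup tables.

A 42-dimensional MQN vector is split into ``m`` contiguous subvectors (6
subvectors of dimension 7 by default). For each subspace a codebook of ``L``
codewords (256 by default) is learned by k-means; a molecule is then encoded
as the m-tuple of nearest-codeword indices — a 6-byte code at the defaults, a
7-fold compression of the 42-entry count vector.

The symmetric distance (SD) between two codes is computed entirely from
precomputed L×L codeword-to-codeword squared-distance tables:

    SD(a, b) = sqrt( Σ_j ‖C_j[a_j] − C_j[b_j]‖² )

The square root keeps SD on the same scale as the Euclidean distance between
the original vectors; for codeword-exact inputs SD equals the true Euclidean
distance exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ProductQuantizer",
    "build_sd_tables",
    "symmetric_distance",
    "sd_matrix",
    "save_codes",
    "load_codes",
]


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Rows of X sorted lexicographically.

    Training on a canonically ordered copy makes the fitted codebook a pure
    function of the training multiset: permuting the input file can never
    change the model.
    """
    return X[np.lexsort(X.T[::-1])]


class ProductQuantizer(BaseEstimator, TransformerMixin):
    """Product-quantization encoder for integer count vectors.

    Parameters
    ----------
    n_subspaces : int, default=6
        Number of contiguous subvectors ``m``; must divide the input
        dimension (42/6 gives subvectors of dimension 7).
    n_codewords : int, default=256
        Codewords per subspace ``L``; at most 256 so each code index fits in
        one unsigned byte.
    n_iter : int, default=20
        k-means iterations for codebook training (k-means++ init, L2).
    batch_size : int, default=100_000
        Encoding batch size; peak memory is bounded by the batch, not by the
        number of vectors encoded.
    random_state : int or None
        Seed for codebook training; fixed seed gives a deterministic model.

    Attributes
    ----------
    codebooks_ : ndarray of shape (m, L, d_sub)
        Learned codewords per subspace.
    sd_tables_ : ndarray of shape (m, L, L)
        Squared Euclidean distances between codewords within each subspace.
    n_features_in_ : int
        Input dimensionality seen at fit.
    """

    def __init__(
        self,
        n_subspaces: int = 6,
        n_codewords: int = 256,
        n_iter: int = 20,
        batch_size: int = 100_000,
        random_state: int | None = None,
    ):
        self.n_subspaces = n_subspaces
        self.n_codewords = n_codewords
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.random_state = random_state

    @property
    def subvector_dim_(self) -> int:
        check_is_fitted(self, "codebooks_")
        return self.codebooks_.shape[2]

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training sample must be a non-empty 2D array")
        n, d = X.shape
        m, L = self.n_subspaces, self.n_codewords
        if L > 256:
            raise ValueError(f"n_codewords must be <= 256 for one-byte codes, got {L}")
        if d % m != 0:
            raise ValueError(f"input dimension {d} is not divisible by n_subspaces={m}")
        if n < L:
            raise ValueError(
                f"training sample of {n} vectors is smaller than n_codewords={L}; "
                f"supply at least {L} vectors or lower n_codewords"
            )
        d_sub = d // m
        Xc = _canonical_order(X)
        codebooks = np.empty((m, L, d_sub), dtype=np.float64)
        base_seed = 0 if self.random_state is None else int(self.random_state)
        for j in range(m):
            sub = Xc[:, j * d_sub : (j + 1) * d_sub]
            km = KMeans(
                n_clusters=L,
                init="k-means++",
                n_init=1,
                max_iter=self.n_iter,
                random_state=(base_seed + j) % (2**31),
            )
            with warnings.catch_warnings():
                # count data often has fewer distinct subvectors than L;
                # duplicate codewords are a benign k-means fixed point
                warnings.simplefilter("ignore", ConvergenceWarning)
                km.fit(sub)
            codebooks[j] = km.cluster_centers_
        self.codebooks_ = codebooks
        self.n_features_in_ = d
        self.sd_tables_ = build_sd_tables(self)
        return self

    def transform(self, X) -> np.ndarray:
        """Encode vectors to PQ codes (uint8 matrix of shape (n, m)).

        Each subvector is assigned to its nearest codeword by Euclidean
        distance; ties resolve to the lowest codeword index. Processing is
        batched so peak memory is independent of ``len(X)``.
        """
        check_is_fitted(self, "codebooks_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_}-dimensional vectors, got {X.shape[1]}"
            )
        m, L, d_sub = self.codebooks_.shape
        codes = np.empty((X.shape[0], m), dtype=np.uint8)
        for start in range(0, X.shape[0], self.batch_size):
            batch = X[start : start + self.batch_size]
            for j in range(m):
                sub = batch[:, j * d_sub : (j + 1) * d_sub]
                # direct squared distances: ties between equidistant codewords
                # must resolve to the lowest index, so avoid the BLAS
                # expansion trick whose rounding can flip exact ties
                d2 = cdist(sub, self.codebooks_[j], metric="sqeuclidean")
                codes[start : start + self.batch_size, j] = np.argmin(d2, axis=1)
        return codes

    def inverse_transform(self, codes) -> np.ndarray:
        """Reconstruct vectors as the concatenation of indexed codewords."""
        check_is_fitted(self, "codebooks_")
        codes = np.asarray(codes)
        if codes.ndim == 1:
            codes = codes[None, :]
        m, L, d_sub = self.codebooks_.shape
        if codes.shape[1] != m:
            raise ValueError(f"codes must have {m} indices per row, got {codes.shape[1]}")
        if codes.min(initial=0) < 0 or codes.max(initial=0) >= L:
            raise ValueError(f"code indices must lie in [0, {L - 1}]")
        out = np.empty((codes.shape[0], m * d_sub), dtype=np.float64)
        for j in range(m):
            out[:, j * d_sub : (j + 1) * d_sub] = self.codebooks_[j][codes[:, j]]
        return out

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the codebook as a portable ``.npz`` array file."""
        check_is_fitted(self, "codebooks_")
        np.savez(
            Path(path),
            codebooks=self.codebooks_,
            params=np.array(
                [self.n_subspaces, self.n_codewords, self.n_iter, self.batch_size], dtype=np.int64
            ),
            random_state=np.array([-1 if self.random_state is None else self.random_state]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProductQuantizer":
        data = np.load(Path(path))
        m, L, n_iter, batch_size = (int(v) for v in data["params"])
        seed = int(data["random_state"][0])
        pq = cls(
            n_subspaces=m,
            n_codewords=L,
            n_iter=n_iter,
            batch_size=batch_size,
            random_state=None if seed < 0 else seed,
        )
        pq.codebooks_ = data["codebooks"]
        pq.n_features_in_ = pq.codebooks_.shape[0] * pq.codebooks_.shape[2]
        pq.sd_tables_ = build_sd_tables(pq)
        return pq


def build_sd_tables(quantizer) -> np.ndarray:
    """Precompute the per-subspace L×L squared codeword-distance tables.

    Accepts any object exposing trained ``codebooks_`` of shape (m, L, d_sub).
    """
    cb = getattr(quantizer, "codebooks_", None)
    if cb is None:
        raise ValueError("quantizer has no trained codebooks_; call fit first")
    m, L, _ = cb.shape
    tables = np.empty((m, L, L), dtype=np.float64)
    for j in range(m):
        diff = cb[j][:, None, :] - cb[j][None, :, :]
        tables[j] = np.einsum("abk,abk->ab", diff, diff)
        np.fill_diagonal(tables[j], 0.0)
    return np.maximum(tables, 0.0)


def symmetric_distance(a, b, tables: np.ndarray) -> float:
    """SD between two PQ codes via table lookups (same units as Euclidean)."""
    a = np.asarray(a)
    b = np.asarray(b)
    m = tables.shape[0]
    if a.shape[-1] != m or b.shape[-1] != m:
        raise ValueError("codes do not match the distance tables' subspace count")
    sq = sum(tables[j, a[..., j], b[..., j]] for j in range(m))
    return float(np.sqrt(sq))


def sd_matrix(codes_a: np.ndarray, codes_b: np.ndarray, tables: np.ndarray) -> np.ndarray:
    """All-pairs SD between two code sets; shape (len(a), len(b))."""
    codes_a = np.asarray(codes_a)
    codes_b = np.asarray(codes_b)
    m = tables.shape[0]
    if codes_a.shape[1] != m or codes_b.shape[1] != m:
        raise ValueError("codes do not match the distance tables' subspace count")
    sq = np.zeros((codes_a.shape[0], codes_b.shape[0]), dtype=np.float64)
    for j in range(m):
        sq += tables[j][codes_a[:, j][:, None], codes_b[:, j][None, :]]
    return np.sqrt(np.maximum(sq, 0.0))


def save_codes(codes: np.ndarray, path: str | Path, quantizer: ProductQuantizer) -> None:
    """Persist codes as a flat binary shard (m bytes/molecule) + JSON manifest."""
    path = Path(path)
    codes = np.ascontiguousarray(codes, dtype=np.uint8)
    codes.tofile(path)
    manifest = {
        "m": int(quantizer.n_subspaces),
        "L": int(quantizer.n_codewords),
        "d_sub": int(quantizer.subvector_dim_),
        "seed": quantizer.random_state,
        "count": int(codes.shape[0]),
        "dtype": "uint8",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def load_codes(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    codes = np.fromfile(path, dtype=np.uint8).reshape(manifest["count"], manifest["m"])
    return codes, manifest
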
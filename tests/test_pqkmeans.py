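import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pqatlas.pq import ProductQuantizer, sd_matrix
from pqatlas.pqkmeans import (
    Assignment,
    PQKMeans,
    compact,
    select_representatives,
    update_centroids,
)


def brute_force_labels(codes, centroids, tables):
    """Independent assignment oracle: full SD matrix, argmin per row."""
    return np.argmin(sd_matrix(codes, centroids, tables), axis=1)


def brute_force_centroid(member_codes, tables):
    """Independent update oracle: scan all L codewords per subspace."""
    m, L, _ = tables.shape
    out = np.empty(m, dtype=np.uint8)
    for j in range(m):
        costs = [tables[j][member_codes[:, j], w].sum() for w in range(L)]
        out[j] = int(np.argmin(costs))
    return out


class TestFit:
    def test_recovers_separated_blobs(self, blobs, fitted_pq, blob_codes):
        _, labels, _ = blobs
        model = PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=0)
        model.fit(blob_codes)
        assert adjusted_rand_score(labels, model.labels_) == 1.0

    def test_objective_nonincreasing(self, blob_codes, fitted_pq):
        model = PQKMeans(n_clusters=7, tables=fitted_pq.sd_tables_, random_state=1)
        model.fit(blob_codes)
        hist = np.asarray(model.objective_history_)
        assert (np.diff(hist) <= 1e-9).all()

    def test_k_equals_n_distinct_codes_reaches_zero(self, fitted_pq):
        rng = np.random.default_rng(2)
        codes = np.unique(rng.integers(0, 32, (40, 6)).astype(np.uint8), axis=0)
        model = PQKMeans(n_clusters=len(codes), tables=fitted_pq.sd_tables_, random_state=0)
        model.fit(codes)
        assert model.inertia_ == pytest.approx(0.0)

    def test_n_smaller_than_k_raises(self, blob_codes, fitted_pq):
        with pytest.raises(ValueError, match="n_clusters"):
            PQKMeans(n_clusters=10**6, tables=fitted_pq.sd_tables_).fit(blob_codes)

    def test_deterministic_and_order_invariant(self, blob_codes, fitted_pq):
        a = PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=3).fit(blob_codes)
        perm = np.random.default_rng(0).permutation(len(blob_codes))
        b = PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=3).fit(
            blob_codes[perm]
        )
        np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)
        np.testing.assert_array_equal(a.labels_[perm], b.labels_)

    def test_subspace_count_mismatch_raises(self, blob_codes, fitted_pq):
        with pytest.raises(ValueError, match="subspace"):
            PQKMeans(n_clusters=3, tables=fitted_pq.sd_tables_[:4]).fit(blob_codes)


class TestUpdateCentroids:
    def test_single_member_cluster_keeps_its_code(self, blob_codes, fitted_pq):
        codes = blob_codes[:3]
        labels = np.array([0, 1, 2])
        new, populated = update_centroids(
            codes, labels, fitted_pq.sd_tables_, 3, codes.copy()
        )
        np.testing.assert_array_equal(new, codes)
        assert populated.all()

    def test_identical_codes_give_that_code(self, blob_codes, fitted_pq):
        codes = np.repeat(blob_codes[:1], 10, axis=0)
        labels = np.zeros(10, dtype=np.int64)
        new, _ = update_centroids(codes, labels, fitted_pq.sd_tables_, 1, codes[:1].copy())
        np.testing.assert_array_equal(new[0], codes[0])

    def test_empty_cluster_unchanged_and_flagged(self, blob_codes, fitted_pq):
        codes = blob_codes[:5]
        labels = np.zeros(5, dtype=np.int64)  # cluster 1 empty
        current = blob_codes[10:12].copy()
        new, populated = update_centroids(codes, labels, fitted_pq.sd_tables_, 2, current)
        np.testing.assert_array_equal(new[1], current[1])
        assert populated[0] and not populated[1]

    def test_matches_bruteforce_scan(self, blob_codes, fitted_pq):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, len(blob_codes))
        current = blob_codes[:4].copy()
        new, _ = update_centroids(blob_codes, labels, fitted_pq.sd_tables_, 4, current)
        for c in range(4):
            members = blob_codes[labels == c]
            np.testing.assert_array_equal(new[c], brute_force_centroid(members, fitted_pq.sd_tables_))


@pytest.fixture(scope="module")
def model(blob_codes, fitted_pq):
    return PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=0).fit(blob_codes)


class TestAssign:
    def test_centroid_code_assigned_to_itself(self, model):
        assignment = model.predict(model.cluster_centers_)
        np.testing.assert_array_equal(assignment.labels, np.arange(5))
        np.testing.assert_allclose(assignment.distances, 0.0)

    def test_streaming_batches_bit_identical(self, model, blob_codes):
        full = model.predict(blob_codes, batch_size=10**6)
        batched = model.predict(blob_codes, batch_size=17)
        np.testing.assert_array_equal(full.labels, batched.labels)
        np.testing.assert_array_equal(full.distances, batched.distances)

    def test_matches_bruteforce_oracle(self, model, blob_codes, fitted_pq):
        assignment = model.predict(blob_codes)
        expected = brute_force_labels(blob_codes, model.cluster_centers_, fitted_pq.sd_tables_)
        np.testing.assert_array_equal(assignment.labels, expected)

    def test_conservation(self, model, blob_codes):
        assignment = model.predict(blob_codes)
        sizes = np.bincount(assignment.labels, minlength=5)
        assert sizes.sum() == len(blob_codes)
        assert (assignment.labels >= 0).all() and (assignment.labels < 5).all()
        assert (assignment.distances >= 0).all()


class TestCompact:
    def test_identity_when_all_populated(self, blob_codes, fitted_pq):
        model = PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=0).fit(blob_codes)
        assignment = model.predict(blob_codes)
        new_model, new_assignment, mapping = compact(model, assignment)
        assert new_model.n_clusters == 5
        np.testing.assert_array_equal(mapping, np.arange(5))
        np.testing.assert_array_equal(new_assignment.labels, assignment.labels)

    def test_drops_empty_and_reindexes(self, fitted_pq):
        model = PQKMeans(n_clusters=3, tables=fitted_pq.sd_tables_)
        model.cluster_centers_ = np.array([[0] * 6, [5] * 6, [9] * 6], dtype=np.uint8)
        model.populated_ = np.array([True, False, True])
        assignment = Assignment(
            labels=np.array([0, 2, 0, 2]), distances=np.zeros(4)
        )
        new_model, new_assignment, mapping = compact(model, assignment)
        assert new_model.n_clusters == 2
        assert set(new_assignment.labels) == {0, 1}
        assert len(new_assignment.labels) == 4  # molecule count conserved
        np.testing.assert_array_equal(mapping, [0, -1, 1])


class TestRepresentatives:
    def test_matches_argmin_oracle_and_dominates_members(self, blob_codes, fitted_pq):
        model = PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=0).fit(blob_codes)
        assignment = model.predict(blob_codes)
        model, assignment, _ = compact(model, assignment)
        reps = select_representatives(blob_codes, assignment, model, fitted_pq.sd_tables_)
        assert len(reps) == model.n_clusters
        D = sd_matrix(blob_codes, model.cluster_centers_, fitted_pq.sd_tables_)
        for cid, row in reps.iterrows():
            members = np.flatnonzero(assignment.labels == cid)
            sds = D[members, cid]
            assert row["sd"] == pytest.approx(sds.min())
            # lowest-id tie-break against a brute-force scan
            best = members[sds == sds.min()].min()
            assert row["molecule_id"] == best
            assert (row["sd"] <= sds + 1e-12).all()

    def test_singleton_cluster_is_its_own_representative(self, fitted_pq):
        codes = np.array([[0] * 6, [1] * 6, [30] * 6], dtype=np.uint8)
        model = PQKMeans(n_clusters=2, tables=fitted_pq.sd_tables_, random_state=0)
        model.cluster_centers_ = np.array([[0] * 6, [30] * 6], dtype=np.uint8)
        assignment = model.predict(codes)
        reps = select_representatives(codes, assignment, model, fitted_pq.sd_tables_)
        assert reps.loc[1, "molecule_id"] == 2

    def test_member_equal_to_centroid_selected(self, blob_codes, fitted_pq):
        model = PQKMeans(n_clusters=5, tables=fitted_pq.sd_tables_, random_state=0).fit(blob_codes)
        assignment = model.predict(blob_codes)
        model, assignment, _ = compact(model, assignment)
        reps = select_representatives(blob_codes, assignment, model, fitted_pq.sd_tables_)
        for cid, row in reps.iterrows():
            match = np.flatnonzero(
                (blob_codes == model.cluster_centers_[cid]).all(axis=1)
                & (assignment.labels == cid)
            )
            if match.size:
                assert row["sd"] == pytest.approx(0.0)
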
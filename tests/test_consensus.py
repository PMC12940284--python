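"""Unit tests for consensus clustering, validation and stability."""

import numpy as np
import pytest

from cnasig import (
    assess_stability,
    cluster_pool,
    consensus_diagnostics,
    cosine_matrix,
    derive_consensus,
    select_partition,
    simulate_cohort,
    validate_cluster,
)
from cnasig.consensus import pool_signatures
from cnasig.extraction import SignatureSet, _l1_normalize


def _sigset(method, rows, exposures=None):
    rows = _l1_normalize(np.atleast_2d(np.asarray(rows, dtype=float)))
    return SignatureSet(
        method=method,
        signatures=rows,
        labels=[f"{method}{i}" for i in range(rows.shape[0])],
        exposures=exposures,
    )


def _pad(v, m=28):
    out = np.zeros(m)
    out[: len(v)] = v
    return out


class TestCosineMatrix:
    def test_closed_forms(self):
        a = _pad([1, 1, 0]) / 2
        b = _pad([1, 0, 1]) / 2
        pool = [_sigset("NMF", [a, a]), _sigset("ICA", [b])]
        sim = cosine_matrix(pool)
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 2] == pytest.approx(0.5)
        assert np.all(np.diag(sim) == 1.0)
        assert np.all((sim >= 0) & (sim <= 1))

    def test_disjoint_support_orthogonal(self):
        sim = cosine_matrix(np.array([_pad([1, 0]), _pad([0, 1])]))
        assert sim[0, 1] == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_matrix(np.array([_pad([1.0]), np.zeros(28)]))


class TestClusterPool:
    def _two_groups(self, rng, n_per=4, eps=0.01):
        base1, base2 = rng.dirichlet(np.ones(28)), rng.dirichlet(np.ones(28))
        rows = []
        for base in (base1, base2):
            for _ in range(n_per):
                rows.append(_l1_normalize((base + eps * rng.random(28))[None])[0])
        return np.vstack(rows)

    def test_two_tight_groups_separate_exactly(self, rng):
        M = self._two_groups(rng)
        labels = cluster_pool(cosine_matrix(M), 2)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_singletons_at_n_equals_pool(self, rng):
        M = self._two_groups(rng)
        labels = cluster_pool(cosine_matrix(M), len(M))
        assert len(set(labels)) == len(M)

    def test_permutation_invariance(self, rng):
        M = self._two_groups(rng)
        perm = rng.permutation(len(M))
        l1 = cluster_pool(cosine_matrix(M), 2)
        l2 = cluster_pool(cosine_matrix(M[perm]), 2)
        # same partition up to relabeling: co-membership matrices agree
        co1 = l1[:, None] == l1[None, :]
        co2 = l2[:, None] == l2[None, :]
        np.testing.assert_array_equal(co1[np.ix_(perm, perm)], co2)

    def test_out_of_range(self, rng):
        M = self._two_groups(rng)
        with pytest.raises(ValueError):
            cluster_pool(cosine_matrix(M), 1)


class TestValidateCluster:
    COUNTS = {"NMF": 8, "ICA": 4, "GD": 4, "HDP": 3}

    def test_cross_method(self):
        ok, crit = validate_cluster(["NMF", "ICA"], self.COUNTS)
        assert ok and crit == "cross_method"

    def test_concentration(self):
        ok, crit = validate_cluster(["GD", "GD", "GD"], self.COUNTS)
        assert ok and crit in ("concentration", "proportional")

    def test_invalid_singleton(self):
        ok, crit = validate_cluster(["NMF"], self.COUNTS)
        assert not ok and crit is None

    def test_proportional(self):
        ok, crit = validate_cluster(["HDP"], self.COUNTS)  # 1/3 = 33% >= 26%
        assert ok and crit == "proportional"


class TestSelectPartition:
    def _random_pool(self, rng, seed_groups=5):
        rows, methods = [], []
        for g in range(seed_groups):
            base = rng.dirichlet(np.ones(28) * 0.3)
            for j, method in enumerate(["NMF", "ICA", "GD", "HDP"][: 2 + g % 3]):
                rows.append(_l1_normalize((base + 0.02 * rng.random(28))[None])[0])
                methods.append(method)
        return np.vstack(rows), methods

    def test_matches_brute_force_oracle(self, rng):
        M, methods = self._random_pool(rng)
        sim = cosine_matrix(M)
        n, membership, scores = select_partition(sim, methods, n_range=(4, 10))
        # independent re-derivation: recluster per n and recount valid
        counts = {m: methods.count(m) for m in set(methods)}
        best_n, best_frac = None, -1.0
        for cand in range(4, min(10, len(M)) + 1):
            mem = cluster_pool(sim, cand)
            n_valid = sum(
                validate_cluster(
                    [methods[i] for i in np.where(mem == cid)[0]], counts
                )[0]
                for cid in np.unique(mem)
            )
            frac = n_valid / cand
            assert scores[cand] == pytest.approx(frac)
            if frac > best_frac:
                best_n, best_frac = cand, frac
        assert n == best_n

    def test_all_valid_ties_to_smallest(self, rng):
        # 6 tight cross-method pairs: every partition in range is all-valid
        rows, methods = [], []
        for g in range(6):
            base = rng.dirichlet(np.ones(28) * 0.3)
            for method in ("NMF", "ICA"):
                rows.append(_l1_normalize((base + 0.01 * rng.random(28))[None])[0])
                methods.append(method)
        sim = cosine_matrix(np.vstack(rows))
        n, _, scores = select_partition(sim, methods, n_range=(4, 6))
        assert scores[4] == 1.0 and n == 4
        assert all(0 <= v <= 1 for v in scores.values())

    def test_pool_too_small(self):
        sim = np.eye(3)
        with pytest.raises(ValueError):
            select_partition(sim, ["NMF"] * 3, n_range=(4, 15))


class TestDeriveConsensus:
    def test_median_of_duplicates_unchanged(self, rng):
        v = rng.dirichlet(np.ones(28))
        pool = [_sigset("NMF", [v]), _sigset("ICA", [v])]
        membership = np.array([1, 1])
        sigs, valid, _ = derive_consensus(membership, pool)
        np.testing.assert_allclose(sigs.signatures[0], v, atol=1e-12)
        assert valid == {1: True}

    def test_median_matches_sort_middle_oracle(self, rng):
        V = rng.dirichlet(np.ones(28), size=3)
        pool = [_sigset("NMF", V[:2]), _sigset("ICA", V[2:])]
        sigs, _, _ = derive_consensus(np.array([1, 1, 1]), pool)
        oracle = np.array([sorted(V[:, j])[1] for j in range(28)])
        np.testing.assert_allclose(sigs.signatures[0], oracle / oracle.sum(),
                                   atol=1e-12)

    def test_median_of_two_is_mean(self, rng):
        a, b = rng.dirichlet(np.ones(28)), rng.dirichlet(np.ones(28))
        pool = [_sigset("NMF", [a]), _sigset("ICA", [b])]
        sigs, _, _ = derive_consensus(np.array([1, 1]), pool)
        mean = (a + b) / 2
        np.testing.assert_allclose(sigs.signatures[0], mean / mean.sum(), atol=1e-12)

    def test_median_within_member_bounds(self, rng):
        V = rng.dirichlet(np.ones(28), size=5)
        pool = [_sigset("NMF", V[:3]), _sigset("ICA", V[3:])]
        sigs, _, _ = derive_consensus(np.ones(5, dtype=int), pool)
        med = np.median(V, axis=0)  # pre-normalization consensus
        assert np.all(med >= V.min(axis=0) - 1e-12)
        assert np.all(med <= V.max(axis=0) + 1e-12)

    def test_invalid_clusters_contribute_nothing(self, rng):
        V = rng.dirichlet(np.ones(28), size=3)
        pool = [_sigset("NMF", V)]  # 3 NMF sigs
        # cluster 1 = 2 sigs (67% of NMF -> valid), cluster 2 = singleton
        # (33% >= 26% -> also valid); use 8 NMF sigs to make singleton invalid
        V8 = rng.dirichlet(np.ones(28), size=8)
        pool = [_sigset("NMF", V8)]
        membership = np.array([1, 1, 1, 2, 2, 2, 2, 3])
        sigs, valid, _ = derive_consensus(membership, pool)
        assert valid[3] is False
        assert sigs.k == 2

    def test_no_valid_cluster_errors(self, rng):
        V = rng.dirichlet(np.ones(28), size=8)
        pool = [_sigset("NMF", V)]
        with pytest.raises(ValueError, match="validation"):
            derive_consensus(np.arange(1, 9), pool)

    def test_permutation_invariant_consensus(self, reference_pool, cohort300):
        from cnasig.consensus import build_consensus

        pool, _ = reference_pool
        m1 = build_consensus(cohort300.features, pool)
        m2 = build_consensus(cohort300.features, list(reversed(pool)))
        s1 = m1.consensus_signatures.signatures
        s2 = m2.consensus_signatures.signatures
        # same set of consensus vectors regardless of pool order
        from cnasig.extraction import _matched_cosines

        assert np.all(_matched_cosines(s1, s2) > 1 - 1e-9)


class TestDiagnostics:
    def test_perfect_groups_silhouette_near_one(self, rng):
        base1, base2 = rng.dirichlet(np.ones(28)), rng.dirichlet(np.ones(28))
        rows = [base1] * 3 + [base2] * 3
        pool = [_sigset("NMF", rows[:3]), _sigset("ICA", rows[3:])]
        M, methods, _, _ = pool_signatures(pool)
        sim = cosine_matrix(M)
        membership = cluster_pool(sim, 2)
        sigs, _, _ = derive_consensus(membership, pool)
        d = consensus_diagnostics(sim, membership, None, sigs, methods)
        assert d["silhouette"] == pytest.approx(1.0, abs=1e-6)
        assert -1 <= d["cophenetic"] <= 1

    def test_zero_noise_reconstruction_near_zero(self, cohort300_zero_noise):
        c = cohort300_zero_noise
        truth = c.true_signatures
        sim = cosine_matrix(truth.signatures)
        membership = np.arange(1, truth.k + 1)
        d = consensus_diagnostics(sim, membership, c.features, truth)
        assert d["nnls_reconstruction_error"] < 1e-6

    def test_singleton_partition_silhouette_missing(self, rng):
        M = np.vstack([rng.dirichlet(np.ones(28)) for _ in range(4)])
        sim = cosine_matrix(M)
        d = consensus_diagnostics(sim, np.arange(1, 5), None,
                                  _sigset("NMF", M), ["NMF"] * 4)
        assert d["silhouette"] is None


class TestStability:
    def test_zero_bootstrap_rejected(self, cohort300):
        with pytest.raises(ValueError):
            assess_stability(cohort300.features, n_bootstrap=0)

    def test_too_few_samples_rejected(self):
        c = simulate_cohort(n_samples=10, k=2, noise_level=0.0, seed=0)
        with pytest.raises(ValueError):
            assess_stability(c.features, n_bootstrap=2)

    def test_strong_structure_high_stability(self):
        # small zero-noise cohort, light config, few iterations
        c = simulate_cohort(n_samples=100, k=3, noise_level=0.0, seed=13)
        cfg = {"backends": ("NMF", "GD"), "k_range": (2, 4), "n_restarts": 5}
        rep = assess_stability(
            c.features, config=cfg, n_bootstrap=5, fraction=0.8, seed=13
        )
        assert rep.n_bootstrap == 5
        assert all(
            -1 <= v <= 1
            for v in rep.per_signature_correlation.values()
            if np.isfinite(v)
        )
        assert rep.mean_stability >= 0.95
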
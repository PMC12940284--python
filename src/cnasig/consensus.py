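"""Consensus clustering of pooled method-level signatures.

Signatures extracted by the four backends are pooled, pairwise cosine
similarities computed, and the pool grouped by Ward hierarchical clustering
on ``1 - cosine``.  The number of clusters is chosen adaptively over a
configured range (default 4-15) to maximize the fraction of clusters passing
a multi-criteria validity test; valid clusters are collapsed to consensus
signatures as the elementwise median of their members, L1-renormalized.
Stability is quantified by bootstrap subsampling of samples, and cluster
quality by silhouette, cophenetic correlation, and NNLS reconstruction
error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_score

from .cnv_features import FeatureMatrix
from .extraction import (
    ExtractionDiagnostics,
    SignatureSet,
    _cosine_sim,
    _l1_normalize,
    _refit_exposures,
    match_signatures,
    run_all_methods,
)

logger = logging.getLogger("cnasig")

__all__ = [
    "ConsensusModel",
    "StabilityReport",
    "pool_signatures",
    "cosine_matrix",
    "cluster_pool",
    "validate_cluster",
    "select_partition",
    "derive_consensus",
    "consensus_diagnostics",
    "build_consensus",
    "assess_stability",
]


@dataclass
class ConsensusModel:
    consensus_signatures: SignatureSet
    membership: np.ndarray  # cluster id per pooled signature
    valid_flags: dict[int, bool]
    criteria: dict[int, str | None]
    chosen_n_clusters: int
    diagnostics: dict
    pool_methods: list[str] = field(default_factory=list)
    pool_labels: list[str] = field(default_factory=list)


@dataclass
class StabilityReport:
    n_bootstrap: int
    subsample_fraction: float
    per_signature_correlation: dict[str, float]
    mean_stability: float
    n_failed: int = 0


def pool_signatures(
    pool: list[SignatureSet],
) -> tuple[np.ndarray, list[str], list[str], list[float]]:
    """Stack pooled signature sets into one matrix with provenance.

    Returns (k_total x 28 matrix, method per row, label per row,
    total-exposure share per row; NaN where exposures are unavailable).
    """
    mats, methods, labels, shares = [], [], [], []
    for s in pool:
        mats.append(s.signatures)
        methods.extend([s.method] * s.k)
        labels.extend(s.labels)
        if s.exposures is not None:
            shares.extend(np.asarray(s.exposures).sum(axis=0).tolist())
        else:
            shares.extend([np.nan] * s.k)
    return np.vstack(mats), methods, labels, shares


def cosine_matrix(pool: list[SignatureSet] | np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity across all pooled signatures."""
    if isinstance(pool, np.ndarray):
        M = pool
    else:
        if sum(s.k for s in pool) < 2:
            raise ValueError("need at least 2 signatures in the pool")
        M, _, _, _ = pool_signatures(pool)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 signatures in the pool")
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector in signature pool")
    sim = _cosine_sim(M, M)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _ward_linkage(similarity: np.ndarray) -> np.ndarray:
    dist = 1.0 - similarity
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    return linkage(squareform(dist, checks=False), method="ward")


def cluster_pool(similarity: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward agglomeration on ``1 - cosine``; returns 1-based cluster ids."""
    n = similarity.shape[0]
    if not 2 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [2, {n}], got {n_clusters}")
    Z = _ward_linkage(similarity)
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def validate_cluster(
    member_methods: list[str], pool_method_counts: dict[str, int],
    min_fraction: float = 0.26, min_concentration: int = 3,
) -> tuple[bool, str | None]:
    """Multi-criteria cluster validity: at least one condition must hold.

    (1) cross-method diversity: members span >= 2 distinct methods;
    (2) proportional representation: the cluster contains >= 26% of one
        method's pooled signatures;
    (3) method concentration: >= 3 members from a single method.
    """
    if not member_methods:
        raise ValueError("cluster is empty")
    counts: dict[str, int] = {}
    for m in member_methods:
        counts[m] = counts.get(m, 0) + 1
    if len(counts) >= 2:
        return True, "cross_method"
    for m, c in counts.items():
        total = pool_method_counts.get(m, 0)
        if total > 0 and c / total >= min_fraction:
            return True, "proportional"
    if any(c >= min_concentration for c in counts.values()):
        return True, "concentration"
    return False, None


def select_partition(
    similarity: np.ndarray,
    methods: list[str],
    n_range: tuple[int, int] = (4, 15),
) -> tuple[int, np.ndarray, dict[int, float]]:
    """Choose the cluster number maximizing the fraction of valid clusters.

    Candidates run over ``n_range`` clipped to the pool size; ties break
    toward smaller n.  Returns (n_clusters, membership, fraction-valid per
    candidate n).
    """
    n_pool = similarity.shape[0]
    lo, hi = int(n_range[0]), int(n_range[1])
    if n_pool < lo:
        raise ValueError(
            f"pool of {n_pool} signatures smaller than cluster-range minimum {lo}"
        )
    pool_counts: dict[str, int] = {}
    for m in methods:
        pool_counts[m] = pool_counts.get(m, 0) + 1

    scores: dict[int, float] = {}
    best_n, best_frac, best_membership = None, -1.0, None
    for n in range(lo, min(hi, n_pool) + 1):
        membership = cluster_pool(similarity, n)
        n_valid = 0
        for cid in np.unique(membership):
            mm = [methods[i] for i in np.where(membership == cid)[0]]
            ok, _ = validate_cluster(mm, pool_counts)
            n_valid += ok
        frac = n_valid / n
        scores[n] = frac
        if frac > best_frac:  # strict: ties toward smaller n
            best_n, best_frac, best_membership = n, frac, membership
        logger.debug("partition n=%d valid fraction=%.3f", n, frac)
    return int(best_n), best_membership, scores


def derive_consensus(
    membership: np.ndarray,
    pool: list[SignatureSet],
) -> tuple[SignatureSet, dict[int, bool], dict[int, str | None]]:
    """Median-aggregate valid clusters into consensus signatures.

    Per valid cluster, the consensus is the elementwise (unweighted) median
    of the member signature vectors, L1-renormalized.  Output signatures are
    labeled CON1..CONm ordered by descending total pooled-exposure share
    where exposures are available, else by cluster size.
    """
    M, methods, _, shares = pool_signatures(pool)
    pool_counts: dict[str, int] = {}
    for m in methods:
        pool_counts[m] = pool_counts.get(m, 0) + 1

    valid_flags: dict[int, bool] = {}
    criteria: dict[int, str | None] = {}
    rows, orders = [], []
    for cid in np.unique(membership):
        idx = np.where(membership == cid)[0]
        mm = [methods[i] for i in idx]
        ok, crit = validate_cluster(mm, pool_counts)
        valid_flags[int(cid)] = bool(ok)
        criteria[int(cid)] = crit
        if not ok:
            continue
        med = np.median(M[idx], axis=0)
        rows.append(_l1_normalize(med[None, :])[0])
        share = np.nansum([shares[i] for i in idx])
        key = share if np.isfinite(share) and share > 0 else float(len(idx))
        orders.append((key, int(cid)))
    if not rows:
        raise ValueError(
            "no cluster passed validation; review the cluster range and "
            "backend configuration"
        )
    order = np.argsort([-o[0] for o in orders], kind="stable")
    sigs = SignatureSet(
        method="CONSENSUS",
        signatures=np.vstack([rows[i] for i in order]),
        labels=[f"CON{j+1}" for j in range(len(order))],
    )
    return sigs, valid_flags, criteria


def consensus_diagnostics(
    similarity: np.ndarray,
    membership: np.ndarray,
    X: FeatureMatrix | np.ndarray | None,
    consensus: SignatureSet,
    methods: list[str] | None = None,
) -> dict:
    """Cluster-quality and reconstruction diagnostics.

    Mean silhouette width on ``1 - cosine``; cophenetic correlation between
    dendrogram and observed distances; relative NNLS reconstruction error of
    X against the consensus signatures; mean distinct methods per cluster.
    Silhouette is reported as None when undefined (singleton-only partition).
    """
    dist = 1.0 - similarity
    np.fill_diagonal(dist, 0.0)
    n_clusters = len(np.unique(membership))
    sizes = np.bincount(membership)[1:]
    if 2 <= n_clusters <= len(membership) - 1 and np.any(sizes > 1):
        sil = float(silhouette_score(dist, membership, metric="precomputed"))
    else:
        sil = None
    Z = _ward_linkage(similarity)
    coph, _ = cophenet(Z, squareform(np.maximum(dist, 0.0), checks=False))
    coph = float(coph)

    recon = None
    if X is not None:
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        E = _refit_exposures(Xv, consensus.signatures)
        recon = float(
            np.linalg.norm(Xv - E @ consensus.signatures)
            / (np.linalg.norm(Xv) + 1e-12)
        )

    mean_methods = None
    if methods is not None:
        per = [
            len({methods[i] for i in np.where(membership == cid)[0]})
            for cid in np.unique(membership)
        ]
        mean_methods = float(np.mean(per))
    return {
        "silhouette": sil,
        "cophenetic": coph,
        "nnls_reconstruction_error": recon,
        "mean_methods_per_cluster": mean_methods,
        "n_clusters": int(n_clusters),
    }


def build_consensus(
    X: FeatureMatrix | np.ndarray,
    pool: list[SignatureSet],
    n_range: tuple[int, int] = (4, 15),
) -> ConsensusModel:
    """Full consensus stage: similarity -> partition -> median signatures."""
    M, methods, labels, _ = pool_signatures(pool)
    sim = cosine_matrix(M)
    n_clusters, membership, scores = select_partition(sim, methods, n_range)
    sigs, valid_flags, criteria = derive_consensus(membership, pool)
    diags = consensus_diagnostics(sim, membership, X, sigs, methods)
    diags["valid_fraction_per_n"] = {int(k): v for k, v in scores.items()}
    logger.info(
        "consensus: %d clusters, %d valid, %d consensus signatures",
        n_clusters, sum(valid_flags.values()), sigs.k,
    )
    return ConsensusModel(
        consensus_signatures=sigs,
        membership=membership,
        valid_flags=valid_flags,
        criteria=criteria,
        chosen_n_clusters=n_clusters,
        diagnostics=diags,
        pool_methods=methods,
        pool_labels=labels,
    )


def assess_stability(
    X: FeatureMatrix | np.ndarray,
    config: dict | None = None,
    n_bootstrap: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    n_range: tuple[int, int] = (4, 15),
    reference: ConsensusModel | None = None,
) -> StabilityReport:
    """Bootstrap stability of the consensus signatures.

    Per iteration, ``ceil(fraction * n)`` samples are subsampled without
    replacement, the full extraction + consensus pipeline is rerun, and each
    resampled consensus signature is matched to the original by
    maximal-cosine (Hungarian) assignment; the Pearson correlation of each
    matched pair is recorded.  Failed iterations are recorded as missing;
    more than 50% failures is an error.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if Xv.shape[0] < 25:
        raise ValueError("need at least 25 samples for stability assessment")
    if reference is None:
        pool, _ = run_all_methods(Xv, config=config, seed=seed)
        reference = build_consensus(Xv, pool, n_range=n_range)
    ref = reference.consensus_signatures
    n_sub = int(np.ceil(fraction * Xv.shape[0]))

    per_sig: dict[str, list[float]] = {lab: [] for lab in ref.labels}
    n_failed = 0
    rng = np.random.default_rng([seed, 811])
    for b in range(n_bootstrap):
        idx = rng.choice(Xv.shape[0], size=n_sub, replace=False)
        try:
            pool_b, _ = run_all_methods(
                Xv[idx], config=config, seed=int(rng.integers(2**31 - 1))
            )
            model_b = build_consensus(Xv[idx], pool_b, n_range=n_range)
        except Exception as exc:  # noqa: BLE001 - iteration failure is data
            logger.warning("bootstrap iteration %d failed: %s", b, exc)
            n_failed += 1
            continue
        rows, cols = match_signatures(
            ref.signatures, model_b.consensus_signatures.signatures
        )
        for r, c in zip(rows, cols):
            rho = pearsonr(
                ref.signatures[r], model_b.consensus_signatures.signatures[c]
            ).statistic
            per_sig[ref.labels[r]].append(float(rho))
    if n_failed > n_bootstrap / 2:
        raise RuntimeError(
            f"{n_failed}/{n_bootstrap} bootstrap iterations failed"
        )
    per_mean = {
        lab: float(np.mean(v)) if v else float("nan") for lab, v in per_sig.items()
    }
    finite = [v for v in per_mean.values() if np.isfinite(v)]
    return StabilityReport(
        n_bootstrap=n_bootstrap,
        subsample_fraction=fraction,
        per_signature_correlation=per_mean,
        mean_stability=float(np.mean(finite)) if finite else float("nan"),
        n_failed=n_failed,
    )
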
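"""Signature extraction backends.

Four complementary deconvolution methods factor the samples x 28 feature
matrix ``X`` into non-negative exposures ``A`` and L1-normalized signatures
``S`` (``X ~ A @ S``):

* ``extract_nmf`` — multiplicative-update NMF (Frobenius objective) with
  restart-stability rank selection;
* ``extract_nnica`` — non-negative ICA: NMF initialization alternated with
  symmetric decorrelation of the components and non-negative projection;
* ``extract_gnmf`` — graph-regularized NMF over the category-correlation
  graph, with diversity and sparsity penalties;
* ``extract_hdp`` — a truncated hierarchical-Dirichlet-process mixture
  sampled by blocked Gibbs over discretized pseudo-counts; the number of
  signatures is inferred rather than fixed.

All backends return rows that are non-negative, sum to 1, and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .cnv_features import FeatureMatrix

logger = logging.getLogger("cnasig")

_EPS = 1e-12

__all__ = [
    "SignatureSet",
    "ExtractionDiagnostics",
    "extract_nmf",
    "extract_nnica",
    "extract_gnmf",
    "extract_hdp",
    "run_all_methods",
]


@dataclass
class SignatureSet:
    """A set of L1-normalized signature profiles with method provenance."""

    method: str  # NMF | HDP | ICA | GD | CONSENSUS | EXTERNAL
    signatures: np.ndarray  # k x 28, rows sum to 1
    labels: list[str]
    exposures: np.ndarray | None = None  # samples x k

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.ndim != 2 or self.signatures.shape[0] < 1:
            raise ValueError("signatures must be a k x m matrix with k >= 1")
        if np.any(self.signatures < 0):
            raise ValueError("signatures must be non-negative")
        sums = self.signatures.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature rows must be L1-normalized")
        if len(self.labels) != self.signatures.shape[0]:
            raise ValueError("labels length must match number of signatures")

    @property
    def k(self) -> int:
        return self.signatures.shape[0]


@dataclass
class ExtractionDiagnostics:
    chosen_k: int
    reconstruction_error: float
    stability: float
    seed: int
    independence: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


def _l1_normalize(S: np.ndarray) -> np.ndarray:
    sums = S.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return S / sums


def _cosine_sim(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (A / na) @ (B / nb).T


def match_signatures(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of signature rows of A to rows of B by cosine.

    Returns (row indices into A, column indices into B) maximizing the
    summed cosine similarity over min(kA, kB) pairs.
    """
    sim = _cosine_sim(A, B)
    rows, cols = linear_sum_assignment(-sim)
    return rows, cols


def _matched_cosines(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sim = _cosine_sim(A, B)
    rows, cols = linear_sum_assignment(-sim)
    return sim[rows, cols]


def _init_factors(
    rng: np.random.Generator, n: int, k: int, m: int, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    A = rng.random((n, k)) * np.sqrt(scale / k) + _EPS
    S = rng.random((k, m)) * np.sqrt(scale / k) + _EPS
    return A, S


def _mu_loop(
    X: np.ndarray,
    A: np.ndarray,
    S: np.ndarray,
    W: np.ndarray | None = None,
    D: np.ndarray | None = None,
    alpha_graph: float = 0.0,
    beta_diversity: float = 0.0,
    gamma_sparsity: float = 0.0,
    max_iter: int = 300,
    tol: float = 1e-8,
    track_objective: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Shared multiplicative-update loop for plain and graph-regularized NMF.

    With all penalties zero this is exactly the classical Lee-Seung
    Frobenius update, so the graph-regularized backend reduces to plain NMF
    in the penalty-free limit.  Returns (A, S, frobenius_error, history).
    """
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        # exposures
        A *= (X @ S.T) / (A @ (S @ S.T) + _EPS)
        # signatures
        numer = A.T @ X
        denom = (A.T @ A) @ S + _EPS
        if alpha_graph > 0 and W is not None:
            numer = numer + alpha_graph * (S @ W)
            denom = denom + alpha_graph * (S @ D)
        if beta_diversity > 0:
            norms = np.linalg.norm(S, axis=1) + _EPS
            U = S / norms[:, None]
            cos = U @ U.T
            np.fill_diagonal(cos, 0.0)
            # d cos(S_i,S_j)/d S_i = S_j/(|S_i||S_j|) - cos_ij S_i/|S_i|^2 ;
            # ascent part -> denominator, descent part -> numerator
            numer = numer + beta_diversity * (cos.sum(axis=1) / norms**2)[:, None] * S
            denom = denom + beta_diversity * _diversity_pos(S)
        if gamma_sparsity > 0:
            denom = denom + gamma_sparsity
        S *= numer / denom
        err = float(np.linalg.norm(X - A @ S))
        if track_objective:
            history.append(err)
        if prev - err < tol * max(prev, 1.0):
            prev = err
            break
        prev = err
    return A, S, float(np.linalg.norm(X - A @ S)), history


def _diversity_pos(S: np.ndarray) -> np.ndarray:
    """Ascent part of the pairwise-cosine diversity penalty gradient."""
    norms = np.linalg.norm(S, axis=1) + _EPS
    U = S / norms[:, None]
    # d/dS_i sum_{j!=i} cos(S_i,S_j): positive term sum_{j!=i} S_j/(|S_i||S_j|)
    T = U.sum(axis=0, keepdims=True) - U  # sum_{j!=i} U_j
    return T / norms[:, None]


def _refit_exposures(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Per-sample NNLS exposures of X against fixed signatures S."""
    E = np.zeros((X.shape[0], S.shape[0]))
    for i in range(X.shape[0]):
        E[i], _ = nnls(S.T, X[i])
    return E


# --------------------------------------------------------------------------
# NMF with restart-stability rank selection


def extract_nmf(
    X: FeatureMatrix | np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[SignatureSet, ExtractionDiagnostics]:
    """Multiplicative-update NMF with resampling-free rank selection.

    For each candidate rank ``k`` the factorization is run from
    ``n_restarts`` random non-negative initializations; restart stability is
    the mean Hungarian-matched cosine over all pairs of restarts (sensitive
    to ranks whose extra components split arbitrarily).  The chosen rank
    maximizes
    ``stability - reconstruction_error / ||X||_F``; score differences below
    0.01 are treated as ties and resolved toward the smaller rank, so
    degenerate low-rank data selects the lower bound of the range.
    Reported signatures are the per-component median over matched restarts,
    L1-normalized; exposures are refit by NNLS.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo > hi or lo < 1:
        raise ValueError(f"invalid k_range {k_range}")
    if lo > Xv.shape[1]:
        raise ValueError("k_range minimum exceeds number of features")
    if Xv.shape[0] < hi + 1:
        raise ValueError("need at least max(k_range)+1 samples")
    norm_x = np.linalg.norm(Xv) + _EPS
    scale = float(Xv.mean()) + _EPS

    candidates: dict[int, dict] = {}
    for k in range(lo, hi + 1):
        runs = []
        for r in range(n_restarts):
            rng = np.random.default_rng([seed, k, r])
            A, S, err, _ = _mu_loop(
                Xv, *_init_factors(rng, Xv.shape[0], k, Xv.shape[1], scale),
                max_iter=max_iter,
            )
            runs.append((err, A, S))
        ref = min(range(len(runs)), key=lambda i: runs[i][0])
        S_ref = runs[ref][2]
        matched = [S_ref]
        for i, (_, _, S_i) in enumerate(runs):
            if i == ref:
                continue
            rows, cols = match_signatures(S_ref, S_i)
            matched.append(S_i[cols][np.argsort(rows)])
        pair_cos = [
            float(np.mean(_matched_cosines(runs[i][2], runs[j][2])))
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        stability = float(np.mean(pair_cos)) if pair_cos else 1.0
        score = stability - runs[ref][0] / norm_x
        candidates[k] = {
            "k": k,
            "score": score,
            "stability": stability,
            "matched": matched,
            "err": runs[ref][0],
        }
        logger.debug("NMF k=%d stability=%.3f err=%.4f", k, stability, runs[ref][0])

    # score differences below the tie margin are restart noise; resolve
    # toward the smallest rank
    best_score = max(c["score"] for c in candidates.values())
    chosen = next(
        candidates[k]
        for k in sorted(candidates)
        if candidates[k]["score"] >= best_score - 0.01
    )

    S_final = _l1_normalize(np.median(np.stack(chosen["matched"]), axis=0))
    E = _refit_exposures(Xv, S_final)
    err = float(np.linalg.norm(Xv - E @ S_final))
    sigs = SignatureSet(
        method="NMF",
        signatures=S_final,
        labels=[f"NMF{i+1}" for i in range(chosen["k"])],
        exposures=E,
    )
    diags = ExtractionDiagnostics(
        chosen_k=chosen["k"],
        reconstruction_error=err,
        stability=chosen["stability"],
        seed=seed,
        extra={"best_restart_error": chosen["err"]},
    )
    return sigs, diags


# --------------------------------------------------------------------------
# non-negative ICA


def extract_nnica(
    X: FeatureMatrix | np.ndarray,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
    decorr_weight: float = 0.1,
) -> tuple[SignatureSet, ExtractionDiagnostics]:
    """Non-negative ICA: NMF-initialized, decorrelation-regularized factors.

    After an NMF warm start, each iteration applies data-fidelity
    multiplicative updates to both factors, then a relaxed symmetric
    decorrelation of the mixing matrix, ``A <- (1 - w) A + w A (A^T A)^{-1/2}``
    with relaxation ``decorr_weight``, which drives the component activities
    toward independence while the data term keeps the factorization
    anchored; components are projected onto the non-negative orthant and L1
    renormalized each iteration.  Non-convergence returns the best iterate
    with ``converged=False`` rather than raising.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if not 1 <= k <= Xv.shape[1]:
        raise ValueError(f"k must be in [1, {Xv.shape[1]}]")
    scale = float(Xv.mean()) + _EPS

    results = []
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, k, r])
        A, S = _init_factors(rng, Xv.shape[0], k, Xv.shape[1], scale)
        A, S, _, _ = _mu_loop(Xv, A, S, max_iter=100)  # NMF warm start
        S = _l1_normalize(np.maximum(S, 0.0) + _EPS)
        converged = False
        for _ in range(max_iter):
            S_old = S.copy()
            # data-fidelity steps
            A *= (Xv @ S.T) / (A @ (S @ S.T) + _EPS)
            S = S * ((A.T @ Xv) / ((A.T @ A) @ S + _EPS))
            # relaxed symmetric decorrelation of the mixing matrix
            if k > 1:
                col_norm = np.linalg.norm(A, axis=0, keepdims=True) + _EPS
                G = (A / col_norm).T @ (A / col_norm)
                vals, vecs = np.linalg.eigh(G)
                vals = np.maximum(vals, _EPS)
                A_orth = (A / col_norm) @ (vecs @ np.diag(vals**-0.5) @ vecs.T)
                A = np.maximum(
                    (1 - decorr_weight) * A
                    + decorr_weight * A_orth * col_norm,
                    0.0,
                )
            # non-negative projection + renormalization of components
            S = _l1_normalize(np.maximum(S, 0.0) + _EPS)
            if np.max(np.abs(S - S_old)) < tol:
                converged = True
                break
        E = _refit_exposures(Xv, S)
        err = float(np.linalg.norm(Xv - E @ S))
        results.append((err, S, E, converged))

    errs = [r[0] for r in results]
    best = int(np.argmin(errs))
    err, S, E, converged = results[best]
    cosines = [
        float(np.mean(_matched_cosines(S, r[1])))
        for i, r in enumerate(results)
        if i != best
    ]
    stability = float(np.mean(cosines)) if cosines else 1.0
    independence = _mean_abs_corr(E)
    sigs = SignatureSet(
        method="ICA",
        signatures=S,
        labels=[f"ICA{i+1}" for i in range(k)],
        exposures=E,
    )
    diags = ExtractionDiagnostics(
        chosen_k=k,
        reconstruction_error=err,
        stability=stability,
        seed=seed,
        independence=independence,
        converged=converged,
    )
    return sigs, diags


def _mean_abs_corr(E: np.ndarray) -> float:
    """Mean absolute pairwise Pearson correlation of activity columns."""
    if E.shape[1] < 2:
        return 0.0
    sd = E.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    C = np.corrcoef(E[:, keep], rowvar=False)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    return float(np.mean(np.abs(off)))


# --------------------------------------------------------------------------
# graph-regularized NMF


def category_graph(Xv: np.ndarray, prune: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency and degree of the category-correlation graph.

    Nodes are the 28 feature categories; edge weights are absolute Pearson
    correlations between category columns, self-loops removed and weights
    below ``prune`` set to zero.
    """
    sd = Xv.std(axis=0)
    nonconst = sd > 1e-12
    if nonconst.sum() < 2:
        raise ValueError(
            "graph construction degenerate: fewer than 2 non-constant "
            "feature columns"
        )
    m = Xv.shape[1]
    W = np.zeros((m, m))
    idx = np.where(nonconst)[0]
    C = np.corrcoef(Xv[:, idx], rowvar=False)
    W[np.ix_(idx, idx)] = np.abs(np.nan_to_num(C))
    np.fill_diagonal(W, 0.0)
    W[W < prune] = 0.0
    D = np.diag(W.sum(axis=1))
    return W, D


def extract_gnmf(
    X: FeatureMatrix | np.ndarray,
    k: int,
    alpha_graph: float = 0.1,
    beta_diversity: float = 0.05,
    gamma_sparsity: float = 0.01,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 300,
) -> tuple[SignatureSet, ExtractionDiagnostics]:
    """Graph-regularized NMF over the category-correlation graph.

    Minimizes ``||X - A S||_F^2 + alpha * tr(S L S^T)
    + beta * sum_{i != j} cos(S_i, S_j) + gamma * ||S||_1`` with
    ``A, S >= 0`` by multiplicative updates; ``L = D - W`` is the
    combinatorial Laplacian of the category graph.  With all penalties zero
    the updates coincide with plain NMF at the same seed.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if not 1 <= k <= Xv.shape[1]:
        raise ValueError(f"k must be in [1, {Xv.shape[1]}]")
    use_graph = alpha_graph > 0
    W = D = None
    if use_graph:
        W, Dm = category_graph(Xv)
        D = Dm
    else:
        # still validate degeneracy so the error contract is uniform
        category_graph(Xv)
    scale = float(Xv.mean()) + _EPS

    results = []
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, k, r])
        A, S = _init_factors(rng, Xv.shape[0], k, Xv.shape[1], scale)
        A, S, err, _ = _mu_loop(
            Xv, A, S,
            W=W, D=D,
            alpha_graph=alpha_graph,
            beta_diversity=beta_diversity,
            gamma_sparsity=gamma_sparsity,
            max_iter=max_iter,
        )
        results.append((err, A, S))
    best = int(np.argmin([r[0] for r in results]))
    err, A, S_raw = results[best]
    cosines = [
        float(np.mean(_matched_cosines(S_raw, r[2])))
        for i, r in enumerate(results)
        if i != best
    ]
    stability = float(np.mean(cosines)) if cosines else 1.0
    S = _l1_normalize(S_raw)
    E = _refit_exposures(Xv, S)
    sigs = SignatureSet(
        method="GD",
        signatures=S,
        labels=[f"GD{i+1}" for i in range(k)],
        exposures=E,
    )
    diags = ExtractionDiagnostics(
        chosen_k=k,
        reconstruction_error=err,
        stability=stability,
        seed=seed,
        independence=_mean_abs_corr(E),
    )
    return sigs, diags


# --------------------------------------------------------------------------
# HDP-lite: truncated blocked Gibbs over pseudo-counts


def extract_hdp(
    X: FeatureMatrix | np.ndarray,
    count_scale: int = 1000,
    n_iter: int = 400,
    burn_in: int = 200,
    seed: int = 0,
    k_max: int = 10,
    alpha: float = 1.0,
    gamma: float = 1.0,
    eta: float = 0.1,
    presence_share: float = 0.02,
    merge_cosine: float = 0.8,
) -> tuple[SignatureSet, ExtractionDiagnostics]:
    """Hierarchical Dirichlet-process mixture over discretized counts.

    Rows are discretized to pseudo-counts ``round(count_scale * x)`` and a
    truncated (``k_max`` components) HDP topic model is sampled by blocked
    Gibbs: token-assignment counts per (sample, category) cell, component
    category distributions (Dirichlet), per-sample mixing weights
    (Dirichlet with shared base weights).  A component is "present" in a
    sweep when it holds at least ``presence_share`` of all tokens; components
    present in more than 5% of post-burn-in sweeps are reported, so the
    number of signatures is inferred from the data.  Because the truncated
    sampler lacks the table dynamics that collapse redundant components,
    posterior-mean components with pairwise cosine above ``merge_cosine``
    are merged (token-share weighted) before the presence rule is applied.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if count_scale < 100:
        raise ValueError("count_scale must be >= 100")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng([seed, 97])
    row_sums = Xv.sum(axis=1, keepdims=True)
    P = np.divide(Xv, row_sums, out=np.zeros_like(Xv), where=row_sums > 0)
    C = np.round(count_scale * P).astype(np.int64)  # n x m pseudo-counts
    n, m = C.shape
    total_tokens = C.sum()
    if total_tokens == 0:
        raise ValueError("feature matrix has no mass to discretize")

    # init component distributions from smoothed random sample profiles
    picks = rng.choice(n, size=k_max, replace=n < k_max)
    phi = _l1_normalize(P[picks] + eta)
    beta_w = np.full(k_max, 1.0 / k_max)
    pi = np.full((n, k_max), 1.0 / k_max)

    keep = n_iter - burn_in
    presence = np.zeros((keep, k_max), dtype=bool)
    phi_sum = np.zeros((k_max, m))
    share_sum = np.zeros(k_max)
    expo_sum = np.zeros((n, k_max))
    first_half = np.zeros((k_max, m))
    second_half = np.zeros((k_max, m))

    for sweep in range(n_iter):
        # blocked assignment: for each cell (i, j) split C[i, j] tokens over
        # components via sequential binomials (exact multinomial sampling)
        prob = pi[:, None, :] * phi.T[None, :, :]  # n x m x k
        prob_sum = prob.sum(axis=2, keepdims=True)
        prob = np.divide(prob, prob_sum, out=np.full_like(prob, 1.0 / k_max),
                         where=prob_sum > 0)
        remaining = C.copy()
        rest = np.ones((n, m))
        counts = np.zeros((n, m, k_max), dtype=np.int64)
        for kk in range(k_max - 1):
            p_k = np.divide(prob[:, :, kk], rest, out=np.zeros((n, m)),
                            where=rest > 1e-300)
            p_k = np.clip(p_k, 0.0, 1.0)
            draw = rng.binomial(remaining, p_k)
            counts[:, :, kk] = draw
            remaining -= draw
            rest = rest - prob[:, :, kk]
        counts[:, :, k_max - 1] = remaining

        n_ik = counts.sum(axis=1)  # n x k
        n_kj = counts.sum(axis=0).T  # k x m

        # component category distributions
        g = rng.gamma(eta + n_kj)
        phi = _l1_normalize(g + _EPS)
        # per-sample mixing weights with shared base
        g = rng.gamma(alpha * beta_w[None, :] + n_ik)
        pi = g / (g.sum(axis=1, keepdims=True) + _EPS)
        # shared base weights; table counts approximated by the number of
        # samples using each component (documented approximation)
        m_k = (n_ik > 0).sum(axis=0)
        g = rng.gamma(gamma / k_max + m_k)
        beta_w = g / g.sum()

        if sweep >= burn_in:
            t = sweep - burn_in
            share = n_ik.sum(axis=0) / total_tokens
            presence[t] = share >= presence_share
            phi_sum += share[:, None] * phi
            share_sum += share
            expo_sum += n_ik / max(total_tokens, 1)
            if t < keep // 2:
                first_half += share[:, None] * phi
            else:
                second_half += share[:, None] * phi

    pres_frac = presence.mean(axis=0)
    share_mean = share_sum / keep
    phi_mean = _l1_normalize(phi_sum + _EPS)

    # The truncated sampler has no table dynamics to collapse redundant
    # components, so posterior means that are near-duplicates (cosine >
    # merge threshold) are merged share-weighted before reporting.
    merge_cos = merge_cosine
    order0 = np.argsort(-share_mean, kind="stable")
    groups: list[list[int]] = []
    for idx in order0:
        for g in groups:
            rep = _l1_normalize(
                np.sum(share_mean[g, None] * phi_mean[g], axis=0)[None, :]
            )
            if float(_cosine_sim(phi_mean[idx][None, :], rep)[0, 0]) > merge_cos:
                g.append(int(idx))
                break
        else:
            groups.append([int(idx)])

    def _group_stats(g: list[int]) -> tuple[float, float, np.ndarray]:
        share = float(share_mean[g].sum())
        pres = float(presence[:, g].any(axis=1).mean())
        prof = _l1_normalize(
            np.sum(share_mean[g, None] * phi_mean[g], axis=0)[None, :]
        )[0]
        return share, pres, prof

    stats = [_group_stats(g) for g in groups]
    reported = [
        (g, s) for g, s in zip(groups, stats)
        if s[0] >= presence_share and s[1] > 0.05
    ]
    if not reported:
        best = int(np.argmax([s[0] for s in stats]))
        reported = [(groups[best], stats[best])]
    reported.sort(key=lambda t: -t[1][0])

    S = np.vstack([s[2] for _, s in reported])
    E = _refit_exposures(Xv, S)
    err = float(np.linalg.norm(Xv - E @ S))

    # split-half stability of the reported (merged) posterior means
    fh = np.vstack([
        _l1_normalize(first_half[g].sum(axis=0)[None, :] + _EPS)[0]
        for g, _ in reported
    ])
    sh = np.vstack([
        _l1_normalize(second_half[g].sum(axis=0)[None, :] + _EPS)[0]
        for g, _ in reported
    ])
    stability = float(np.mean(np.sum(
        (fh / (np.linalg.norm(fh, axis=1, keepdims=True) + _EPS))
        * (sh / (np.linalg.norm(sh, axis=1, keepdims=True) + _EPS)),
        axis=1,
    )))

    sigs = SignatureSet(
        method="HDP",
        signatures=S,
        labels=[f"HDP{i+1}" for i in range(len(reported))],
        exposures=E,
    )
    diags = ExtractionDiagnostics(
        chosen_k=len(reported),
        reconstruction_error=err,
        stability=stability,
        seed=seed,
        extra={
            "presence_fraction": [s[1] for _, s in reported],
            "token_share": [s[0] for _, s in reported],
        },
    )
    return sigs, diags


# --------------------------------------------------------------------------
# pooled run


DEFAULT_BACKENDS = ("NMF", "HDP", "ICA", "GD")


def run_all_methods(
    X: FeatureMatrix | np.ndarray,
    config: dict | None = None,
    seed: int = 0,
) -> tuple[list[SignatureSet], dict[str, ExtractionDiagnostics]]:
    """Run the enabled extraction backends and pool their signature sets.

    ICA and GD take their rank from NMF's chosen rank unless overridden in
    ``config``; HDP infers its own.  At least two backends must be enabled.
    """
    config = dict(config or {})
    backends = tuple(config.get("backends", DEFAULT_BACKENDS))
    if len(backends) < 2:
        raise ValueError("at least 2 extraction backends must be enabled")
    unknown = set(backends) - set(DEFAULT_BACKENDS)
    if unknown:
        raise ValueError(f"unknown backends: {sorted(unknown)}")

    pool: list[SignatureSet] = []
    diags: dict[str, ExtractionDiagnostics] = {}
    nmf_k = config.get("k")

    if "NMF" in backends:
        sigs, d = extract_nmf(
            X,
            k_range=tuple(config.get("k_range", (2, 8))),
            n_restarts=int(config.get("n_restarts", 20)),
            seed=seed,
        )
        pool.append(sigs)
        diags["NMF"] = d
        nmf_k = nmf_k or d.chosen_k
    if nmf_k is None:
        nmf_k = 4  # fallback when NMF disabled and no k configured
    if "ICA" in backends:
        sigs, d = extract_nnica(X, k=int(nmf_k), seed=seed)
        pool.append(sigs)
        diags["ICA"] = d
    if "GD" in backends:
        sigs, d = extract_gnmf(
            X,
            k=int(nmf_k),
            alpha_graph=float(config.get("alpha_graph", 0.1)),
            beta_diversity=float(config.get("beta_diversity", 0.05)),
            gamma_sparsity=float(config.get("gamma_sparsity", 0.01)),
            seed=seed,
        )
        pool.append(sigs)
        diags["GD"] = d
    if "HDP" in backends:
        sigs, d = extract_hdp(
            X,
            count_scale=int(config.get("count_scale", 1000)),
            n_iter=int(config.get("hdp_iter", 400)),
            burn_in=int(config.get("hdp_burn_in", 200)),
            seed=seed,
        )
        pool.append(sigs)
        diags["HDP"] = d

    for s in pool:
        logger.info("backend %s extracted k=%d signatures", s.method, s.k)
    return pool, diags
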
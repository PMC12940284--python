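"""Synthetic panel-CNA cohorts with planted signature structure.

Cohorts are generated top-down: sparse L1-normalized signatures over the 28
categories (optionally including a near-diploid signature that concentrates
its mass on 2-copy categories, mirroring the ubiquitous stable-genome
pattern of real panel cohorts), per-sample exposures with signature-specific
prevalences ranging from near-ubiquitous to rare, multiplicative noise on the
composed feature rows, and finally a segment-level realization that places
concrete copy-number segments on a genome model so the SEG reader and
classifier are exercised end to end.

Defaults reflect the study conditions the framework targets: cohorts of 300
samples, 4 planted signatures (one diploid-like), prevalences
(0.999, 0.64, 0.6, 0.385) echoing the observed prevalence ladder of panel
signatures, and 5% multiplicative noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cnv_features import CATALOG, CNASegment, FeatureCatalog, FeatureMatrix
from .extraction import SignatureSet, _cosine_sim, _l1_normalize

logger = logging.getLogger("cnasig")

__all__ = [
    "SyntheticCohort",
    "GENOME_HG19_MB",
    "simulate_signatures",
    "simulate_exposures",
    "compose_features",
    "realize_segments",
    "simulate_cohort",
]

#: hg19 autosome + X lengths rounded to Mb; Y is excluded from the feature
#: space so it is not modeled.
GENOME_HG19_MB: dict[str, int] = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59, "20": 63,
    "21": 48, "22": 51, "X": 155,
}

DEFAULT_PREVALENCES = (0.999, 0.64, 0.6, 0.385)

# per-category copy-number states and length-class bp intervals, aligned with
# the catalog ordering (draw caps keep single segments below chromosome size)
_HD_INTERVALS = [(1_000, 100_000), (100_000, 1_000_000), (1_000_000, 40_000_000)]
_LEN_INTERVALS = [
    (1_000, 100_000),
    (100_000, 1_000_000),
    (1_000_000, 10_000_000),
    (10_000_000, 40_000_000),
    (40_000_000, 240_000_000),
]
_STATE_CN = {"HD": (0, 0), "LOH": (1, 1), "diploid": (2, 2),
             "gain3-4": (3, 4), "gain5-8": (5, 8), "gain9+": (9, 12)}


@dataclass
class SyntheticCohort:
    true_signatures: SignatureSet
    true_exposures: np.ndarray
    features: FeatureMatrix
    segments: list[CNASegment]
    seed: int
    noise_level: float


def simulate_signatures(
    k: int,
    sparsity: float = 0.15,
    include_diploid_like: bool = True,
    seed: int = 0,
    max_cosine: float = 0.6,
    max_draws: int = 10_000,
    catalog: FeatureCatalog | None = None,
) -> SignatureSet:
    """Draw k sparse, mutually dissimilar signatures over the 28 categories.

    Signatures are symmetric-Dirichlet draws (concentration ``sparsity``;
    smaller is sparser), rejection-sampled so every off-diagonal pairwise
    cosine is at most ``max_cosine``.  With ``include_diploid_like`` the
    first signature places at least 90% of its mass on the diploid (2-copy)
    categories.
    """
    if not 2 <= k <= 10:
        raise ValueError("k must be in [2, 10]")
    catalog = catalog or CATALOG
    rng = np.random.default_rng([seed, 17])
    m = len(catalog)
    dip = catalog.diploid_indices

    rows: list[np.ndarray] = []
    if include_diploid_like:
        sig = np.zeros(m)
        w = rng.dirichlet(np.full(len(dip), 1.0))
        sig[dip] = 0.95 * w
        others = np.setdiff1d(np.arange(m), dip)
        sig[others] = 0.05 * rng.dirichlet(np.full(len(others), sparsity))
        rows.append(sig / sig.sum())

    draws = 0
    while len(rows) < k:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not draw {k} signatures with pairwise cosine <= "
                f"{max_cosine} in {max_draws} attempts; lower k or sparsity"
            )
        draws += 1
        cand = rng.dirichlet(np.full(m, sparsity))
        if rows:
            cos = _cosine_sim(cand[None, :], np.vstack(rows))
            if cos.max() > max_cosine:
                continue
        rows.append(cand)
    return SignatureSet(
        method="EXTERNAL",
        signatures=np.vstack(rows),
        labels=[f"TRUE{i+1}" for i in range(k)],
    )


def simulate_exposures(
    n_samples: int,
    k: int,
    prevalences: tuple[float, ...] | None = None,
    concentration: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Sparse non-negative exposures with per-signature prevalence.

    Each signature is active in a sample with its prevalence probability;
    active weights are gamma-drawn (shape ``concentration``) and each row is
    normalized to sum 1.  Samples where no signature activates are re-rolled
    onto the most prevalent signature so every sample has mass.
    """
    if prevalences is None:
        prevalences = DEFAULT_PREVALENCES[:k] if k <= 4 else tuple(
            np.linspace(0.999, 0.3, k)
        )
    prev = np.asarray(prevalences, dtype=float)
    if prev.shape != (k,):
        raise ValueError(f"need {k} prevalences, got {prev.shape}")
    if np.any(prev <= 0) or np.any(prev > 1):
        raise ValueError("prevalences must lie in (0, 1]")
    rng = np.random.default_rng([seed, 29])
    active = rng.random((n_samples, k)) < prev[None, :]
    empty = ~active.any(axis=1)
    active[empty, int(np.argmax(prev))] = True
    E = np.where(active, rng.gamma(concentration, 1.0, size=(n_samples, k)), 0.0)
    return E / E.sum(axis=1, keepdims=True)


def compose_features(
    exposures: np.ndarray,
    signatures: SignatureSet | np.ndarray,
    noise_level: float = 0.05,
    noise_model: str = "multiplicative",
    seed: int = 0,
    sample_ids: list[str] | None = None,
    catalog: FeatureCatalog | None = None,
) -> FeatureMatrix:
    """Compose a feature matrix as a noisy exposure-weighted mixture.

    ``multiplicative`` noise multiplies each entry of ``E @ S`` by a
    lognormal factor with sigma ``noise_level``; ``dirichlet_resample``
    redraws each row from a Dirichlet with concentration
    ``row / noise_level``.  Rows are renormalized to sum 1; zero-exposure
    samples produce zero rows.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    S = signatures.signatures if isinstance(signatures, SignatureSet) else signatures
    E = np.asarray(exposures, dtype=float)
    if E.shape[1] != S.shape[0]:
        raise ValueError("exposure columns must match number of signatures")
    rng = np.random.default_rng([seed, 41])
    X = E @ S
    if noise_level > 0:
        if noise_model == "multiplicative":
            X = X * np.exp(rng.normal(0.0, noise_level, size=X.shape))
        elif noise_model == "dirichlet_resample":
            out = np.zeros_like(X)
            for i, row in enumerate(X):
                if row.sum() > 0:
                    out[i] = rng.dirichlet(
                        np.maximum(row / noise_level, 1e-6)
                    )
            X = out
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    sums = X.sum(axis=1, keepdims=True)
    X = np.divide(X, sums, out=np.zeros_like(X), where=sums > 0)
    ids = sample_ids or [f"SIM{i+1:04d}" for i in range(X.shape[0])]
    return FeatureMatrix(sample_ids=ids, values=X, catalog=catalog or CATALOG)


def _category_spec(catalog: FeatureCatalog) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Per-category ((cn_lo, cn_hi), (len_lo, len_hi)) sampling intervals."""
    spec = []
    for label in catalog.categories:
        state, _ = label.split(":")
        cn = _STATE_CN[state]
        if state == "HD":
            idx = catalog.categories.index(label)
            spec.append((cn, _HD_INTERVALS[idx]))
        else:
            offset = (catalog.index(label) - 3) % 5
            spec.append((cn, _LEN_INTERVALS[offset]))
    return spec


def realize_segments(
    features: FeatureMatrix,
    genome_model: dict[str, int] | None = None,
    seed: int = 0,
    total_length: float = 2.2e9,
) -> list[CNASegment]:
    """Place concrete segments on chromosomes matching the feature fractions.

    Per sample, each category receives a total length proportional to its
    feature fraction; segments are drawn log-uniform within the category's
    length interval (the final segment is trimmed, or merged with its
    predecessor, so the category total is hit almost exactly), copy numbers
    uniform within the category's copy-number class, and segments are packed
    non-overlapping onto chromosomes largest-first.
    """
    genome = genome_model or GENOME_HG19_MB
    chrom_len = {c: int(l) * 1_000_000 for c, l in genome.items()}
    capacity = sum(chrom_len.values())
    if total_length > capacity:
        raise ValueError(
            f"requested segmented length {total_length:.3g} exceeds genome "
            f"model capacity {capacity:.3g}"
        )
    spec = _category_spec(features.catalog)
    rng = np.random.default_rng([seed, 53])

    segments: list[CNASegment] = []
    for si, sid in enumerate(features.sample_ids):
        row = features.values[si]
        if row.sum() == 0:
            continue
        drawn: list[tuple[int, int]] = []  # (length, cn)
        for ci, frac in enumerate(row):
            target = frac * total_length
            (cn_lo, cn_hi), (len_lo, len_hi) = spec[ci]
            if target < max(len_lo, 1_000) / 2:
                continue
            # draw log-uniform lengths in vectorized chunks until the
            # category target is covered, then trim/merge the last one
            log_lo, log_hi = math.log(len_lo), math.log(len_hi)
            mean_len = (len_hi - len_lo) / (log_hi - log_lo)
            lens: list[int] = []
            acc = 0.0
            while acc < target:
                est = max(8, int((target - acc) / mean_len * 1.2))
                chunk = np.exp(rng.uniform(log_lo, log_hi, size=est)).astype(np.int64)
                cum = acc + np.cumsum(chunk)
                cut = int(np.searchsorted(cum, target))
                lens.extend(chunk[:cut].tolist())
                acc = float(cum[cut - 1]) if cut > 0 else acc
                if cut < len(chunk):
                    resid = int(round(target - acc))
                    if resid >= len_lo:
                        lens.append(min(resid, len_hi - 1))
                    elif lens and lens[-1] + resid < len_hi:
                        lens[-1] += resid
                    elif resid >= len_lo / 2:
                        lens.append(len_lo)
                    acc = target
            cns = rng.integers(cn_lo, cn_hi + 1, size=len(lens))
            drawn.extend(zip(lens, cns.tolist()))
        # pack largest-first onto chromosomes
        drawn.sort(key=lambda t: -t[0])
        cursors = {c: 1 for c in chrom_len}
        chrom_order = sorted(chrom_len, key=lambda c: -chrom_len[c])
        for length, cn in drawn:
            placed = False
            for c in chrom_order:
                if cursors[c] + length - 1 <= chrom_len[c]:
                    start = cursors[c]
                    end = start + length - 1
                    cursors[c] = end + 2  # 1 bp gap between segments
                    seg_mean = math.log2(max(cn, 0.5) / 2.0)
                    segments.append(
                        CNASegment(
                            sample_id=sid,
                            chromosome=c,
                            start_bp=start,
                            end_bp=end,
                            seg_mean=seg_mean,
                            total_cn=cn,
                        )
                    )
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"sample {sid}: segment of {length} bp unrealizable "
                    "within the genome model"
                )
    return segments


def simulate_cohort(
    n_samples: int = 300,
    k: int = 4,
    noise_level: float = 0.05,
    seed: int = 0,
    include_diploid_like: bool = True,
    prevalences: tuple[float, ...] | None = None,
    sparsity: float = 0.15,
    concentration: float = 2.0,
    realize: bool = False,
) -> SyntheticCohort:
    """Generate a full synthetic cohort with planted signature structure.

    Defaults are the framework's reference study conditions: 300 samples,
    4 signatures including a diploid-like one, prevalence ladder
    (0.999, 0.64, 0.6, 0.385), 5% multiplicative noise.  Segment-level
    realization is optional (``realize=True``) since most consumers work at
    feature level.
    """
    sigs = simulate_signatures(
        k, sparsity=sparsity, include_diploid_like=include_diploid_like, seed=seed
    )
    E = simulate_exposures(
        n_samples, k, prevalences=prevalences, concentration=concentration, seed=seed
    )
    X = compose_features(E, sigs, noise_level=noise_level, seed=seed)
    segments = realize_segments(X, seed=seed) if realize else []
    return SyntheticCohort(
        true_signatures=sigs,
        true_exposures=E,
        features=X,
        segments=segments,
        seed=seed,
        noise_level=noise_level,
    )
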
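"""Genomic and clinical correlates of signature activities.

Association statistics downstream of signature fitting:

* fraction of genome altered (FGA), length-weighted, with the conventional
  ``|log2 ratio| >= 0.2`` alteration threshold;
* median split of continuous activities into high/low groups (ties to low);
* Mann-Whitney U comparison of activities between altered and wild-type
  samples with Cohen's d (pooled SD) for effect size;
* Fisher exact enrichment of alterations in a signature's high-activity
  samples versus high-activity samples of the other signatures, with fold
  enrichment;
* 120-day progression odds ratios between high and low activity groups;
* Benjamini-Hochberg FDR adjustment, applied within declared test families.

Meaningful-effect flags follow ``|d| > 0.2`` for associations and
``fold > 1.2`` with FDR < 0.05 for enrichments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cnv_features import CNASegment

logger = logging.getLogger("cnasig")

__all__ = [
    "AssociationRecord",
    "compute_fga",
    "median_split",
    "mw_association",
    "fisher_enrichment",
    "progression_or",
    "bh_adjust",
    "associate_alterations",
]

EFFECT_SIZE_THRESHOLD = 0.2
FOLD_THRESHOLD = 1.2
FDR_THRESHOLD = 0.05


@dataclass
class AssociationRecord:
    gene: str
    signature: str
    effect_size: float  # Cohen's d, altered minus wild-type
    p_value: float
    fdr: float | None
    direction: str  # "enrichment" | "depletion"
    n_altered: int
    n_wildtype: int

    @property
    def meaningful(self) -> bool:
        return (
            abs(self.effect_size) > EFFECT_SIZE_THRESHOLD
            and self.fdr is not None
            and self.fdr < FDR_THRESHOLD
        )


def compute_fga(
    segments: list[CNASegment], log2_threshold: float = 0.2
) -> dict[str, float]:
    """Length-weighted fraction of the segmented genome that is altered.

    A segment counts as altered when ``|seg_mean| >= log2_threshold``, or
    when only integer copies are available, ``total_cn != 2``.  Samples with
    no segments are absent from the result (missing, not 0).
    """
    total: dict[str, float] = {}
    altered: dict[str, float] = {}
    for seg in segments:
        sid = seg.sample_id
        total[sid] = total.get(sid, 0.0) + seg.length_bp
        if seg.seg_mean is not None:
            is_alt = abs(seg.seg_mean) >= log2_threshold
        else:
            is_alt = seg.total_cn != 2
        if is_alt:
            altered[sid] = altered.get(sid, 0.0) + seg.length_bp
    return {sid: altered.get(sid, 0.0) / t for sid, t in total.items() if t > 0}


def median_split(values: np.ndarray | pd.Series) -> np.ndarray:
    """Dichotomize at the median: value > median -> "high", else "low"."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least 2 samples")
    med = float(np.median(v))
    labels = np.where(v > med, "high", "low")
    if np.all(labels == "low"):
        warnings.warn("all values <= median; every sample labeled low", stacklevel=2)
    return labels


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled SD (a minus b)."""
    na, nb = len(a), len(b)
    va = np.var(a, ddof=1) if na > 1 else 0.0
    vb = np.var(b, ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1))
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def mw_association(
    activity: np.ndarray,
    altered: np.ndarray,
    gene: str = "",
    signature: str = "",
) -> AssociationRecord:
    """Mann-Whitney U comparison of activities, altered vs wild-type.

    Two-sided p-value; effect size is Cohen's d on the pooled SD, positive
    when the altered group has higher activity (enrichment).
    """
    activity = np.asarray(activity, dtype=float)
    altered = np.asarray(altered).astype(bool)
    a = activity[altered]
    b = activity[~altered]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both altered and wild-type groups must be non-empty")
    stat = mannwhitneyu(a, b, alternative="two-sided")
    d = _cohens_d(a, b)
    return AssociationRecord(
        gene=gene,
        signature=signature,
        effect_size=d,
        p_value=float(stat.pvalue),
        fdr=None,
        direction="enrichment" if d >= 0 else "depletion",
        n_altered=len(a),
        n_wildtype=len(b),
    )


def _fisher_table(table: np.ndarray) -> tuple[float | None, float, float | None]:
    """(odds ratio or None on zero margin, two-sided p, Haldane OR)."""
    table = np.asarray(table, dtype=float)
    odds, p = fisher_exact(table.astype(int), alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if min(a + b, c + d, a + c, b + d) == 0 or b * c == 0:
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return None, float(p), float(haldane)
    return float(odds), float(p), None


def fisher_enrichment(
    high_in_signature: np.ndarray,
    altered: np.ndarray,
    background: np.ndarray,
) -> dict:
    """Fisher enrichment of an alteration in one signature's high group.

    ``high_in_signature`` marks samples in the focal signature's
    high-activity group; ``background`` marks the comparison set (high
    activity in any other signature).  Returns odds ratio, fold enrichment
    (alteration rate ratio), two-sided exact p, and the meaningful flag
    inputs (fold > 1.2; FDR is attached by the caller across the family).
    """
    hi = np.asarray(high_in_signature).astype(bool)
    alt = np.asarray(altered).astype(bool)
    bg = np.asarray(background).astype(bool) & ~hi
    if hi.sum() == 0 or bg.sum() == 0:
        raise ValueError("focal and background groups must be non-empty")
    a = int((hi & alt).sum())
    b = int((hi & ~alt).sum())
    c = int((bg & alt).sum())
    d = int((bg & ~alt).sum())
    odds, p, haldane = _fisher_table(np.array([[a, b], [c, d]]))
    rate_s = a / hi.sum()
    rate_b = c / bg.sum() if bg.sum() else np.nan
    fold = rate_s / rate_b if rate_b and rate_b > 0 else np.inf
    return {
        "odds_ratio": odds,
        "odds_ratio_haldane": haldane,
        "fold_enrichment": float(fold),
        "p_value": p,
        "table": [[a, b], [c, d]],
    }


def progression_or(
    group_labels: np.ndarray,
    progressed: np.ndarray,
) -> dict:
    """120-day progression odds ratio, high- vs low-activity group.

    ``group_labels`` are "high"/"low" (from :func:`median_split`);
    ``progressed`` is a boolean progression-at-120-days indicator (unclear
    labels are excluded upstream).  OR > 1 means the high group progresses
    more; BH-FDR across a family of tests is attached by the caller.
    """
    g = np.asarray(group_labels)
    prog = np.asarray(progressed).astype(bool)
    hi = g == "high"
    a = int((hi & prog).sum())
    b = int((hi & ~prog).sum())
    c = int((~hi & prog).sum())
    d = int((~hi & ~prog).sum())
    odds, p, haldane = _fisher_table(np.array([[a, b], [c, d]]))
    return {
        "odds_ratio": odds,
        "odds_ratio_haldane": haldane,
        "p_value": p,
        "table": [[a, b], [c, d]],
    }


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def associate_alterations(
    activities: pd.DataFrame,
    alterations: pd.DataFrame,
    min_altered_fraction: float = 0.01,
) -> pd.DataFrame:
    """Scan all (gene, signature) activity associations with BH-FDR.

    ``activities``: samples x signatures; ``alterations``: samples x genes
    binary (mutated = 1).  Genes altered in fewer than
    ``min_altered_fraction`` of samples are excluded before testing; BH
    adjustment is applied across the whole scan (one test family).
    """
    common = activities.index.intersection(alterations.index)
    act = activities.loc[common]
    alt = alterations.loc[common].astype(bool)
    keep = alt.mean(axis=0) >= min_altered_fraction
    alt = alt.loc[:, keep]
    if alt.shape[1] == 0:
        return pd.DataFrame(
            columns=["gene", "signature", "effect_size", "p_value", "fdr",
                     "direction", "meaningful"]
        )
    records = []
    for gene in alt.columns:
        a = alt[gene].to_numpy()
        if a.all() or not a.any():
            continue
        for sig in act.columns:
            rec = mw_association(act[sig].to_numpy(), a, gene=gene, signature=sig)
            records.append(rec)
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "signature": [r.signature for r in records],
            "effect_size": [r.effect_size for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
        }
    )
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df["meaningful"] = (df["effect_size"].abs() > EFFECT_SIZE_THRESHOLD) & (
        df["fdr"] < FDR_THRESHOLD
    )
    return df
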
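"""28-category copy-number feature encoding for targeted-panel segment data.

Somatic copy-number alteration (CNA) segments are classified by total copy
number and segment length into a fixed 28-category scheme:

* homozygous deletion (0 copies): 3 length classes
  ``[0, 100 Kb)``, ``[100 Kb, 1 Mb)``, ``[1 Mb, inf)``
* LOH (1 copy), diploid (2 copies), gain 3-4, gain 5-8, gain 9+:
  5 length classes each,
  ``[0, 100 Kb)``, ``[100 Kb, 1 Mb)``, ``[1 Mb, 10 Mb)``,
  ``[10 Mb, 40 Mb)``, ``[40 Mb, inf)``

Intervals are half-open on length in bp, so every (copy number, length) pair
falls in exactly one of the 28 categories.  Per sample the feature value of a
category is the fraction of that sample's total segmented length falling in
the category, so non-empty rows sum to 1.  Allele-specific data are absent in
public panel releases; total copy number 1 is used as the LOH proxy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cnasig")

__all__ = [
    "CNASegment",
    "FeatureCatalog",
    "FeatureMatrix",
    "CATALOG",
    "read_seg",
    "log2_to_cn",
    "classify_segment",
    "build_feature_matrix",
    "write_features",
    "read_features",
    "SegFormatError",
]

# length-class boundaries in bp (half-open [lo, hi))
_LEN_BOUNDS = (100_000, 1_000_000, 10_000_000, 40_000_000)
_HD_BOUNDS = (100_000, 1_000_000)

_LEN_LABELS = ("0-100Kb", "100Kb-1Mb", "1Mb-10Mb", "10Mb-40Mb", ">40Mb")
_HD_LABELS = ("0-100Kb", "100Kb-1Mb", ">1Mb")
_STATES = ("LOH", "diploid", "gain3-4", "gain5-8", "gain9+")


class SegFormatError(ValueError):
    """Raised when a segment or feature file does not match its declared schema."""


@dataclass
class CNASegment:
    """One copy-number segment on 1-based inclusive genome coordinates."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_probes: int | None = None
    seg_mean: float | None = None
    total_cn: int | None = None

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"segment end ({self.end_bp}) precedes start ({self.start_bp})"
            )
        if self.seg_mean is None and self.total_cn is None:
            raise ValueError("segment needs seg_mean or total_cn")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _make_labels() -> tuple[str, ...]:
    labels = [f"HD:{lab}" for lab in _HD_LABELS]
    for state in _STATES:
        labels.extend(f"{state}:{lab}" for lab in _LEN_LABELS)
    return tuple(labels)


@dataclass(frozen=True)
class FeatureCatalog:
    """Fixed ordered list of the 28 (copy-state, length-class) categories."""

    categories: tuple[str, ...] = field(default_factory=_make_labels)

    def __post_init__(self) -> None:
        if len(self.categories) != 28:
            raise ValueError("catalog must have exactly 28 categories")

    def __len__(self) -> int:
        return len(self.categories)

    def index(self, label: str) -> int:
        return self.categories.index(label)

    @property
    def diploid_indices(self) -> np.ndarray:
        """Column indices of the 2-copy (diploid) categories."""
        return np.array(
            [i for i, c in enumerate(self.categories) if c.startswith("diploid:")]
        )


#: module-level default catalog; signature vectors are comparable across runs
#: only because this ordering is fixed.
CATALOG = FeatureCatalog()


@dataclass
class FeatureMatrix:
    """Samples x 28 matrix of genome-fraction features."""

    sample_ids: list[str]
    values: np.ndarray
    catalog: FeatureCatalog = field(default_factory=lambda: CATALOG)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.catalog):
            raise ValueError(
                f"feature matrix must be n x {len(self.catalog)}, "
                f"got shape {self.values.shape}"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match rows")
        if np.any(self.values < 0):
            raise ValueError("feature values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=list(self.catalog.categories)
        )


def classify_segment(total_cn: int, length_bp: int) -> int:
    """Map a (total copy number, segment length) pair to its category index.

    Length intervals are half-open ``[lo, hi)`` with boundaries at 100 Kb,
    1 Mb, 10 Mb and 40 Mb (homozygous deletions use only the first two).
    """
    if length_bp <= 0:
        raise ValueError(f"length_bp must be positive, got {length_bp}")
    if total_cn < 0:
        raise ValueError(f"copy number must be non-negative, got {total_cn}")

    if total_cn == 0:
        return int(np.searchsorted(_HD_BOUNDS, length_bp, side="right"))

    if total_cn == 1:
        state = 0
    elif total_cn == 2:
        state = 1
    elif total_cn <= 4:
        state = 2
    elif total_cn <= 8:
        state = 3
    else:
        state = 4
    len_idx = int(np.searchsorted(_LEN_BOUNDS, length_bp, side="right"))
    return 3 + state * 5 + len_idx


def log2_to_cn(seg_mean: float, ploidy: int = 2) -> int:
    """Convert a log2 copy-ratio to integer total copy number.

    Returns ``round(ploidy * 2**seg_mean)`` with half-away-from-zero
    rounding, floored at 0.  No tumor-purity correction is applied.
    """
    if not math.isfinite(seg_mean):
        raise ValueError(f"seg_mean must be finite, got {seg_mean}")
    value = ploidy * 2.0**seg_mean
    return max(0, int(math.floor(value + 0.5)))


# --------------------------------------------------------------------------
# SEG reading

_COLUMN_ALIASES = {
    "sample": ("id", "sample", "sample_id", "sampleid"),
    "chromosome": ("chrom", "chromosome", "chr"),
    "start": ("loc.start", "start", "start_bp", "loc_start"),
    "end": ("loc.end", "end", "end_bp", "loc_end"),
    "n_probes": ("num.mark", "num_mark", "n_probes", "num_probes"),
    "seg_mean": ("seg.mean", "seg_mean", "segmean", "log2"),
    "total_cn": ("total_cn", "cn", "copy_number", "tcn", "copies"),
}


def _find_column(columns: Sequence[str], key: str) -> str | None:
    lowered = {c.lower(): c for c in columns}
    for alias in _COLUMN_ALIASES[key]:
        if alias in lowered:
            return lowered[alias]
    return None


def _present(value: object) -> bool:
    if value is None or value == "":
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return True


def _normalize_chrom(label: object) -> str:
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def read_seg(
    path: str | Path,
    dialect: str = "cbioportal_log2",
    drop_chrom_y: bool = True,
) -> list[CNASegment]:
    """Read a tab-separated segment file into :class:`CNASegment` records.

    Parameters
    ----------
    path
        Path to a SEG-style TSV.
    dialect
        ``"cbioportal_log2"`` (requires a segment-mean column carrying log2
        copy ratios) or ``"integer_cn"`` (requires an integer copy-number
        column).
    drop_chrom_y
        Drop chromosome Y rows (default; the panel feature space treats X as
        autosome-like and excludes Y).
    """
    if dialect not in ("cbioportal_log2", "integer_cn"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = list(df.columns)

    required = ["sample", "chromosome", "start", "end"]
    required.append("seg_mean" if dialect == "cbioportal_log2" else "total_cn")
    resolved: dict[str, str] = {}
    for key in required:
        col = _find_column(cols, key)
        if col is None:
            raise SegFormatError(
                f"{path.name}: missing required column for {key!r} "
                f"(accepted names: {', '.join(_COLUMN_ALIASES[key])})"
            )
        resolved[key] = col
    for key in ("n_probes", "seg_mean", "total_cn"):
        if key not in resolved:
            col = _find_column(cols, key)
            if col is not None:
                resolved[key] = col

    segments: list[CNASegment] = []
    n_dropped_y = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(cols, row))
        chrom = _normalize_chrom(rec[resolved["chromosome"]])
        if drop_chrom_y and chrom.upper() == "Y":
            n_dropped_y += 1
            continue
        try:
            start = int(float(rec[resolved["start"]]))
            end = int(float(rec[resolved["end"]]))
        except (TypeError, ValueError) as exc:
            raise SegFormatError(
                f"{path.name} line {row_no}: non-numeric coordinates"
            ) from exc
        if end < start:
            raise SegFormatError(
                f"{path.name} line {row_no}: end ({end}) < start ({start})"
            )
        kwargs: dict = {}
        if "n_probes" in resolved and _present(rec.get(resolved["n_probes"])):
            kwargs["n_probes"] = int(float(rec[resolved["n_probes"]]))
        if "seg_mean" in resolved and _present(rec.get(resolved["seg_mean"])):
            kwargs["seg_mean"] = float(rec[resolved["seg_mean"]])
        if "total_cn" in resolved and _present(rec.get(resolved["total_cn"])):
            kwargs["total_cn"] = int(float(rec[resolved["total_cn"]]))
        segments.append(
            CNASegment(
                sample_id=str(rec[resolved["sample"]]),
                chromosome=chrom,
                start_bp=start,
                end_bp=end,
                **kwargs,
            )
        )

    if not segments:
        logger.warning("%s: no data rows retained", path.name)
    logger.info(
        "%s: %d segments retained (%d chrY rows dropped)",
        path.name,
        len(segments),
        n_dropped_y,
    )
    return segments


# --------------------------------------------------------------------------
# feature matrix construction


def build_feature_matrix(
    segments: Iterable[CNASegment],
    catalog: FeatureCatalog | None = None,
    ploidy: int = 2,
) -> FeatureMatrix:
    """Build the samples x 28 genome-fraction feature matrix.

    Per sample, each category value is the summed length of the sample's
    segments in that category divided by the sample's total segmented length,
    so rows of non-empty samples sum to 1.  Segments lacking ``total_cn`` are
    converted from ``seg_mean`` via :func:`log2_to_cn`.  Row order is the
    order of first appearance of each sample; overlapping segments are kept
    as-is (the panel caller is trusted) with a warning.
    """
    catalog = catalog or CATALOG
    order: list[str] = []
    cat_len: dict[str, np.ndarray] = {}
    intervals: dict[str, list[tuple[str, int, int]]] = {}

    for seg in segments:
        sid = seg.sample_id
        if sid not in cat_len:
            order.append(sid)
            cat_len[sid] = np.zeros(len(catalog))
            intervals[sid] = []
        cn = seg.total_cn
        if cn is None:
            cn = log2_to_cn(seg.seg_mean, ploidy=ploidy)
        idx = classify_segment(cn, seg.length_bp)
        cat_len[sid][idx] += seg.length_bp
        intervals[sid].append((seg.chromosome, seg.start_bp, seg.end_bp))

    for sid, ivs in intervals.items():
        ivs.sort()
        for (c1, s1, e1), (c2, s2, _) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 <= e1:
                logger.warning("sample %s: overlapping segments kept as-is", sid)
                break

    values = np.zeros((len(order), len(catalog)))
    for i, sid in enumerate(order):
        total = cat_len[sid].sum()
        if total > 0:
            values[i] = cat_len[sid] / total
        else:
            logger.warning("sample %s has no segments; zero feature row", sid)
    return FeatureMatrix(sample_ids=order, values=values, catalog=catalog)


# --------------------------------------------------------------------------
# TSV round trip


def write_features(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV (sample column + 28 category columns)."""
    df = matrix.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_features(
    path: str | Path, catalog: FeatureCatalog | None = None
) -> FeatureMatrix:
    """Read a feature-matrix TSV written by :func:`write_features`."""
    catalog = catalog or CATALOG
    df = pd.read_csv(path, sep="\t", index_col=0)
    expected = list(catalog.categories)
    if list(df.columns) != expected:
        raise SegFormatError(
            f"feature file columns do not match the 28-category catalog "
            f"(got {len(df.columns)} columns)"
        )
    return FeatureMatrix(
        sample_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        catalog=catalog,
    )
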
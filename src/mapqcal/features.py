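"""Per-read alignment features, truth labels and [0,1] scaling.

Twenty-two features are computed for every primary, mapped,
non-multi-mapped alignment: aligner-tag features (alignment score,
best-secondary score, their difference, mate score, edit distance,
mismatches, gap opens/extensions, MAPQ), pair features (alignment type,
orientation, insert size), sequence features (GC content, gzip-
compressed size, the least-squares line of base quality against read
position, low-quality-base counts) and reference-window features (GC
and compressed size of the aligned span, read depth at the leftmost
aligned base).

A read is *multi-mapped* when its alignment score equals its best
secondary alignment score (the aligner placed it equally well in at
least two locations); such reads are excluded from training and testing
and keep their original MAPQ during recalibration.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .alignment_io import AlignmentRecord
from .simgen import ReadOrigin, parse_origin

__all__ = [
    "FEATURE_NAMES",
    "ScalingParams",
    "label_alignment",
    "is_multimapped",
    "base_quality_line",
    "gc_content",
    "complexity_size",
    "DepthIndex",
    "depth_at",
    "extract_features",
    "feature_table",
    "fit_scaler",
    "apply_scaler",
]

#: The 22-feature universe, in ranking-table order.
FEATURE_NAMES = [
    "MAPPING_QUALITY",
    "ALIGN_SCORES_DIFF",
    "EDIT_DISTANCE",
    "ALIGNMENT_SCORE",
    "MISMATCHES",
    "SECONDARY_ALIGN_SCORE",
    "MATE_ALIGN_SCORE",
    "GAP_OPENS",
    "GAP_EXT",
    "PAIR_ALIGN_TYPE",
    "INSERT_SIZE",
    "REF_GC_CONT",
    "READ_GC_CONT",
    "PAIR_ORIENTATION",
    "N_LOWQ_BASES",
    "REF_COMPR_SIZE",
    "READ_COMPR_SIZE",
    "SLOPE",
    "AVG_LOWQ_SCORE",
    "INTERCEPT",
    "R_VALUE",
    "DEPTH",
]

DEFAULT_LOWQ_THRESHOLD = 20
DEFAULT_TOLERANCE_BP = 20
DEFAULT_MIN_SCORE = -61  # aligner minimum; sentinel for absent XS/YS is min-1
GZIP_LEVEL = 6


# ----------------------------------------------------------------------
# labelling and filtering

def label_alignment(record: AlignmentRecord, origin: ReadOrigin,
                    tolerance_bp: int = DEFAULT_TOLERANCE_BP) -> int:
    """0 if the record sits at its true origin (same chrom, leftmost
    position within ``tolerance_bp``), else 1."""
    if record.is_unmapped:
        raise ValueError("cannot label an unmapped record")
    chrom, start, _end, _strand = origin.span_for_mate(record.mate)
    if record.chrom == chrom and abs(record.pos - start) <= tolerance_bp:
        return 0
    return 1


def is_multimapped(record: AlignmentRecord) -> bool:
    """True iff AS and XS are both present and equal."""
    tags = record.tags
    return "AS" in tags and "XS" in tags and tags["AS"] == tags["XS"]


# ----------------------------------------------------------------------
# per-feature primitives

def base_quality_line(quals: Iterable[int]) -> Tuple[float, float, float]:
    """OLS of base quality on 0-based read position: (slope, intercept,
    Pearson r).  Zero-variance qualities give (0, mean, 0)."""
    q = np.asarray(list(quals), dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 bases for the quality line")
    x = np.arange(q.size, dtype=float)
    xm = x.mean()
    qm = q.mean()
    sxx = ((x - xm) ** 2).sum()
    sqq = ((q - qm) ** 2).sum()
    sxq = ((x - xm) * (q - qm)).sum()
    if sqq == 0.0:
        return 0.0, qm, 0.0
    slope = sxq / sxx
    intercept = qm - slope * xm
    r = sxq / math.sqrt(sxx * sqq)
    return slope, intercept, r


def gc_content(seq: str) -> float:
    """(#G + #C) / #unambiguous bases; 0 (with a warning) when no
    unambiguous base exists."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    informative = gc + s.count("A") + s.count("T")
    if informative == 0:
        warnings.warn("sequence contains no unambiguous bases; GC undefined")
        return 0.0
    return gc / informative


def complexity_size(seq: str) -> int:
    """Size in bytes of the gzip-compressed sequence (fixed level); a
    proxy for repetitiveness — low-complexity sequence compresses well."""
    if not seq:
        raise ValueError("empty sequence")
    return len(gzip.compress(seq.encode("ascii"), compresslevel=GZIP_LEVEL))


class DepthIndex:
    """Per-position primary-read depth, built in one pass."""

    def __init__(self, records: Iterable[AlignmentRecord],
                 chrom_lengths: Dict[str, int]):
        self._cov = {c: np.zeros(n + 2, dtype=np.int32)
                     for c, n in chrom_lengths.items()}
        for rec in records:
            if not rec.is_primary_mapped:
                continue
            d = self._cov.get(rec.chrom)
            if d is None:
                raise KeyError(f"alignment references unknown chrom {rec.chrom!r}")
            end = min(rec.reference_end(), len(d) - 2)
            d[rec.pos] += 1
            d[end + 1] -= 1
        self._depth = {c: np.cumsum(d) for c, d in self._cov.items()}

    def depth_at(self, chrom: str, pos: int) -> int:
        if chrom not in self._depth:
            raise KeyError(f"unknown chrom {chrom!r}")
        return int(self._depth[chrom][pos])


def depth_at(index: DepthIndex, chrom: str, pos: int) -> int:
    """Number of primary mapped reads covering (chrom, pos)."""
    return index.depth_at(chrom, pos)


# ----------------------------------------------------------------------
# feature extraction

def _pair_align_type(rec: AlignmentRecord) -> int:
    if rec.mate_is_unmapped or not rec.is_paired:
        return 2
    if rec.is_proper_pair:
        return 0
    return 1


def _pair_orientation(rec: AlignmentRecord) -> int:
    """0 = FR, 1 = RF, 2 = same strand / no mate."""
    if rec.mate_is_unmapped or not rec.is_paired:
        return 2
    if rec.is_reverse == rec.mate_is_reverse:
        return 2
    # leftmost read's strand decides FR vs RF
    if rec.pos <= rec.pnext:
        leftmost_fwd = not rec.is_reverse
    else:
        leftmost_fwd = not rec.mate_is_reverse
    return 0 if leftmost_fwd else 1


def extract_features(record: AlignmentRecord, reference: Dict[str, str],
                     depth_index: DepthIndex,
                     lowq_threshold: int = DEFAULT_LOWQ_THRESHOLD,
                     min_score: int = DEFAULT_MIN_SCORE) -> Dict[str, float]:
    """Compute the 22-feature vector for one eligible alignment."""
    if not record.is_primary_mapped:
        raise ValueError("features are defined on primary mapped alignments")
    tags = record.tags
    if "NM" not in tags:
        raise ValueError("required tag NM absent")
    if "AS" not in tags:
        raise ValueError("required tag AS absent")
    sentinel = min_score - 1
    as_score = tags["AS"]
    xs = tags.get("XS", sentinel)
    ys = tags.get("YS", sentinel)
    quals = np.asarray(record.quals, dtype=float)
    slope, intercept, r = base_quality_line(quals)
    low = quals[quals < lowq_threshold]
    ref_seq = reference[record.chrom][record.pos - 1: record.reference_end()]
    feats = {
        "MAPPING_QUALITY": float(record.mapq),
        "ALIGN_SCORES_DIFF": float(as_score - xs),
        "EDIT_DISTANCE": float(tags["NM"]),
        "ALIGNMENT_SCORE": float(as_score),
        "MISMATCHES": float(tags.get("XM", tags["NM"])),
        "SECONDARY_ALIGN_SCORE": float(xs),
        "MATE_ALIGN_SCORE": float(ys),
        "GAP_OPENS": float(tags.get("XO", 0)),
        "GAP_EXT": float(tags.get("XG", 0)),
        "PAIR_ALIGN_TYPE": float(_pair_align_type(record)),
        "INSERT_SIZE": float(abs(record.tlen)),
        "REF_GC_CONT": gc_content(ref_seq),
        "READ_GC_CONT": gc_content(record.seq),
        "PAIR_ORIENTATION": float(_pair_orientation(record)),
        "N_LOWQ_BASES": float(low.size),
        "REF_COMPR_SIZE": float(complexity_size(ref_seq)),
        "READ_COMPR_SIZE": float(complexity_size(record.seq)),
        "SLOPE": slope,
        "AVG_LOWQ_SCORE": float(low.mean()) if low.size else 0.0,
        "INTERCEPT": intercept,
        "R_VALUE": r,
        "DEPTH": float(depth_index.depth_at(record.chrom, record.pos)),
    }
    assert len(feats) == len(FEATURE_NAMES)
    return feats


def feature_table(records: List[AlignmentRecord], reference: Dict[str, str],
                  labels: Optional[Dict[Tuple[str, int], int]] = None,
                  tolerance_bp: int = DEFAULT_TOLERANCE_BP,
                  lowq_threshold: int = DEFAULT_LOWQ_THRESHOLD,
                  min_score: int = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Feature matrix for every eligible record.

    The LABEL column comes from ``labels`` (read key -> 0/1) when given,
    else from origin-encoded read names (-1 when neither applies).
    Multi-mapped, secondary, supplementary and unmapped records are
    excluded.
    """
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    depth_index = DepthIndex(records, chrom_lengths)
    rows = []
    keys = []
    labs = []
    for rec in records:
        if not rec.is_primary_mapped or is_multimapped(rec):
            continue
        feats = extract_features(rec, reference, depth_index,
                                 lowq_threshold=lowq_threshold,
                                 min_score=min_score)
        key = rec.key()
        if labels is not None and key in labels:
            lab = labels[key]
        else:
            origin = parse_origin(rec.read_name)
            lab = label_alignment(rec, origin, tolerance_bp) if origin else -1
        rows.append(feats)
        keys.append(f"{key[0]}/{key[1]}")
        labs.append(lab)
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "READ_KEY", keys)
    df["LABEL"] = labs
    return df


# ----------------------------------------------------------------------
# scaling

@dataclass
class ScalingParams:
    """Per-feature (min, max) learned from the training matrix only."""

    mins: pd.Series
    maxs: pd.Series

    def __post_init__(self) -> None:
        if (self.maxs < self.mins).any():
            raise ValueError("max < min in scaling params")


def fit_scaler(matrix: pd.DataFrame) -> ScalingParams:
    """Learn per-column (min, max); fit on the training matrix only."""
    if len(matrix) == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    return ScalingParams(mins=matrix.min(axis=0), maxs=matrix.max(axis=0))


def apply_scaler(params: ScalingParams, matrix: pd.DataFrame) -> pd.DataFrame:
    """(x - min) / (max - min), clipped to [0, 1]; constant training
    columns map to 0 (matches sklearn's MinMaxScaler with clipping)."""
    span = (params.maxs - params.mins).replace(0, 1.0)
    scaled = (matrix - params.mins) / span
    return scaled.clip(0.0, 1.0)
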
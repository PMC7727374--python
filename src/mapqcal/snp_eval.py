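"""SNP-call evaluation against a truth set.

Called variants are filtered to SNPs with quality strictly above a
threshold (20 by default — Phred 20 is a 1-in-100 chance the call is a
false positive) and matched to the truth on exact (chrom, pos, ref,
alt) identity; genotypes are ignored (this evaluates detection, not
genotyping).  Before/after recalibration comparisons are reported as
relative percent change, ``100 * (after - before) / before``.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd
from cyvcf2 import VCF

from .calibration import f1 as _f1
from .calibration import precision_recall

__all__ = [
    "SNPCall",
    "EvalResult",
    "read_vcf_snps",
    "match_snps",
    "pr_curve",
    "delta_report",
    "call_variants_bcftools",
]


@dataclass(frozen=True)
class SNPCall:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    qual: float = 0.0


@dataclass
class EvalResult:
    threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        return _f1(self.precision, self.recall)


def read_vcf_snps(path: str) -> List[SNPCall]:
    """SNP records only (ref and alt both length 1); INDELs and SVs are
    skipped; multi-allelic lines are split into one call per alt."""
    calls: List[SNPCall] = []
    for rec in VCF(path):
        for alt in rec.ALT:
            if len(rec.REF) == 1 and len(alt) == 1 and alt in "ACGT":
                calls.append(SNPCall(rec.CHROM, rec.POS, rec.REF, alt,
                                     float(rec.QUAL or 0.0)))
    return calls


def _dedup(calls: Sequence[SNPCall]) -> List[SNPCall]:
    seen: Dict[Tuple[str, int, str, str], SNPCall] = {}
    dups = 0
    for c in calls:
        key = (c.chrom, c.pos, c.ref_allele, c.alt_allele)
        if key in seen:
            dups += 1
            continue
        seen[key] = c
    if dups:
        warnings.warn(f"{dups} duplicate called records deduplicated")
    return list(seen.values())


def match_snps(truth: Sequence[SNPCall], called: Sequence[SNPCall],
               min_qual: float = 20.0) -> EvalResult:
    """Match calls with qual > min_qual (strict) to the truth on exact
    (chrom, pos, ref, alt)."""
    truth_keys = {(c.chrom, c.pos, c.ref_allele, c.alt_allele) for c in truth}
    kept = _dedup([c for c in called if c.qual > min_qual])
    tp = sum(1 for c in kept
             if (c.chrom, c.pos, c.ref_allele, c.alt_allele) in truth_keys)
    fp = len(kept) - tp
    fn = len(truth_keys) - tp
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall = precision_recall(tp, fp, fn)
    return EvalResult(min_qual, tp, fp, fn, precision, recall)


def pr_curve(truth: Sequence[SNPCall], called: Sequence[SNPCall],
             thresholds: Sequence[float] = (10, 15, 20, 25, 30, 35, 40)
             ) -> pd.DataFrame:
    """Precision/recall at each quality threshold (one row each)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        r = match_snps(truth, called, min_qual=t)
        rows.append({"THRESHOLD": t, "TP": r.tp, "FP": r.fp, "FN": r.fn,
                     "PRECISION": r.precision, "RECALL": r.recall})
    return pd.DataFrame(rows)


def delta_report(before: EvalResult, after: EvalResult
                 ) -> Tuple[float, float]:
    """Relative percent change of precision and recall:
    ``100 * (after - before) / before``."""
    if before.threshold != after.threshold:
        raise ValueError("results must be at the same threshold")
    if before.precision == 0 or before.recall == 0:
        raise ValueError("relative change undefined from zero")
    dp = 100.0 * (after.precision - before.precision) / before.precision
    dr = 100.0 * (after.recall - before.recall) / before.recall
    return dp, dr


# ----------------------------------------------------------------------
# optional external-caller integration

def call_variants_bcftools(bam_path: str, ref_fasta: str, out_vcf: str,
                           extra_mpileup_args: Sequence[str] = ("-A", "-B"),
                           ) -> str:
    """Call variants with bcftools (must be on PATH).

    Defaults keep the caller as permissive as possible: ``-A`` counts
    anomalous read pairs and ``-B`` disables BAQ realignment.
    """
    if shutil.which("bcftools") is None:
        raise RuntimeError("bcftools not found on PATH; stage 'call' needs it "
                           "or a precomputed VCF")
    mpileup = subprocess.run(
        ["bcftools", "mpileup", *extra_mpileup_args, "-f", ref_fasta,
         bam_path, "-O", "u"],
        check=True, capture_output=True)
    subprocess.run(
        ["bcftools", "call", "-m", "-v", "-O", "v", "-o", out_vcf],
        input=mpileup.stdout, check=True, capture_output=True)
    return out_vcf
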
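"""Truth-tracked synthetic sequencing universe.

Everything downstream of read alignment in this package can be exercised
without external genomes, aligners or read simulators: this module
generates a reference with controllable repeat content, implants
SNPs/INDELs/SVs into two haplotypes, simulates paired-end Illumina-like
reads whose names encode their reference-coordinate origin, and
fabricates aligner-style SAM records (AS/XS/YS/NM/XM/XO/XG tags, flags,
TLEN) with a controlled fraction of deliberately misplaced reads whose
truth labels are returned alongside the file.

Default settings mirror a low-coverage plant resequencing experiment:
100 bp paired-end reads at 3x depth, fragment lengths Normal(240, 80),
roughly one small variant per 3,000 bp, and a per-cycle base-quality
profile decaying from ~Q38 to ~Q28 across the read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pysam

from .alignment_io import AlignmentRecord

__all__ = [
    "VariantRecord",
    "SimConfig",
    "QualityProfile",
    "ReadOrigin",
    "CoordMap",
    "generate_reference",
    "generate_variants",
    "write_truth_vcf",
    "implant_variants",
    "build_quality_profile",
    "default_quality_profile",
    "sample_fragment_lengths",
    "simulate_reads",
    "encode_origin",
    "parse_origin",
    "fabricate_alignments",
    "write_fasta",
    "read_fasta",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ----------------------------------------------------------------------
# domain types

@dataclass
class VariantRecord:
    """One implanted variant; ``pos`` is 1-based, alleles VCF-style
    (anchored for INDELs)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str  # SNP | INS | DEL | DUP | INV
    genotype: str  # hom | het
    length: int = 0  # SV length in bp (0 for small variants)
    het_hap: int = 1  # haplotype carrying a het variant

    @property
    def ref_end(self) -> int:
        """Last 1-based reference base touched by the variant."""
        if self.vtype == "DUP":
            return self.pos + self.length - 1
        if self.vtype == "INV":
            return self.pos + self.length - 1
        return self.pos + len(self.ref_allele) - 1


@dataclass
class SimConfig:
    """Read-simulation settings (paper-like defaults)."""

    read_len: int = 100
    coverage: float = 3.0
    frag_mean: float = 240.0
    frag_sd: float = 80.0
    snp_rate: float = 1 / 3500.0
    indel_rate: float = 1 / 21000.0
    sv_count: Dict[str, int] = field(default_factory=dict)
    quality_profile: Optional["QualityProfile"] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.frag_mean < self.read_len:
            raise ValueError("frag_mean must be >= read_len")
        if self.frag_sd < 0:
            raise ValueError("frag_sd must be >= 0")


class QualityProfile:
    """Per-cycle empirical distribution over Phred base-quality scores."""

    def __init__(self, scores: np.ndarray, probs: np.ndarray):
        scores = np.asarray(scores, dtype=int)
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != scores.size:
            raise ValueError("probs must be (n_cycles, n_scores)")
        sums = probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each cycle's probabilities must sum to 1")
        self.scores = scores
        self.probs = probs
        self._cum = np.cumsum(probs, axis=1)

    @property
    def n_cycles(self) -> int:
        return self.probs.shape[0]

    def mean_per_cycle(self) -> np.ndarray:
        return self.probs @ self.scores

    def sample(self, rng: np.random.Generator, n_reads: int = 1) -> np.ndarray:
        """Draw an (n_reads, n_cycles) matrix of Phred scores."""
        u = rng.random((n_reads, self.n_cycles))
        idx = np.empty((n_reads, self.n_cycles), dtype=int)
        for c in range(self.n_cycles):
            idx[:, c] = np.searchsorted(self._cum[c], u[:, c], side="right")
        idx = np.minimum(idx, self.scores.size - 1)
        return self.scores[idx]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("CYCLE\tSCORE\tPROB\n")
            for c in range(self.n_cycles):
                for s, p in zip(self.scores, self.probs[c]):
                    if p > 0:
                        fh.write(f"{c + 1}\t{s}\t{p:.8g}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "QualityProfile":
        cycles: Dict[int, Dict[int, float]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("CYCLE"):
                raise ValueError("quality-profile TSV must have a CYCLE header")
            for line in fh:
                c, s, p = line.split("\t")
                cycles.setdefault(int(c), {})[int(s)] = float(p)
        n_cycles = max(cycles)
        scores = sorted({s for d in cycles.values() for s in d})
        probs = np.zeros((n_cycles, len(scores)))
        score_idx = {s: i for i, s in enumerate(scores)}
        for c, d in cycles.items():
            for s, p in d.items():
                probs[c - 1, score_idx[s]] = p
        return cls(np.array(scores), probs)


@dataclass(frozen=True)
class ReadOrigin:
    """True reference-coordinate origin of a read pair.

    ``chrom/start/end/strand`` describe the first-in-pair read,
    ``mate_*`` the second; coordinates are 1-based inclusive on the
    *reference* (not the haplotype).
    """

    hap_index: int
    chrom: str
    start: int
    end: int
    strand: str
    mate_chrom: str
    mate_start: int
    mate_end: int
    mate_strand: str
    serial: int = 0

    def span_for_mate(self, mate: int) -> Tuple[str, int, int, str]:
        """(chrom, start, end, strand) for mate 1 or 2."""
        if mate == 2:
            return (self.mate_chrom, self.mate_start, self.mate_end, self.mate_strand)
        return (self.chrom, self.start, self.end, self.strand)


_ORIGIN_RE = re.compile(
    r"^sim:([12]):([^:]+):(\d+):(\d+):([+-]):([^:]+):(\d+):(\d+):([+-]):(\d+)$"
)


def encode_origin(origin: ReadOrigin) -> str:
    """Origin -> read name, ``sim:HAP:CHROM:START:END:STRAND:MCHROM:MSTART:MEND:MSTRAND:SERIAL``."""
    return (
        f"sim:{origin.hap_index}:{origin.chrom}:{origin.start}:{origin.end}:"
        f"{origin.strand}:{origin.mate_chrom}:{origin.mate_start}:"
        f"{origin.mate_end}:{origin.mate_strand}:{origin.serial}"
    )


def parse_origin(read_name: str) -> Optional[ReadOrigin]:
    """Inverse of :func:`encode_origin`; ``None`` for foreign names."""
    m = _ORIGIN_RE.match(read_name)
    if m is None:
        return None
    return ReadOrigin(
        hap_index=int(m.group(1)),
        chrom=m.group(2),
        start=int(m.group(3)),
        end=int(m.group(4)),
        strand=m.group(5),
        mate_chrom=m.group(6),
        mate_start=int(m.group(7)),
        mate_end=int(m.group(8)),
        mate_strand=m.group(9),
        serial=int(m.group(10)),
    )


# ----------------------------------------------------------------------
# FASTA helpers

def write_fasta(reference: Dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            out[entry.name] = entry.sequence.upper()
    return out


# ----------------------------------------------------------------------
# reference generation

def generate_reference(n_chroms: int, chrom_len: int, repeat_fraction: float,
                       seed: int) -> Dict[str, str]:
    """Random ACGT reference with ``repeat_fraction`` of each chromosome
    built from tandem/dispersed copies of short seed motifs, so that
    multi-mapping and low-complexity regions exist."""
    if chrom_len < 1000:
        raise ValueError("chrom_len must be >= 1000")
    if not (0 <= repeat_fraction < 1):
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))

    def random_seq(n: int) -> str:
        return "".join(_BASES[rng.integers(0, 4, n)])

    out: Dict[str, str] = {}
    for ci in range(n_chroms):
        if repeat_fraction == 0:
            out[f"chr{ci + 1}"] = random_seq(chrom_len)
            continue
        motif_pool: List[str] = []
        parts: List[str] = []
        total = 0
        repeat_bases = 0
        while total < chrom_len:
            # greedy: emit repeat segments until the running fraction is met
            if repeat_bases < repeat_fraction * max(total, 1):
                # tandem copies of a new motif, or a dispersed copy of an old one
                if motif_pool and rng.random() < 0.5:
                    motif = motif_pool[rng.integers(len(motif_pool))]
                else:
                    motif = random_seq(int(rng.integers(50, 300)))
                    motif_pool.append(motif)
                seg = motif * int(rng.integers(2, 8))
                repeat_bases += len(seg)
            else:
                seg = random_seq(int(rng.integers(500, 2000)))
            parts.append(seg)
            total += len(seg)
        out[f"chr{ci + 1}"] = "".join(parts)[:chrom_len]
    return out


# ----------------------------------------------------------------------
# variant generation

_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def generate_variants(reference: Dict[str, str], snp_rate: float,
                      indel_rate: float, sv_counts: Optional[Dict[str, int]] = None,
                      seed: int = 0, het_fraction: float = 0.5,
                      sv_len: int = 1000, max_retries: int = 20) -> List[VariantRecord]:
    """Place non-overlapping SNPs, short INDELs (1-10 bp) and SVs.

    Per-chromosome SNP/INDEL counts are binomial draws at the given
    per-base rates; genotypes are het with probability ``het_fraction``.
    """
    if snp_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    sv_counts = dict(sv_counts or {})
    rng = np.random.Generator(np.random.PCG64(seed))
    variants: List[VariantRecord] = []
    for chrom, seq in reference.items():
        L = len(seq)
        placed: List[Tuple[int, int]] = []  # (start, end) 1-based occupied spans

        def free(start: int, end: int) -> bool:
            for s, e in placed:
                if start <= e and s <= end:
                    return False
            return True

        def genotype() -> str:
            return "het" if rng.random() < het_fraction else "hom"

        # SVs first (largest footprint)
        for vtype, count in sv_counts.items():
            for _ in range(count):
                ok = False
                for _ in range(max_retries):
                    pos = int(rng.integers(2, L - sv_len - 1))
                    if free(pos, pos + sv_len - 1):
                        ok = True
                        break
                if not ok:
                    raise RuntimeError(
                        f"could not place {vtype} on {chrom} after {max_retries} retries")
                placed.append((pos, pos + sv_len - 1))
                if vtype == "DEL":
                    ref = seq[pos - 2: pos - 1 + sv_len]  # anchor + deleted span
                    variants.append(VariantRecord(chrom, pos - 1, ref, ref[0],
                                                  "DEL", genotype(), sv_len))
                elif vtype == "DUP":
                    span = seq[pos - 1: pos - 1 + sv_len]
                    variants.append(VariantRecord(chrom, pos, seq[pos - 1],
                                                  seq[pos - 1] + span, "DUP",
                                                  genotype(), sv_len))
                elif vtype == "INV":
                    span = seq[pos - 1: pos - 1 + sv_len]
                    variants.append(VariantRecord(chrom, pos, span, revcomp(span),
                                                  "INV", genotype(), sv_len))
                else:
                    raise ValueError(f"unknown SV type {vtype!r}")

        n_snp = rng.binomial(L, snp_rate) if snp_rate > 0 else 0
        n_indel = rng.binomial(L, indel_rate) if indel_rate > 0 else 0
        budget = (n_snp + n_indel) * max_retries + max_retries
        while n_snp > 0 and budget > 0:
            budget -= 1
            pos = int(rng.integers(1, L + 1))
            refb = seq[pos - 1]
            if refb not in _ALT or not free(pos, pos):
                continue
            alt = _ALT[refb][rng.integers(3)]
            variants.append(VariantRecord(chrom, pos, refb, alt, "SNP", genotype()))
            placed.append((pos, pos))
            n_snp -= 1
        while n_indel > 0 and budget > 0:
            budget -= 1
            ilen = int(rng.integers(1, 11))
            ins = rng.random() < 0.5
            pos = int(rng.integers(2, L - ilen))
            span_end = pos if ins else pos + ilen
            if not free(pos, span_end):
                continue
            anchor = seq[pos - 1]
            if anchor not in _ALT:
                continue
            if ins:
                extra = "".join("ACGT"[rng.integers(4)] for _ in range(ilen))
                variants.append(VariantRecord(chrom, pos, anchor, anchor + extra,
                                              "INS", genotype()))
            else:
                ref = seq[pos - 1: pos + ilen]
                variants.append(VariantRecord(chrom, pos, ref, anchor, "DEL",
                                              genotype()))
            placed.append((pos, span_end))
            n_indel -= 1
        if n_snp > 0 or n_indel > 0:
            raise RuntimeError(
                f"could not place all variants on {chrom}: density unsatisfiable")
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def write_truth_vcf(variants: Sequence[VariantRecord],
                    reference: Dict[str, str], path: str,
                    sample: str = "SIM") -> None:
    """Write implanted variants as a VCF 4.2 truth set with GT."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##INFO=<ID=VTYPE,Number=1,Type=String,Description="Simulated variant type">')
    for chrom, seq in reference.items():
        header.contigs.add(chrom, length=len(seq))
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele))
            rec.info["VTYPE"] = v.vtype
            gt = (1, 1) if v.genotype == "hom" else (0, 1)
            rec.samples[sample]["GT"] = gt
            out.write(rec)


# ----------------------------------------------------------------------
# haplotype implantation + coordinate maps

class CoordMap:
    """Monotone haplotype -> reference coordinate map (1-based).

    Built from mapping blocks: linear blocks invert exactly; positions
    inside inserted material map to the insertion's reference anchor.
    """

    def __init__(self, hap_starts: np.ndarray, ref_starts: np.ndarray,
                 linear: np.ndarray, hap_len: int, ref_len: int):
        self.hap_starts = hap_starts
        self.ref_starts = ref_starts
        self.linear = linear
        self.hap_len = hap_len
        self.ref_len = ref_len

    def hap_to_ref(self, pos: int) -> int:
        if not (1 <= pos <= self.hap_len):
            raise ValueError(f"haplotype position {pos} out of range")
        i = int(np.searchsorted(self.hap_starts, pos, side="right")) - 1
        if self.linear[i]:
            return int(self.ref_starts[i] + (pos - self.hap_starts[i]))
        return int(self.ref_starts[i])


class _MapBuilder:
    def __init__(self) -> None:
        self.hap_starts: List[int] = []
        self.ref_starts: List[int] = []
        self.linear: List[bool] = []
        self.hap_pos = 1
        self.ref_pos = 1

    def emit_linear(self, length: int) -> None:
        if length <= 0:
            return
        self.hap_starts.append(self.hap_pos)
        self.ref_starts.append(self.ref_pos)
        self.linear.append(True)
        self.hap_pos += length
        self.ref_pos += length

    def emit_insert(self, length: int, anchor_ref: int) -> None:
        if length <= 0:
            return
        self.hap_starts.append(self.hap_pos)
        self.ref_starts.append(anchor_ref)
        self.linear.append(False)
        self.hap_pos += length

    def skip_ref(self, length: int) -> None:
        self.ref_pos += length

    def build(self, ref_len: int) -> CoordMap:
        return CoordMap(np.array(self.hap_starts), np.array(self.ref_starts),
                        np.array(self.linear), self.hap_pos - 1, ref_len)


def implant_variants(reference: Dict[str, str], variants: Sequence[VariantRecord]
                     ) -> Tuple[List[Dict[str, str]], List[Dict[str, CoordMap]]]:
    """Apply variants to two haplotypes.

    Hom variants go to both haplotypes, het variants to ``het_hap``
    only.  Returns ``([hap1_seqs, hap2_seqs], [hap1_maps, hap2_maps])``.
    Overlapping variants raise a consistency error.
    """
    by_chrom: Dict[str, List[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.pos)
        for a, b in zip(vs, vs[1:]):
            if b.pos <= a.ref_end:
                raise ValueError(
                    f"overlapping variants on {chrom} at {a.pos} and {b.pos}")
    haps: List[Dict[str, str]] = [{}, {}]
    maps: List[Dict[str, CoordMap]] = [{}, {}]
    for hap_idx in (1, 2):
        for chrom, seq in reference.items():
            vs = [v for v in by_chrom.get(chrom, [])
                  if v.genotype == "hom" or v.het_hap == hap_idx]
            parts: List[str] = []
            mb = _MapBuilder()
            cur = 1  # next unconsumed 1-based reference position
            for v in vs:
                if v.ref_allele != seq[v.pos - 1: v.pos - 1 + len(v.ref_allele)] \
                        and v.vtype not in ("DUP",):
                    raise ValueError(
                        f"variant at {chrom}:{v.pos} ref allele mismatch")
                pre = v.pos - cur
                parts.append(seq[cur - 1: v.pos - 1])
                mb.emit_linear(pre)
                if v.vtype == "SNP":
                    parts.append(v.alt_allele)
                    mb.emit_linear(1)
                    cur = v.pos + 1
                elif v.vtype in ("INS", "DUP"):
                    parts.append(v.alt_allele)
                    mb.emit_linear(1)  # anchor base
                    mb.emit_insert(len(v.alt_allele) - 1, v.pos)
                    cur = v.pos + 1
                elif v.vtype == "DEL":
                    parts.append(v.alt_allele)
                    mb.emit_linear(1)  # anchor base
                    mb.skip_ref(len(v.ref_allele) - 1)
                    cur = v.pos + len(v.ref_allele)
                elif v.vtype == "INV":
                    parts.append(v.alt_allele)
                    mb.emit_linear(len(v.alt_allele))  # approx: linear within
                    cur = v.pos + len(v.ref_allele)
                else:
                    raise ValueError(f"unknown variant type {v.vtype!r}")
            parts.append(seq[cur - 1:])
            mb.emit_linear(len(seq) - cur + 1)
            haps[hap_idx - 1][chrom] = "".join(parts)
            maps[hap_idx - 1][chrom] = mb.build(len(seq))
    return haps, maps


# ----------------------------------------------------------------------
# quality profiles

def build_quality_profile(fastq_paths: Sequence[str]) -> QualityProfile:
    """Empirical per-cycle Phred distribution from FASTQ files."""
    counts: Optional[np.ndarray] = None
    read_len: Optional[int] = None
    for path in fastq_paths:
        with pysam.FastxFile(path) as fh:
            for entry in fh:
                quals = entry.get_quality_array()
                if quals is None:
                    raise ValueError(f"FASTQ record without qualities in {path}")
                if read_len is None:
                    read_len = len(quals)
                    counts = np.zeros((read_len, 94), dtype=np.int64)
                elif len(quals) != read_len:
                    raise ValueError(
                        f"mixed read lengths: expected {read_len}, got {len(quals)}")
                counts[np.arange(read_len), np.asarray(quals)] += 1
    if counts is None or counts.sum() == 0:
        raise ValueError("no reads found in FASTQ inputs")
    used = counts.sum(axis=0) > 0
    scores = np.nonzero(used)[0]
    probs = counts[:, used] / counts.sum(axis=1, keepdims=True)
    return QualityProfile(scores, probs)


def default_quality_profile(read_len: int = 100) -> QualityProfile:
    """Built-in profile: per-cycle mean decaying Q38 -> Q28 across the
    read with a discretised-normal spread (sd 4, support [2, 40])."""
    scores = np.arange(2, 41)
    means = np.linspace(38.0, 28.0, read_len)
    sd = 4.0
    z = (scores[None, :] - means[:, None]) / sd
    probs = np.exp(-0.5 * z ** 2)
    probs /= probs.sum(axis=1, keepdims=True)
    return QualityProfile(scores, probs)


# ----------------------------------------------------------------------
# read simulation

def sample_fragment_lengths(n: int, mean: float, sd: float,
                            rng: np.random.Generator,
                            min_len: Optional[int] = None,
                            max_len: Optional[int] = None) -> np.ndarray:
    """Normal(mean, sd) fragment lengths, rounded to int.

    Optional bounds are enforced by resampling (truncation), not
    clamping, so no point mass accumulates at the bound.
    """
    out = np.rint(rng.normal(mean, sd, n)).astype(int)
    if min_len is not None or max_len is not None:
        lo = min_len if min_len is not None else -np.inf
        hi = max_len if max_len is not None else np.inf
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = np.rint(rng.normal(mean, sd, int(bad.sum()))).astype(int)
            bad = (out < lo) | (out > hi)
    return out


def _inject_errors(seq: np.ndarray, quals: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Substitute bases with probability 10^(-Q/10), uniformly among the
    three alternatives.  ``seq`` is an integer array (0..3)."""
    p_err = 10.0 ** (-quals / 10.0)
    hit = rng.random(seq.size) < p_err
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, n)
        seq = seq.copy()
        seq[hit] = (seq[hit] + shift) % 4
    return seq


_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _seq_to_int(seq: str, rng: np.random.Generator) -> np.ndarray:
    arr = np.array([_BASE_IDX.get(b, -1) for b in seq], dtype=int)
    unknown = arr < 0
    if unknown.any():
        arr[unknown] = rng.integers(0, 4, int(unknown.sum()))
    return arr


def simulate_reads(haplotypes: List[Dict[str, str]],
                   coord_maps: List[Dict[str, CoordMap]],
                   config: SimConfig,
                   out_prefix: str) -> Tuple[str, str, int]:
    """Simulate FR paired-end reads from two haplotypes.

    The number of pairs is ``round(coverage * reference_length /
    (2 * read_len))``, split evenly across haplotypes.  Read names
    encode the pair's reference-coordinate origin.  Returns
    ``(fastq1, fastq2, n_pairs)``.
    """
    rl = config.read_len
    profile = config.quality_profile or default_quality_profile(rl)
    if profile.n_cycles != rl:
        raise ValueError("quality profile cycle count != read_len")
    ref_len = sum(m.ref_len for m in coord_maps[0].values())
    n_pairs = int(round(config.coverage * ref_len / (2 * rl)))
    rng = np.random.Generator(np.random.PCG64(config.seed))

    chroms = list(haplotypes[0].keys())
    for hap in haplotypes:
        for chrom in chroms:
            if len(hap[chrom]) < rl:
                raise ValueError(f"chromosome {chrom} shorter than read_len")
    # pre-convert haplotype sequences to int arrays once
    hap_int = [{c: _seq_to_int(h[c], rng) for c in chroms} for h in haplotypes]
    hap_lens = [{c: len(h[c]) for c in chroms} for h in haplotypes]
    weights = [np.array([hap_lens[i][c] for c in chroms], dtype=float)
               for i in range(2)]
    weights = [w / w.sum() for w in weights]

    f1 = f"{out_prefix}_1.fastq"
    f2 = f"{out_prefix}_2.fastq"
    qual_batch = profile.sample(rng, 2 * n_pairs) if n_pairs else \
        np.zeros((0, rl), dtype=int)
    with open(f1, "w") as out1, open(f2, "w") as out2:
        for serial in range(n_pairs):
            hap = serial % 2  # even split across haplotypes
            chrom = chroms[rng.choice(len(chroms), p=weights[hap])]
            clen = hap_lens[hap][chrom]
            frag = int(sample_fragment_lengths(
                1, config.frag_mean, config.frag_sd, rng,
                min_len=rl, max_len=clen)[0])
            start = int(rng.integers(1, clen - frag + 2))  # 1-based hap coord
            left = (start, start + rl - 1)
            right = (start + frag - rl, start + frag - 1)
            cmap = coord_maps[hap][chrom]
            spans_ref = [
                tuple(sorted((cmap.hap_to_ref(left[0]), cmap.hap_to_ref(left[1])))),
                tuple(sorted((cmap.hap_to_ref(right[0]), cmap.hap_to_ref(right[1])))),
            ]
            seq = hap_int[hap][chrom]
            left_seq = seq[left[0] - 1: left[1]]
            right_seq = seq[right[0] - 1: right[1]]
            # FR library: read1 is the left mate on '+' or right mate on '-'
            if rng.random() < 0.5:
                r1_int, r1_strand, r1_span = left_seq, "+", spans_ref[0]
                r2_int, r2_strand, r2_span = right_seq, "-", spans_ref[1]
            else:
                r1_int, r1_strand, r1_span = right_seq, "-", spans_ref[1]
                r2_int, r2_strand, r2_span = left_seq, "+", spans_ref[0]
            q1 = qual_batch[2 * serial]
            q2 = qual_batch[2 * serial + 1]
            r1_int = _inject_errors(r1_int, q1, rng)
            r2_int = _inject_errors(r2_int, q2, rng)
            r1 = "".join(_BASES[r1_int])
            r2 = "".join(_BASES[r2_int])
            if r1_strand == "-":
                r1 = revcomp(r1)
                q1 = q1[::-1]
            if r2_strand == "-":
                r2 = revcomp(r2)
                q2 = q2[::-1]
            origin = ReadOrigin(
                hap_index=hap + 1, chrom=chrom,
                start=r1_span[0], end=r1_span[1], strand=r1_strand,
                mate_chrom=chrom, mate_start=r2_span[0], mate_end=r2_span[1],
                mate_strand=r2_strand, serial=serial)
            name = encode_origin(origin)
            out1.write(f"@{name}/1\n{r1}\n+\n"
                       + "".join(chr(q + 33) for q in q1) + "\n")
            out2.write(f"@{name}/2\n{r2}\n+\n"
                       + "".join(chr(q + 33) for q in q2) + "\n")
    return f1, f2, n_pairs


# ----------------------------------------------------------------------
# fabricated alignments

_GAP_OPEN = 5
_GAP_EXTEND = 3
_MISMATCH = 6
MIN_ALIGN_SCORE = -61  # end-to-end minimum for 100 bp reads


def _parse_ext_cigar(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cigar)]


def _collapse_to_sam_cigar(ops: List[Tuple[int, str]]) -> str:
    """Collapse =/X into M runs."""
    sam_ops: List[Tuple[int, str]] = []
    for n, op in ops:
        op = "M" if op in "=X" else op
        if sam_ops and sam_ops[-1][1] == op:
            sam_ops[-1] = (sam_ops[-1][0] + n, op)
        else:
            sam_ops.append((n, op))
    return "".join(f"{n}{op}" for n, op in sam_ops)


def _affine_realign(read: str, window: str) -> Tuple[List[Tuple[int, str]], int]:
    """Affine-gap semi-global alignment (gap open 5, extend 3).

    Unit-cost edit-distance alignment scatters a single multi-base
    indel into several small gaps with misaligned bases in between;
    real aligners use affine penalties and recover one clean gap, so
    gapped placements are refined here.  Returns (=/X/I/D op runs,
    target start offset).
    """
    from biotite.sequence import NucleotideSequence
    from biotite.sequence.align import SubstitutionMatrix, align_optimal

    mat = SubstitutionMatrix.std_nucleotide_matrix()
    aln = align_optimal(NucleotideSequence(read), NucleotideSequence(window),
                        mat, gap_penalty=(-_GAP_OPEN, -_GAP_EXTEND),
                        terminal_penalty=False)[0]
    trace = aln.trace
    q_rows = np.flatnonzero(trace[:, 0] >= 0)
    first, last = q_rows[0], q_rows[-1]
    t_start = int(trace[:first, 1].max(initial=-1)) + 1
    ops: List[Tuple[int, str]] = []
    for q, t in trace[first:last + 1]:
        if q >= 0 and t >= 0:
            op = "=" if read[q] == window[t] else "X"
        elif q >= 0:
            op = "I"
        else:
            op = "D"
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + 1, op)
        else:
            ops.append((1, op))
    return ops, t_start


def _align_stats(read: str, window: str) -> Tuple[int, int, int, int, int, str, int]:
    """Align a read against a reference window, aligner-style.

    Fast unit-cost (edlib) infix alignment first; placements
    containing gaps are refined with affine gap penalties.  Returns
    (NM, XM, XO, XG, AS, cigar, target_start_offset).
    """
    res = edlib.align(read, window, mode="HW", task="path")
    ops = _parse_ext_cigar(res["cigar"] or f"{len(read)}M")
    start = res["locations"][0][0] if res["locations"] else 0
    if any(op in "ID" for _, op in ops):
        ops, start = _affine_realign(read, window)
    xm = sum(n for n, op in ops if op == "X")
    gaps = [(n, op) for n, op in ops if op in "ID"]
    xo = len(gaps)
    xg = sum(n for n, _ in gaps)
    nm = xm + xg
    score = -(_MISMATCH * xm + sum(_GAP_OPEN + _GAP_EXTEND * n for n, _ in gaps))
    return nm, xm, xo, xg, score, _collapse_to_sam_cigar(ops), start


def _fabricated_mapq(as_score: int, xs_score: Optional[int],
                     min_score: int = MIN_ALIGN_SCORE) -> int:
    """Aligner-style MAPQ from AS/XS, mimicking Bowtie2's end-to-end
    table: unique high-scoring alignments get 42, equal-best get 1,
    others fall off with the best/secondary score gap.  Only loosely
    calibrated — the point of the package is to replace these scores.
    """
    norm = max(0.0, min(1.0, (as_score - min_score) / float(-min_score)))
    if xs_score is None:
        if norm >= 0.8:
            return 42
        if norm >= 0.6:
            return 24
        if norm >= 0.4:
            return 8
        return 3
    if xs_score >= as_score:
        return 1  # multi-mapped
    diff = as_score - xs_score
    if diff >= 30:
        base = 40
    elif diff >= 20:
        base = 31
    elif diff >= 10:
        base = 25
    elif diff >= 5:
        base = 18
    else:
        base = 10
    return max(0, base - 10) if norm < 0.5 else base


def fabricate_alignments(fastq1: str, fastq2: str, reference: Dict[str, str],
                         mislocation_rate: float, seed: int, out_sam: str,
                         window_pad: int = 15,
                         xs_prob_correct: float = 0.3,
                         xs_prob_misplaced: float = 0.9,
                         multimap_prob: float = 0.02,
                         ) -> Dict[Tuple[str, int], int]:
    """Aligner-free stand-in producing Bowtie2-style SAM records.

    Each read is placed at its true origin with probability
    ``1 - mislocation_rate``, otherwise at a random other position.
    NM/XM/XO/XG and the CIGAR are computed by edit-distance alignment of
    the read against the reference window at its placement, so misplaced
    reads naturally carry elevated edit distances and degraded alignment
    scores.  Returns the truth labels ``{(name, mate): 0|1}`` (1 =
    misplaced), matching the placement decisions.
    """
    if not (0 <= mislocation_rate < 1):
        raise ValueError("mislocation_rate must be in [0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    chroms = list(reference.keys())
    clens = np.array([len(reference[c]) for c in chroms], dtype=float)
    cweights = clens / clens.sum()

    labels: Dict[Tuple[str, int], int] = {}
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    })

    def placements_for(origin: ReadOrigin, mate: int, read_len: int
                       ) -> Tuple[str, int, int]:
        """(chrom, pos, label) for one mate."""
        chrom, start, end, _ = origin.span_for_mate(mate)
        if rng.random() < mislocation_rate:
            for _ in range(20):
                ci = rng.choice(len(chroms), p=cweights)
                wrong_chrom = chroms[ci]
                wrong_pos = int(rng.integers(
                    1, len(reference[wrong_chrom]) - read_len + 1))
                if wrong_chrom != chrom or abs(wrong_pos - start) > 2 * read_len:
                    return wrong_chrom, wrong_pos, 1
        return chrom, start, 0

    with pysam.AlignmentFile(out_sam, "w", header=header) as out, \
            pysam.FastxFile(fastq1) as fq1, pysam.FastxFile(fastq2) as fq2:
        for e1, e2 in zip(fq1, fq2):
            name = e1.name.rsplit("/", 1)[0]
            origin = parse_origin(name)
            if origin is None:
                raise ValueError(f"read name without parseable origin: {e1.name}")
            mates = []
            for mate, entry in ((1, e1), (2, e2)):
                seq = entry.sequence.upper()
                quals = entry.get_quality_array()
                _, _, _, strand = origin.span_for_mate(mate)
                # reference-oriented sequence for the SAM record
                if strand == "-":
                    ref_seq = revcomp(seq)
                    ref_quals = quals[::-1]
                else:
                    ref_seq = seq
                    ref_quals = quals
                chrom, pos, label = placements_for(origin, mate, len(seq))
                ref = reference[chrom]
                w_start = max(0, pos - 1 - window_pad)
                w_end = min(len(ref), pos - 1 + len(seq) + window_pad)
                nm, xm, xo, xg, as_score, cigar, t_off = _align_stats(
                    ref_seq, ref[w_start:w_end])
                final_pos = w_start + t_off + 1
                if label == 1:
                    # a real aligner would only report a wrong placement
                    # if it scores plausibly; keep the random pos
                    pass
                xs: Optional[int] = None
                if label == 0:
                    if rng.random() < multimap_prob:
                        xs = as_score
                    elif rng.random() < xs_prob_correct:
                        xs = as_score - int(rng.integers(4, 24))
                else:
                    if rng.random() < xs_prob_misplaced:
                        xs = as_score - int(rng.integers(0, 7))
                mapq = _fabricated_mapq(as_score, xs)
                mates.append(dict(
                    mate=mate, chrom=chrom, pos=final_pos, strand=strand,
                    seq=ref_seq, quals=list(ref_quals), nm=nm, xm=xm, xo=xo,
                    xg=xg, as_score=as_score, xs=xs, mapq=mapq, cigar=cigar,
                    label=label,
                    ref_span=sum(int(n) for n, op in
                                 re.findall(r"(\d+)([MIDNSHP=X])", cigar)
                                 if op in "MDN")))
            m1, m2 = mates
            same_chrom = m1["chrom"] == m2["chrom"]
            lo = min(m1["pos"], m2["pos"])
            hi = max(m1["pos"] + m1["ref_span"], m2["pos"] + m2["ref_span"]) - 1
            tlen_abs = hi - lo + 1 if same_chrom else 0
            fr = same_chrom and m1["strand"] != m2["strand"]
            proper = (fr and m1["label"] == 0 and m2["label"] == 0
                      and tlen_abs < 2 * len(m1["seq"]) + 1000)
            for m, other in ((m1, m2), (m2, m1)):
                flag = 0x1  # paired
                if proper:
                    flag |= 0x2
                if m["strand"] == "-":
                    flag |= 0x10
                if other["strand"] == "-":
                    flag |= 0x20
                flag |= 0x40 if m["mate"] == 1 else 0x80
                if same_chrom:
                    if m["pos"] <= other["pos"]:
                        tlen = tlen_abs
                    else:
                        tlen = -tlen_abs
                else:
                    tlen = 0
                tags = {"AS": m["as_score"], "NM": m["nm"], "XM": m["xm"],
                        "XO": m["xo"], "XG": m["xg"], "YS": other["as_score"]}
                if m["xs"] is not None:
                    tags["XS"] = m["xs"]
                rec = AlignmentRecord(
                    read_name=name, flag=flag, chrom=m["chrom"], pos=m["pos"],
                    mapq=m["mapq"], cigar=m["cigar"], rnext=other["chrom"],
                    pnext=other["pos"], tlen=tlen, seq=m["seq"],
                    quals=m["quals"], tags=tags)
                from .alignment_io import _to_pysam
                out.write(_to_pysam(rec, header))
                labels[(name, m["mate"])] = m["label"]
    return labels
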
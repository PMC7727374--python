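"""Reading, writing and MAPQ-rewriting of SAM/BAM alignments.

This module owns the alignment data model shared by the rest of the
package.  All parsing and serialisation is delegated to :mod:`pysam`;
records cross module boundaries as lightweight :class:`AlignmentRecord`
objects with 1-based leftmost coordinates (SAM convention).

Read identity throughout the package is the *read key*:
``(read name, mate)`` where ``mate`` is 1 for first-in-pair and 2 for
second-in-pair (0 for unpaired reads).  Secondary and supplementary
alignments are never rewritten and never contribute features or labels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import pysam

__all__ = [
    "AlignmentRecord",
    "read_key",
    "read_alignments",
    "write_alignments",
    "rewrite_mapq",
    "subsample",
]


@dataclass
class AlignmentRecord:
    """One SAM alignment line.

    ``pos`` is the 1-based leftmost aligned reference base; ``quals`` are
    per-base Phred integers; ``tags`` maps two-letter SAM tags (AS, XS,
    YS, NM, XM, XO, XG, ...) to their native-typed values.
    """

    read_name: str
    flag: int
    chrom: Optional[str]
    pos: int  # 1-based; 0 for unmapped
    mapq: int
    cigar: Optional[str]
    rnext: Optional[str]
    pnext: int
    tlen: int
    seq: Optional[str]
    quals: Optional[List[int]]
    tags: Dict[str, object] = field(default_factory=dict)

    # -- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & 0x1)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & 0x2)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def mate_is_unmapped(self) -> bool:
        return bool(self.flag & 0x8)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def mate_is_reverse(self) -> bool:
        return bool(self.flag & 0x20)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & 0x40)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & 0x80)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    @property
    def is_primary_mapped(self) -> bool:
        return not (self.is_unmapped or self.is_secondary or self.is_supplementary)

    @property
    def mate(self) -> int:
        """1 for first-in-pair, 2 for second, 0 for unpaired."""
        if self.is_read1:
            return 1
        if self.is_read2:
            return 2
        return 0

    def key(self) -> Tuple[str, int]:
        return (self.read_name, self.mate)

    def reference_span(self) -> int:
        """Number of reference bases consumed by the CIGAR (M/D/N/=/X)."""
        if not self.cigar or self.cigar == "*":
            return 0
        n = 0
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MDN=X":
                    n += int(num)
                num = ""
        return n

    def reference_end(self) -> int:
        """1-based inclusive rightmost aligned reference base."""
        return self.pos + self.reference_span() - 1


def read_key(name: str, mate: int) -> Tuple[str, int]:
    """Canonical read key: (read name, 1|2 for mate, 0 if unpaired)."""
    return (name, mate)


# ----------------------------------------------------------------------
# pysam conversion

def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    quals = list(seg.query_qualities) if seg.query_qualities is not None else None
    return AlignmentRecord(
        read_name=seg.query_name,
        flag=seg.flag,
        chrom=seg.reference_name,
        pos=(seg.reference_start + 1) if seg.reference_start is not None and seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=seg.cigarstring,
        rnext=seg.next_reference_name,
        pnext=(seg.next_reference_start + 1) if seg.next_reference_start >= 0 else 0,
        tlen=seg.template_length,
        seq=seg.query_sequence,
        quals=quals,
        tags=dict(seg.get_tags()),
    )


def _to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.read_name
    seg.flag = rec.flag
    if rec.chrom is not None:
        try:
            seg.reference_id = header.get_tid(rec.chrom)
        except KeyError:
            raise ValueError(f"record references unknown chrom {rec.chrom!r}")
        if seg.reference_id < 0:
            raise ValueError(f"record references unknown chrom {rec.chrom!r}")
    else:
        seg.reference_id = -1
    seg.reference_start = rec.pos - 1 if rec.pos >= 1 else -1
    seg.mapping_quality = rec.mapq
    seg.cigarstring = rec.cigar if rec.cigar not in (None, "*") else None
    if rec.rnext is not None:
        seg.next_reference_id = header.get_tid(rec.rnext)
    else:
        seg.next_reference_id = -1
    seg.next_reference_start = rec.pnext - 1 if rec.pnext >= 1 else -1
    seg.template_length = rec.tlen
    seg.query_sequence = rec.seq
    if rec.quals is not None:
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in rec.quals)
        )
    for tag, value in rec.tags.items():
        vtype = None
        if isinstance(value, int):
            vtype = "i"
        elif isinstance(value, float):
            vtype = "f"
        seg.set_tag(tag, value, value_type=vtype)
    return seg


# ----------------------------------------------------------------------
# operations

def read_alignments(path: str) -> Tuple[List[AlignmentRecord], pysam.AlignmentHeader]:
    """Read every record of a SAM/BAM file, in file order.

    Returns ``(records, header)``; tag values keep native types so a
    round trip through :func:`write_alignments` is lossless.
    """
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
    except FileNotFoundError:
        raise FileNotFoundError(f"alignment file not found: {path}")
    except ValueError as exc:
        raise ValueError(f"cannot parse alignment file {path}: {exc}") from exc
    with af:
        header = af.header
        records = []
        for i, seg in enumerate(af):
            try:
                records.append(_from_pysam(seg))
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed record at index {i} in {path}: {exc}") from exc
    return records, header


def iter_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Stream records without materialising the whole file."""
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for seg in af:
            yield _from_pysam(seg)


def write_alignments(records, header, path: str, fmt: str = "sam") -> None:
    """Write records under ``header`` as SAM (text) or BAM (binary)."""
    if fmt not in ("sam", "bam"):
        raise ValueError(f"format must be 'sam' or 'bam', got {fmt!r}")
    mode = "w" if fmt == "sam" else "wb"
    if not isinstance(header, pysam.AlignmentHeader):
        header = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for rec in records:
            out.write(_to_pysam(rec, header))


def rewrite_mapq(in_path: str, out_path: str, new_mapq: Dict[Tuple[str, int], int],
                 fmt: str = "sam") -> int:
    """Copy an alignment file, replacing MAPQ for keyed primary records.

    Only the MAPQ column of records whose read key appears in
    ``new_mapq`` changes; record count and order are preserved.
    Unmapped, secondary and supplementary records pass through
    untouched.  Returns the number of records updated.
    """
    for key, q in new_mapq.items():
        if not (0 <= q <= 254):
            raise ValueError(f"MAPQ for {key} out of range [0, 254]: {q}")
    records, header = read_alignments(in_path)
    seen: Dict[Tuple[str, int], int] = {}
    count = 0
    for rec in records:
        if not rec.is_primary_mapped:
            continue
        key = rec.key()
        if key in new_mapq:
            seen[key] = seen.get(key, 0) + 1
            if seen[key] > 1:
                raise ValueError(f"read key {key} matches multiple primary alignments")
            rec.mapq = int(new_mapq[key])
            count += 1
    write_alignments(records, header, out_path, fmt=fmt)
    return count


def subsample(in_path: str, out_path: str, fraction: float, seed: int,
              fmt: str = "sam") -> int:
    """Keep each read *pair* with probability ``fraction``.

    Mates are kept or dropped together (decision keyed on the read
    name), mirroring ``samtools view -s``.  Returns records written.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    records, header = read_alignments(in_path)
    rng = random.Random(seed)
    decision: Dict[str, bool] = {}
    kept = []
    for rec in records:
        if rec.read_name not in decision:
            decision[rec.read_name] = rng.random() < fraction
        if decision[rec.read_name]:
            kept.append(rec)
    write_alignments(kept, header, out_path, fmt=fmt)
    return len(kept)
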
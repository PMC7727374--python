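"""Shared fixtures: a small truth-tracked simulation universe and
hand-built SAM/VCF fixtures, all generated programmatically."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from mapqcal import alignment_io, features, simgen


@pytest.fixture(scope="session")
def small_universe(tmp_path_factory):
    """2 x 100 kb reference with tomato-like variant density, 3x
    100 bp paired reads, fabricated alignments with 1% misplacement
    (inflated from the paper-like ~0.17% so the minority class has
    enough rows for unit tests)."""
    root = tmp_path_factory.mktemp("universe")
    ref = simgen.generate_reference(2, 100_000, 0.15, seed=11)
    variants = simgen.generate_variants(ref, 1 / 3500, 1 / 21000, seed=12)
    haps, maps = simgen.implant_variants(ref, variants)
    cfg = simgen.SimConfig(seed=13)
    fq1, fq2, n_pairs = simgen.simulate_reads(haps, maps, cfg, str(root / "u"))
    sam = str(root / "u.sam")
    labels = simgen.fabricate_alignments(fq1, fq2, ref, 0.01, 14, sam)
    records, header = alignment_io.read_alignments(sam)
    return dict(ref=ref, variants=variants, haps=haps, maps=maps,
                fq1=fq1, fq2=fq2, n_pairs=n_pairs, sam=sam, labels=labels,
                records=records, header=header, root=root)


@pytest.fixture(scope="session")
def training_universe(tmp_path_factory):
    """~50k fabricated reads at 0.5% mislocation: the easy-regime
    parameter-recovery fixture for classifier training."""
    root = tmp_path_factory.mktemp("training")
    ref = simgen.generate_reference(1, 1_670_000, 0.15, seed=41)
    variants = simgen.generate_variants(ref, 1 / 3500, 1 / 21000, seed=42)
    haps, maps = simgen.implant_variants(ref, variants)
    cfg = simgen.SimConfig(seed=43)
    fq1, fq2, _ = simgen.simulate_reads(haps, maps, cfg, str(root / "t"))
    sam = str(root / "t.sam")
    labels = simgen.fabricate_alignments(fq1, fq2, ref, 0.005, 44, sam)
    records, _ = alignment_io.read_alignments(sam)
    table = features.feature_table(records, ref, labels=labels)
    return dict(ref=ref, sam=sam, labels=labels, records=records, table=table)


@pytest.fixture(scope="session")
def small_feature_table(small_universe):
    return features.feature_table(small_universe["records"],
                                  small_universe["ref"],
                                  labels=small_universe["labels"])


@pytest.fixture()
def fixture_sam(tmp_path):
    """A hand-built 10-record SAM (5 proper pairs) with aligner tags."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 10_000}, {"SN": "chr2", "LN": 8_000}],
    })
    path = str(tmp_path / "fixture.sam")
    rng = np.random.default_rng(7)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in range(5):
            pos1 = 100 + 500 * i
            pos2 = pos1 + 180
            for mate, (pos, mpos, flag) in enumerate(
                    [(pos1, pos2, 0x1 | 0x2 | 0x20 | 0x40),
                     (pos2, pos1, 0x1 | 0x2 | 0x10 | 0x80)]):
                seg = pysam.AlignedSegment(header)
                seg.query_name = f"read{i}"
                seg.flag = flag
                seg.reference_id = 0
                seg.reference_start = pos
                seg.mapping_quality = 40 - i
                seg.cigarstring = "50M"
                seg.next_reference_id = 0
                seg.next_reference_start = mpos
                seg.template_length = 230 if mate == 0 else -230
                seg.query_sequence = "".join(rng.choice(list("ACGT"), 50))
                seg.query_qualities = pysam.qualitystring_to_array("I" * 50)
                seg.set_tag("AS", -5 - i, value_type="i")
                if i % 2 == 0:
                    seg.set_tag("XS", -10 - i, value_type="i")
                seg.set_tag("NM", i, value_type="i")
                seg.set_tag("XM", i, value_type="i")
                seg.set_tag("XO", 0, value_type="i")
                seg.set_tag("XG", 0, value_type="i")
                seg.set_tag("YS", -5 - i, value_type="i")
                out.write(seg)
    return path


def make_gaussian_problem(n: int, prevalence: float, separation: float,
                          n_features: int = 4, seed: int = 0):
    """Overlapping-Gaussian binary problem with a rare positive class.

    Majority at the origin, minority shifted by ``separation`` (in SD
    units) along every axis; small separation = hard problem.
    """
    rng = np.random.default_rng(seed)
    n_pos = max(2, int(round(n * prevalence)))
    n_neg = n - n_pos
    X_neg = rng.normal(0.0, 1.0, (n_neg, n_features))
    X_pos = rng.normal(separation, 1.0, (n_pos, n_features))
    X = np.vstack([X_neg, X_pos])
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    perm = rng.permutation(n)
    # range-scale to [0, 1] as the training contract requires
    X = X[perm]
    X = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
    return X, y[perm]
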
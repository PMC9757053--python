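"""Interval engine: exact agreement with a per-base boolean-array oracle,
bedtools cross-checks, and the random-placement null."""

import subprocess

import numpy as np
import pytest

from cisnet.intervals import (
    GenomicInterval,
    IntervalSet,
    MutationRecord,
    closest_tss,
    flank_regions,
    intersect_intervals,
    intersect_mutations,
    merge_intervals,
    read_bed,
    read_mutations_tsv,
    read_mutations_vcf,
    shuffle_mutations,
    subtract_intervals,
    write_bed,
    write_mutations_tsv,
)
from cisnet.mapping import TSSRecord

CHROM_LEN = 10_000
GENOME = {"chr1": CHROM_LEN, "chr2": CHROM_LEN}


def to_mask(s: IntervalSet) -> dict:
    masks = {c: np.zeros(CHROM_LEN, dtype=bool) for c in GENOME}
    for iv in s:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def from_random(rng, n=50):
    ivs = []
    for _ in range(int(rng.integers(0, n + 1))):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, CHROM_LEN - 1))
        end = int(rng.integers(start + 1, min(start + 500, CHROM_LEN) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs, genome=GENOME)


def mask_to_intervals(masks) -> set:
    out = set()
    for chrom, m in masks.items():
        padded = np.concatenate([[False], m, [False]]).astype(int)
        d = np.diff(padded)
        for s, e in zip(np.where(d == 1)[0], np.where(d == -1)[0]):
            out.add((chrom, int(s), int(e)))
    return out


def as_tuples(s: IntervalSet) -> set:
    return {(iv.chrom, iv.start, iv.end) for iv in s}


def test_merge_examples():
    a = IntervalSet([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 15)])
    assert as_tuples(merge_intervals(a)) == {("chr1", 0, 15)}
    # book-ended intervals merge, matching the reference tool's default
    b = IntervalSet([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)])
    assert as_tuples(merge_intervals(b)) == {("chr1", 0, 20)}
    assert as_tuples(merge_intervals(IntervalSet([]))) == set()


def test_malformed_interval_identifies_record():
    with pytest.raises(ValueError, match="chr1:10-5"):
        GenomicInterval("chr1", 10, 5)


def test_merge_subtract_intersect_match_per_base_oracle(rng):
    """100 random instances: set algebra agrees base-by-base with boolean
    arrays, except that merge also joins book-ended runs (checked via
    coverage equality)."""
    for _ in range(100):
        a, b = from_random(rng), from_random(rng)
        ma, mb = to_mask(a), to_mask(b)
        merged = merge_intervals(a)
        assert to_mask(merged).keys() == ma.keys()
        for c in ma:
            np.testing.assert_array_equal(to_mask(merged)[c], ma[c])
        sub = subtract_intervals(a, b)
        inter = intersect_intervals(a, b)
        for c in ma:
            np.testing.assert_array_equal(to_mask(sub)[c], ma[c] & ~mb[c])
            np.testing.assert_array_equal(to_mask(inter)[c], ma[c] & mb[c])
        # merged output is sorted, non-overlapping, non-bookended per chrom
        assert as_tuples(merged) == mask_to_intervals(ma)


def test_flank_matches_per_base_oracle(rng):
    for _ in range(50):
        a = from_random(rng, n=20)
        excl = from_random(rng, n=20)
        width = int(rng.choice([100, 500, 1000]))
        got = flank_regions(a, width, exclude=excl)
        ma, me = to_mask(a), to_mask(excl)
        expect = {c: np.zeros(CHROM_LEN, dtype=bool) for c in GENOME}
        for iv in a:
            expect[iv.chrom][max(0, iv.start - width) : iv.start] = True
            expect[iv.chrom][iv.end : min(CHROM_LEN, iv.end + width)] = True
        for c in expect:
            np.testing.assert_array_equal(to_mask(got)[c], expect[c] & ~me[c])


def test_flank_examples():
    s = IntervalSet([GenomicInterval("chr1", 1000, 1010)], genome=GENOME)
    fl = flank_regions(s, 100, exclude=s)
    assert as_tuples(fl) == {("chr1", 900, 1000), ("chr1", 1010, 1110)}
    # truncation at the chromosome start: left flank vanishes
    s2 = IntervalSet([GenomicInterval("chr1", 0, 10)], genome=GENOME)
    assert as_tuples(flank_regions(s2, 100, exclude=s2)) == {("chr1", 10, 110)}


def test_flank_requires_genome():
    s = IntervalSet([GenomicInterval("chr1", 100, 200)])
    with pytest.raises(ValueError, match="genome"):
        flank_regions(s, 100)


def test_merge_idempotent_and_subadditive(rng):
    for _ in range(20):
        a, b = from_random(rng), from_random(rng)
        m = merge_intervals(a)
        assert as_tuples(merge_intervals(m)) == as_tuples(m)
        both = merge_intervals(IntervalSet(list(a) + list(b), genome=GENOME))
        assert both.total_length <= m.total_length + merge_intervals(b).total_length


def test_agrees_with_bedtools(rng, tmp_path):
    """Independent oracle: bedtools merge/subtract on a random instance."""
    a, b = from_random(rng), from_random(rng)
    if len(a) == 0 or len(b) == 0:
        a = IntervalSet([GenomicInterval("chr1", 5, 25)], genome=GENOME)
        b = IntervalSet([GenomicInterval("chr1", 10, 15)], genome=GENOME)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(IntervalSet(sorted(a)), fa)
    write_bed(IntervalSet(sorted(b)), fb)
    try:
        merged = subprocess.run(
            ["bedtools", "merge", "-i", str(fa)], capture_output=True, text=True,
            check=True,
        ).stdout
    except (FileNotFoundError, subprocess.CalledProcessError):
        pytest.skip("bedtools unavailable")
    expect = {
        (f[0], int(f[1]), int(f[2]))
        for f in (line.split("\t") for line in merged.strip().split("\n") if line)
    }
    assert as_tuples(merge_intervals(a)) == expect
    sub = subprocess.run(
        ["bedtools", "subtract", "-a", str(fa.with_suffix(".m.bed")), "-b", str(fb)],
        capture_output=True, text=True,
    )
    # subtract against our merged output to compare normalized forms
    write_bed(merge_intervals(a), fa.with_suffix(".m.bed"))
    sub = subprocess.run(
        ["bedtools", "subtract", "-a", str(fa.with_suffix(".m.bed")), "-b", str(fb)],
        capture_output=True, text=True, check=True,
    ).stdout
    expect_sub = {
        (f[0], int(f[1]), int(f[2]))
        for f in (line.split("\t") for line in sub.strip().split("\n") if line)
    }
    got = as_tuples(subtract_intervals(a, b))
    # bedtools subtract does not re-merge book-ended leftovers; compare masks
    def cover(tuples):
        m = {c: np.zeros(CHROM_LEN, bool) for c in GENOME}
        for c, s, e in tuples:
            m[c][s:e] = True
        return m
    for c in GENOME:
        np.testing.assert_array_equal(cover(got)[c], cover(expect_sub)[c])


class TestMutationIntersection:
    REGIONS = IntervalSet([GenomicInterval("chr1", 0, 10)], genome=GENOME)

    def test_snv_inside_kept(self):
        m = MutationRecord("s1", "chr1", 5, "A", "T")
        assert intersect_mutations([m], self.REGIONS) == [m]

    def test_snv_at_half_open_end_dropped(self):
        m = MutationRecord("s1", "chr1", 10, "A", "T")
        assert intersect_mutations([m], self.REGIONS) == []

    def test_deletion_partial_overlap_kept(self):
        m = MutationRecord("s1", "chr1", 8, "AAA", "A", variant_class="deletion")
        assert intersect_mutations([m], self.REGIONS) == [m]
        m2 = MutationRecord("s1", "chr1", 10, "AAA", "A", variant_class="deletion")
        assert intersect_mutations([m2], self.REGIONS) == []

    def test_missing_chromosome_skipped(self):
        m = MutationRecord("s1", "chrX", 5, "A", "T")
        assert intersect_mutations([m], self.REGIONS) == []

    def test_matches_per_base_oracle(self, rng):
        regions = from_random(rng)
        muts = []
        for _ in range(200):
            pos = int(rng.integers(0, CHROM_LEN - 5))
            span = int(rng.integers(1, 4))
            muts.append(
                MutationRecord("s", "chr1", pos, "A" * span,
                               "A" if span > 1 else "T",
                               variant_class="deletion" if span > 1 else "SNV")
            )
        mask = to_mask(regions)["chr1"]
        expect = [m for m in muts if mask[m.pos : m.end].any()]
        assert intersect_mutations(muts, regions) == expect

    def test_idempotent_and_order_preserving(self, rng):
        regions = from_random(rng)
        muts = [
            MutationRecord("s", "chr1", int(p), "A", "T")
            for p in rng.integers(0, CHROM_LEN, 100)
        ]
        once = intersect_mutations(muts, regions)
        assert intersect_mutations(once, regions) == once


class TestShuffle:
    def test_counts_and_class_multiset_preserved(self, rng):
        muts = [MutationRecord("s", "chr1", i * 10, "A", "T") for i in range(5)]
        muts += [
            MutationRecord("s", "chr2", i * 10, "AAT", "A", variant_class="deletion")
            for i in range(3)
        ]
        out = shuffle_mutations(muts, GENOME, seed=1)
        assert sum(m.chrom == "chr1" for m in out) == 5
        assert sum(m.chrom == "chr2" for m in out) == 3
        assert sorted(m.variant_class for m in out) == sorted(
            m.variant_class for m in muts
        )
        assert all(0 <= m.pos and m.end <= GENOME[m.chrom] for m in out)

    def test_deterministic(self):
        muts = [MutationRecord("s", "chr1", i, "A", "T") for i in range(10)]
        a = shuffle_mutations(muts, GENOME, seed=7)
        b = shuffle_mutations(muts, GENOME, seed=7)
        assert a == b
        assert a != shuffle_mutations(muts, GENOME, seed=8)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrX"):
            shuffle_mutations([MutationRecord("s", "chrX", 1, "A", "T")], GENOME, 0)


class TestClosestTSS:
    TSS = [
        TSSRecord("gA", "chr1", 100),
        TSSRecord("gB", "chr1", 1000),
    ]

    def test_nearest_wins(self):
        assert closest_tss(GenomicInterval("chr1", 450, 460), self.TSS) == "gA"

    def test_contained_tss_distance_zero(self):
        tss = self.TSS + [TSSRecord("gC", "chr1", 455)]
        assert closest_tss(GenomicInterval("chr1", 450, 460), tss) == "gC"

    def test_tie_breaks_to_lower_coordinate(self):
        # interval [450,460): ends at 450 and 459; TSSs at 400 and 509
        # both at distance 50 -> lower coordinate wins
        tss = [TSSRecord("gHigh", "chr1", 509), TSSRecord("gLow", "chr1", 400)]
        assert closest_tss(GenomicInterval("chr1", 450, 460), tss) == "gLow"

    def test_brute_force_distance_scan(self, rng):
        tss = [TSSRecord(f"g{i}", "chr1", int(p))
               for i, p in enumerate(rng.integers(0, CHROM_LEN, 30))]
        for _ in range(50):
            s = int(rng.integers(0, CHROM_LEN - 20))
            iv = GenomicInterval("chr1", s, s + 15)
            def dist(rec):
                if iv.start <= rec.pos < iv.end:
                    return 0
                return min(abs(rec.pos - iv.start), abs(rec.pos - (iv.end - 1)))
            best = min(tss, key=lambda r: (dist(r), r.pos, r.gene_id))
            assert closest_tss(iv, tss) == best.gene_id

    def test_no_tss_on_chromosome(self):
        assert closest_tss(GenomicInterval("chr9", 0, 10), self.TSS) is None


def test_bed_and_mutation_io_round_trip(tmp_path, rng):
    s = from_random(rng, n=20)
    p = tmp_path / "x.bed"
    write_bed(s, p)
    back = read_bed(p, genome=GENOME)
    assert as_tuples(back) == as_tuples(s)
    muts = [
        MutationRecord("s1", "chr1", 10, "A", "T", consequence="stop gained"),
        MutationRecord("s2", "chr2", 99, "AT", "A", variant_class="deletion"),
    ]
    mp = tmp_path / "m.tsv"
    write_mutations_tsv(muts, mp)
    assert read_mutations_tsv(mp) == muts


def test_minimal_vcf_reader(tmp_path):
    vcf = tmp_path / "x.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t11\t.\tA\tT\t.\tPASS\tSAMPLE=s1;CSQ=stop_gained\n"
        "chr2\t5\t.\tAT\tA\t.\tPASS\tSAMPLE=s2\n"
    )
    muts = read_mutations_vcf(vcf)
    assert muts[0].pos == 10 and muts[0].sample_id == "s1"
    assert muts[0].consequence == "stop_gained"
    assert muts[1].variant_class == "deletion"
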
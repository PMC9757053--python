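"""Genomic interval arithmetic: merge, subtract, flank, intersect, shuffle.

All coordinates are 0-based half-open ([start, end)), the BED convention.
1-based inputs (MAF-like mutation tables) are converted at the reader
boundary, never downstream.  Book-ended intervals (a.end == b.start) are
merged, matching the default behaviour of the standard merge tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "MutationRecord",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "flank_regions",
    "intersect_mutations",
    "shuffle_mutations",
    "closest_tss",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_mutations_tsv",
    "write_mutations_tsv",
    "read_mutations_vcf",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic region [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                f"(name={self.name!r}): require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call in one sample.

    ``pos`` is 0-based.  The reference span is ``[pos, pos + ref_span)``
    where SNVs and deletions span ``len(ref)`` bases and insertions anchor
    on a single base.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.variant_class == "SNV" and not (
            len(self.ref) == len(self.alt) == 1
        ):
            raise ValueError(
                f"SNV must have single-base ref/alt, got {self.ref}>{self.alt}"
            )

    @property
    def ref_span(self) -> int:
        """Number of reference bases the variant occupies (>= 1)."""
        if self.variant_class == "insertion":
            return 1  # anchor base only
        return max(1, len(self.ref))

    @property
    def end(self) -> int:
        return self.pos + self.ref_span


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


class IntervalSet:
    """A collection of genomic intervals, optionally bound to a genome.

    ``normalize()`` (called by the set-algebra operations) sorts intervals
    and merges overlapping or book-ended ones per chromosome, after which
    ``total_length`` counts each base once.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome: dict[str, int] | None = dict(genome) if genome is not None else None
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom in self.genome and iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {self.genome[iv.chrom]}"
                    )
        self._normalized = False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return sorted(self.intervals) == sorted(other.intervals)

    @property
    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """(n, 2) start/end arrays per chromosome, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {
            c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
            for c, pairs in out.items()
        }

    def normalize(self) -> "IntervalSet":
        return merge_intervals(self)


def _merge_arr(arr: np.ndarray) -> np.ndarray:
    """Merge a sorted (n, 2) array; book-ended intervals are joined."""
    if len(arr) == 0:
        return arr
    starts, ends = arr[:, 0], arr[:, 1]
    keep_start = [starts[0]]
    keep_end = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= keep_end[-1]:  # overlap or book-ended
            keep_end[-1] = max(keep_end[-1], e)
        else:
            keep_start.append(s)
            keep_end.append(e)
    return np.column_stack([keep_start, keep_end])


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Sort and merge overlapping or book-ended intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(s.by_chrom()):
        for start, end in _merge_arr(s.by_chrom()[chrom]):
            merged.append(GenomicInterval(chrom, int(start), int(end)))
    out = IntervalSet(merged, genome=s.genome)
    out._normalized = True
    return out


def _subtract_arr(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """a minus b, both merged-sorted (n, 2) arrays on one chromosome."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b`` (both merged internally)."""
    am = merge_intervals(a).by_chrom()
    bm = merge_intervals(b).by_chrom()
    res: list[GenomicInterval] = []
    for chrom in sorted(am):
        barr = bm.get(chrom, np.empty((0, 2), dtype=np.int64))
        for s, e in _subtract_arr(am[chrom], barr):
            res.append(GenomicInterval(chrom, int(s), int(e)))
    out = IntervalSet(res, genome=a.genome)
    out._normalized = True
    return out


def intersect_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by both ``a`` and ``b``."""
    am = merge_intervals(a).by_chrom()
    bm = merge_intervals(b).by_chrom()
    res: list[GenomicInterval] = []
    for chrom in sorted(am):
        if chrom not in bm:
            continue
        aarr, barr = am[chrom], bm[chrom]
        i = j = 0
        while i < len(aarr) and j < len(barr):
            s = max(aarr[i, 0], barr[j, 0])
            e = min(aarr[i, 1], barr[j, 1])
            if s < e:
                res.append(GenomicInterval(chrom, int(s), int(e)))
            if aarr[i, 1] <= barr[j, 1]:
                i += 1
            else:
                j += 1
    out = IntervalSet(res, genome=a.genome)
    out._normalized = True
    return out


def flank_regions(
    s: IntervalSet, width: int, exclude: IntervalSet | None = None
) -> IntervalSet:
    """Left+right flanks of width ``width`` around each interval of ``s``,
    truncated at chromosome bounds, merged, minus ``exclude``.

    Used to build the TFBS/exon flanking-region sets at widths 100, 500 and
    1000 nt with the source regions themselves removed.
    """
    if width <= 0:
        raise ValueError("flank width must be positive")
    if s.genome is None:
        raise ValueError("flank_regions requires genome lengths to bound flanks")
    flanks: list[GenomicInterval] = []
    for iv in s:
        if iv.chrom not in s.genome:
            raise ValueError(f"chromosome {iv.chrom} missing from genome")
        clen = s.genome[iv.chrom]
        ls, le = max(0, iv.start - width), iv.start
        if ls < le:
            flanks.append(GenomicInterval(iv.chrom, ls, le))
        rs, re = iv.end, min(clen, iv.end + width)
        if rs < re:
            flanks.append(GenomicInterval(iv.chrom, rs, re))
    fl = merge_intervals(IntervalSet(flanks, genome=s.genome))
    if exclude is not None and len(exclude):
        fl = subtract_intervals(fl, exclude)
    return fl


def intersect_mutations(
    muts: Sequence[MutationRecord], s: IntervalSet
) -> list[MutationRecord]:
    """Mutations whose reference span overlaps any base of ``s``.

    Order is preserved; chromosomes absent from ``s`` are skipped (logged
    once per chromosome).
    """
    regions = merge_intervals(s).by_chrom()
    missing: set[str] = set()
    kept: list[MutationRecord] = []
    for m in muts:
        arr = regions.get(m.chrom)
        if arr is None:
            if m.chrom not in missing:
                logger.info("chromosome %s not in interval set; mutations skipped", m.chrom)
                missing.add(m.chrom)
            continue
        # first region with end > pos; overlap iff its start < mutation end
        i = int(np.searchsorted(arr[:, 1], m.pos, side="right"))
        if i < len(arr) and arr[i, 0] < m.end:
            kept.append(m)
    return kept


def shuffle_mutations(
    muts: Sequence[MutationRecord],
    genome: Mapping[str, int],
    seed: int,
) -> list[MutationRecord]:
    """Random placement null: redraw each mutation's position uniformly on
    its own chromosome, preserving per-chromosome counts and reference
    spans (indels never run off chromosome ends)."""
    rng = np.random.default_rng(seed)
    out: list[MutationRecord] = []
    for m in muts:
        if m.chrom not in genome:
            raise ValueError(f"chromosome {m.chrom} absent from genome")
        hi = genome[m.chrom] - m.ref_span
        if hi < 0:
            raise ValueError(
                f"variant span {m.ref_span} exceeds chromosome {m.chrom}"
            )
        out.append(replace(m, pos=int(rng.integers(0, hi + 1))))
    return out


def closest_tss(
    region: GenomicInterval,
    tss_table: Sequence,
) -> str | None:
    """Gene id of the TSS closest to ``region`` (0 if the TSS lies inside).

    Distance is min(|tss - start|, |tss - (end-1)|).  Ties are broken by
    lowest TSS coordinate, then lexicographic gene id, so assignment is
    deterministic.  Returns None when the chromosome has no TSS.
    """
    best: tuple[int, int, str] | None = None
    for rec in tss_table:
        if rec.chrom != region.chrom:
            continue
        if region.start <= rec.pos < region.end:
            d = 0
        else:
            d = min(abs(rec.pos - region.start), abs(rec.pos - (region.end - 1)))
        key = (d, rec.pos, rec.gene_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


# ---------------------------------------------------------------------------
# I/O: BED3/BED6, chrom.sizes, mutation TSV (1-based), minimal VCF

def read_bed(path: str | Path, genome: Mapping[str, int] | None = None) -> IntervalSet:
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 else None
            ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand))
    return IntervalSet(ivs, genome=genome)


def write_bed(s: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in s:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    genome: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            genome[chrom] = int(size)
    return genome


def write_chrom_sizes(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.items():
            fh.write(f"{chrom}\t{size}\n")


_MUT_COLS = ["sample_id", "chrom", "pos_1based", "ref", "alt", "consequence"]


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    """Tab-separated mutation calls with 1-based positions (MAF-like);
    positions are converted to 0-based here and nowhere else."""
    muts: list[MutationRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in _MUT_COLS if c in header}
        for c in _MUT_COLS[:5]:
            if c not in idx:
                raise ValueError(f"{path}: missing required column {c!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 5 or not f[0]:
                continue
            ref, alt = f[idx["ref"]], f[idx["alt"]]
            cons = f[idx["consequence"]] if "consequence" in idx and len(f) > idx["consequence"] else ""
            muts.append(
                MutationRecord(
                    sample_id=f[idx["sample_id"]],
                    chrom=f[idx["chrom"]],
                    pos=int(f[idx["pos_1based"]]) - 1,
                    ref=ref,
                    alt=alt,
                    variant_class=classify_variant(ref, alt),
                    consequence=cons or None,
                )
            )
    return muts


def write_mutations_tsv(muts: Sequence[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MUT_COLS) + "\n")
        for m in muts:
            fh.write(
                f"{m.sample_id}\t{m.chrom}\t{m.pos + 1}\t{m.ref}\t{m.alt}\t"
                f"{m.consequence or ''}\n"
            )


def read_mutations_vcf(path: str | Path) -> list[MutationRecord]:
    """Minimal VCF 4.x reader: CHROM/POS/REF/ALT plus a SAMPLE info key.

    Multi-sample genotype columns and symbolic alleles are out of scope.
    """
    muts: list[MutationRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, ref, alt = f[0], int(f[1]), f[3], f[4]
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            ) if len(f) > 7 else {}
            sample = info.get("SAMPLE", "unknown")
            cons = info.get("CSQ")
            muts.append(
                MutationRecord(
                    sample_id=sample,
                    chrom=chrom,
                    pos=pos - 1,
                    ref=ref,
                    alt=alt,
                    variant_class=classify_variant(ref, alt),
                    consequence=cons,
                )
            )
    return muts
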
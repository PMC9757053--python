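"""Mutation-to-gene assignment: LoF classification, TFBS->gene mapping via
regulatory elements or closest TSS, and the binary gene x sample matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, MutationRecord, closest_tss

logger = logging.getLogger(__name__)

__all__ = [
    "TSSRecord",
    "ElementGeneMap",
    "MutationMatrix",
    "LOF_TERMS",
    "classify_lof",
    "assign_tfbs_to_genes",
    "build_mutation_matrix",
    "read_tss_table",
    "write_tss_table",
    "read_element_map",
    "write_element_map",
]

# Loss-of-function consequence whitelist: nonsense, frameshift and
# splice-site classes.  Matching is case- and underscore-insensitive.
LOF_TERMS = frozenset(
    {
        "disruptive in-frame deletion",
        "disruptive in-frame insertion",
        "stop gained",
        "start lost",
        "stop lost",
        "stop retained variant",
        "frameshift variant",
        "initiator codon variant",
        "splice region variant",
        "splice donor variant",
        "splice acceptor variant",
    }
)


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    pos: int
    strand: str = "."
    gene_class: str = "protein_coding"  # or "miRNA" (pri-miRNA start)


@dataclass
class ElementGeneMap:
    """Distal regulatory elements (e.g. enhancers) linked to target genes."""

    elements: list[GenomicInterval] = field(default_factory=list)
    genes: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.elements) != len(self.genes):
            raise ValueError("elements and gene lists differ in length")
        for gs in self.genes:
            if not gs:
                raise ValueError("element with empty gene list")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class MutationMatrix:
    """Binary gene x sample association matrix for one mutation channel."""

    values: pd.DataFrame  # 0/1 ints
    channel: str  # "lof" or "cis_tfbs"

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def drop_empty_genes(self) -> "MutationMatrix":
        keep = self.values.sum(axis=1) > 0
        return MutationMatrix(self.values.loc[keep], self.channel)


def _normalize_term(term: str) -> str:
    return term.strip().lower().replace("_", " ")


def classify_lof(consequence: str) -> bool:
    """True iff the consequence term is in the 11-term LoF whitelist."""
    if not consequence:
        raise ValueError("empty consequence term")
    hit = _normalize_term(consequence) in LOF_TERMS
    if not hit and _normalize_term(consequence) not in _SEEN_NON_LOF:
        _SEEN_NON_LOF.add(_normalize_term(consequence))
        logger.debug("non-LoF consequence: %s", consequence)
    return hit


_SEEN_NON_LOF: set[str] = set()


def assign_tfbs_to_genes(
    tfbs: IntervalSet,
    elements: ElementGeneMap | None,
    tss: Sequence[TSSRecord],
) -> dict[GenomicInterval, tuple[str, ...]]:
    """Map each TFBS to its target gene(s).

    A TFBS overlapping an annotated regulatory element is linked to all of
    that element's genes (element overlap takes priority); any other TFBS
    is linked to the single gene with the closest TSS, protein-coding and
    miRNA TSSs pooled.  TFBSs on chromosomes with neither elements nor
    TSSs are flagged unassigned (empty tuple).
    """
    # sorted element arrays per chromosome for binary-search overlap
    elem_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    if elements is not None:
        for i, iv in enumerate(elements.elements):
            elem_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
        for lst in elem_by_chrom.values():
            lst.sort()
    out: dict[GenomicInterval, tuple[str, ...]] = {}
    n_unassigned = 0
    for site in tfbs:
        linked: list[str] = []
        for s, e, i in elem_by_chrom.get(site.chrom, ()):
            if s < site.end and site.start < e:
                linked.extend(elements.genes[i])
        if linked:
            out[site] = tuple(dict.fromkeys(linked))  # dedupe, keep order
            continue
        gene = closest_tss(site, tss)
        if gene is None:
            n_unassigned += 1
            out[site] = ()
        else:
            out[site] = (gene,)
    if n_unassigned:
        logger.warning("%d TFBSs unassignable (no element, no TSS)", n_unassigned)
    return out


def tfbs_mutation_gene_pairs(
    muts: Sequence[MutationRecord],
    tfbs_map: Mapping[GenomicInterval, tuple[str, ...]],
) -> list[tuple[str, str]]:
    """(gene, sample) pairs implied by mutations overlapping mapped TFBSs."""
    by_chrom: dict[str, list[tuple[int, int, tuple[str, ...]]]] = {}
    for site, genes in tfbs_map.items():
        if genes:
            by_chrom.setdefault(site.chrom, []).append((site.start, site.end, genes))
    for lst in by_chrom.values():
        lst.sort()
    pairs: list[tuple[str, str]] = []
    for m in muts:
        for s, e, genes in by_chrom.get(m.chrom, ()):
            if s < m.end and m.pos < e:
                for g in genes:
                    pairs.append((g, m.sample_id))
    return pairs


def build_mutation_matrix(
    pairs: Sequence[tuple[str, str]],
    samples: Sequence[str],
    channel: str,
    z_flags: pd.DataFrame | None = None,
) -> MutationMatrix:
    """Binary gene x sample matrix from qualifying (gene, sample) pairs.

    For the protein-coding cis-TFBS channel a ``z_flags`` boolean frame
    (gene x sample, True where |z| > 1) must be supplied: a cis entry is
    kept only when the mutated gene itself looks dysregulated in that
    sample.  LoF and miRNA cis channels take ``z_flags=None`` (no filter).
    Genes absent from ``z_flags`` are dropped with a warning.
    """
    if channel not in ("lof", "cis_tfbs"):
        raise ValueError(f"unknown channel {channel!r}")
    filtered: list[tuple[str, str]] = []
    dropped_genes: set[str] = set()
    for gene, sample in pairs:
        if sample not in samples:
            continue
        if z_flags is not None:
            if gene not in z_flags.index or sample not in z_flags.columns:
                dropped_genes.add(gene)
                continue
            if not bool(z_flags.at[gene, sample]):
                continue
        filtered.append((gene, sample))
    if dropped_genes:
        logger.warning(
            "%d genes absent from expression dropped from the %s matrix",
            len(dropped_genes), channel,
        )
    genes = sorted({g for g, _ in filtered})
    mat = pd.DataFrame(0, index=genes, columns=list(samples), dtype=int)
    for gene, sample in filtered:
        mat.at[gene, sample] = 1
    return MutationMatrix(mat, channel)


def expand_mirna_arms(
    pairs: Sequence[tuple[str, str]], arms: Mapping[str, Sequence[str]]
) -> list[tuple[str, str]]:
    """Expand pre-miRNA-level (gene, sample) pairs to mature arms.

    A cis mutation mapped to a pri-miRNA TSS marks both mature arms (5p and
    3p) as mutated; each arm is analyzed separately downstream.
    """
    out: list[tuple[str, str]] = []
    for gene, sample in pairs:
        for arm in arms.get(gene, (gene,)):
            out.append((arm, sample))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_tss_table(path: str | Path) -> list[TSSRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TSSRecord(r.gene_id, r.chrom, int(r.pos), getattr(r, "strand", "."),
                  getattr(r, "gene_class", "protein_coding"))
        for r in df.itertuples(index=False)
    ]


def write_tss_table(tss: Sequence[TSSRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(t.gene_id, t.chrom, t.pos, t.strand, t.gene_class) for t in tss],
        columns=["gene_id", "chrom", "pos", "strand", "gene_class"],
    ).to_csv(path, sep="\t", index=False)


def read_element_map(path: str | Path) -> ElementGeneMap:
    """BED3 plus a comma-separated gene-list 4th column."""
    elements: list[GenomicInterval] = []
    genes: list[tuple[str, ...]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            elements.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            genes.append(tuple(f[3].split(",")))
    return ElementGeneMap(elements, genes)


def write_element_map(em: ElementGeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, gs in zip(em.elements, em.genes):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{','.join(gs)}\n")


def write_mutation_matrix(m: MutationMatrix, path: str | Path) -> None:
    """Sparse triplet TSV (gene, sample, 1)."""
    with open(path, "w") as fh:
        fh.write("gene\tsample\tmutated\n")
        for gene in m.genes:
            row = m.values.loc[gene]
            for sample in m.samples[row.to_numpy() == 1]:
                fh.write(f"{gene}\t{sample}\t1\n")


def read_mutation_matrix(
    path: str | Path, samples: Sequence[str], channel: str
) -> MutationMatrix:
    df = pd.read_csv(path, sep="\t")
    pairs = list(zip(df["gene"], df["sample"]))
    return build_mutation_matrix(pairs, samples, channel)
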
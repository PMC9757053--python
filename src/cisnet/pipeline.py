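"""End-to-end orchestration: preprocess -> mutation mapping -> network
update -> hierarchical inference -> shuffled controls -> selection.

Channels are analyzed independently:

* ``lof`` — loss-of-function exonic mutations per gene;
* ``cis_protein_coding`` — TFBS mutations assigned to protein-coding
  genes, prefiltered to samples where the gene itself looks dysregulated
  (|z| > 1);
* ``cis_mirna`` — TFBS mutations assigned to pri-miRNAs, expanded to both
  mature arms, no z prefilter, scored against the miRNA-target network.

All randomness (control shuffles) derives from one master seed via a
counter, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    ExpressionMatrix,
    cpm_log2,
    dysregulation_flags,
    expressed_gene_filter,
    filter_zero_genes,
    gistic_matrix,
    z_values,
)
from .intervals import (
    IntervalSet,
    MutationRecord,
    read_bed,
    read_chrom_sizes,
    read_mutations_tsv,
)
from .mapping import (
    ElementGeneMap,
    MutationMatrix,
    TSSRecord,
    assign_tfbs_to_genes,
    build_mutation_matrix,
    classify_lof,
    expand_mirna_arms,
    read_element_map,
    read_tss_table,
    tfbs_mutation_gene_pairs,
    write_mutation_matrix,
)
from .networks import (
    WeightedNetwork,
    build_mirna_network,
    read_edge_list,
    read_mirna_targets,
    shuffle_mutation_matrix,
    shuffle_network,
    update_weights,
)
from .selection import (
    SelectionConfig,
    fdr_threshold,
    mutation_rate_report,
    select_genes,
    selection_report,
)
from .xseq import XseqPriors, XseqResult, run_cohort

logger = logging.getLogger(__name__)

CHANNELS = ("lof", "cis_protein_coding", "cis_mirna")


@dataclass
class CohortData:
    """All inputs for one cohort, in memory."""

    genome: dict[str, int]
    tfbs: IntervalSet
    exons: IntervalSet
    tss: list[TSSRecord]
    elements: ElementGeneMap
    network: WeightedNetwork
    mirna_network: WeightedNetwork
    arms: dict[str, list[str]]
    mutations: list[MutationRecord]
    counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    cna: pd.DataFrame | None = None
    samples: list[str] = field(default_factory=list)
    pre_normalized: bool = False  # microarray-style input: skip cpm/zero filter

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = list(self.counts.columns)


def load_cohort(path: str | Path) -> CohortData:
    """Read a cohort directory in the on-disk formats the package writes."""
    path = Path(path)
    genome = read_chrom_sizes(path / "genome.chrom.sizes")
    arms: dict[str, list[str]] = {}
    arms_file = path / "mirna_arms.tsv"
    if arms_file.exists():
        df = pd.read_csv(arms_file, sep="\t")
        for r in df.itertuples(index=False):
            arms.setdefault(str(r.pre_mirna), []).append(str(r.arm))
    counts = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
    return CohortData(
        genome=genome,
        tfbs=read_bed(path / "tfbs.bed", genome=genome),
        exons=read_bed(path / "exons.bed", genome=genome),
        tss=read_tss_table(path / "tss.tsv"),
        elements=read_element_map(path / "elements.bed"),
        network=read_edge_list(path / "network.tsv"),
        mirna_network=build_mirna_network(read_mirna_targets(path / "mirna_targets.tsv")),
        arms=arms,
        mutations=read_mutations_tsv(path / "mutations.tsv"),
        counts=counts,
        mirna_counts=pd.read_csv(path / "mirna_counts.tsv", sep="\t", index_col=0),
        cna=gistic_matrix(pd.read_csv(path / "cna.tsv", sep="\t", index_col=0))
        if (path / "cna.tsv").exists()
        else None,
    )


def preprocess_expression(
    counts: pd.DataFrame, pre_normalized: bool = False
) -> ExpressionMatrix:
    """Zero-gene filter then log2(cpm + 1); bypassed for pre-normalized
    (microarray) matrices."""
    if pre_normalized:
        return ExpressionMatrix(counts.astype(float), normalized=True)
    return cpm_log2(filter_zero_genes(counts))


@dataclass
class ChannelResult:
    channel: str
    mut_matrix: MutationMatrix
    updated_network: WeightedNetwork
    result: XseqResult
    control_dacs: list[list[float]]
    t: float
    selected: list[str]
    report: pd.DataFrame


def build_channel_matrix(
    data: CohortData,
    channel: str,
    expr: ExpressionMatrix,
    z_flags: pd.DataFrame | None,
) -> MutationMatrix:
    """Construct the binary gene x sample matrix for one channel."""
    if channel == "lof":
        exon_map: dict = {}
        for iv in data.exons:
            if iv.name:
                exon_map[iv] = (iv.name,)
        lof_muts = [
            m for m in data.mutations if m.consequence and classify_lof(m.consequence)
        ]
        pairs = tfbs_mutation_gene_pairs(lof_muts, exon_map)
        return build_mutation_matrix(pairs, data.samples, "lof").drop_empty_genes()
    tfbs_map = assign_tfbs_to_genes(data.tfbs, data.elements, data.tss)
    pairs = tfbs_mutation_gene_pairs(data.mutations, tfbs_map)
    pc_genes = {t.gene_id for t in data.tss if t.gene_class == "protein_coding"}
    if channel == "cis_protein_coding":
        pairs = [(g, s) for g, s in pairs if g in pc_genes]
        return build_mutation_matrix(
            pairs, data.samples, "cis_tfbs", z_flags=z_flags
        ).drop_empty_genes()
    if channel == "cis_mirna":
        pairs = [(g, s) for g, s in pairs if g not in pc_genes]
        pairs = expand_mirna_arms(pairs, data.arms)
        return build_mutation_matrix(pairs, data.samples, "cis_tfbs").drop_empty_genes()
    raise ValueError(f"unknown channel {channel!r}")


def run_channel(
    data: CohortData,
    channel: str = "cis_protein_coding",
    priors: XseqPriors = XseqPriors(),
    sel_cfg: SelectionConfig = SelectionConfig(),
    master_seed: int = 0,
    de_alpha: float = 0.05,
) -> ChannelResult:
    """One channel end to end, including the empirical-FDR controls.

    Control runs shuffle the (updated) network and the mutation matrix
    with seeds derived from ``master_seed`` by a counter; expression is
    never shuffled, so partner status mixtures are fitted once and shared
    across the observed run and all controls.
    """
    expr = preprocess_expression(data.counts, data.pre_normalized)
    keep = expressed_gene_filter(expr)
    expr = expr.subset(keep)
    z = z_values(expr)
    flags = dysregulation_flags(z)
    mut = build_channel_matrix(data, channel, expr, flags)
    net = data.mirna_network if channel == "cis_mirna" else data.network
    updated = update_weights(net, mut, expr.values, alpha=de_alpha)
    cna = data.cna
    result = run_cohort(
        mut, expr, updated, cna=cna, priors=priors, mixture_cache={}, compute_grs=True
    )
    cache: dict = {}
    control_dacs: list[list[float]] = []
    rng = np.random.default_rng([master_seed, 7])
    seeds = rng.integers(0, 2**31 - 1, size=(sel_cfg.n_controls, 2))
    for i in range(sel_cfg.n_controls):
        if mut.values.empty:
            control_dacs.append([])
            continue
        null_net = shuffle_network(updated, int(seeds[i, 0]))
        null_mut = shuffle_mutation_matrix(mut, int(seeds[i, 1]))
        null_res = run_cohort(
            null_mut, expr, null_net, cna=cna, priors=priors,
            mixture_cache=cache, compute_grs=False,
        )
        control_dacs.append([r.dac for r in null_res.genes.values()])
    if result.genes:
        t = fdr_threshold(result.dac.to_numpy(), control_dacs, sel_cfg)
        selected = select_genes(result, t, sel_cfg)
    else:
        t, selected = float("inf"), []
    report = selection_report(result, t, sel_cfg)
    return ChannelResult(channel, mut, updated, result, control_dacs, t, selected, report)


def run_pipeline(
    data: CohortData,
    channels: Sequence[str] = ("cis_protein_coding",),
    priors: XseqPriors = XseqPriors(),
    sel_cfg: SelectionConfig = SelectionConfig(),
    master_seed: int = 0,
    outdir: str | Path | None = None,
) -> dict[str, ChannelResult]:
    """Run one or more channels; optionally write all result files plus a
    JSON run manifest recording versions, seeds and realized thresholds."""
    results: dict[str, ChannelResult] = {}
    for ch in channels:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}; choose from {CHANNELS}")
        logger.info("running channel %s", ch)
        results[ch] = run_channel(data, ch, priors, sel_cfg, master_seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "version": __version__,
            "master_seed": master_seed,
            "priors": dataclasses.asdict(priors),
            "selection": dataclasses.asdict(sel_cfg),
            "channels": {},
        }
        for ch, cr in results.items():
            chdir = outdir / ch
            chdir.mkdir(exist_ok=True)
            cr.result.write(chdir)
            write_mutation_matrix(cr.mut_matrix, chdir / "mutation_matrix.tsv")
            cr.report.to_csv(chdir / "selection.tsv", sep="\t", index=False,
                             float_format="%.6f")
            manifest["channels"][ch] = {
                "t": cr.t if np.isfinite(cr.t) else "inf",
                "n_selected": len(cr.selected),
                "selected": cr.selected,
            }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def rates_report(
    data: CohortData,
    n_shuffles: int = 150,
    seed: int = 0,
    flank_widths: Sequence[int] = (100, 500, 1000),
):
    """Per-sample TFBS/exon/flank mutation rates with shuffle expectations."""
    return mutation_rate_report(
        data.mutations, data.tfbs, data.exons, data.genome,
        flank_widths=flank_widths, n_shuffles=n_shuffles, seed=seed,
    )


def checksum_tree(path: str | Path) -> dict[str, str]:
    """SHA-256 of every file under ``path`` (determinism checks)."""
    path = Path(path)
    out = {}
    for f in sorted(path.rglob("*")):
        if f.is_file():
            out[str(f.relative_to(path))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return out
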
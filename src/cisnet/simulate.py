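"""Synthetic cancer-cohort generator with planted cis-regulatory drivers.

Generates everything the pipeline consumes — genome, TFBS/exon/TSS
annotations, element-gene map, weighted networks, somatic mutations,
RNA-seq and small-RNA count matrices, CNA, survival — together with a
machine-readable ground truth, so the full method is testable without any
external data.

The statistical structure mirrors the signal the method looks for: a
planted driver carries TFBS mutations in a fixed set of samples, its own
expression is dysregulated in cis in those samples, and a fraction of its
network partners shift in trans by a configurable effect size.  Baseline
counts are negative-binomial (log-normal gene means, fixed dispersion);
effects are injected by scaling counts on the log2 scale so ground-truth
effect sizes stay exact up to integer rounding.  ``null_mode`` suppresses
every planted effect while leaving the marginal data distributions intact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import cpm_log2
from .intervals import (
    GenomicInterval,
    IntervalSet,
    MutationRecord,
    write_bed,
    write_chrom_sizes,
    write_mutations_tsv,
)
from .mapping import TSSRecord, ElementGeneMap, write_element_map, write_tss_table
from .networks import MiRNATargetRecord, WeightedNetwork

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Annotation",
    "simulate_annotation",
    "simulate_network",
    "simulate_mirna_targets",
    "simulate_cohort",
    "emit_truth",
    "read_truth",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_samples: int = 60
    n_genes: int = 200
    n_mirnas: int = 20
    n_tfbs: int = 1000
    tfbs_length_min: int = 10
    tfbs_length_max: int = 20
    element_fraction: float = 0.5  # TFBSs covered by element-gene records
    n_planted_drivers: int = 5
    n_planted_mirna_drivers: int = 1
    mutated_samples_per_driver: int = 8
    partner_count: int = 20
    effect_size: float = 2.0  # Delta, in units of within-gene sd (log2 scale)
    fraction_partners_affected: float = 0.7
    direction_mix: float = 0.5  # fraction of affected partners shifted up
    background_mutation_rate: float = 1e-5  # per nt per sample
    cna_alteration_rate: float = 0.02
    nb_dispersion: float = 0.2
    mean_log_counts: float = 5.0  # log of log-normal gene mean (expressed class)
    sd_log_counts: float = 1.0
    fraction_low_expressed: float = 0.15  # lowly expressed gene class
    mean_log_counts_low: float = 0.0
    sd_log_counts_low: float = 0.5
    censor_fraction: float = 0.3
    survival_beta: float = 0.8  # log-hazard slope on the designated miRNA
    null_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_mirnas", "n_tfbs",
                     "n_planted_drivers", "mutated_samples_per_driver",
                     "partner_count", "n_chromosomes", "chrom_length"):
            if getattr(self, name) < 0 or (name.startswith("n_") and getattr(self, name) == 0 and name not in ("n_planted_drivers", "n_planted_mirna_drivers")):
                raise ValueError(f"{name} must be positive")
        for name in ("element_fraction", "fraction_partners_affected",
                     "direction_mix", "censor_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown simulation config field(s): {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class Annotation:
    genome: dict[str, int]
    tfbs: IntervalSet
    exons: IntervalSet
    tss: list[TSSRecord]
    elements: ElementGeneMap
    genes: list[str]
    mirnas: list[str]  # pre-miRNA ids
    arms: dict[str, list[str]]  # pre-miRNA -> mature 5p/3p ids
    tfbs_owner: dict[GenomicInterval, str]  # construction-time linkage


@dataclass
class GroundTruth:
    drivers: list[str] = field(default_factory=list)
    driver_samples: dict[str, list[str]] = field(default_factory=dict)
    affected_partners: dict[str, dict[str, int]] = field(default_factory=dict)
    # (gene, sample) -> functional flag
    functional: dict[tuple[str, str], int] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (
            sorted(self.drivers) == sorted(other.drivers)
            and {k: sorted(v) for k, v in self.driver_samples.items()}
            == {k: sorted(v) for k, v in other.driver_samples.items()}
            and self.affected_partners == other.affected_partners
            and self.functional == other.functional
        )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_annotation(cfg: SimulationConfig) -> Annotation:
    """Lay out non-overlapping gene loci with TSSs, exons and TFBSs.

    TFBSs sit within 2 kb upstream of their gene's TSS; a configurable
    fraction is additionally covered by a distal-element record linking it
    to the gene (emulating the element-map/closest-TSS assignment split).
    Loci are spaced so closest-TSS assignment is unambiguous.
    """
    rng = _rng(cfg, 1)
    genome = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
    chroms = list(genome)
    n_loci = cfg.n_genes + cfg.n_mirnas
    per_chrom = int(np.ceil(n_loci / cfg.n_chromosomes))
    spacing = cfg.chrom_length // (per_chrom + 1)
    if spacing < 5000:
        raise ValueError(
            f"genome too small: need >= {(per_chrom + 1) * 5000} nt per "
            "chromosome for the requested loci"
        )
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"MIR{i:03d}" for i in range(cfg.n_mirnas)]
    arms = {m: [f"{m}-5p", f"{m}-3p"] for m in mirnas}
    loci = genes + mirnas
    tss: list[TSSRecord] = []
    exon_ivs: list[GenomicInterval] = []
    locus_pos: dict[str, tuple[str, int]] = {}
    for i, gid in enumerate(loci):
        chrom = chroms[i % cfg.n_chromosomes]
        slot = i // cfg.n_chromosomes
        pos = (slot + 1) * spacing
        gene_class = "protein_coding" if gid in genes else "miRNA"
        tss.append(TSSRecord(gid, chrom, pos, "+", gene_class))
        locus_pos[gid] = (chrom, pos)
        if gene_class == "protein_coding":
            for e in range(3):
                s = pos + 200 + e * 500
                exon_ivs.append(GenomicInterval(chrom, s, s + 150, name=gid))
    # >= 1 TFBS per locus, remainder randomly assigned
    owners = loci * (cfg.n_tfbs // n_loci)
    owners += list(rng.choice(loci, size=cfg.n_tfbs - len(owners), replace=False))
    tfbs_ivs: list[GenomicInterval] = []
    tfbs_owner: dict[GenomicInterval, str] = {}
    elem_ivs: list[GenomicInterval] = []
    elem_genes: list[tuple[str, ...]] = []
    in_element = rng.random(cfg.n_tfbs) < cfg.element_fraction
    for j, gid in enumerate(owners):
        chrom, pos = locus_pos[gid]
        length = int(rng.integers(cfg.tfbs_length_min, cfg.tfbs_length_max + 1))
        offset = int(rng.integers(50, 2000 - length))
        start = max(0, pos - offset - length)
        iv = GenomicInterval(chrom, start, start + length, name=f"TFBS{j:05d}")
        tfbs_ivs.append(iv)
        tfbs_owner[iv] = gid
        if in_element[j]:
            es = max(0, iv.start - 50)
            elem_ivs.append(GenomicInterval(chrom, es, min(iv.end + 50, genome[chrom])))
            elem_genes.append((gid,))
    return Annotation(
        genome=genome,
        tfbs=IntervalSet(tfbs_ivs, genome=genome),
        exons=IntervalSet(exon_ivs, genome=genome),
        tss=tss,
        elements=ElementGeneMap(elem_ivs, elem_genes),
        genes=genes,
        mirnas=mirnas,
        arms=arms,
        tfbs_owner=tfbs_owner,
    )


def simulate_network(cfg: SimulationConfig, genes: Sequence[str]) -> WeightedNetwork:
    """Random prior network: each gene gets ``partner_count`` partners drawn
    uniformly from the other genes, weights Uniform(0.2, 1)."""
    rng = _rng(cfg, 2)
    net = WeightedNetwork()
    genes = list(genes)
    for g in genes:
        others = [x for x in genes if x != g]
        k = min(cfg.partner_count, len(others))
        chosen = rng.choice(others, size=k, replace=False)
        for p in chosen:
            net.add_edge(g, str(p), float(rng.uniform(0.2, 1.0)))
    return net


def simulate_mirna_targets(
    cfg: SimulationConfig, arms: Mapping[str, Sequence[str]], genes: Sequence[str]
) -> list[MiRNATargetRecord]:
    """Predicted miRNA-target records with site counts and context-score
    percentiles for every mature arm."""
    rng = _rng(cfg, 3)
    records: list[MiRNATargetRecord] = []
    genes = list(genes)
    for pre in sorted(arms):
        for arm in arms[pre]:
            chosen = rng.choice(genes, size=min(2 * cfg.partner_count, len(genes)),
                                replace=False)
            for t in chosen:
                records.append(
                    MiRNATargetRecord(
                        mirna_id=arm,
                        target=str(t),
                        n_sites=int(rng.integers(1, 5)),
                        t_score=float(np.round(rng.uniform(1, 100), 2)),
                    )
                )
    return records


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, lib_factor: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts, genes x samples."""
    mu = means[:, None] * lib_factor[None, :]
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_cohort(
    cfg: SimulationConfig,
    annotation: Annotation,
    network: WeightedNetwork,
    mirna_targets: Sequence[MiRNATargetRecord] | None = None,
):
    """Generate mutations, count matrices, CNA, survival and ground truth.

    Returns a dict with keys: mutations (list of MutationRecord), counts
    (genes x samples DataFrame), mirna_counts (pre-miRNAs x samples), cna
    (genes x samples GISTIC ints), survival (list of SurvivalRecord rows as
    DataFrame), truth (GroundTruth).
    """
    from .selection import SurvivalRecord  # local import avoids cycle

    rng = _rng(cfg, 4)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    genes, mirnas = annotation.genes, annotation.mirnas

    # bimodal baseline: an expressed class and a lowly expressed class,
    # the structure the two-Gaussian expressed-gene filter is built for
    low_class = rng.random(len(genes)) < cfg.fraction_low_expressed
    gene_means = np.where(
        low_class,
        np.exp(rng.normal(cfg.mean_log_counts_low, cfg.sd_log_counts_low, len(genes))),
        np.exp(rng.normal(cfg.mean_log_counts, cfg.sd_log_counts, len(genes))),
    )
    mirna_means = np.exp(rng.normal(cfg.mean_log_counts, cfg.sd_log_counts, len(mirnas)))
    lib_factor = np.exp(rng.normal(0, 0.15, cfg.n_samples))
    counts = pd.DataFrame(
        _nb_counts(rng, gene_means, lib_factor, cfg.nb_dispersion),
        index=genes, columns=samples,
    )
    mirna_counts = pd.DataFrame(
        _nb_counts(rng, mirna_means, lib_factor, cfg.nb_dispersion),
        index=mirnas, columns=samples,
    )

    # per-gene baseline sd on the log2 cpm scale, the unit of effect sizes
    base_sd = cpm_log2(counts + 1).values.std(axis=1, ddof=1)
    base_sd_m = cpm_log2(mirna_counts + 1).values.std(axis=1, ddof=1)
    sd_of = dict(zip(genes, base_sd))
    sd_of.update(zip(mirnas, base_sd_m))

    tfbs_by_owner: dict[str, list[GenomicInterval]] = {}
    for iv, gid in annotation.tfbs_owner.items():
        tfbs_by_owner.setdefault(gid, []).append(iv)

    truth = GroundTruth()
    mutations: list[MutationRecord] = []
    bases = np.array(list("ACGT"))

    def plant_driver(driver: str, partner_dirs: dict[str, int]) -> None:
        if driver not in tfbs_by_owner:
            raise ValueError(f"planted driver {driver} has no linked TFBS")
        mut_samples = [str(s) for s in rng.choice(samples,
                       size=cfg.mutated_samples_per_driver, replace=False)]
        truth.drivers.append(driver)
        truth.driver_samples[driver] = mut_samples
        truth.affected_partners[driver] = partner_dirs
        own_dir = 1 if rng.random() < 0.5 else -1
        for s in mut_samples:
            site = tfbs_by_owner[driver][int(rng.integers(len(tfbs_by_owner[driver])))]
            pos = int(rng.integers(site.start, site.end))
            ref, alt = rng.choice(bases, size=2, replace=False)
            mutations.append(MutationRecord(s, site.chrom, pos, str(ref), str(alt)))
            truth.functional[(driver, s)] = 1
            if cfg.null_mode:
                continue
            # cis effect on the driver's (or pre-miRNA's) own expression
            tgt = counts if driver in counts.index else mirna_counts
            sd = sd_of[driver]
            tgt.loc[driver, s] = int(round(
                tgt.at[driver, s] * 2.0 ** (own_dir * cfg.effect_size * sd)
            ))
            # trans effects on affected partners
            for p, d in partner_dirs.items():
                counts.loc[p, s] = int(round(
                    counts.at[p, s] * 2.0 ** (d * cfg.effect_size * sd_of[p])
                ))

    def pick_partner_dirs(partners: Sequence[str]) -> dict[str, int]:
        k = int(round(cfg.fraction_partners_affected * len(partners)))
        chosen = [str(p) for p in rng.choice(list(partners), size=k, replace=False)]
        n_up = int(round(cfg.direction_mix * k))
        dirs = [1] * n_up + [-1] * (k - n_up)
        return dict(zip(chosen, dirs))

    # planted drivers come from the expressed class (a cis-regulatory
    # driver of a silent gene would be invisible to any expression method)
    expressed_genes = [g for g, lo in zip(genes, low_class) if not lo]
    drivers = [str(g) for g in rng.choice(expressed_genes,
                                          size=cfg.n_planted_drivers,
                                          replace=False)]
    for d in drivers:
        plant_driver(d, pick_partner_dirs(list(network.partners(d)) or genes[:cfg.partner_count]))

    target_by_arm: dict[str, list[str]] = {}
    if mirna_targets:
        for r in mirna_targets:
            if r.n_sites >= 2:
                target_by_arm.setdefault(r.mirna_id, []).append(r.target)
    mirna_drivers = [str(m) for m in rng.choice(
        mirnas, size=min(cfg.n_planted_mirna_drivers, len(mirnas)), replace=False)]
    for pre in mirna_drivers:
        arm = annotation.arms[pre][0]
        targets = target_by_arm.get(arm) or []
        plant_driver(pre, pick_partner_dirs(targets) if targets else {})

    # background mutations, uniform over the genome, per sample
    genome_size = sum(annotation.genome.values())
    chroms = list(annotation.genome)
    exon_arrs = annotation.exons.by_chrom()
    cons_terms = ["missense variant", "synonymous variant", "stop gained",
                  "frameshift variant"]
    cons_probs = [0.55, 0.25, 0.1, 0.1]
    for s in samples:
        n_bg = int(rng.poisson(cfg.background_mutation_rate * genome_size))
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(annotation.genome[chrom]))
            ref, alt = rng.choice(bases, size=2, replace=False)
            cons = None
            arr = exon_arrs.get(chrom)
            if arr is not None:
                i = int(np.searchsorted(arr[:, 1], pos, side="right"))
                if i < len(arr) and arr[i, 0] <= pos:
                    cons = str(rng.choice(cons_terms, p=cons_probs))
            mutations.append(
                MutationRecord(s, chrom, pos, str(ref), str(alt), consequence=cons)
            )
    mutations.sort(key=lambda m: (m.chrom, m.pos, m.sample_id))

    cna_vals = rng.choice(
        [-2, -1, 0, 1, 2],
        size=(len(genes), cfg.n_samples),
        p=[cfg.cna_alteration_rate / 4, cfg.cna_alteration_rate / 4,
           1 - cfg.cna_alteration_rate, cfg.cna_alteration_rate / 4,
           cfg.cna_alteration_rate / 4],
    )
    cna = pd.DataFrame(cna_vals, index=genes, columns=samples)

    # survival: exponential, log-hazard linear in one designated miRNA
    marker = mirna_drivers[0] if mirna_drivers else mirnas[0]
    mexp = np.log2(mirna_counts.loc[marker].to_numpy(dtype=float) + 1)
    zm = (mexp - mexp.mean()) / (mexp.std() or 1.0)
    beta = 0.0 if cfg.null_mode else cfg.survival_beta
    hazard = 0.001 * np.exp(beta * zm)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(cfg.n_samples) < cfg.censor_fraction
    survival = pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.round(times, 1),
            "event": (~censored).astype(int),
        }
    )
    surv_records = [
        SurvivalRecord(r.sample_id, float(r.time), int(r.event))
        for r in survival.itertuples(index=False)
    ]
    return {
        "samples": samples,
        "mutations": mutations,
        "counts": counts,
        "mirna_counts": mirna_counts,
        "cna": cna,
        "survival": survival,
        "survival_records": surv_records,
        "truth": truth,
        "survival_marker": marker,
    }


# ---------------------------------------------------------------------------
# ground truth serialization

def emit_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as one tidy TSV (record_type rows)."""
    with open(path, "w") as fh:
        fh.write("record_type\tdriver\tsample\tpartner\tdirection\n")
        for d in gt.drivers:
            fh.write(f"driver\t{d}\t\t\t\n")
            for s in gt.driver_samples.get(d, []):
                fh.write(f"driver_sample\t{d}\t{s}\t\t\n")
            for p, direction in gt.affected_partners.get(d, {}).items():
                fh.write(f"affected_partner\t{d}\t\t{p}\t{direction}\n")
        for (g, s), flag in sorted(gt.functional.items()):
            fh.write(f"functional\t{g}\t{s}\t\t{flag}\n")


def read_truth(path: str | Path) -> GroundTruth:
    gt = GroundTruth()
    with open(path) as fh:
        next(fh)
        for line in fh:
            rt, driver, sample, partner, direction = line.rstrip("\n").split("\t")
            if rt == "driver":
                gt.drivers.append(driver)
                gt.driver_samples.setdefault(driver, [])
                gt.affected_partners.setdefault(driver, {})
            elif rt == "driver_sample":
                gt.driver_samples.setdefault(driver, []).append(sample)
            elif rt == "affected_partner":
                gt.affected_partners.setdefault(driver, {})[partner] = int(direction)
            elif rt == "functional":
                gt.functional[(driver, sample)] = int(direction)
    return gt


def write_cohort(outdir: str | Path, cfg: SimulationConfig) -> Path:
    """Simulate one cohort and write every file the pipeline reads."""
    from .networks import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(cfg)
    net = simulate_network(cfg, ann.genes)
    targets = simulate_mirna_targets(cfg, ann.arms, ann.genes)
    cohort = simulate_cohort(cfg, ann, net, targets)
    write_chrom_sizes(ann.genome, outdir / "genome.chrom.sizes")
    write_bed(ann.tfbs, outdir / "tfbs.bed")
    write_bed(ann.exons, outdir / "exons.bed")
    write_tss_table(ann.tss, outdir / "tss.tsv")
    write_element_map(ann.elements, outdir / "elements.bed")
    write_edge_list(net, outdir / "network.tsv")
    with open(outdir / "mirna_targets.tsv", "w") as fh:
        fh.write("mirna\ttarget\tn_sites\tt_score_percentile\n")
        for r in targets:
            fh.write(f"{r.mirna_id}\t{r.target}\t{r.n_sites}\t{r.t_score}\n")
    with open(outdir / "mirna_arms.tsv", "w") as fh:
        fh.write("pre_mirna\tarm\n")
        for pre, arm_list in sorted(ann.arms.items()):
            for a in arm_list:
                fh.write(f"{pre}\t{a}\n")
    write_mutations_tsv(cohort["mutations"], outdir / "mutations.tsv")
    cohort["counts"].to_csv(outdir / "counts.tsv", sep="\t")
    cohort["mirna_counts"].to_csv(outdir / "mirna_counts.tsv", sep="\t")
    cohort["cna"].to_csv(outdir / "cna.tsv", sep="\t")
    cohort["survival"].to_csv(outdir / "survival.tsv", sep="\t", index=False)
    emit_truth(cohort["truth"], outdir / "truth.tsv")
    cfg.to_yaml(outdir / "sim_config.yaml")
    return outdir
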
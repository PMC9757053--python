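"""Gene selection with empirical FDR from shuffled controls, dysregulation
tables, enrichment and survival tests, and the mutation-rate report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet, MutationRecord, flank_regions, merge_intervals, shuffle_mutations
from .xseq import XseqResult

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SurvivalRecord",
    "fdr_threshold",
    "select_genes",
    "dysregulation_table",
    "hypergeometric_enrichment",
    "bh_adjust",
    "km_logrank",
    "mutation_rate_report",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for calling predicted genes.

    The DAC threshold t is computed from shuffled controls at ``fdr_level``
    and floored at ``dac_floor``; a gene is selected when DAC >= t and its
    SSD reaches ``ssd_min`` in at least ``min_ssd_samples`` samples.
    """

    fdr_level: float = 0.05
    n_controls: int = 100
    dac_floor: float = 0.5
    ssd_min: float = 0.5
    min_ssd_samples: int = 2
    grs_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("fdr_level", "dac_floor", "ssd_min", "grs_min"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_controls < 1 or self.min_ssd_samples < 1:
            raise ValueError("integer config fields must be >= 1")


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int  # 1 death/event, 0 censored
    cause_specific: int | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be >= 0")


def fdr_threshold(
    observed_dac: Sequence[float],
    control_dacs: Sequence[Sequence[float]],
    cfg: SelectionConfig = SelectionConfig(),
) -> float:
    """Empirical-FDR threshold t on DAC from shuffled controls.

    FDR(t) = (mean over controls of #{null DAC > t}) / #{observed DAC >= t};
    t* is the smallest value in the pooled grid of observed and control
    DACs with FDR(t*) <= the target level, floored at ``dac_floor``.
    Null exceedance is strict so a threshold sitting exactly on the top
    null value already excludes it, matching a cutoff "above the nulls".
    Returns +inf when no threshold reaches the level (nothing selectable).
    """
    obs = np.asarray([d for d in observed_dac if np.isfinite(d)], dtype=float)
    if len(obs) == 0:
        raise ValueError("no observed DAC values")
    nulls = [np.asarray([d for d in c if np.isfinite(d)]) for c in control_dacs]
    n_controls = max(1, len(nulls))
    pooled = np.concatenate(nulls) if nulls else np.array([])
    candidates = np.unique(np.concatenate([obs, pooled, [0.0]]))
    best = np.inf
    for t in candidates:
        n_obs = int((obs >= t).sum())
        mean_null = float((pooled > t).sum()) / n_controls if len(pooled) else 0.0
        fdr = mean_null / max(1, n_obs)
        if fdr <= cfg.fdr_level:
            best = min(best, float(t))
    if not np.isfinite(best):
        return float("inf")
    return max(best, cfg.dac_floor)


def select_genes(
    result: XseqResult, t: float, cfg: SelectionConfig = SelectionConfig()
) -> list[str]:
    """Genes with DAC >= t and SSD >= ssd_min in >= min_ssd_samples samples."""
    selected = []
    for gene, r in result.genes.items():
        if not np.isfinite(r.dac) or r.dac < t:
            continue
        if int((r.ssd >= cfg.ssd_min).sum()) >= cfg.min_ssd_samples:
            selected.append(gene)
    return sorted(selected)


def dysregulation_table(
    result: XseqResult, gene: str, cfg: SelectionConfig = SelectionConfig()
) -> pd.DataFrame:
    """Partner x mutated-sample table of signed GRS for one predicted gene.

    Rows are partners dysregulated (|GRS| >= grs_min) in at least one
    sample whose SSD >= ssd_min; values are GRS with down-regulation
    negated.  Columns (mutated samples) are always present.
    """
    if gene not in result.genes:
        raise KeyError(f"gene {gene!r} not in result")
    r = result.genes[gene]
    qual_samples = [s for s in r.mutated_samples if r.ssd[s] >= cfg.ssd_min]
    keep_rows = (
        r.grs[qual_samples].abs().ge(cfg.grs_min).any(axis=1)
        if qual_samples
        else pd.Series(False, index=r.grs.index)
    )
    return r.grs.loc[keep_rows]


def selection_report(
    result: XseqResult, t: float, cfg: SelectionConfig = SelectionConfig()
) -> pd.DataFrame:
    """Per-gene report: DAC, threshold, qualifying-SSD sample count, call."""
    selected = set(select_genes(result, t, cfg))
    rows = []
    for gene, r in sorted(result.genes.items()):
        rows.append(
            {
                "gene": gene,
                "dac": r.dac,
                "t": t,
                "n_ssd_samples": int((r.ssd >= cfg.ssd_min).sum()),
                "selected": gene in selected,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "dac", "t", "n_ssd_samples", "selected"])


def hypergeometric_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k): k hits among n draws from a
    universe of N containing K category members.

    Exact integer-arithmetic summation for moderate universes (full float
    precision); log-space summation for very large ones (stable but with
    accumulation error around 1e-12).
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    if N <= 5000:
        from math import comb

        num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
        return num / comb(N, n)
    kk = np.arange(k, min(K, n) + 1)
    logp = stats.hypergeom.logpmf(kk, N, K, n)
    return min(1.0, float(np.exp(logsumexp(logp))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def km_logrank(
    expr_values: Mapping[str, float],
    surv: Sequence[SurvivalRecord],
) -> tuple[pd.Series, float, float]:
    """Median-split survival comparison.

    Samples with expression strictly above the median form the "high"
    group, the rest "low" (ties to low).  Returns (group labels, log-rank
    chi-square, p-value).
    """
    surv = [r for r in surv if r.sample_id in expr_values]
    if len(surv) < 4:
        raise ValueError("need >= 4 samples with both expression and survival")
    vals = np.array([expr_values[r.sample_id] for r in surv])
    med = float(np.median(vals))
    groups = pd.Series(
        np.where(vals > med, "high", "low"), index=[r.sample_id for r in surv]
    )
    for g in ("high", "low"):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples after median split")
    times = np.array([r.time for r in surv])
    events = np.array([r.event for r in surv])
    hi = groups.to_numpy() == "high"
    res = logrank_test(times[hi], times[~hi], events[hi], events[~hi])
    return groups, float(res.test_statistic), float(res.p_value)


def mutation_rate_report(
    muts: Sequence[MutationRecord],
    tfbs: IntervalSet,
    exons: IntervalSet,
    genome: Mapping[str, int],
    flank_widths: Sequence[int] = (100, 500, 1000),
    n_shuffles: int = 150,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample mutation rates in TFBSs, exons and their flanks, with
    shuffle-based expectations and a paired rate comparison.

    The rate in a region set is the number of distinct mutated reference
    positions inside the set divided by the set's total length (an indel
    of span k contributes min(k, overlap) positions).  Expectations come
    from ``n_shuffles`` chromosome-preserving random placements.  The
    cohort-level test is a paired two-tailed Wilcoxon signed-rank of TFBS
    vs exon rates across samples.
    """
    if len(tfbs) == 0 or len(exons) == 0:
        raise ValueError("empty region set")
    tfbs = merge_intervals(IntervalSet(list(tfbs), genome=genome))
    exons = merge_intervals(IntervalSet(list(exons), genome=genome))
    both = merge_intervals(IntervalSet(list(tfbs) + list(exons), genome=genome))
    region_sets: dict[str, IntervalSet] = {"tfbs": tfbs, "exons": exons}
    for w in flank_widths:
        region_sets[f"tfbs_flank_{w}"] = flank_regions(tfbs, w, exclude=both)
        region_sets[f"exons_flank_{w}"] = flank_regions(exons, w, exclude=both)
    lengths = {k: s.total_length for k, s in region_sets.items()}
    arrs = {k: s.by_chrom() for k, s in region_sets.items()}

    def mutated_positions(mut_list: Sequence[MutationRecord], arr_by_chrom) -> int:
        covered = 0
        for m in mut_list:
            arr = arr_by_chrom.get(m.chrom)
            if arr is None:
                continue
            i = int(np.searchsorted(arr[:, 1], m.pos, side="right"))
            while i < len(arr) and arr[i, 0] < m.end:
                covered += min(m.end, arr[i, 1]) - max(m.pos, arr[i, 0])
                i += 1
        return covered

    by_sample: dict[str, list[MutationRecord]] = {}
    for m in muts:
        by_sample.setdefault(m.sample_id, []).append(m)
    rows = []
    rng = np.random.default_rng(seed)
    shuffle_seeds = rng.integers(0, 2**31 - 1, size=n_shuffles)
    for sample in sorted(by_sample):
        ml = by_sample[sample]
        row: dict[str, float | str] = {"sample": sample, "n_mutations": len(ml)}
        for k in region_sets:
            row[f"rate_{k}"] = mutated_positions(ml, arrs[k]) / lengths[k]
        if n_shuffles > 0:
            exp_counts = {k: 0.0 for k in region_sets}
            for s in shuffle_seeds:
                shuffled = shuffle_mutations(ml, genome, int(s))
                for k in region_sets:
                    exp_counts[k] += mutated_positions(shuffled, arrs[k])
            for k in region_sets:
                row[f"expected_rate_{k}"] = exp_counts[k] / n_shuffles / lengths[k]
        rows.append(row)
    table = pd.DataFrame(rows)
    nonzero = table[table["n_mutations"] > 0]
    if len(nonzero) < len(table):
        logger.warning(
            "%d samples with 0 mutations excluded from the paired test",
            len(table) - len(nonzero),
        )
    tests: dict[str, float] = {}
    x = nonzero["rate_tfbs"].to_numpy()
    yv = nonzero["rate_exons"].to_numpy()
    if len(x) >= 2 and not np.allclose(x, yv):
        tests["wilcoxon_tfbs_vs_exons_p"] = float(
            stats.wilcoxon(x, yv, alternative="two-sided").pvalue
        )
    else:
        tests["wilcoxon_tfbs_vs_exons_p"] = 1.0
    return table, tests
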
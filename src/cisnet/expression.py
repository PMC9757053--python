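"""Expression preprocessing: cpm/log2 normalization, z-values, CNA coding,
and the two-component "expressed gene" mixture filter.

Count matrices are pandas DataFrames with feature rows and sample columns.
The normalized matrix carried through the pipeline is log2(cpm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "filter_zero_genes",
    "cpm_log2",
    "z_values",
    "ascat_to_gistic",
    "gistic_matrix",
    "expressed_gene_filter",
    "fit_two_component_mixture",
    "read_expression_tsv",
    "write_expression_tsv",
]

GISTIC_LEVELS = (-2, -1, 0, 1, 2)


@dataclass
class ExpressionMatrix:
    """Feature x sample real-valued matrix with cohort per-feature stats.

    ``mu``/``sigma`` are the cohort mean and sample (n-1) standard
    deviation per feature; they are recomputed whenever rows are filtered.
    """

    values: pd.DataFrame
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.values.isna().all(axis=1).any():
            bad = self.values.index[self.values.isna().all(axis=1)][:3].tolist()
            raise ValueError(f"features with all-missing values: {bad} ...")
        self._recompute_stats()

    def _recompute_stats(self) -> None:
        self.mu = self.values.mean(axis=1)
        self.sigma = self.values.std(axis=1, ddof=1)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[features], normalized=self.normalized)


def filter_zero_genes(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Drop features with zero reads in more than half of the samples.

    The inequality is strict: zeros in exactly 50% of samples keeps the
    feature.
    """
    if (raw_counts.to_numpy() < 0).any():
        raise ValueError("negative counts in raw count matrix")
    n_zero = (raw_counts == 0).sum(axis=1)
    keep = n_zero <= 0.5 * raw_counts.shape[1]
    return raw_counts.loc[keep]


def cpm_log2(raw_counts: pd.DataFrame) -> ExpressionMatrix:
    """log2(counts-per-million + 1) with a pseudo-count of 1.

    Per-sample cpm columns (pre-log, pre-pseudo-count) sum to 1e6.
    """
    if (raw_counts.to_numpy() < 0).any():
        raise ValueError("negative counts in raw count matrix")
    libsize = raw_counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {zero.index.tolist()}")
    cpm = raw_counts.div(libsize, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), normalized=True)


def z_values(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature z-scores (v - mu) / sigma against the cohort.

    Features with sigma == 0 get NaN rows (never flagged as dysregulated).
    """
    sigma = m.sigma.replace(0.0, np.nan)
    n_flat = int((m.sigma == 0).sum())
    if n_flat:
        logger.warning("%d features with zero variance: z undefined", n_flat)
    return m.values.sub(m.mu, axis=0).div(sigma, axis=0)


def dysregulation_flags(z: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean mask of |z| strictly greater than ``threshold``; NaN -> False."""
    return (z < -threshold) | (z > threshold)


def ascat_to_gistic(n_minor: int, n_major: int) -> int:
    """Total-copy-number to 5-level GISTIC code.

    0 copies -> -2 (homozygous loss), 1 -> -1, 2 -> 0, 3 -> 1, >3 -> 2.
    """
    if n_minor < 0 or n_major < 0:
        raise ValueError("allele copy numbers must be non-negative")
    total = n_minor + n_major
    if total == 0:
        return -2
    if total == 1:
        return -1
    if total == 2:
        return 0
    if total == 3:
        return 1
    return 2


def gistic_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene x sample CNA matrix against the 5-level coding."""
    vals = df.to_numpy()
    if not np.isin(vals[~np.isnan(vals.astype(float))], GISTIC_LEVELS).all():
        raise ValueError("CNA matrix contains values outside {-2,-1,0,1,2}")
    return df.astype(int)


def fit_two_component_mixture(
    x: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> dict:
    """Two-component 1-D Gaussian mixture by EM, means ordered low < high.

    Deterministic: components are initialized from a 2-means split (Lloyd
    iterations started at the data min and max), which lands the two
    centers on the natural low/high clusters even when they are far from
    equal-sized.  Returns dict with means, sds, weights, posterior-of-high
    per point, and the log-likelihood trace.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(
            "degenerate input: all values equal; mixture unfit "
            "(use the bypass flag to keep all features)"
        )
    centers = np.array([x.min(), x.max()])
    for _ in range(100):
        assign = np.abs(x[:, None] - centers).argmin(axis=1)
        if not assign.any() or assign.all():  # a cluster emptied
            break
        new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    lo, hi = x[assign == 0], x[assign == 1]
    if len(lo) == 0 or len(hi) == 0:
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if len(hi) == 0:
            lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-3 * x.std()), max(hi.std(), 1e-3 * x.std())])
    lam = np.array([len(lo), len(hi)], dtype=float) / len(x)
    ll_trace: list[float] = []
    sd_floor = 1e-3 * x.std()
    for _ in range(max_iter):
        logpdf = (
            -0.5 * ((x[:, None] - mu) / sd) ** 2
            - np.log(sd)
            - 0.5 * np.log(2 * np.pi)
            + np.log(lam)
        )
        m = logpdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        if ll_trace and abs(ll - ll_trace[-1]) < tol:
            ll_trace.append(ll)
            break
        ll_trace.append(ll)
        nk = resp.sum(axis=0)
        lam = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, sd_floor)
    order = np.argsort(mu)
    mu, sd, lam = mu[order], sd[order], lam[order]
    logpdf = (
        -0.5 * ((x[:, None] - mu) / sd) ** 2
        - np.log(sd)
        - 0.5 * np.log(2 * np.pi)
        + np.log(lam)
    )
    m = logpdf.max(axis=1, keepdims=True)
    resp = np.exp(logpdf - m)
    resp /= resp.sum(axis=1, keepdims=True)
    return {
        "means": mu,
        "sds": sd,
        "weights": lam,
        "posterior_high": resp[:, 1],
        "loglik_trace": np.array(ll_trace),
    }


def expressed_gene_filter(
    m: ExpressionMatrix,
    posterior_min: float = 0.8,
    bypass: bool = False,
) -> pd.Index:
    """Keep features whose 90th-percentile expression falls in the high
    component of a two-Gaussian decomposition with posterior >= 0.8.

    This is the low-expression filter applied before network inference: the
    90th percentile over samples is computed per feature, the distribution
    of those values is split into a low- and a high-expression Gaussian by
    EM, and a feature is retained iff its posterior of belonging to the
    high component is at least ``posterior_min`` (inclusive).
    """
    if bypass:
        return m.features
    if m.values.shape[0] < 20:
        raise ValueError("need >= 20 features to fit the expression mixture")
    p90 = np.percentile(m.values.to_numpy(), 90, axis=1)
    fit = fit_two_component_mixture(p90)
    keep = fit["posterior_high"] >= posterior_min
    return m.features[keep]


# ---------------------------------------------------------------------------
# I/O

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
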
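"""Hierarchical Bayesian association of mutations with gene-network
dysregulation.

The model couples a cohort-level indicator with sample-level indicators and
per-partner expression statuses:

* ``D ~ Bernoulli(pi_d)`` — the gene's mutations are functional at the
  cohort level;
* for each mutated sample ``s``, ``F_s | D ~ Bernoulli(pi_f if D else eps)``
  — the mutation in sample ``s`` is functional;
* for each network partner ``p`` with weight ``w`` and each mutated sample,
  a regulatory status ``R in {down, neutral, up}`` with
  ``P(R != neutral | F=1) = alpha * w`` (split equally up/down), while
  under ``F=0`` the status follows the partner's own fitted mixing
  weights (its cohort-marginal status distribution, tails floored at
  ``b/2``) — so absent a functional mutation the model predicts exactly
  the cohort-wide expression distribution and null evidence is calibrated;
* the observed expression ``y_{p,s}`` is emitted from the partner's fitted
  three-component Gaussian mixture conditional on ``R``.

All inference is exact: the model is a tree, so posteriors are obtained by
summing out ``R`` per observation, then ``F`` per sample, then ``D``, in
log space.  Three posteriors are reported: GRS (partner dysregulated in a
sample, marginal over the mixture), SSD (the mutation in a sample is
associated with network dysregulation) and DAC (the gene's mutations are
associated with dysregulation across the cohort).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .expression import ExpressionMatrix
from .mapping import MutationMatrix
from .networks import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureParams",
    "XseqPriors",
    "GeneResult",
    "XseqResult",
    "fit_status_mixture",
    "status_posteriors",
    "infer_gene",
    "run_cohort",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Three-component Gaussian mixture over one gene's expression:
    down-regulated, neutral and up-regulated statuses, means ordered."""

    means: np.ndarray  # (3,) mu_down < mu_neutral < mu_up
    sds: np.ndarray  # (3,) > 0
    weights: np.ndarray  # (3,) sum to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        if not (m[0] < m[1] < m[2]):
            raise ValueError(f"means must be strictly ordered, got {m}")
        if (np.asarray(self.sds) <= 0).any():
            raise ValueError("component sds must be positive")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-8:
            raise ValueError("mixing weights must sum to 1")


@dataclass(frozen=True)
class XseqPriors:
    """Free parameters of the hierarchical model.

    pi_d : prior that a gene's mutations are cohort-level functional.
    pi_f : P(sample mutation functional | D=1).
    eps  : P(sample mutation functional | D=0); must be < pi_f.
    alpha: maximum dysregulation probability of a partner given a
           functional mutation (scaled by the edge weight).
    b    : floor on the background non-neutral probability absent a
           functional mutation.  The background status distribution is the
           partner's cohort-marginal mixing weights, with each tail
           component floored at b/2 (guards against unbounded evidence
           from partners with vanishing tail components); must be < alpha.
    """

    pi_d: float = 0.5
    pi_f: float = 0.8
    eps: float = 0.01
    alpha: float = 0.9
    b: float = 0.1

    def __post_init__(self) -> None:
        for name in ("pi_d", "pi_f", "eps", "alpha", "b"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.eps >= self.pi_f:
            raise ValueError("eps must be < pi_f")
        if self.b >= self.alpha:
            raise ValueError("b must be < alpha")


def fit_status_mixture(
    values: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> MixtureParams:
    """EM fit of the 3-status Gaussian mixture for one gene.

    The mixture is homoscedastic (one shared variance): with free
    variances a tail component can either collapse onto a few points or
    inflate to absorb half the bulk, and in both cases a minority of
    genuinely shifted samples stops being resolvable as a low-weight tail
    component.  Initialization is deterministic: component means at the
    10th/50th/90th percentiles, equal weights, common sd.  The shared sd
    is floored at 1e-3 x overall sd (guards collapse on near-degenerate
    data); the ordering constraint is enforced by relabeling after
    convergence, with ties broken by an infinitesimal spread.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need >= 10 finite values to fit the status mixture")
    total_sd = float(x.std())
    if total_sd == 0:
        raise ValueError("zero-variance expression: status mixture undefined")
    med = float(np.median(x))
    if total_sd < 1e-4 * max(1.0, abs(med)):
        # essentially constant (spread under 0.01% of magnitude): call it
        # neutral rather than let EM carve noise into statuses
        logger.debug("near-degenerate expression: neutral-dominant fallback")
        eps = max(total_sd, 1e-12)
        return MixtureParams(
            means=np.array([med - 6 * eps, med, med + 6 * eps]),
            sds=np.full(3, eps),
            weights=np.array([0.005, 0.99, 0.005]),
        )
    sd_floor = 1e-3 * total_sd
    mu = np.percentile(x, [10, 50, 90]).astype(float)
    # percentile ties (heavily discrete data): spread deterministically
    for k in (1, 2):
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + sd_floor
    sd = np.full(3, max(total_sd, sd_floor))
    lam = np.full(3, 1.0 / 3.0)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = (
            -0.5 * ((x[:, None] - mu) / sd) ** 2
            - np.log(sd)
            - 0.5 * _LOG2PI
            + np.log(lam)
        )
        mx = logp.max(axis=1)
        lse = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        lam = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        pooled = np.sqrt((resp * (x[:, None] - mu) ** 2).sum() / len(x))
        if pooled < sd_floor:
            logger.debug("EM sd floor triggered")
        sd = np.full(3, max(pooled, sd_floor))
    order = np.argsort(mu, kind="stable")
    mu, sd, lam = mu[order], sd[order], lam[order]
    for k in (1, 2):  # enforce strict ordering after a possible collapse
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + max(sd_floor, 1e-12)
    lam = lam / lam.sum()
    return MixtureParams(means=mu, sds=sd, weights=lam)


def status_posteriors(y: float | np.ndarray, mix: MixtureParams) -> np.ndarray:
    """Posterior (P_down, P_neutral, P_up) of the regulatory status of an
    expression value under the marginal mixture; GRS = P_down + P_up."""
    y = np.asarray(y, dtype=float)
    logp = (
        -0.5 * ((y[..., None] - mix.means) / mix.sds) ** 2
        - np.log(mix.sds)
        - 0.5 * _LOG2PI
        + np.log(mix.weights)
    )
    return np.exp(logp - logsumexp(logp, axis=-1, keepdims=True))


def _status_logliks(
    y: np.ndarray, means: np.ndarray, sds: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Relative status evidence log( q_r(y) / lambda_r ) per observation.

    q_r is the fitted-mixture status posterior, so the term equals the
    component density divided by the marginal density: evidence is
    measured relative to the cohort-wide expression distribution, and a
    value that merely sits where cohort values sit carries no signal.

    y: (k, m) partner x sample values; means/sds/lams: (k, 3).
    Returns (k, m, 3).
    """
    logp = (
        -0.5 * ((y[:, :, None] - means[:, None, :]) / sds[:, None, :]) ** 2
        - np.log(sds[:, None, :])
        - 0.5 * _LOG2PI
        + np.log(lams[:, None, :])
    )
    return (
        logp
        - logsumexp(logp, axis=2, keepdims=True)
        - np.log(lams[:, None, :])
    )


def _background_status(lams: np.ndarray, b: float) -> np.ndarray:
    """Status distribution under F=0: the partner's marginal mixing
    weights, tails floored at b/2, renormalized.  (k, 3) -> (k, 3)."""
    p0 = lams.copy()
    p0[:, 0] = np.maximum(p0[:, 0], b / 2)
    p0[:, 2] = np.maximum(p0[:, 2], b / 2)
    return p0 / p0.sum(axis=1, keepdims=True)


def _sample_logliks(
    obs_ll: np.ndarray,
    weights: np.ndarray,
    lams: np.ndarray,
    mask: np.ndarray,
    priors: XseqPriors,
) -> tuple[np.ndarray, np.ndarray]:
    """log P(observations in sample s | F_s = f) for f in {0, 1}, up to a
    constant shared by both (it cancels in every posterior).

    obs_ll: (k, m, 3) relative status evidence; weights: (k,) edge
    weights; lams: (k, 3) mixing weights; mask: (k, m) True where the
    observation is used (CNA-clean).  Returns (logL0, logL1), each (m,).
    """
    p_nn1 = priors.alpha * weights  # (k,) non-neutral prob given F=1
    pr1 = np.stack([p_nn1 / 2, 1.0 - p_nn1, p_nn1 / 2], axis=1)  # (k, 3)
    pr0 = _background_status(lams, priors.b)  # (k, 3)
    with np.errstate(divide="ignore"):
        l1 = logsumexp(obs_ll + np.log(pr1)[:, None, :], axis=2)  # (k, m)
        l0 = logsumexp(obs_ll + np.log(pr0)[:, None, :], axis=2)
    l1 = np.where(mask, l1, 0.0)
    l0 = np.where(mask, l0, 0.0)
    return l0.sum(axis=0), l1.sum(axis=0)


def infer_gene(
    y: np.ndarray,
    weights: np.ndarray,
    mixtures: list[MixtureParams],
    priors: XseqPriors,
    cna_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Exact posterior inference for one mutated gene.

    Parameters
    ----------
    y : (k, m) expression of k partners in the m mutated samples.
    weights : (k,) network edge weights in (0, 1].
    mixtures : per-partner fitted status mixtures.
    cna_mask : (k, m) boolean, True where the partner observation is
        *excluded* (|GISTIC| >= 1 in that sample: cis effect of a copy
        number alteration, not usable as trans evidence).

    Returns
    -------
    (ssd, dac) : SSD per mutated sample (m,) and the scalar DAC.  If every
        observation is masked in every sample, DAC is NaN.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    k, m = y.shape
    if k == 0 or m == 0:
        raise ValueError("need at least one partner and one mutated sample")
    means = np.stack([mx.means for mx in mixtures])
    sds = np.stack([mx.sds for mx in mixtures])
    lams = np.stack([mx.weights for mx in mixtures])
    use = np.ones((k, m), dtype=bool) if cna_mask is None else ~np.asarray(cna_mask)
    use &= np.isfinite(y)
    if not use.any():
        return np.full(m, np.nan), float("nan")
    obs_ll = _status_logliks(np.where(use, y, 0.0), means, sds, lams)
    logl0, logl1 = _sample_logliks(
        obs_ll, np.asarray(weights, float), lams, use, priors
    )
    # marginalize F_s given D
    la1 = np.logaddexp(np.log(priors.pi_f) + logl1, np.log1p(-priors.pi_f) + logl0)
    la0 = np.logaddexp(np.log(priors.eps) + logl1, np.log1p(-priors.eps) + logl0)
    log_post_d1 = np.log(priors.pi_d) + la1.sum()
    log_post_d0 = np.log1p(-priors.pi_d) + la0.sum()
    norm = np.logaddexp(log_post_d1, log_post_d0)
    dac = float(np.exp(log_post_d1 - norm))
    # P(F_s = 1 | data) = sum_d P(D=d | data) P(F_s=1 | D=d, data_s)
    pf_d1 = np.exp(np.log(priors.pi_f) + logl1 - la1)
    pf_d0 = np.exp(np.log(priors.eps) + logl1 - la0)
    ssd = dac * pf_d1 + (1.0 - dac) * pf_d0
    return ssd, dac


@dataclass
class GeneResult:
    gene: str
    mutated_samples: list[str]
    dac: float
    ssd: pd.Series  # indexed by mutated sample
    grs: pd.DataFrame  # partners x mutated samples, signed (negative = down)


@dataclass
class XseqResult:
    """Cohort-level posteriors for every gene with >= 1 mutated sample."""

    genes: dict[str, GeneResult] = field(default_factory=dict)

    @property
    def dac(self) -> pd.Series:
        return pd.Series({g: r.dac for g, r in self.genes.items()}, dtype=float)

    def ssd_count(self, ssd_min: float = 0.5) -> pd.Series:
        return pd.Series(
            {g: int((r.ssd >= ssd_min).sum()) for g, r in self.genes.items()},
            dtype=int,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "dac.tsv", "w") as fh:
            fh.write("driver\tdac\n")
            for g, r in sorted(self.genes.items()):
                fh.write(f"{g}\t{r.dac:.6f}\n")
        with open(outdir / "ssd.tsv", "w") as fh:
            fh.write("driver\tsample\tssd\n")
            for g, r in sorted(self.genes.items()):
                for s, v in r.ssd.items():
                    fh.write(f"{g}\t{s}\t{v:.6f}\n")
        with open(outdir / "grs.tsv", "w") as fh:
            fh.write("driver\tpartner\tsample\tgrs\n")
            for g, r in sorted(self.genes.items()):
                for p in r.grs.index:
                    for s in r.grs.columns:
                        fh.write(f"{g}\t{p}\t{s}\t{r.grs.at[p, s]:.6f}\n")


def run_cohort(
    mut_matrix: MutationMatrix,
    expr: ExpressionMatrix,
    net: WeightedNetwork,
    cna: pd.DataFrame | None = None,
    priors: XseqPriors = XseqPriors(),
    mixture_cache: dict[str, MixtureParams] | None = None,
    compute_grs: bool = True,
) -> XseqResult:
    """Run inference for every mutated gene in the cohort.

    Partner status mixtures are fitted once per partner and reused (pass a
    shared ``mixture_cache`` to amortize fits across the shuffled-control
    runs, which leave the expression matrix untouched).
    """
    result = XseqResult()
    if mut_matrix.values.empty:
        return result
    samples = [s for s in mut_matrix.samples if s in expr.samples]
    if len(samples) < len(mut_matrix.samples):
        logger.warning(
            "%d samples absent from expression dropped",
            len(mut_matrix.samples) - len(samples),
        )
    cache = mixture_cache if mixture_cache is not None else {}
    expr_vals = expr.values
    warned_missing = 0
    for gene in mut_matrix.genes:
        row = mut_matrix.values.loc[gene, samples]
        mut_samples = [s for s in samples if row[s] == 1]
        if not mut_samples:
            continue
        partners = {
            p: w for p, w in net.partners(gene).items() if p in expr_vals.index
        }
        warned_missing += len(net.partners(gene)) - len(partners)
        if not partners:
            continue
        plist = list(partners)
        mixtures = []
        for p in plist:
            if p not in cache:
                cache[p] = fit_status_mixture(expr_vals.loc[p].to_numpy())
            mixtures.append(cache[p])
        y = expr_vals.loc[plist, mut_samples].to_numpy(dtype=float)
        mask = None
        if cna is not None:
            mask = np.zeros(y.shape, dtype=bool)
            for i, p in enumerate(plist):
                if p in cna.index:
                    mask[i] = np.abs(cna.loc[p, mut_samples].to_numpy()) >= 1
        ssd, dac = infer_gene(
            y, np.array(list(partners.values())), mixtures, priors, mask
        )
        if compute_grs:
            post = np.stack(
                [status_posteriors(y[i], mixtures[i]) for i in range(len(plist))]
            )  # (k, m, 3)
            grs = post[:, :, 0] + post[:, :, 2]
            sign = np.where(post[:, :, 2] >= post[:, :, 0], 1.0, -1.0)
            grs_df = pd.DataFrame(grs * sign, index=plist, columns=mut_samples)
        else:
            grs_df = pd.DataFrame(index=plist, columns=mut_samples, dtype=float)
        result.genes[gene] = GeneResult(
            gene=gene,
            mutated_samples=mut_samples,
            dac=dac,
            ssd=pd.Series(ssd, index=mut_samples),
            grs=grs_df,
        )
    if warned_missing:
        logger.debug("%d network partners absent from expression dropped", warned_missing)
    return result
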
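"""Hierarchical inference: brute-force enumeration oracle, mixture
recovery, and posterior invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cisnet.expression import ExpressionMatrix
from cisnet.mapping import MutationMatrix
from cisnet.networks import WeightedNetwork
from cisnet.xseq import (
    MixtureParams,
    XseqPriors,
    fit_status_mixture,
    infer_gene,
    run_cohort,
    status_posteriors,
)


def brute_force(y, weights, mixtures, priors, cna_mask=None):
    """Exact posteriors by summing the joint over every latent
    configuration (D, F per sample, R per partner x sample).

    The observation term for status r is the mixture status posterior
    divided by its mixing weight, exactly as the model defines it; the
    background status distribution is the partner's mixing weights with
    tails floored at b/2.
    """
    y = np.atleast_2d(y)
    k, m = y.shape
    obs = np.zeros((k, m, 3))
    p0 = np.zeros((k, 3))
    for i, mix in enumerate(mixtures):
        dens = np.array(
            [norm.pdf(y[i], mix.means[r], mix.sds[r]) for r in range(3)]
        ).T  # (m, 3)
        marg = dens @ mix.weights
        q = dens * mix.weights / marg[:, None]
        obs[i] = q / mix.weights
        lam = mix.weights.copy()
        lam[0] = max(lam[0], priors.b / 2)
        lam[2] = max(lam[2], priors.b / 2)
        p0[i] = lam / lam.sum()
    use = np.ones((k, m), bool) if cna_mask is None else ~np.asarray(cna_mask)
    pr1 = lambda w: np.array([priors.alpha * w / 2, 1 - priors.alpha * w,
                              priors.alpha * w / 2])
    total = 0.0
    post_d1 = 0.0
    post_f = np.zeros(m)
    for d in (0, 1):
        pd_ = priors.pi_d if d else 1 - priors.pi_d
        pf = priors.pi_f if d else priors.eps
        for fvec in itertools.product((0, 1), repeat=m):
            pfv = np.prod([pf if f else 1 - pf for f in fvec])
            like = 1.0
            for i in range(k):
                for s in range(m):
                    if not use[i, s]:
                        continue
                    pr = pr1(weights[i]) if fvec[s] else p0[i]
                    like *= float(pr @ obs[i, s])
            w = pd_ * pfv * like
            total += w
            if d:
                post_d1 += w
            for s in range(m):
                if fvec[s]:
                    post_f[s] += w
    return post_f / total, post_d1 / total


def random_mixture(rng):
    mu = np.sort(rng.normal(0, 3, 3))
    mu += np.array([0, 0.5, 1.0])  # enforce strict ordering
    lam = rng.dirichlet([2, 5, 2])
    sd = np.full(3, float(rng.uniform(0.3, 1.5)))
    return MixtureParams(means=mu, sds=sd, weights=lam)


class TestInferGeneOracle:
    def test_matches_enumeration_over_random_parameterizations(self):
        """50 random small instances (<=3 partners, <=3 mutated samples):
        exact tree inference equals brute-force enumeration to 1e-9."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            k = int(rng.integers(1, 4))
            m = int(rng.integers(1, 4))
            mixtures = [random_mixture(rng) for _ in range(k)]
            weights = rng.uniform(0.1, 1.0, k)
            y = rng.normal(0, 3, size=(k, m))
            priors = XseqPriors(
                pi_d=float(rng.uniform(0.2, 0.8)),
                pi_f=float(rng.uniform(0.5, 0.95)),
                eps=float(rng.uniform(0.001, 0.1)),
                alpha=float(rng.uniform(0.5, 0.95)),
                b=float(rng.uniform(0.01, 0.3)),
            )
            mask = (rng.random((k, m)) < 0.2) if trial % 3 == 0 else None
            if mask is not None and mask.all():
                mask[0, 0] = False
            ssd, dac = infer_gene(y, weights, mixtures, priors, mask)
            ssd_bf, dac_bf = brute_force(y, weights, mixtures, priors, mask)
            assert abs(dac - dac_bf) < 1e-9
            np.testing.assert_allclose(ssd, ssd_bf, atol=1e-9)

    def test_all_masked_returns_nan(self):
        rng = np.random.default_rng(0)
        mix = [random_mixture(rng)]
        ssd, dac = infer_gene(
            np.array([[1.0, 2.0]]), np.array([0.5]), mix, XseqPriors(),
            cna_mask=np.ones((1, 2), bool),
        )
        assert np.isnan(dac) and np.isnan(ssd).all()

    def test_neutral_partners_give_negative_evidence(self):
        """All partners exactly neutral in every mutated sample:
        SSD < 0.5 and DAC < pi_d."""
        mix = MixtureParams(
            means=np.array([-6.0, 0.0, 6.0]),
            sds=np.array([1.0, 1.0, 1.0]),
            weights=np.array([0.1, 0.8, 0.1]),
        )
        y = np.zeros((3, 2))  # at the neutral mean
        priors = XseqPriors()
        ssd, dac = infer_gene(y, np.full(3, 0.9), [mix] * 3, priors)
        assert (ssd < 0.5).all()
        assert dac < priors.pi_d

    def test_strong_evidence_drives_dac_monotonically_to_one(self):
        """eps -> 0 with strongly non-neutral partners in every mutated
        sample: DAC increases monotonically with the number of samples."""
        mix = MixtureParams(
            means=np.array([-6.0, 0.0, 6.0]),
            sds=np.array([1.0, 1.0, 1.0]),
            weights=np.array([0.1, 0.8, 0.1]),
        )
        priors = XseqPriors(eps=1e-6)
        dacs = []
        for m in (1, 2, 3, 4):
            y = np.full((3, m), 6.0)  # at the up mean
            _, dac = infer_gene(y, np.full(3, 0.9), [mix] * 3, priors)
            dacs.append(dac)
        assert all(b > a for a, b in zip(dacs, dacs[1:]))
        assert dacs[-1] > 0.99

    def test_dac_monotone_in_partner_evidence(self):
        mix = MixtureParams(
            means=np.array([-4.0, 0.0, 4.0]),
            sds=np.array([1.0, 1.0, 1.0]),
            weights=np.array([0.15, 0.7, 0.15]),
        )
        dacs = []
        for shift in (0.0, 1.0, 2.0, 3.0, 4.0):
            y = np.full((2, 2), shift)
            _, dac = infer_gene(y, np.array([0.8, 0.8]), [mix] * 2, XseqPriors())
            dacs.append(dac)
        assert all(b >= a for a, b in zip(dacs, dacs[1:]))

    def test_no_underflow_with_many_extreme_partners(self):
        rng = np.random.default_rng(1)
        k = 500
        mix = [random_mixture(rng) for _ in range(k)]
        y = rng.normal(0, 50, size=(k, 3))  # absurdly extreme observations
        ssd, dac = infer_gene(y, rng.uniform(0.1, 1, k), mix, XseqPriors())
        assert np.isfinite(dac) and np.isfinite(ssd).all()
        assert 0 <= dac <= 1 and ((ssd >= 0) & (ssd <= 1)).all()


class TestStatusMixture:
    def test_recovers_three_well_separated_components(self):
        rng = np.random.default_rng(11)
        x = np.concatenate(
            [rng.normal(2, 0.5, 1000), rng.normal(5, 0.5, 1000),
             rng.normal(8, 0.5, 1000)]
        )
        mix = fit_status_mixture(x)
        np.testing.assert_allclose(mix.means, [2, 5, 8], atol=0.2)
        post = status_posteriors(x, mix)
        labels = post.argmax(axis=1)
        truth = np.repeat([0, 1, 2], 1000)
        assert (labels == truth).mean() >= 0.85

    def test_ordering_invariant_on_random_data(self, rng):
        for _ in range(20):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 80)
            mix = fit_status_mixture(x)
            assert mix.means[0] < mix.means[1] < mix.means[2]
            assert abs(mix.weights.sum() - 1) < 1e-8

    def test_degenerate_data_floors_sd_neutral_dominant(self):
        rng = np.random.default_rng(3)
        x = np.full(100, 5.0) + rng.normal(0, 1e-6, 100)
        mix = fit_status_mixture(x)
        assert (mix.sds > 0).all()
        assert mix.weights[1] > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_status_mixture(np.full(50, 2.0))
        with pytest.raises(ValueError, match=">= 10"):
            fit_status_mixture(np.arange(5.0))


class TestStatusPosteriors:
    MIX = MixtureParams(
        means=np.array([-6.0, 0.0, 6.0]),
        sds=np.array([1.0, 1.0, 1.0]),
        weights=np.array([0.25, 0.5, 0.25]),
    )

    def test_neutral_value_confidently_neutral(self):
        p = status_posteriors(0.0, self.MIX)
        assert p[1] > 0.99
        assert p[0] + p[2] < 0.01  # GRS ~ 0

    def test_up_value_confidently_up(self):
        p = status_posteriors(6.0, self.MIX)
        assert p[2] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        y = rng.normal(0, 10, 200)
        p = status_posteriors(y, self.MIX)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestRunCohort:
    def _toy(self, rng, n_samples=30):
        samples = [f"s{i}" for i in range(n_samples)]
        genes = [f"p{i}" for i in range(6)] + ["drv"]
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(len(genes), n_samples)),
            index=genes, columns=samples,
        )
        mut = pd.DataFrame(0, index=["drv"], columns=samples)
        mut.iloc[0, :3] = 1
        expr.loc[[f"p{i}" for i in range(4)], samples[:3]] += 4.0
        net = WeightedNetwork()
        for i in range(6):
            net.add_edge("drv", f"p{i}", 0.9)
        return (
            MutationMatrix(mut, "cis_tfbs"),
            ExpressionMatrix(expr),
            net,
        )

    def test_sample_order_permutation_invariance(self, rng):
        mut, expr, net = self._toy(rng)
        r1 = run_cohort(mut, expr, net)
        perm = list(rng.permutation(expr.samples))
        mut2 = MutationMatrix(mut.values[perm], mut.channel)
        expr2 = ExpressionMatrix(expr.values[perm])
        r2 = run_cohort(mut2, expr2, net)
        assert r1.genes["drv"].dac == pytest.approx(r2.genes["drv"].dac, abs=1e-12)
        for s in r1.genes["drv"].ssd.index:
            assert r1.genes["drv"].ssd[s] == pytest.approx(
                r2.genes["drv"].ssd[s], abs=1e-12
            )

    def test_planted_signal_detected_and_grs_signed(self, rng):
        mut, expr, net = self._toy(rng)
        res = run_cohort(mut, expr, net)
        g = res.genes["drv"]
        assert g.dac > 0.9
        assert (g.ssd > 0.5).all()
        # shifted-up partners show mostly positive signed GRS in mutated
        # samples (sign can flip where the baseline draw cancels the shift)
        shifted = g.grs.loc[[f"p{i}" for i in range(4)]].to_numpy()
        assert (shifted > 0.5).mean() >= 0.6
        assert shifted.max() > 0.9

    def test_cna_masking_excludes_cis_confounded_partners(self, rng):
        mut, expr, net = self._toy(rng)
        cna = pd.DataFrame(0, index=expr.features, columns=expr.samples)
        cna.loc[[f"p{i}" for i in range(4)]] = 2  # amplified everywhere
        res_masked = run_cohort(mut, expr, net, cna=cna)
        res_free = run_cohort(mut, expr, net)
        # with the shifted partners masked, evidence must drop
        assert res_masked.genes["drv"].dac < res_free.genes["drv"].dac

    def test_empty_matrix_empty_result(self, rng):
        mut, expr, net = self._toy(rng)
        empty = MutationMatrix(mut.values.iloc[:0], "cis_tfbs")
        assert run_cohort(empty, expr, net).genes == {}

    def test_ssd_contrast_between_functional_and_background(self, rng):
        """Mean SSD over truly functional entries exceeds background
        mutated entries by >= 0.3."""
        mut, expr, net = self._toy(rng, n_samples=40)
        # add a background gene mutated in 2 samples with no partner signal
        mut2 = mut.values.copy()
        mut2.loc["bg"] = 0
        mut2.iloc[1, 10:12] = 1
        net.add_edge("bg", "p4", 0.9)
        net.add_edge("bg", "p5", 0.9)
        res = run_cohort(MutationMatrix(mut2, "cis_tfbs"), expr, net)
        functional = res.genes["drv"].ssd.mean()
        background = res.genes["bg"].ssd.mean()
        assert functional - background >= 0.3

    def test_results_written_as_tsv(self, rng, tmp_path):
        mut, expr, net = self._toy(rng)
        res = run_cohort(mut, expr, net)
        res.write(tmp_path)
        dac = pd.read_csv(tmp_path / "dac.tsv", sep="\t")
        assert list(dac.columns) == ["driver", "dac"]
        assert dac.iloc[0].driver == "drv"
        grs = pd.read_csv(tmp_path / "grs.tsv", sep="\t")
        assert set(grs.columns) == {"driver", "partner", "sample", "grs"}


def test_priors_validated():
    with pytest.raises(ValueError):
        XseqPriors(eps=0.9, pi_f=0.8)
    with pytest.raises(ValueError):
        XseqPriors(b=0.95, alpha=0.9)
    with pytest.raises(ValueError):
        XseqPriors(pi_d=0.0)
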
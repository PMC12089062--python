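"""Likelihood correctness: closed forms, brute-force enumeration oracles,
factorization identities, and structural invariances."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom, poisson

from roadcline.likelihood import (
    DORModelParams,
    LivingLikelihood,
    LivingModelParams,
    detection_probability,
    dor_model_loglik,
    living_model_loglik,
    prob_at_least_one,
    site_marginal_loglik,
)

PARAMS = LivingModelParams(
    beta0_N=2.58, beta1_N=-0.62, beta0_M=-0.85, beta1_M=-0.80,
    det_melanic=(-2.16, -0.058, -0.34), det_gray=(-1.53, -0.019, -0.39),
)


def brute_force_site_loglik(lam, counts, p_counts, dets, p_dets, n_top=250):
    """Independent oracle: direct enumeration over the latent abundance."""
    total = 0.0
    for n in range(0, n_top + 1):
        term = poisson.pmf(n, lam)
        for c, p in zip(counts, p_counts):
            term *= binom.pmf(c, n, p)
        for d, p in zip(dets, p_dets):
            p_star = 1 - (1 - p) ** n
            term *= p_star if d else 1 - p_star
        total += term
    return np.log(total)


class TestDetectionProbability:
    def test_zero_coefficients_give_half(self):
        p = LivingModelParams(0, 0, 0, 0, (0, 0, 0), (0, 0, 0))
        assert detection_probability(p, 1.7, "melanic") == pytest.approx(0.5)

    def test_gray_intercept_matches_closed_form(self):
        # expit(-1.53) at standardized temperature 0
        assert detection_probability(PARAMS, 0.0, "gray") == pytest.approx(
            expit(-1.53), abs=1e-12)
        assert detection_probability(PARAMS, 0.0, "gray") == pytest.approx(0.178, abs=5e-4)

    def test_even_in_temperature_without_linear_term(self):
        p = LivingModelParams(0, 0, 0, 0, (-1.0, 0.0, -0.3), (0, 0, 0))
        t = np.linspace(-2, 2, 9)
        np.testing.assert_allclose(
            detection_probability(p, t, "melanic"),
            detection_probability(p, -t, "melanic"))

    def test_unknown_morph_rejected(self):
        with pytest.raises(ValueError):
            detection_probability(PARAMS, 0.0, "albino")


class TestProbAtLeastOne:
    @pytest.mark.parametrize("p,n,expected", [
        (0.5, 1, 0.5),
        (0.5, 2, 0.75),
        (0.0, 5, 0.0),
        (0.3, 0, 0.0),
        (1.0, 0, 0.0),
    ])
    def test_closed_form(self, p, n, expected):
        assert prob_at_least_one(p, n) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_p_and_n(self):
        ps = np.linspace(0.01, 0.9, 20)
        vals_p = prob_at_least_one(ps, 3)
        assert np.all(np.diff(vals_p) > 0)
        vals_n = [prob_at_least_one(0.2, n) for n in range(0, 15)]
        assert np.all(np.diff(vals_n) >= 0)

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            prob_at_least_one(1.3, 2)


class TestSiteMarginal:
    @pytest.mark.parametrize("lam,counts,p_counts,dets,p_dets", [
        (2.0, [1, 0], [0.4, 0.3], [1, 0, 1], [0.35, 0.2, 0.5]),
        (0.7, [0], [0.25], [0, 0], [0.1, 0.15]),
        (8.0, [3, 5, 2], [0.5, 0.6, 0.3], [1, 1], [0.2, 0.4]),
        (15.0, [4], [0.15], [], []),
    ])
    def test_matches_bruteforce_enumeration(self, lam, counts, p_counts, dets, p_dets):
        got = site_marginal_loglik(lam, counts, p_counts, dets, p_dets, n_max=250)
        want = brute_force_site_loglik(lam, counts, p_counts, dets, p_dets)
        assert got == pytest.approx(want, abs=1e-10)

    def test_truncation_converged(self):
        args = (2.0, [1, 0], [0.4, 0.3], [1, 0, 1], [0.35, 0.2, 0.5])
        base = site_marginal_loglik(*args)  # default 1e-12-tail truncation
        doubled = site_marginal_loglik(*args, n_max=200)
        assert abs(base - doubled) < 1e-10

    def test_empty_site_limit(self):
        # no observations and lambda -> 0: probability -> 1
        ll = site_marginal_loglik(1e-9, [0, 0], [0.4, 0.3], [0, 0], [0.2, 0.2])
        assert -1e-6 < ll <= 0

    def test_nmax_below_observed_count_rejected(self):
        with pytest.raises(ValueError):
            site_marginal_loglik(2.0, [7], [0.4], [], [], n_max=5)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            site_marginal_loglik(0.0, [1], [0.4], [], [])


def _site_term(data, params, site, morph, n_top=250):
    z = data.distance_std.transform(
        data.sites.set_index("site").loc[site, "distance_km"])
    lam_tot = np.exp(params.beta0_N + params.beta1_N * z)
    p_mel = expit(params.beta0_M + params.beta1_M * z)
    lam = lam_tot * p_mel if morph == "melanic" else lam_tot * (1 - p_mel)
    cnt = data.counts[data.counts["site"] == site]
    cam = data.cameras[data.cameras["site"] == site]
    return brute_force_site_loglik(
        lam,
        cnt[f"count_{morph}"].to_numpy(),
        detection_probability(params, cnt["temperature_std"].to_numpy(), morph),
        cam[f"det_{morph}"].to_numpy(),
        detection_probability(params, cam["temperature_std"].to_numpy(), morph),
        n_top=n_top,
    )


class TestLivingModel:
    def test_equals_product_of_site_terms(self, tiny_dataset):
        want = sum(
            _site_term(tiny_dataset, PARAMS, s, m)
            for s in tiny_dataset.sites["site"]
            for m in ("melanic", "gray")
        )
        got = living_model_loglik(PARAMS, tiny_dataset, n_max=250)
        assert got == pytest.approx(want, abs=1e-9)

    def test_fast_path_matches_reference(self, tiny_dataset):
        fast = LivingLikelihood(tiny_dataset)(PARAMS.to_vector())
        ref = living_model_loglik(PARAMS, tiny_dataset)
        assert fast == pytest.approx(ref, abs=1e-9)

    def test_single_precision_kernel_close(self, tiny_dataset):
        f32 = LivingLikelihood(tiny_dataset, cam_dtype=np.float32)(PARAMS.to_vector())
        f64 = LivingLikelihood(tiny_dataset)(PARAMS.to_vector())
        assert f32 == pytest.approx(f64, abs=1e-3)

    def test_invariant_to_site_and_survey_order(self, tiny_dataset):
        import pandas as pd

        from roadcline.data import SiteDataset

        base = LivingLikelihood(tiny_dataset)(PARAMS.to_vector())
        rng = np.random.default_rng(3)
        shuffled = SiteDataset(
            sites=tiny_dataset.sites.sample(frac=1, random_state=1).reset_index(drop=True),
            counts=tiny_dataset.counts.sample(frac=1, random_state=2).reset_index(drop=True),
            cameras=tiny_dataset.cameras.sample(frac=1, random_state=3).reset_index(drop=True),
            distance_std=tiny_dataset.distance_std,
            temperature_std=tiny_dataset.temperature_std,
        )
        assert LivingLikelihood(shuffled)(PARAMS.to_vector()) == pytest.approx(base, abs=1e-9)

    def test_poisson_thinning_equals_joint_marginalization(self, tiny_dataset):
        """Independent morph Poissons == Poisson total + Binomial split,
        marginalized over both latents by brute-force double enumeration."""
        data = tiny_dataset
        n_top = 120
        total = 0.0
        for _, row in data.sites.iterrows():
            s = row["site"]
            z = data.distance_std.transform(row["distance_km"])
            lam_tot = float(np.exp(PARAMS.beta0_N + PARAMS.beta1_N * z))
            p_mel = float(expit(PARAMS.beta0_M + PARAMS.beta1_M * z))
            cnt = data.counts[data.counts["site"] == s]
            cam = data.cameras[data.cameras["site"] == s]

            def obs_prob(n_k, morph):
                prob = 1.0
                for _, r in cnt.iterrows():
                    p = float(detection_probability(PARAMS, r["temperature_std"], morph))
                    prob *= binom.pmf(r[f"count_{morph}"], n_k, p)
                for _, r in cam.iterrows():
                    p = float(detection_probability(PARAMS, r["temperature_std"], morph))
                    p_star = 1 - (1 - p) ** n_k
                    prob *= p_star if r[f"det_{morph}"] else 1 - p_star
                return prob

            site_prob = 0.0
            for n_tot in range(n_top):
                w_tot = poisson.pmf(n_tot, lam_tot)
                if w_tot < 1e-18:
                    continue
                inner = sum(
                    binom.pmf(n_mel, n_tot, p_mel)
                    * obs_prob(n_mel, "melanic") * obs_prob(n_tot - n_mel, "gray")
                    for n_mel in range(n_tot + 1)
                )
                site_prob += w_tot * inner
            total += np.log(site_prob)
        thinned = living_model_loglik(PARAMS, data, n_max=n_top)
        assert thinned == pytest.approx(total, abs=1e-8)


class TestDORModel:
    def test_matches_hand_computation(self):
        params = DORModelParams(alpha_D=-1.0, beta_D=0.5)
        z = np.array([-1.2, -0.3, 0.0, 0.8, 1.5])
        m = np.array([1, 0, 1, 0, 0])
        p = expit(params.alpha_D + params.beta_D * z)
        want = float(np.sum(m * np.log(p) + (1 - m) * np.log(1 - p)))
        assert dor_model_loglik(params, z, m) == pytest.approx(want, abs=1e-12)

    def test_all_melanic_saturates_to_zero(self):
        z = np.zeros(10)
        ll = dor_model_loglik(DORModelParams(alpha_D=40.0, beta_D=0.0), z, np.ones(10))
        assert -1e-10 < ll <= 0

    def test_label_swap_symmetry(self):
        z = np.array([-1.0, 0.0, 2.0])
        m = np.array([1, 0, 1])
        a = dor_model_loglik(DORModelParams(0.7, -0.4), z, m)
        b = dor_model_loglik(DORModelParams(-0.7, 0.4), z, 1 - m)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            dor_model_loglik(DORModelParams(0, 0), [], [])
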
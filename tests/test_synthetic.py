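"""Generator correctness: reproducibility, closed-form moments, thinning
consistency, and type invariants of every synthetic stream."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import chisquare, poisson

from roadcline.data import LatentAbundance
from roadcline.synthetic import (
    RiskTruth,
    SurveyDesign,
    TruthParams,
    make_citizen_table,
    simulate_dor_records,
    simulate_observations,
    simulate_risk_dataset,
    simulate_squirrel_landscape,
    simulate_study,
)


class TestLandscape:
    def test_study_scale_and_range(self, truth):
        sites, latents, std = simulate_squirrel_landscape(truth, 41, seed=5)
        assert len(sites) == 41 and len(latents) == 41
        assert sites["distance_km"].between(0.93, 11.3).all()
        for la in latents:
            assert 0 <= la.n_melanic <= la.n_total

    def test_identical_seeds_identical_output(self, truth):
        a = simulate_squirrel_landscape(truth, 20, seed=9)
        b = simulate_squirrel_landscape(truth, 20, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_flat_cline_shows_no_trend(self):
        t = TruthParams(beta1_N=0.0, beta1_M=0.0)
        sites, latents, std = simulate_squirrel_landscape(t, 4000, seed=2)
        z = std.transform(sites["distance_km"].to_numpy())
        n_tot = np.array([la.n_total for la in latents], dtype=float)
        slope_n = np.polyfit(z, n_tot, 1)[0]
        se_n = n_tot.std() / np.sqrt(len(z))
        assert abs(slope_n) < 3 * se_n
        frac = np.array([
            la.n_melanic / la.n_total for la in latents if la.n_total > 0])
        zf = z[np.array([la.n_total > 0 for la in latents])]
        slope_f = np.polyfit(zf, frac, 1)[0]
        assert abs(slope_f) < 3 * frac.std() / np.sqrt(len(frac))

    def test_poisson_mean_closed_form(self):
        # intercept 2.58 with a flat cline: E[N_total] = exp(2.58) ~ 13.2
        t = TruthParams(beta0_N=2.58, beta1_N=0.0)
        _, latents, _ = simulate_squirrel_landscape(t, 10_000, seed=3)
        n = np.array([la.n_total for la in latents], dtype=float)
        mu = np.exp(2.58)
        assert abs(n.mean() - mu) < 2 * np.sqrt(mu / len(n))

    def test_poisson_thinning_distribution(self):
        """N_melanic over replicate sites is Poisson(lambda * p_mel):
        the two-stage Poisson->Binomial draw equals independent morph
        Poissons (chi-square GOF at alpha=0.01)."""
        t = TruthParams(beta0_N=2.0, beta1_N=0.0, beta0_M=-0.6, beta1_M=0.0)
        _, latents, _ = simulate_squirrel_landscape(t, 20_000, seed=4)
        n_mel = np.array([la.n_melanic for la in latents])
        lam_mel = np.exp(2.0) * expit(-0.6)
        hi = int(poisson.isf(1e-4, lam_mel))
        observed = np.bincount(np.minimum(n_mel, hi), minlength=hi + 1)
        expected = poisson.pmf(np.arange(hi + 1), lam_mel)
        expected[-1] += poisson.sf(hi, lam_mel)
        expected *= len(n_mel)
        stat, p = chisquare(observed, expected)
        assert p > 0.01

    def test_invalid_inputs_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_squirrel_landscape(truth, 1, seed=0)
        with pytest.raises(ValueError):
            TruthParams(distance_range_km=(5.0, 2.0))


class TestObservations:
    def test_perfect_detection_reveals_latents(self, truth):
        t = TruthParams(det_melanic=(50.0, 0.0, 0.0), det_gray=(50.0, 0.0, 0.0))
        sites, latents, std = simulate_squirrel_landscape(t, 12, seed=6, n_camera_sites=5)
        data = simulate_observations(t, sites, latents, SurveyDesign(
            surveys_per_site=3, camera_days=10, n_camera_sites=5), seed=7,
            distance_std=std)
        by_site = {la.site: la for la in latents}
        for _, r in data.counts.iterrows():
            la = by_site[r["site"]]
            assert r["count_melanic"] == la.n_melanic
            assert r["count_gray"] == la.n_total - la.n_melanic
        for _, r in data.cameras.iterrows():
            la = by_site[r["site"]]
            assert r["det_melanic"] == int(la.n_melanic > 0)
            assert r["det_gray"] == int(la.n_total - la.n_melanic > 0)

    def test_empty_sites_yield_zero_observations(self, truth):
        sites = pd.DataFrame({"site": [0, 1], "distance_km": [2.0, 9.0],
                              "camera_flag": [1, 0]})
        latents = [LatentAbundance(0, 0, 0), LatentAbundance(1, 0, 0)]
        data = simulate_observations(truth, sites, latents,
                                     SurveyDesign(surveys_per_site=4, camera_days=6,
                                                  n_camera_sites=1), seed=8)
        assert (data.counts[["count_melanic", "count_gray"]] == 0).all().all()
        assert (data.cameras[["det_melanic", "det_gray"]] == 0).all().all()

    def test_detection_frequency_closed_form(self):
        """Daily detection rate for N=2 at p=0.3 approaches 1-0.7^2=0.51."""
        t = TruthParams(det_melanic=(logit(0.3), 0.0, 0.0),
                        det_gray=(logit(0.3), 0.0, 0.0))
        n_sites = 400
        sites = pd.DataFrame({"site": np.arange(n_sites),
                              "distance_km": np.full(n_sites, 5.0),
                              "camera_flag": np.ones(n_sites, dtype=int)})
        latents = [LatentAbundance(i, 4, 2) for i in range(n_sites)]
        from roadcline.data import Standardizer

        data = simulate_observations(t, sites, latents,
                                     SurveyDesign(surveys_per_site=1, camera_days=250,
                                                  n_camera_sites=n_sites), seed=9,
                                     distance_std=Standardizer(5.0, 1.0))
        freq = data.cameras["det_melanic"].mean()
        p_star = 1 - 0.7**2
        n_days = len(data.cameras)
        assert abs(freq - p_star) < 3 * np.sqrt(p_star * (1 - p_star) / n_days)

    def test_latent_mismatch_rejected(self, truth):
        sites, latents, _ = simulate_squirrel_landscape(truth, 5, seed=1)
        with pytest.raises(ValueError):
            simulate_observations(truth, sites, latents[:-1], SurveyDesign(), seed=2)

    def test_study_default_design(self, truth):
        data, dor, _ = simulate_study(truth, seed=10)
        assert data.n_sites == 41
        assert data.sites["camera_flag"].sum() == 24
        assert (data.counts.groupby("site").size() == 5).all()
        assert (data.cameras.groupby("site").size() == 263).all()
        assert len(dor) == 141


class TestDORRecords:
    def test_count_and_range(self, truth):
        dor = simulate_dor_records(truth, 141, seed=11)
        assert len(dor) == 141
        assert dor["distance_km"].between(0.93, 11.3).all()
        assert dor["morph"].isin([0, 1]).all()

    def test_constant_proportion(self):
        t = TruthParams(alpha_D=float(logit(0.2)), beta_D=0.0)
        dor = simulate_dor_records(t, 50_000, seed=12)
        frac = dor["morph"].mean()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 50_000)

    def test_slope_recovered_by_logistic_fit(self):
        import statsmodels.api as sm

        t = TruthParams(beta_D=-0.22)
        dor = simulate_dor_records(t, 20_000, seed=13)
        z = (dor["distance_km"] - dor["distance_km"].mean()) / dor["distance_km"].std()
        fit = sm.Logit(dor["morph"], sm.add_constant(z)).fit(disp=0)
        assert abs(fit.params.iloc[1] - (-0.22)) < 3 * fit.bse.iloc[1]

    def test_invalid_count_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_dor_records(truth, 0, seed=0)


class TestRiskDataset:
    def test_matched_design_sizes(self):
        ds = simulate_risk_dataset(RiskTruth.default_gray(), 141, seed=14)
        assert len(ds.frame) == 282
        assert ds.group_sizes == (141, 141)
        ds.validate()

    def test_null_outcome_balanced_prevalence(self):
        t = RiskTruth(outcome_intercept=0.0, outcome_coefs={})
        ds = simulate_risk_dataset(t, 500, seed=15, balanced=False)
        prev = ds.frame["outcome"].mean()
        assert abs(prev - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_orphan_node_uncorrelated_with_outcome(self):
        # habitat split has no outcome effect under the gray defaults
        t = RiskTruth.default_gray()
        ds = simulate_risk_dataset(t, 4000, seed=16, balanced=False)
        r = np.corrcoef(ds.frame["habitat_split"], ds.frame["outcome"])[0, 1]
        # habitat_split <- fragmentation <- distance is outcome-disconnected
        # except through morph abundance; allow its weak induced correlation
        assert abs(r) < 0.1

    def test_cyclic_structure_rejected(self):
        t = RiskTruth(edges={("pop_density", "speed"): 1.0,
                             ("speed", "pop_density"): 1.0})
        with pytest.raises(ValueError):
            simulate_risk_dataset(t, 50, seed=17)

    def test_unknown_node_rejected(self):
        t = RiskTruth(edges={("distance", "coyotes"): 1.0})
        with pytest.raises(ValueError):
            simulate_risk_dataset(t, 50, seed=18)


class TestCitizenTable:
    def test_published_totals(self):
        table = make_citizen_table(12_705, 174, 96_025, 1_581)
        np.testing.assert_array_equal(
            table.cells, [[174, 12_531], [1_581, 94_444]])
        assert table.n == 108_730

    def test_zero_dead_row(self):
        table = make_citizen_table(10, 0, 10, 0)
        assert (table.cells[:, 0] == 0).all()

    @pytest.mark.parametrize("args", [(10, 3, 20, 5), (1, 1, 1, 0), (100, 0, 50, 50)])
    def test_total_conserved(self, args):
        table = make_citizen_table(*args)
        assert table.n == args[0] + args[2]

    def test_dead_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            make_citizen_table(10, 11, 5, 0)
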
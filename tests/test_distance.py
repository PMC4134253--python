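"""Detection-function fitting, density conversion and stratified abundance."""

import dataclasses

import numpy as np
import pytest

from parkviable.distance import (
    EASTERN_AREA_HA,
    WESTERN_AREA_HA,
    LineTransect,
    StratumDensity,
    Transect,
    TransectLayout,
    abundance,
    default_park_layout,
    density_estimate,
    detection_probability,
    fit_detection,
    select_detection,
)
from parkviable.synth import synth_sightings


def halfnormal_distances(n, sigma, w, seed):
    """Rejection-sample perpendicular distances from a half-normal g(x)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        x = rng.uniform(0, w, size=4 * n)
        keep = rng.random(4 * n) < np.exp(-(x**2) / (2 * sigma**2))
        out.extend(x[keep][: n - len(out)])
    return np.asarray(out)


def hazard_distances(n, sigma, b, w, seed):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        x = rng.uniform(0, w, size=4 * n)
        g = detection_probability(x, key="hazard-rate", sigma=sigma, b=b)
        keep = rng.random(4 * n) < g
        out.extend(x[keep][: n - len(out)])
    return np.asarray(out)


class TestDetectionFit:
    def test_halfnormal_parameter_recovery_within_3se(self):
        x = halfnormal_distances(500, sigma=10.0, w=40.0, seed=1)
        fit = fit_detection(x, key="half-normal", truncation_w=40.0)
        sigma = fit.key_params["sigma"]
        se_log = np.sqrt(fit.cov_params[0, 0])
        assert abs(np.log(sigma) - np.log(10.0)) < 3 * se_log
        assert 0 < fit.esw <= 40.0
        assert fit.g(0.0) == pytest.approx(1.0)

    def test_uniform_distances_push_esw_to_w(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 30, size=400)
        fit = fit_detection(x, key="half-normal", truncation_w=30.0)
        assert fit.esw > 0.9 * 30.0

    def test_esw_monotone_in_sigma(self):
        x = halfnormal_distances(200, sigma=8.0, w=30.0, seed=3)
        model = LineTransect(x, key="half-normal", truncation_w=30.0)
        esws = [model._esw_of(np.array([np.log(s)])) for s in (5.0, 10.0, 20.0)]
        assert esws[0] < esws[1] < esws[2]

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            LineTransect([1.0, 2.0], key="half-normal", truncation_w=10.0)

    def test_hazard_rate_recovery_and_aic_selection(self):
        x = hazard_distances(500, sigma=12.0, b=3.0, w=40.0, seed=4)
        fit = fit_detection(x, key="hazard-rate", truncation_w=40.0)
        assert fit.key_params["sigma"] == pytest.approx(12.0, rel=0.35)
        assert fit.key_params["b"] == pytest.approx(3.0, rel=0.5)
        best = select_detection(x, truncation_w=40.0)
        assert best.aic <= fit.aic

    def test_model_selection_recovers_hazard_shape_mostly(self):
        wins = 0
        n_rep = 30
        for seed in range(n_rep):
            x = hazard_distances(500, sigma=12.0, b=3.0, w=40.0, seed=100 + seed)
            best = select_detection(x, candidate_orders=(), truncation_w=40.0)
            wins += best.key == "hazard-rate"
        assert wins >= 0.8 * n_rep


class TestDensity:
    def fake_model(self, esw, esw_se=None):
        x = halfnormal_distances(50, sigma=10.0, w=30.0, seed=9)
        fit = fit_detection(x, key="half-normal", truncation_w=30.0)
        return dataclasses.replace(fit, esw=esw, esw_se=esw_se)

    def test_hand_arithmetic(self):
        # 100 sightings over 10 km with ESW 25 m -> 2.0 / ha
        d = density_estimate(self.fake_model(25.0), 100, 10_000.0, area_ha=50.0)
        assert d.density == pytest.approx(2.0)

    def test_zero_sightings_zero_density(self):
        d = density_estimate(self.fake_model(25.0), 0, 10_000.0, area_ha=50.0)
        assert d.density == 0.0 and d.se == 0.0

    def test_scale_invariance(self):
        m = self.fake_model(20.0)
        d1 = density_estimate(m, 50, 5_000.0, area_ha=10.0)
        d2 = density_estimate(m, 100, 10_000.0, area_ha=10.0)
        assert d1.density == pytest.approx(d2.density)

    def test_zero_effort_rejected(self):
        with pytest.raises(ValueError):
            density_estimate(self.fake_model(20.0), 10, 0.0, area_ha=10.0)

    def test_ci_brackets_point(self):
        d = density_estimate(self.fake_model(20.0, esw_se=2.0),
                             [12, 18, 9, 20], [800.0, 900.0, 700.0, 1000.0],
                             area_ha=28.0)
        assert d.ci95[0] <= d.density <= d.ci95[1]


class TestAbundance:
    def test_march_session_worked_example(self):
        # printed March densities x stratum areas: 2.3*28 + 0.9*44 = 104.4
        strata = [
            StratumDensity("eastern", 2.3, 0.7, (1.3, 4.4), EASTERN_AREA_HA, 54, 1.0),
            StratumDensity("western", 0.9, 0.4, (0.3, 2.3), WESTERN_AREA_HA, 24, 1.0),
        ]
        est = abundance(strata)
        assert est.n_hat == pytest.approx(104.0)
        assert round(est.n_hat) == 104

    def test_all_zero_densities(self):
        strata = [StratumDensity("e", 0, 0, (0, 0), 28.0, 0, 1.0),
                  StratumDensity("w", 0, 0, (0, 0), 44.0, 0, 1.0)]
        assert abundance(strata).n_hat == 0.0

    def test_single_stratum(self):
        est = abundance([StratumDensity("s", 1.0, 0.1, (0.8, 1.2), 50.0, 10, 1.0)])
        assert est.n_hat == pytest.approx(50.0)

    def test_duplicate_stratum_labels_rejected(self):
        s = StratumDensity("e", 1.0, 0.1, (0.8, 1.2), 28.0, 10, 1.0)
        with pytest.raises(ValueError, match="overlapping"):
            abundance([s, s])


class TestFullPipeline:
    def test_stratified_survey_recovers_park_abundance(self):
        # survey at the two published stratum densities; the stratified
        # estimator should recover D within 3 SE in a single survey
        layout = default_park_layout()
        recs = synth_sightings({"eastern": 2.4, "western": 1.2}, layout, seed=31)
        fit = select_detection(recs, candidate_orders=(),
                               truncation_w=layout.truncation_w)
        strata = []
        for name, true_d, area in [("eastern", 2.4, EASTERN_AREA_HA),
                                   ("western", 1.2, WESTERN_AREA_HA)]:
            ts = [t for t in layout.transects if t.stratum == name]
            counts = [sum(r.transect_id == t.transect_id for r in recs) for t in ts]
            d = density_estimate(fit, counts, [t.length_m for t in ts],
                                 area_ha=area, stratum=name)
            assert abs(d.density - true_d) < 3 * max(d.se, 0.2)
            strata.append(d)
        est = abundance(strata)
        truth = 2.4 * EASTERN_AREA_HA + 1.2 * WESTERN_AREA_HA  # 120
        assert abs(est.n_hat - truth) < 3 * est.se
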
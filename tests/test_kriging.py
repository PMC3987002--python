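"""Bayesian Kriging, buffer eligibility, and the two-stage error model."""

import numpy as np
import pandas as pd
import pytest

from spatsel import (
    BayesianKriging,
    MCMCSettings,
    SpikeSlabLogisticRegression,
    buffer_filter,
    fit_kriging,
    krige_predict,
    two_stage_fit,
)
from spatsel.exposure import great_circle_distance


def _sites_frame(lon, lat, values, chemical="Pb"):
    return pd.DataFrame(
        {
            "site_id": [f"T{i}" for i in range(len(lon))],
            "lon": lon,
            "lat": lat,
            "medium": "strip",
            "chemical": chemical,
            "concentration": values,
        }
    )


class TestKrigingFixedParams:
    FIX = {"sill": 2.0, "range_km": 5.0, "nugget": 0.0, "mean": 1.0}

    def test_exact_interpolation_zero_nugget(self):
        m = BayesianKriging(log_transform=False, fixed_params=self.FIX)
        X = np.array([[0.0, 0.0], [0.05, 0.0], [0.0, 0.04]])
        y = np.array([3.0, 0.5, -1.0])
        m.fit(X, y)
        mu, sd = m.predict(X, return_std=True)
        np.testing.assert_allclose(mu, y, atol=1e-5)
        assert np.all(sd < 1e-2)

    def test_far_field_reverts_to_process_mean(self):
        m = BayesianKriging(log_transform=False, fixed_params=self.FIX)
        m.fit(np.array([[0.0, 0.0], [0.05, 0.0]]), np.array([3.0, 0.5]))
        mu, sd = m.predict(np.array([[10.0, 10.0]]), return_std=True)
        assert mu[0] == pytest.approx(self.FIX["mean"], abs=1e-6)
        assert sd[0] == pytest.approx(np.sqrt(self.FIX["sill"]), abs=1e-6)

    def test_two_point_closed_form_oracle(self):
        # explicit 2x2 GP regression computed by hand in the test
        sill, rng_km, mean = 2.0, 5.0, 1.0
        m = BayesianKriging(
            log_transform=False,
            fixed_params={"sill": sill, "range_km": rng_km, "nugget": 0.0,
                          "mean": mean},
        )
        pts = np.array([[0.0, 0.0], [0.1, 0.0]])
        y = np.array([2.5, 0.3])
        m.fit(pts, y)
        target = np.array([[0.04, 0.01]])
        mu, sd = m.predict(target, return_std=True)

        d = lambda a, b: great_circle_distance((a[0], a[1]), (b[0], b[1]))
        C = sill * np.exp(-np.array([[0.0, d(pts[0], pts[1])],
                                     [d(pts[1], pts[0]), 0.0]]) / rng_km)
        np.fill_diagonal(C, sill)
        k = sill * np.exp(-np.array([d(target[0], pts[0]),
                                     d(target[0], pts[1])]) / rng_km)
        Ci = np.linalg.inv(C + 1e-12 * sill * np.eye(2))
        mu_exp = mean + k @ Ci @ (y - mean)
        var_exp = sill - k @ Ci @ k
        assert mu[0] == pytest.approx(mu_exp, abs=1e-8)
        assert sd[0] ** 2 == pytest.approx(var_exp, abs=1e-8)

    def test_predictive_sd_nondecreasing_with_distance(self):
        m = BayesianKriging(log_transform=False, fixed_params=self.FIX)
        m.fit(np.array([[0.0, 0.0]]), np.array([2.0]))
        lons = np.linspace(0.0, 0.5, 20)
        _, sd = m.predict(np.c_[lons, np.zeros(20)], return_std=True)
        assert np.all(np.diff(sd) >= -1e-9)

    def test_conflicting_duplicates_zero_nugget_flagged(self):
        m = BayesianKriging(log_transform=False,
                            fixed_params={"sill": 1.0, "range_km": 5.0,
                                          "nugget": 0.0})
        X = np.array([[0.0, 0.0], [0.0, 0.0], [0.1, 0.0]])
        with pytest.raises(ValueError, match="singular|duplicat"):
            m.fit(X, np.array([1.0, 5.0, 2.0]))

    def test_constant_field_rejected_for_inference(self):
        m = BayesianKriging(log_transform=False)
        X = np.c_[np.linspace(0, 0.3, 6), np.zeros(6)]
        with pytest.raises(ValueError, match="constant.*nugget-only"):
            m.fit(X, np.full(6, 2.0))


class TestKrigingPosterior:
    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(-80.3, -80.1, 30)
        lat = rng.uniform(32.5, 32.7, 30)
        vals = np.exp(rng.standard_normal(30))
        sites = _sites_frame(lon, lat, vals)
        kw = dict(mcmc={"n_iter": 300, "burn_in": 100, "thin": 5}, seed=3)
        a = fit_kriging(sites, **kw)
        b = fit_kriging(sites, **kw)
        pd.testing.assert_frame_equal(a.draws_, b.draws_)

    def test_positive_hyperparameters_and_predictions(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-80.3, -80.1, 40)
        lat = rng.uniform(32.5, 32.7, 40)
        vals = np.exp(rng.standard_normal(40))
        model = fit_kriging(_sites_frame(lon, lat, vals),
                            mcmc={"n_iter": 400, "burn_in": 200, "thin": 5},
                            seed=0)
        assert (model.draws_[["sill", "range_km", "nugget"]] > 0).all().all()
        targets = pd.DataFrame({"participant_id": ["P0"], "address_class": ["first"],
                                "lon": [-80.2], "lat": [32.6]})
        pred = krige_predict(model, targets)
        assert set(pred.columns) == {"participant_id", "chemical", "mean", "sd"}
        assert (pred["sd"] >= 0).all()

    def test_too_few_sites_rejected(self):
        sites = _sites_frame([-80.2, -80.21], [32.6, 32.61], [1.0, 2.0])
        with pytest.raises(ValueError, match="5 sites"):
            fit_kriging(sites)


class TestBufferFilter:
    @staticmethod
    def _strip():
        lon = np.linspace(-80.3, -80.1, 40)
        lat = np.full(40, 32.62)
        lat[::2] += 0.004
        return pd.DataFrame({"site_id": [f"T{i}" for i in range(40)],
                             "lon": lon, "lat": lat, "medium": "strip"})

    def test_address_on_site_eligible(self):
        strip = self._strip()
        addr = pd.DataFrame({"participant_id": ["P0"], "address_class": ["first"],
                             "lon": [strip["lon"][5]], "lat": [strip["lat"][5]]})
        assert len(buffer_filter(addr, strip)) == 1

    def test_far_address_excluded(self):
        addr = pd.DataFrame({"participant_id": ["P0"], "address_class": ["first"],
                             "lon": [-80.2], "lat": [33.1]})  # ~50 km north
        assert buffer_filter(addr, self._strip()).empty

    def test_matches_bruteforce_hull_oracle(self):
        strip = self._strip()
        rng = np.random.default_rng(2)
        addr = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(200)],
            "address_class": "first",
            "lon": rng.uniform(-80.35, -80.05, 200),
            "lat": rng.uniform(32.55, 32.70, 200),
        })
        got = set(buffer_filter(addr, strip, radius_km=1.0)["participant_id"])

        # oracle: scipy convex hull + segment distances in the same projection
        from scipy.spatial import ConvexHull
        from spatsel.kriging import _local_km

        lon0, lat0 = strip["lon"].mean(), strip["lat"].mean()
        sx, sy = _local_km(strip["lon"], strip["lat"], lon0, lat0)
        hull = ConvexHull(np.c_[sx, sy])
        verts = np.c_[sx, sy][hull.vertices]
        from matplotlib.path import Path

        poly = Path(verts)
        ax, ay = _local_km(addr["lon"], addr["lat"], lon0, lat0)

        def seg_dist(p, a, b):
            ab, ap = b - a, p - a
            t = np.clip(ap @ ab / (ab @ ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        expected = set()
        for pid, x, y in zip(addr["participant_id"], ax, ay):
            p = np.array([x, y])
            inside = poly.contains_point((x, y))
            dmin = min(
                seg_dist(p, verts[i], verts[(i + 1) % len(verts)])
                for i in range(len(verts))
            )
            if inside or dmin <= 1.0:
                expected.add(pid)
        assert got == expected

    def test_empty_strip_rejected(self):
        addr = pd.DataFrame({"participant_id": ["P0"], "address_class": ["first"],
                             "lon": [-80.2], "lat": [32.6]})
        with pytest.raises(ValueError):
            buffer_filter(addr, self._strip().iloc[:0])


def _two_stage_inputs(seed=3, n=15, sd=0.3, beta=2.5):
    rng = np.random.default_rng(seed)
    chems = ["As", "Cr", "Cu", "Mn", "Pb"]
    means = {c: rng.standard_normal(n) for c in chems}
    lp = beta * means["Pb"]
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp)))
    kriged = {
        c: pd.DataFrame({"participant_id": [f"P{i}" for i in range(n)],
                         "chemical": c, "mean": means[c],
                         "sd": np.full(n, sd)})
        for c in chems
    }
    return y, kriged, means


class TestTwoStage:
    def test_true_metal_attains_highest_inclusion(self):
        wins = 0
        for seed in range(5):
            y, kriged, _ = _two_stage_inputs(seed=seed)
            fit = two_stage_fit(
                y, kriged,
                mcmc=MCMCSettings(n_iter=1500, burn_in=500, thin=2,
                                  n_chains=1, seed=seed),
            )
            chems = fit.chemicals
            probs = fit.summary.table.loc[chems, "prob_mean"]
            wins += probs.idxmax() == "Pb"
        assert wins >= 4

    def test_zero_sd_collapses_to_plain_fit(self):
        y, kriged, means = _two_stage_inputs(seed=9, n=40, sd=0.0)
        fit = two_stage_fit(
            y, kriged,
            mcmc=MCMCSettings(n_iter=3000, burn_in=1000, thin=2, n_chains=1,
                              seed=1),
        )
        X = pd.DataFrame(means)
        plain = SpikeSlabLogisticRegression(
            n_iter=3000, burn_in=1000, thin=2, n_chains=1, random_state=1
        ).fit(X, y)
        a = fit.samples.beta.mean(axis=0)
        b = plain.samples_.beta.mean(axis=0)
        # same posterior up to MCMC error (identical model, different stream)
        np.testing.assert_allclose(a[X.columns], b[X.columns], atol=0.35)
        # and the latent errors really are pinned to zero
        assert np.abs(fit.omega).max() == 0.0

    def test_intervals_widen_with_measurement_error(self):
        # moderate error levels, where the true term stays in the slab; at
        # extreme error the spike absorbs the coefficient and intervals
        # re-tighten around zero
        widths = []
        for sd in (0.0, 0.4, 0.8):
            y, kriged, _ = _two_stage_inputs(seed=5, n=60, sd=sd, beta=2.0)
            fit = two_stage_fit(
                y, kriged,
                mcmc=MCMCSettings(n_iter=3000, burn_in=1000, thin=2,
                                  n_chains=1, seed=2),
            )
            draws = fit.samples.beta["Pb"].to_numpy()
            lo, hi = np.quantile(draws, [0.025, 0.975])
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_missing_prediction_named(self):
        y, kriged, _ = _two_stage_inputs(seed=1)
        kriged["Cr"] = kriged["Cr"].iloc[:-1]
        with pytest.raises(ValueError, match="Cr"):
            two_stage_fit(y, kriged)
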
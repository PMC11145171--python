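"""Poisson signature fitting, the presence LRT and the synthetic calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats

from chemotrace.catalog import MutationCatalog96
from chemotrace.channels import N_CHANNELS
from chemotrace.signatures import (
    ExposureVector,
    SignatureActivityModel,
    SignatureProfile,
    SignatureSet,
    calibrate_activity,
    fit_exposures,
    load_bundled_signatures,
    log_likelihood,
    test_signature_presence as presence_test,
)
from chemotrace.simulate import simulate_catalog, simulate_catalogs


def _profile(name, hot, weight=1.0):
    """Toy profile with mass on the given channels."""
    p = np.zeros(N_CHANNELS)
    for c in hot:
        p[c] = weight / len(hot)
    return SignatureProfile(name, p / p.sum())


class TestContainers:
    def test_profile_must_normalize(self):
        with pytest.raises(ValueError):
            SignatureProfile("bad", np.full(N_CHANNELS, 0.5))
        with pytest.raises(ValueError):
            SignatureProfile("bad", -np.ones(N_CHANNELS) / N_CHANNELS)

    def test_set_rejects_duplicates(self, signatures):
        with pytest.raises(ValueError):
            SignatureSet(signatures.profiles + [signatures.profiles[0]])

    def test_tsv_roundtrip(self, tmp_path, signatures):
        path = tmp_path / "sigs.tsv"
        signatures.to_tsv(path)
        back = SignatureSet.from_tsv(path)
        assert back.names == signatures.names
        np.testing.assert_allclose(back.matrix, signatures.matrix, atol=1e-12)

    def test_bundled_platinum_profile_peaks(self, signatures):
        """The platinum profile's two largest channels are C[C>T]T and
        C[C>T]C, the contexts that dominate platinum-exposed samples."""
        ser = signatures["SBS31"].to_series()
        assert set(ser.nlargest(2).index) == {"C[C>T]T", "C[C>T]C"}

    def test_exposure_vector(self):
        e = ExposureVector(names=["A", "B"], activities=[3.0, 7.0])
        assert e.total == 10.0
        assert e["B"] == 7.0
        assert e.group_total(["B", "missing"]) == 7.0
        with pytest.raises(ValueError):
            ExposureVector(names=["A"], activities=[-1.0])


class TestLogLikelihood:
    def test_empty_catalog_zero_exposures(self, signatures):
        cat = MutationCatalog96(np.zeros(N_CHANNELS))
        exp = ExposureVector(names=signatures.names, activities=np.zeros(5))
        assert log_likelihood(cat, signatures, exp) == 0.0

    def test_matches_direct_poisson_sum(self, signatures):
        """Oracle: independent per-channel Poisson log-pmf summation."""
        sig = signatures["SBS5"]
        n = 2000.0
        counts = np.round(n * sig.probs)
        cat = MutationCatalog96(counts)
        ss = SignatureSet([sig])
        exp = ExposureVector(names=["SBS5"], activities=[n])
        expected = stats.poisson.logpmf(counts, n * sig.probs).sum()
        assert log_likelihood(cat, ss, exp) == pytest.approx(expected, rel=1e-12)

    def test_zero_intensity_with_counts_is_minus_inf(self):
        a = _profile("A", [0, 1])
        cat = MutationCatalog96(np.eye(N_CHANNELS)[5] * 3)
        exp = ExposureVector(names=["A"], activities=[10.0])
        assert log_likelihood(cat, SignatureSet([a]), exp) == -np.inf

    def test_dimension_mismatch(self, signatures):
        cat = MutationCatalog96(np.ones(N_CHANNELS))
        exp = ExposureVector(names=["SBS1"], activities=[1.0])
        with pytest.raises(ValueError):
            log_likelihood(cat, signatures, exp)


class TestFitExposures:
    def test_single_signature_identity(self, signatures):
        sig = signatures["SBS31"]
        counts = np.round(1000 * sig.probs)
        exp = fit_exposures(MutationCatalog96(counts), SignatureSet([sig]))
        assert exp["SBS31"] == pytest.approx(1000, rel=0.01)

    def test_disjoint_support_closed_form(self):
        a = _profile("A", range(0, 10))
        b = _profile("B", range(50, 60))
        counts = np.zeros(N_CHANNELS)
        counts[range(0, 10)] = 30.0  # 300 from A
        counts[range(50, 60)] = 70.0  # 700 from B
        exp = fit_exposures(MutationCatalog96(counts), SignatureSet([a, b]))
        assert exp["A"] == pytest.approx(300.0, abs=1e-4)
        assert exp["B"] == pytest.approx(700.0, abs=1e-4)

    def test_mle_is_local_optimum(self, signatures, rng):
        cat, _ = simulate_catalog({"SBS5": 0.7, "SBS31": 0.3}, 1500, seed=5)
        ss = signatures.subset(["SBS5", "SBS31"])
        model = SignatureActivityModel(cat, ss)
        res = model.fit()
        best = model.loglike(res.exposures.activities)
        for _ in range(50):
            step = rng.normal(scale=0.5, size=2)
            trial = np.maximum(res.exposures.activities + step, 0.0)
            assert model.loglike(trial) <= best + 1e-9

    @pytest.mark.parametrize("k", [2, 5])
    def test_scale_equivariance(self, signatures, k):
        cat, _ = simulate_catalog({"SBS5": 0.6, "SBS1": 0.4}, 1000, seed=9)
        ss = signatures.subset(["SBS5", "SBS1"])
        e1 = fit_exposures(cat, ss).activities
        ek = fit_exposures(MutationCatalog96(cat.counts * k), ss).activities
        np.testing.assert_allclose(ek, k * e1, rtol=0.01)

    def test_matches_brute_force_grid_search(self, signatures):
        """On small 3-signature catalogs the optimizer's log-likelihood
        matches a nested brute-force grid search to 1e-6."""
        ss = signatures.subset(["SBS1", "SBS5", "SBS31"])
        P = ss.matrix
        for seed in (1, 2, 3):
            cat, _ = simulate_catalog(
                {"SBS1": 0.3, "SBS5": 0.4, "SBS31": 0.3}, 50, seed=seed
            )
            x = cat.counts
            model = SignatureActivityModel(cat, ss)

            def ll(e):
                mu = e @ P
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = np.where(x > 0, x * np.log(mu), 0.0)
                t = np.where((mu == 0) & (x > 0), -np.inf, t)
                return (t - mu).sum()  # constant log(x!) dropped on both sides

            # stage 1: integer grid over [0, n]^3 (step 1 mutation)
            n = int(x.sum())
            axes = [np.arange(0, n + 1.0)] * 3
            best, best_ll = None, -np.inf
            for e in itertools.product(*axes):
                v = ll(np.array(e))
                if v > best_ll:
                    best, best_ll = np.array(e), v
            # nested refinement around the integer optimum, still brute force
            for step in (0.1, 0.01, 1e-3, 1e-4):
                grid = [b + np.arange(-10, 11) * step for b in best]
                for e in itertools.product(*grid):
                    e = np.maximum(np.array(e), 0.0)
                    v = ll(e)
                    if v > best_ll:
                        best, best_ll = e, v
            fitted = model.fit()
            assert ll(fitted.exposures.activities) == pytest.approx(best_ll, abs=1e-6)

    def test_reconstruction_cosine_similarity(self, signatures):
        """Catalogs simulated from a fitted model are close (cosine > 0.95)
        to the fitted reconstruction."""
        cat, _ = simulate_catalog({"SBS5": 0.5, "SBS1": 0.2, "SBS31": 0.3}, 2000, seed=21)
        ss = signatures.subset(["SBS5", "SBS1", "SBS31"])
        res = SignatureActivityModel(cat, ss).fit()
        assert res.cosine_similarity() > 0.95
        rng = np.random.default_rng(22)
        sim = rng.poisson(res.fittedvalues)
        mu = res.fittedvalues
        cos = sim @ mu / np.linalg.norm(sim) / np.linalg.norm(mu)
        assert cos > 0.95

    def test_summary_mentions_all_signatures(self, signatures):
        cat, _ = simulate_catalog({"SBS5": 1.0}, 500, seed=2)
        res = SignatureActivityModel(cat, signatures.subset(["SBS5", "SBS1"])).fit()
        text = res.summary()
        assert "SBS5" in text and "SBS1" in text and "log-likelihood" in text


class TestPresenceTest:
    def test_nested_loglik_ordering(self, signatures, baseline):
        for seed, mix in ((1, {"SBS5": 1.0}), (2, {"SBS5": 0.6, "SBS31": 0.4})):
            cat, _ = simulate_catalog(mix, 1000, seed=seed)
            res = presence_test(cat, baseline, signatures["SBS31"])
            assert res.loglik_with >= res.loglik_without - 1e-9
            assert res.lr_statistic >= 0.0
            assert 0.0 <= res.p_value <= 1.0

    def test_detects_strong_signal(self, signatures, baseline):
        cat, _ = simulate_catalog({"SBS5": 0.6, "SBS31": 0.4}, 2231, seed=3)
        res = presence_test(cat, baseline, signatures["SBS31"])
        assert res.decision == "present"
        assert res.p_value < 1e-6

    def test_bootstrap_mode_reproducible(self, signatures, baseline):
        cat, _ = simulate_catalog({"SBS5": 0.7, "SBS31": 0.3}, 800, seed=4)
        r1 = presence_test(
            cat, baseline, signatures["SBS31"], mode="bootstrap", n_boot=200, seed=7
        )
        r2 = presence_test(
            cat, baseline, signatures["SBS31"], mode="bootstrap", n_boot=200, seed=7
        )
        assert r1.p_value == r2.p_value
        assert r1.decision == "present"

    def test_degenerate_candidate_rejected(self, signatures, baseline):
        cat, _ = simulate_catalog({"SBS5": 1.0}, 100, seed=5)
        with pytest.raises(ValueError):
            presence_test(cat, baseline, signatures["SBS5"])


class TestCalibration:
    def test_recovers_injected_platinum_activity(self, signatures, baseline):
        """Injected platinum activity at the therapy-AML scale (932 of 2231)
        is recovered within 15% on average."""
        rng_seeds = np.random.SeedSequence(31).spawn(40)
        points = []
        for i in range(20):
            counts, _ = simulate_catalogs(
                {"SBS1": 0.117, "SBS5": 0.349, "SBS40": 0.116, "SBS31": 0.418},
                2231, 1, seed=rng_seeds[2 * i],
            )
            cal = calibrate_activity(
                MutationCatalog96(counts[0]), baseline, signatures["SBS31"],
                seed=rng_seeds[2 * i + 1],
            )
            points.append(cal.point_activity)
            assert cal.interval[0] <= cal.point_activity <= cal.interval[1]
        assert np.mean(points) == pytest.approx(932, rel=0.15)

    def test_mean_response_is_monotone(self, signatures, baseline):
        cat, _ = simulate_catalog({"SBS5": 1.0}, 1000, seed=33)
        cal = calibrate_activity(
            MutationCatalog96(cat.counts), baseline, signatures["SBS31"], seed=34
        )
        assert (np.diff(cal.mean_recovered) >= 0).all()
        assert cal.n_synthetic >= 100

    def test_requires_enough_synthetic_samples(self, signatures, baseline):
        cat, _ = simulate_catalog({"SBS5": 1.0}, 200, seed=35)
        with pytest.raises(ValueError):
            calibrate_activity(
                MutationCatalog96(cat.counts), baseline, signatures["SBS31"],
                n_replicates=5, grid_size=11,
            )
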
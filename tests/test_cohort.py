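"""Synthetic cohort generator: prototype geometry, waveform statistics,
text model, outcome model, on-disk round trips."""

import json

import numpy as np
import pytest

from riemecg import cohort as C
from riemecg import geometry as g
from riemecg.evaluate import CohortDataset


class TestPrototypes:
    def test_zero_separation_collapses_to_base(self):
        cfg = C.CohortConfig(separation=0.0)
        protos = C.make_class_prototypes(cfg, np.random.default_rng(0))
        base = C.base_covariance(cfg.dim)
        assert all(np.allclose(p, base) for p in protos)

    def test_pairwise_distance_grows_with_separation(self):
        dmins = []
        for sep in (0.5, 1.0, 2.0):
            cfg = C.CohortConfig(separation=sep)
            protos = C.make_class_prototypes(cfg, np.random.default_rng(3))
            d = min(
                g.riemannian_distance(protos[i], protos[j])
                for i in range(len(protos))
                for j in range(i + 1, len(protos))
            )
            assert d >= 0.5 * sep
            dmins.append(d)
        assert dmins[0] < dmins[1] < dmins[2]

    def test_prototypes_are_spd(self):
        protos = C.make_class_prototypes(C.CohortConfig(), np.random.default_rng(1))
        assert all(np.linalg.eigvalsh(p).min() > 0 for p in protos)


class TestPatientCovariance:
    def test_zero_dispersion_returns_prototype(self, rand_spd):
        proto = rand_spd(12, scale=0.04)
        assert np.array_equal(C.sample_patient_covariance(proto, 0.0, np.random.default_rng(0)), proto)

    def test_draws_are_spd_and_centred_on_prototype(self, rand_spd):
        """Frechet mean of many draws sits near the prototype (Karcher consistency)."""
        proto = rand_spd(6, scale=0.1)
        rng = np.random.default_rng(8)
        dispersion = 0.4
        draws = [C.sample_patient_covariance(proto, dispersion, rng) for _ in range(200)]
        assert all(np.linalg.eigvalsh(d).min() > 0 for d in draws)
        mean = g.frechet_mean(draws)
        assert g.riemannian_distance(mean, proto) < 0.1 * dispersion * np.sqrt(200 / 50)

    def test_dispersion_sets_the_riemannian_radius(self, rand_spd):
        proto = rand_spd(12, scale=0.05)
        rng = np.random.default_rng(5)
        dists = [
            g.riemannian_distance(C.sample_patient_covariance(proto, 0.3, rng), proto)
            for _ in range(100)
        ]
        assert np.mean(dists) == pytest.approx(0.3, rel=0.2)


class TestEcgSimulation:
    def test_long_record_covariance_converges(self, rng):
        cov = C.base_covariance(12)
        cfg = C.EcgSimConfig(duration_s=120.0, qrs_amplitude=0.0)
        sig, _ = C.simulate_ecg(cov, cfg, rng)
        est = np.cov(sig)
        assert np.linalg.norm(est - cov) / np.linalg.norm(cov) < 0.05

    def test_contract_with_record_invariants(self, rng):
        sig, peaks = C.simulate_ecg(C.base_covariance(12), C.EcgSimConfig(), rng)
        assert sig.shape == (12, 15000)  # 30 s at 500 Hz
        assert np.all(np.diff(peaks) > 0)

    def test_too_short_duration_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            C.simulate_ecg(
                C.base_covariance(12),
                C.EcgSimConfig(duration_s=1.2, heart_rate_bpm=(40.0, 40.0)),
                rng,
            )


class TestTextSimulation:
    def test_lengths_and_determinism(self):
        tcfg = C.TextSimConfig(doc_length=(5, 9))
        model = C.make_text_model(tcfg, 3, np.random.default_rng(2))
        import datetime

        kw = dict(patient_id="p", doc_date=datetime.date(2020, 1, 1))
        docs1 = [
            C.simulate_letters(0, model, tcfg, np.random.default_rng(4), **kw)
            for _ in range(20)
        ]
        docs2 = [
            C.simulate_letters(0, model, tcfg, np.random.default_rng(4), **kw)
            for _ in range(20)
        ]
        assert all(5 <= len(d.terms) <= 9 for d in docs1)
        assert [d.terms for d in docs1] == [d.terms for d in docs2]

    def test_high_concentration_limit_makes_classes_indistinct(self):
        """Dirichlet limit: class term distributions converge to the base."""
        rng = np.random.default_rng(0)
        tight = C.make_text_model(
            C.TextSimConfig(class_topic_concentration=1e5), 5, rng
        ).class_probs
        loose = C.make_text_model(
            C.TextSimConfig(class_topic_concentration=0.2), 5, np.random.default_rng(0)
        ).class_probs
        div_tight = np.abs(tight - tight.mean(axis=0)).sum(axis=1).mean()
        div_loose = np.abs(loose - loose.mean(axis=0)).sum(axis=1).mean()
        assert div_tight < 0.02 < div_loose

    def test_severity_weight_shifts_mass_to_severity_terms(self):
        import datetime

        tcfg = C.TextSimConfig(severity_weight=0.9, doc_length=(200, 200))
        model = C.make_text_model(tcfg, 2, np.random.default_rng(3))
        kw = dict(patient_id="p", doc_date=datetime.date(2020, 1, 1))
        sev_tokens = set(np.array(model.tokens)[model.severity_probs > 0])
        low = C.simulate_letters(0, model, tcfg, np.random.default_rng(9), severity=-4.0, **kw)
        high = C.simulate_letters(0, model, tcfg, np.random.default_rng(9), severity=4.0, **kw)
        frac = lambda d: np.mean([t in sev_tokens for t in d.terms])
        assert frac(high) > frac(low)


class TestOutcomeSimulation:
    def test_noiseless_outcome_equals_linear_map(self):
        import datetime

        ocfg = C.OutcomeSimConfig(noise_sd={"ve_vco2": 0.0, "vo2_pred_pct": 0.0, "vo2_peak": 0.0})
        out, means, n_cl = C.simulate_cpet(
            1.3, ocfg, np.random.default_rng(0),
            patient_id="p", test_date=datetime.date(2020, 1, 1),
        )
        assert out.ve_vco2 == pytest.approx(30.0 + 8.0 * 1.3)
        assert out.ve_vco2 == pytest.approx(means["ve_vco2"])
        assert n_cl == 0

    def test_empirical_r2_matches_target(self):
        """Signal-to-noise identity on a large cohort of standardised scores."""
        import datetime

        rng = np.random.default_rng(6)
        ocfg = C.OutcomeSimConfig(target_r2=0.6)
        zs = rng.standard_normal(4000)
        vals = np.array(
            [
                C.simulate_cpet(z, ocfg, rng, patient_id="p", test_date=datetime.date(2020, 1, 1))[0].ve_vco2
                for z in zs
            ]
        )
        means = 30.0 + 8.0 * zs
        ss_res = np.sum((vals - means) ** 2)
        ss_tot = np.sum((vals - vals.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.6, abs=0.05)

    def test_default_scales_never_clamp(self, small_cohort):
        assert small_cohort.truth.n_clamped == 0


class TestCohortAssembly:
    def test_counts_and_linkage(self, small_cohort):
        assert len(small_cohort.records) == 10
        assert len(small_cohort.histories) == 10  # one letter per patient
        assert len(small_cohort.outcomes) == 10
        for h, r in zip(small_cohort.histories, small_cohort.records):
            assert abs((h.doc_date - r.record_date).days) <= 90

    def test_default_cohort_shape(self):
        cfg = C.CohortConfig()
        assert sum(cfg.patients_per_class) == 40
        assert cfg.n_classes == 5

    def test_reingestion_runs_without_warnings(self, small_cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ds = C.to_dataset(small_cohort)
        assert len(ds.entries) == 10
        assert all(e.doc is not None for e in ds.entries)

    def test_generated_directory_round_trips(self, tmp_path):
        cfg = C.CohortConfig(
            n_classes=2,
            patients_per_class=(2, 2),
            ecg=C.EcgSimConfig(duration_s=5.0),
            seed=31,
        )
        out = C.generate_cohort(cfg, tmp_path / "cohort")
        gt = json.loads((out / "ground_truth.json").read_text())
        assert len(gt["class_ids"]) == 4
        assert len(list((out / "ecg").glob("*.csv"))) == 4
        ds = CohortDataset.from_directory(out)
        assert len(ds.entries) == 4
        sim = C.simulate_cohort(cfg)
        for e in ds.entries:
            rec = next(r for r in sim.records if r.patient_id == e.patient_id)
            assert e.class_id == str(sim.class_by_patient[e.patient_id])

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = C.CohortConfig(
            n_classes=2,
            patients_per_class=(2, 2),
            ecg=C.EcgSimConfig(duration_s=3.0),
            seed=13,
        )
        a = C.generate_cohort(cfg, tmp_path / "a")
        b = C.generate_cohort(cfg, tmp_path / "b")
        for rel in ["records.csv", "clinical.csv", "cpet.csv", "ground_truth.json", "ecg/P000.csv"]:
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_distractor_docs_exercise_linkage(self):
        cfg = C.CohortConfig(
            n_classes=2,
            patients_per_class=(2, 2),
            ecg=C.EcgSimConfig(duration_s=3.0),
            distractor_docs=True,
            seed=5,
        )
        sim = C.simulate_cohort(cfg)
        assert len(sim.histories) == 8  # near + far letter per patient
        ds = C.to_dataset(sim)
        for e in ds.entries:
            assert abs((e.doc.doc_date - e.ecg_date).days) <= 90  # near one chosen
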
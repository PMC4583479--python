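"""Panel-LD imputation, INFO scores, and variant QC."""

import numpy as np
import pytest

from finemapsim.assoc import MetaResult
from finemapsim.impute import (QCThresholds, fit_imputation_model,
                               impute_study, qc_filter)
from finemapsim.simulate import (ScenarioSpec, apply_scenario,
                                 build_disease_model, select_array_mask,
                                 simulate_case_control)

from conftest import make_panel


def proxy_fixture(seed=0, h=200):
    """Five typed variants; u0 duplicates t0 (r^2=1), u1 is independent."""
    rng = np.random.default_rng(seed)
    t = [(rng.random(h) < p).astype(np.uint8)
         for p in (0.3, 0.5, 0.2, 0.4, 0.25)]
    u0 = t[0].copy()
    u1 = (rng.random(h) < 0.3).astype(np.uint8)
    hap = np.stack(t[:3] + [u0] + t[3:] + [u1], axis=1)
    ids = ["t0", "t1", "t2", "u0", "t3", "t4", "u1"]
    panel = make_panel(hap, ids=ids,
                       positions=[100, 200, 300, 350, 400, 500, 90000],
                       region_length=100_000)
    return panel, ["t0", "t1", "t2", "t3", "t4"]


def study_from_panel(panel, n=300, seed=1):
    """Phenotype-free cohort: random pairs of panel haplotypes."""
    model = build_disease_model(panel, [(panel.variants[0].id, 1.0)], 0.01)
    return simulate_case_control(panel, model, n // 2, n - n // 2, seed,
                                 switch_rate=0.0)


class TestFitImputationModel:
    def test_perfect_proxy(self):
        panel, mask = proxy_fixture()
        model = fit_imputation_model(panel, mask, k_neighbors=5, ridge=1e-4,
                                     n_augment=0)
        u0 = panel.index_of("u0")
        assert model.theoretical_info[u0] >= 0.99
        coefs = dict(zip(model.neighbors[u0], model.coefs[u0]))
        t0 = panel.index_of("t0")
        assert coefs[t0] == pytest.approx(1.0, abs=0.05)

    def test_independent_variant_uninformative(self):
        panel, mask = proxy_fixture()
        model = fit_imputation_model(panel, ["t0", "t1", "t2"],
                                     k_neighbors=3, ridge=1e-4, n_augment=0)
        u1 = panel.index_of("u1")
        assert model.theoretical_info[u1] <= 0.05

    def test_removing_best_proxy_never_raises_info(self):
        panel, mask = proxy_fixture()
        with_proxy = fit_imputation_model(panel, mask, k_neighbors=5,
                                          ridge=1e-4, n_augment=0)
        without = fit_imputation_model(panel, [m for m in mask if m != "t0"],
                                       k_neighbors=5, ridge=1e-4, n_augment=0)
        u0 = panel.index_of("u0")
        assert without.theoretical_info[u0] <= \
            with_proxy.theoretical_info[u0] + 1e-9

    def test_monomorphic_unimputable(self):
        panel, mask = proxy_fixture()
        panel.haplotypes[:, panel.index_of("u1")] = 0
        for v in panel.variants:
            v.alt_freq = float(
                panel.haplotypes[:, panel.index_of(v.id)].mean())
        panel.__dict__.pop("_views", None)
        model = fit_imputation_model(panel, mask, n_augment=0)
        assert panel.index_of("u1") in model.unimputable


class TestImputeStudy:
    def test_fully_typed_is_identity(self):
        panel, mask = proxy_fixture()
        study = study_from_panel(panel)
        model = fit_imputation_model(panel, list(panel.ids), n_augment=0)
        out = impute_study(study, model)
        assert np.array_equal(out.dosages, study.dosages)
        assert np.all(out.info == 1.0)

    def test_perfect_proxy_recovers_truth(self):
        panel, mask = proxy_fixture()
        study = study_from_panel(panel)
        truth = study.dosages.copy()
        masked = apply_scenario(study, ScenarioSpec("gwas",
                                                    array_mask=mask))
        model = fit_imputation_model(panel, mask, k_neighbors=5, ridge=1e-4,
                                     n_augment=0)
        out = impute_study(masked, model)
        u0 = panel.index_of("u0")
        agree = np.mean(np.abs(out.dosages[:, u0] - truth[:, u0]) < 0.5)
        assert agree >= 0.99
        assert out.info[u0] > 0.9

    def test_independent_variant_flat_dosage(self):
        panel, _ = proxy_fixture()
        mask = ["t0", "t1", "t2", "t3", "t4", "u0"]
        study = study_from_panel(panel)
        masked = apply_scenario(study, ScenarioSpec("gwas",
                                                    array_mask=mask))
        model = fit_imputation_model(panel, mask, k_neighbors=5, ridge=1e-4,
                                     n_augment=0)
        out = impute_study(masked, model)
        u1 = panel.index_of("u1")
        assert out.info[u1] < 0.1
        p = panel.alt_freqs[u1]
        assert np.mean(out.dosages[:, u1]) == pytest.approx(2 * p, abs=0.15)

    def test_typed_calls_never_modified(self, panel600):
        mask = select_array_mask(
            panel600, 0.3 * panel600.n_variants / 1.0, seed=3)
        study = study_from_panel(panel600, n=200, seed=5)
        truth = study.dosages.copy()
        masked = apply_scenario(study, ScenarioSpec("gwas", array_mask=mask))
        model = fit_imputation_model(panel600, mask, seed=4)
        out = impute_study(masked, model)
        typed_cols = np.where(out.typed)[0]
        assert np.array_equal(out.dosages[:, typed_cols],
                              truth[:, typed_cols])
        assert np.all(out.info[typed_cols] == 1.0)

    def test_empirical_tracks_theoretical_info(self, panel600):
        from scipy.stats import spearmanr

        mask = select_array_mask(
            panel600, 0.3 * panel600.n_variants / 1.0, seed=3)
        study = study_from_panel(panel600, n=400, seed=6)
        masked = apply_scenario(study, ScenarioSpec("gwas", array_mask=mask))
        model = fit_imputation_model(panel600, mask, seed=4)
        out = impute_study(masked, model)
        untyped = sorted(model.theoretical_info)
        theo = np.array([model.theoretical_info[u] for u in untyped])
        emp = out.info[untyped]
        rho = spearmanr(theo, emp).statistic
        assert rho > 0.8

    def test_failed_variants_imputed_per_cohort(self, panel600):
        mask = select_array_mask(
            panel600, 0.3 * panel600.n_variants / 1.0, seed=3)
        study = study_from_panel(panel600, n=200, seed=7)
        spec = ScenarioSpec("gwas_failure", array_mask=mask,
                            failure_fraction=0.1, seed=1)
        masked = apply_scenario(study, spec)
        assert masked.failed.any()
        model = fit_imputation_model(panel600, mask, seed=4)
        out = impute_study(masked, model, panel=panel600)
        assert not out.missing_mask.any()
        failed_cols = np.where(masked.failed)[0]
        assert np.all(out.info[failed_cols] <= 1.0)
        assert np.all(out.dosages[:, failed_cols] >= 0)


class TestQCFilter:
    def _meta(self, eaf, se=None):
        m = len(eaf)
        return MetaResult(
            ids=np.array([f"v{i}" for i in range(m)], dtype=object),
            positions=np.arange(m), ea=np.array(["G"] * m, dtype=object),
            nea=np.array(["A"] * m, dtype=object),
            eaf=np.asarray(eaf, dtype=float),
            beta=np.zeros(m), se=np.asarray(se if se else [0.1] * m),
            z=np.zeros(m), n_eff=np.full(m, 100.0),
            n_studies=np.ones(m, dtype=int),
            presence=np.ones((1, m), dtype=bool), info_min=np.ones(m))

    def test_toy_table_two_survivors(self):
        meta = self._meta([0.05, 0.005, 0.3, 0.3, 0.02])
        info = np.array([1.0, 0.9, 0.4, 0.2, 1.0])
        keep = qc_filter(meta, info)
        assert keep.tolist() == [True, False, False, False, True]

    def test_info_boundary_is_strict(self):
        meta = self._meta([0.3])
        assert not qc_filter(meta, np.array([0.4]))[0]
        assert qc_filter(meta, np.array([0.4000001]))[0]

    def test_maf_boundary_is_inclusive(self):
        meta = self._meta([0.01, 0.0099])
        keep = qc_filter(meta, None)
        assert keep.tolist() == [True, False]

    def test_folded_frequency(self):
        meta = self._meta([0.995])
        assert not qc_filter(meta, None)[0]

    def test_invalid_thresholds(self):
        meta = self._meta([0.3])
        with pytest.raises(Exception):
            qc_filter(meta, None, QCThresholds(info_min=1.5))
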
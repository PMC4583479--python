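"""Disease model, retrospective case-control sampling, scenario transforms."""

import numpy as np
import pytest

from finemapsim.errors import ConfigError, DataError, SimulationError
from finemapsim.panel import PanelModelParams, compute_r2, synthesize_panel
from finemapsim.simulate import (ScenarioSpec, apply_scenario,
                                 build_disease_model, select_array_mask,
                                 select_multi_causal_pair,
                                 simulate_case_control)

from conftest import make_panel


def panel_with_freqs(freqs, h=200, seed=0):
    """Panel whose column frequencies are exact (independent variants)."""
    rng = np.random.default_rng(seed)
    cols = []
    for p in freqs:
        col = np.zeros(h, dtype=np.uint8)
        col[: int(round(p * h))] = 1
        rng.shuffle(col)
        cols.append(col)
    return make_panel(np.stack(cols, axis=1))


@pytest.fixture(scope="module")
def small_panel():
    return synthesize_panel(
        PanelModelParams(target_density=300, seed=21), 300_000)


class TestDiseaseModel:
    def test_baseline_penetrance_hand_example(self):
        # p=0.5, OR=1.5: denominator q^2 + 2pq*OR + p^2*OR^2 = 1.5625
        panel = panel_with_freqs([0.5])
        model = build_disease_model(panel, [(panel.variants[0].id, 1.5)],
                                    prevalence=0.0055)
        assert model.f0 == pytest.approx(0.0055 / 1.5625, rel=1e-8)

    def test_null_model_flat_penetrance(self):
        panel = panel_with_freqs([0.3])
        model = build_disease_model(panel, [(panel.variants[0].id, 1.0)],
                                    prevalence=0.0055)
        assert model.f0 == pytest.approx(0.0055, rel=1e-10)
        assert np.allclose(model.penetrance(np.array([[0], [1], [2]])),
                           0.0055)

    def test_expected_case_raf(self):
        panel = panel_with_freqs([0.1])
        model = build_disease_model(panel, [(panel.variants[0].id, 1.2)],
                                    prevalence=0.0055)
        assert model.expected_case_raf() == pytest.approx(0.1176, abs=2e-4)

    def test_prevalence_constraint_solved_exactly(self):
        panel = panel_with_freqs([0.2, 0.4], seed=3)
        model = build_disease_model(
            panel, [(panel.variants[0].id, 1.3), (panel.variants[1].id, 1.2)],
            prevalence=0.0055)
        combos, probs = model.genotype_table()
        assert abs(float(probs @ model.penetrance(combos)) - 0.0055) < 1e-10

    def test_raf_matching_tolerance(self):
        panel = panel_with_freqs([0.30, 0.10])
        model = build_disease_model(panel, [(0.102, 1.2)], prevalence=0.0055)
        assert model.causal_ids == [panel.variants[1].id]
        with pytest.raises(DataError):
            build_disease_model(panel, [(0.15, 1.2)], prevalence=0.0055)

    def test_degenerate_penetrance_rejected(self):
        panel = panel_with_freqs([0.5])
        with pytest.raises(DataError):
            build_disease_model(panel, [(panel.variants[0].id, 10.0)],
                                prevalence=0.4)


class TestRetrospectiveSampling:
    def test_case_enrichment_matches_expectation(self, small_panel):
        from finemapsim.simulate import find_variant_by_raf
        idx = find_variant_by_raf(small_panel, 0.10, tolerance=0.02)
        vid = small_panel.variants[idx].id
        model = build_disease_model(small_panel, [(vid, 1.2)], 0.0055)
        rafs = []
        for s in range(40):
            st = simulate_case_control(small_panel, model, 250, 250, seed=s)
            rafs.append(st.dosages[st.phenotype == 1, idx].mean() / 2.0)
        expected = model.expected_case_raf()
        se = np.sqrt(expected * (1 - expected) / (2 * 250 * 40))
        assert abs(np.mean(rafs) - expected) < 4 * se

    def test_null_model_no_enrichment(self, small_panel):
        idx = int(np.argmin(np.abs(small_panel.alt_freqs - 0.2)))
        vid = small_panel.variants[idx].id
        model = build_disease_model(small_panel, [(vid, 1.0)], 0.0055)
        diffs = []
        for s in range(40):
            st = simulate_case_control(small_panel, model, 250, 250, seed=s)
            diffs.append(st.dosages[st.phenotype == 1, idx].mean()
                         - st.dosages[st.phenotype == 0, idx].mean())
        p = small_panel.alt_freqs[idx]
        se = np.sqrt(2 * p * (1 - p) * 2 / 500 / 40)
        assert abs(np.mean(diffs)) < 3 * se

    def test_case_enrichment_monotone_in_or(self, small_panel):
        from finemapsim.simulate import find_variant_by_raf
        idx = find_variant_by_raf(small_panel, 0.10, tolerance=0.02)
        vid = small_panel.variants[idx].id
        means = []
        for or_ in (1.0, 1.1, 1.2, 1.5):
            model = build_disease_model(small_panel, [(vid, or_)], 0.0055)
            vals = [simulate_case_control(small_panel, model, 250, 250,
                                          seed=100 + s)
                    .dosages[:250, idx].mean() / 2 for s in range(40)]
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_ld_preserved_in_cohort(self, small_panel):
        # pick a close pair with mid-range panel r^2 and compare in controls
        pos = small_panel.positions
        pair = None
        for a in range(small_panel.n_variants - 1):
            for b in range(a + 1, small_panel.n_variants):
                if pos[b] - pos[a] > 15_000:
                    break
                try:
                    r2 = compute_r2(small_panel, a, b)
                except Exception:
                    continue
                if 0.3 < r2 < 0.9:
                    pair = (a, b, r2)
                    break
            if pair:
                break
        assert pair is not None
        a, b, panel_r2 = pair
        vid = small_panel.variants[a].id
        model = build_disease_model(small_panel, [(vid, 1.0)], 0.0055)
        st = simulate_case_control(small_panel, model, 500, 500, seed=9)
        da, db = st.dosages[:, a], st.dosages[:, b]
        study_r2 = np.corrcoef(da, db)[0, 1] ** 2
        assert abs(study_r2 - panel_r2) < 0.15

    def test_deterministic_under_seed(self, small_panel):
        vid = small_panel.variants[5].id
        model = build_disease_model(small_panel, [(vid, 1.2)], 0.0055)
        a = simulate_case_control(small_panel, model, 100, 100, seed=4)
        b = simulate_case_control(small_panel, model, 100, 100, seed=4)
        assert np.array_equal(a.dosages, b.dosages)

    def test_empty_required_class_raises(self, small_panel):
        idx = int(np.argmax(small_panel.mafs))
        vid = small_panel.variants[idx].id
        model = build_disease_model(small_panel, [(vid, 1.5)], 0.0055)
        broken = make_panel(np.where(
            np.arange(small_panel.n_variants) == idx, 0,
            small_panel.haplotypes),
            positions=list(small_panel.positions))
        with pytest.raises(SimulationError):
            simulate_case_control(broken, model, 50, 50, seed=1)


class TestScenarios:
    def test_gold_is_identity(self, small_panel):
        vid = small_panel.variants[3].id
        model = build_disease_model(small_panel, [(vid, 1.0)], 0.0055)
        st = simulate_case_control(small_panel, model, 50, 50, seed=2)
        out = apply_scenario(st, ScenarioSpec(name="gold"))
        assert out is st

    def test_gwas_flags_untyped(self, small_panel):
        vid = small_panel.variants[3].id
        model = build_disease_model(small_panel, [(vid, 1.0)], 0.0055)
        st = simulate_case_control(small_panel, model, 50, 50, seed=2)
        mask = small_panel.ids[:30]
        out = apply_scenario(st, ScenarioSpec(name="gwas", array_mask=mask))
        assert out.typed.sum() == 30
        assert (~out.typed).sum() == small_panel.n_variants - 30
        assert out.missing_mask[:, ~out.typed].all()

    def test_failure_fraction_binomial(self, small_panel):
        vid = small_panel.variants[3].id
        model = build_disease_model(small_panel, [(vid, 1.0)], 0.0055)
        st = simulate_case_control(small_panel, model, 50, 50, seed=2)
        mask = small_panel.ids
        fails = []
        for c in range(25):
            spec = ScenarioSpec(name="gwas_failure", array_mask=mask,
                                failure_fraction=0.05, seed=c)
            st2 = st.copy()
            st2.study_id = f"c{c}"
            out = apply_scenario(st2, spec)
            fails.append(out.failed.mean())
        assert 0.035 < np.mean(fails) < 0.065

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioSpec(name="gwas").validate()
        with pytest.raises(ConfigError):
            ScenarioSpec(name="nope").validate()
        with pytest.raises(ConfigError):
            ScenarioSpec(name="gold", failure_fraction=0.1).validate()


class TestArrayMask:
    def test_full_density_selects_all(self, small_panel):
        density = small_panel.n_variants / (small_panel.region_length / 1e6)
        mask = select_array_mask(small_panel, density, seed=1)
        assert len(mask) == small_panel.n_variants

    def test_target_count_and_maf_bias(self, small_panel):
        density = 0.3 * small_panel.n_variants \
            / (small_panel.region_length / 1e6)
        mask = select_array_mask(small_panel, density, seed=1)
        assert len(mask) == int(round(density
                                      * small_panel.region_length / 1e6))
        on = np.isin(small_panel.ids.astype(str), mask.astype(str))
        assert small_panel.mafs[on].mean() > small_panel.mafs.mean()

    def test_density_above_panel_rejected(self, small_panel):
        with pytest.raises(DataError):
            select_array_mask(small_panel, 1e6, seed=1)


class TestMultiCausalPair:
    def test_two_block_fixture_returns_the_pair(self):
        rng = np.random.default_rng(0)
        h = 200
        a = np.zeros(h, dtype=np.uint8)
        a[:20] = 1
        rng.shuffle(a)
        b = np.zeros(h, dtype=np.uint8)
        b[:20] = 1
        rng.shuffle(b)
        hap = np.stack([a, a, b, b], axis=1)  # two independent proxy pairs
        panel = make_panel(hap, positions=[300_000, 300_100, 600_000,
                                           600_100],
                           region_length=1_000_000)
        pair = select_multi_causal_pair(panel, maf_target=0.10, max_r2=0.05)
        got = {panel.index_of(v) for v in pair}
        assert got in ({0, 2}, {0, 3}, {1, 2}, {1, 3})
        assert compute_r2(panel, *sorted(got)) < 0.05

    def test_all_perfect_proxies_raises(self):
        rng = np.random.default_rng(1)
        col = (rng.random(200) < 0.1).astype(np.uint8)
        hap = np.stack([col] * 4, axis=1)
        panel = make_panel(hap, positions=[300_000, 400_000, 500_000,
                                           600_000],
                           region_length=1_000_000)
        with pytest.raises(DataError):
            select_multi_causal_pair(panel, maf_target=float(col.mean()),
                                     max_r2=0.05)
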
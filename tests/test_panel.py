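"""Haplotype panel generator: LD structure, drift model, r^2, VCF I/O."""

import numpy as np
import pytest

from finemapsim.errors import ConfigError, MonomorphicVariantError, PanelError
from finemapsim.panel import (PanelModelParams, compute_r2,
                              derive_diverged_panel, read_vcf,
                              synthesize_panel, write_vcf)

from conftest import make_panel


def hap_from_counts(n_ab, n_aB, n_Ab, n_AB):
    """Two-variant haplotype matrix from the four haplotype counts."""
    rows = ([(1, 1)] * n_AB + [(1, 0)] * n_Ab + [(0, 1)] * n_aB
            + [(0, 0)] * n_ab)
    return np.array(rows, dtype=np.uint8)


class TestComputeR2:
    def test_self_correlation_is_one(self):
        panel = make_panel(hap_from_counts(1, 1, 1, 1))
        assert compute_r2(panel, 0, 0) == pytest.approx(1.0)

    @pytest.mark.parametrize("counts,expected", [
        ((1, 1, 1, 1), 0.0),        # D = 0.25 - 0.5*0.5 = 0
        ((40, 10, 10, 40), 0.36),   # D = 0.4 - 0.25, r2 = 0.0225/0.0625
    ])
    def test_hand_computed_values(self, counts, expected):
        panel = make_panel(hap_from_counts(*counts))
        assert compute_r2(panel, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_raises_not_zero(self):
        hap = np.array([[0, 1], [0, 0], [0, 1], [0, 0]], dtype=np.uint8)
        panel = make_panel(hap)
        with pytest.raises(MonomorphicVariantError):
            compute_r2(panel, 0, 1)


class TestSynthesizePanel:
    def test_density_within_20_percent(self, panel600):
        common = int((panel600.mafs >= 0.01).sum())
        assert 0.8 * 600 <= common <= 1.2 * 600
        panel600.validate()

    def test_frequency_spectrum_skewed_to_rare(self, panel600):
        maf = panel600.mafs
        low = ((maf >= 0.01) & (maf < 0.05)).mean()
        high = (maf >= 0.4).mean()
        assert low > high

    def test_ld_decays_with_distance(self, panel600):
        rng = np.random.default_rng(0)
        pos = panel600.positions
        bins = [(0, 10_000), (40_000, 60_000), (200_000, 400_000)]
        means = []
        for lo, hi in bins:
            vals = []
            while len(vals) < 150:
                a = int(rng.integers(panel600.n_variants))
                cand = np.where((np.abs(pos - pos[a]) >= lo)
                                & (np.abs(pos - pos[a]) < hi))[0]
                cand = cand[cand != a]
                if len(cand) == 0:
                    continue
                b = int(cand[rng.integers(len(cand))])
                try:
                    vals.append(compute_r2(panel600, a, b))
                except MonomorphicVariantError:
                    continue
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_within_block_ld_exceeds_cross_block(self):
        params = PanelModelParams(n_haplotypes=200, target_density=3000,
                                  block_length_mean=20_000,
                                  haplotypes_per_block=6,
                                  inter_block_correlation=0.7, seed=1)
        panel = synthesize_panel(params, 1_000_000)
        vb = panel.block_model.var_block
        rng = np.random.default_rng(2)
        within, cross = [], []
        for _ in range(4000):
            a, b = rng.integers(0, panel.n_variants, 2)
            if a == b:
                continue
            try:
                r2 = compute_r2(panel, int(a), int(b))
            except MonomorphicVariantError:
                continue
            (within if vb[a] == vb[b] else cross).append(r2)
        assert np.median(within) > np.median(cross)

    def test_bit_identical_under_same_seed(self):
        params = PanelModelParams(target_density=300, seed=42)
        a = synthesize_panel(params, 400_000)
        b = synthesize_panel(params, 400_000)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert [v.id for v in a.variants] == [v.id for v in b.variants]

    def test_region_too_short_rejected(self):
        with pytest.raises(PanelError):
            synthesize_panel(PanelModelParams(seed=0), 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            synthesize_panel(PanelModelParams(fst=1.0), 100_000)


class TestDivergedPanel:
    def test_balding_nichols_drift_variance(self, panel3000):
        derived = derive_diverged_panel(panel3000, fst=0.15, recomb_scale=1.0,
                                        seed=77)
        p0 = panel3000.alt_freqs
        dp = derived.alt_freqs - p0
        ok = (p0 > 0.02) & (p0 < 0.98)
        assert ok.sum() >= 1000
        ratio = np.var(dp[ok] / np.sqrt(p0[ok] * (1 - p0[ok])))
        assert 0.7 * 0.15 <= ratio <= 1.3 * 0.15

    def test_no_drift_limit(self, panel600):
        derived = derive_diverged_panel(panel600, fst=0.0, recomb_scale=1.0,
                                        seed=78)
        assert np.mean(np.abs(derived.alt_freqs - panel600.alt_freqs)) < 0.02

    def test_shorter_ld_when_blocks_subdivided(self, panel600):
        derived = derive_diverged_panel(panel600, fst=0.15, recomb_scale=2.0,
                                        seed=79)
        rng = np.random.default_rng(3)
        pos = panel600.positions
        src, der = [], []
        while len(src) < 120:
            a = int(rng.integers(panel600.n_variants))
            cand = np.where(np.abs(np.abs(pos - pos[a]) - 50_000) < 10_000)[0]
            if len(cand) == 0:
                continue
            b = int(cand[rng.integers(len(cand))])
            try:
                src.append(compute_r2(panel600, a, b))
                der.append(compute_r2(derived, a, b))
            except MonomorphicVariantError:
                continue
        assert np.mean(der) < np.mean(src)

    def test_variant_list_preserved(self, panel600):
        derived = derive_diverged_panel(panel600, fst=0.15, recomb_scale=2.0,
                                        seed=80)
        assert [v.id for v in derived.variants] == \
            [v.id for v in panel600.variants]

    def test_fst_one_rejected(self, panel600):
        with pytest.raises(ConfigError):
            derive_diverged_panel(panel600, fst=1.0, recomb_scale=1.0, seed=0)


class TestVcfIO:
    def test_round_trip_preserves_matrix(self, tmp_path):
        panel = synthesize_panel(
            PanelModelParams(target_density=200, n_haplotypes=20, seed=5),
            200_000)
        path = tmp_path / "panel.vcf"
        write_vcf(panel, str(path))
        back = read_vcf(str(path))
        assert np.array_equal(back.haplotypes, panel.haplotypes)
        assert back.population == panel.population
        assert back.region_length == panel.region_length
        for a, b in zip(back.variants, panel.variants):
            assert (a.id, a.position, a.is_coding) == \
                (b.id, b.position, b.is_coding)
            assert a.ancestral_freq == pytest.approx(b.ancestral_freq,
                                                     abs=1e-6)

    def test_toy_panel_has_expected_shape(self, tmp_path):
        hap = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1], [1, 1, 0]],
                       dtype=np.uint8)
        panel = make_panel(hap)
        path = tmp_path / "toy.vcf"
        write_vcf(panel, str(path))
        lines = [l for l in path.read_text().splitlines()
                 if not l.startswith("##")]
        header = lines[0].split("\t")
        assert len(header) == 9 + 2  # two diploid samples
        assert len(lines) - 1 == 3   # M records

    def test_unphased_genotype_rejected_with_position(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "1\t101\tv1\tA\tG\t.\t.\t.\tGT\t0/1\n")
        with pytest.raises(PanelError, match="101"):
            read_vcf(str(path))

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\n"
            "1\t55\tv1\tA\tG,T\t.\t.\t.\tGT\t0|1\n")
        with pytest.raises(PanelError, match="55"):
            read_vcf(str(path))
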
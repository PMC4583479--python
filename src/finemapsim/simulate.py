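"""Case-control cohort simulation on a haplotype panel, plus study-design
scenario transforms (array downsampling, per-cohort genotype failure,
multi-causal variant selection).

Disease model: each causal variant carries an allelic odds ratio acting
multiplicatively on penetrance, ``f_g = f0 * prod_i OR_i^{g_i}`` (log-additive
per allele). The baseline penetrance ``f0`` is solved so the population
prevalence equals ``K`` under Hardy-Weinberg genotype frequencies at the
panel's allele frequencies.

Sampling is retrospective and genotype-first, in the spirit of haplotype
resamplers used for GWAS simulation: a case's causal genotype is drawn from
``P(g | case) ∝ P(g) f_g`` and a control's from ``P(g | control) ∝
P(g)(1 - f_g)`` (controls are unaffected individuals, not population
samples). Each individual is then assembled as two panel haplotypes drawn
conditional on carrying the required causal alleles and perturbed by a
block-mosaic switching process (default one expected switch per 100 kb) so
that individuals are recombinant mosaics of panel haplotypes rather than
copies, while local LD is preserved.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigError, DataError, SimulationError
from .panel import HaplotypePanel, compute_r2

__all__ = [
    "DiseaseModel",
    "StudyGenotypes",
    "ScenarioSpec",
    "build_disease_model",
    "find_variant_by_raf",
    "simulate_case_control",
    "apply_scenario",
    "select_array_mask",
    "select_multi_causal_pair",
]

# Population-scaled haplotype-copying switch rate, as in Li-Stephens-based
# resamplers: 4*Ne*c/H with Ne = 11418, c = 1.2e-8 per bp, H = 200 panel
# haplotypes -> about one donor switch per 365 kb.
DEFAULT_SWITCH_RATE = 4 * 11418 * 1.2e-8 / 200


@dataclass
class DiseaseModel:
    """Additive-risk disease model on one or more causal variants."""

    causal_ids: list
    causal_indices: np.ndarray
    odds_ratios: np.ndarray
    prevalence: float
    f0: float
    allele_freqs: np.ndarray  # panel alt-allele freq at each causal variant

    def penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        """f_g for an (n, n_causal) genotype matrix."""
        g = np.atleast_2d(genotypes)
        return self.f0 * np.prod(self.odds_ratios[None, :] ** g, axis=1)

    def genotype_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Joint genotype combinations (rows) and their HWE probabilities."""
        per_locus = []
        for p in self.allele_freqs:
            per_locus.append(np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]))
        combos = np.array(list(itertools.product([0, 1, 2],
                                                 repeat=len(self.allele_freqs))))
        probs = np.ones(len(combos))
        for i in range(combos.shape[1]):
            probs *= per_locus[i][combos[:, i]]
        return combos, probs

    def case_control_genotype_dists(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(combos, P(g|case), P(g|control)) over the joint genotype space."""
        combos, probs = self.genotype_table()
        f = self.penetrance(combos)
        w_case = probs * f
        w_ctrl = probs * (1.0 - f)
        return combos, w_case / w_case.sum(), w_ctrl / w_ctrl.sum()

    def expected_case_raf(self, locus: int = 0) -> float:
        combos, pc, _ = self.case_control_genotype_dists()
        return float(np.sum(combos[:, locus] * pc) / 2.0)

    def expected_control_raf(self, locus: int = 0) -> float:
        combos, _, pq = self.case_control_genotype_dists()
        return float(np.sum(combos[:, locus] * pq) / 2.0)


@dataclass
class StudyGenotypes:
    """One cohort: dosage matrix, phenotypes, and typing/missingness state.

    ``dosages`` holds 0/1/2 hard calls after simulation, or expected dosages
    in [0, 2] after imputation. ``typed`` marks variants observed directly
    (array content minus failures); ``failed`` marks per-cohort genotyping
    failures. ``info`` is the per-variant imputation quality (1 for typed
    hard calls).
    """

    dosages: np.ndarray           # (N, M) float32
    phenotype: np.ndarray         # (N,) int8, 1 = case
    missing_mask: np.ndarray      # (N, M) bool
    study_id: str
    population: str
    variant_ids: np.ndarray       # (M,) object
    positions: np.ndarray         # (M,) int64
    ref: np.ndarray
    alt: np.ndarray
    typed: np.ndarray = field(default=None)   # (M,) bool
    failed: np.ndarray = field(default=None)  # (M,) bool
    info: np.ndarray = field(default=None)    # (M,) float

    def __post_init__(self):
        n, m = self.dosages.shape
        if self.typed is None:
            self.typed = np.ones(m, dtype=bool)
        if self.failed is None:
            self.failed = np.zeros(m, dtype=bool)
        if self.info is None:
            self.info = np.ones(m, dtype=float)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.phenotype) - self.phenotype.sum())

    def copy(self) -> "StudyGenotypes":
        return StudyGenotypes(
            dosages=self.dosages.copy(), phenotype=self.phenotype.copy(),
            missing_mask=self.missing_mask.copy(), study_id=self.study_id,
            population=self.population, variant_ids=self.variant_ids,
            positions=self.positions, ref=self.ref, alt=self.alt,
            typed=self.typed.copy(), failed=self.failed.copy(),
            info=self.info.copy(),
        )


@dataclass
class ScenarioSpec:
    """Study-design scenario.

    ``gold``: full sequence data, identity transform. ``gwas``: variants
    outside ``array_mask`` are flagged untyped (to be imputed).
    ``gwas_failure``: additionally, a random ``failure_fraction`` of array
    variants lose all genotypes in each cohort.
    """

    name: str = "gold"
    array_mask: np.ndarray | None = None  # variant ids on the array
    failure_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.name not in ("gold", "gwas", "gwas_failure"):
            raise ConfigError(f"unknown scenario {self.name!r}")
        if self.name == "gold":
            if self.array_mask is not None or self.failure_fraction:
                raise ConfigError("gold scenario takes no mask and no failure")
        else:
            if self.array_mask is None or len(self.array_mask) == 0:
                raise ConfigError(f"{self.name} scenario requires a non-empty "
                                  "array mask")
        if self.name == "gwas_failure" and not self.failure_fraction > 0:
            raise ConfigError("gwas_failure requires failure_fraction > 0")


# ----------------------------------------------------------------------
# disease model
# ----------------------------------------------------------------------

def find_variant_by_raf(panel: HaplotypePanel, raf: float,
                        tolerance: float = 0.005,
                        central_fraction: float | None = None,
                        coding_only: bool = False,
                        rng: np.random.Generator | None = None) -> int:
    """Index of a panel variant with alt-allele frequency nearest ``raf``.

    Raises :class:`DataError` if no variant lies within ``tolerance``
    (0.5 percentage points by default). Optionally restrict to the central
    ``central_fraction`` of the region and/or to coding variants; ties and
    near-ties (within 1e-6) are broken at random when ``rng`` is given.
    """
    freqs = panel.alt_freqs
    ok = np.ones(panel.n_variants, dtype=bool)
    if central_fraction is not None:
        margin = (1.0 - central_fraction) / 2.0 * panel.region_length
        pos = panel.positions
        ok &= (pos >= margin) & (pos < panel.region_length - margin)
    if coding_only:
        ok &= panel.coding_mask
    if not ok.any():
        raise DataError("no candidate causal variants under the restrictions")
    dist = np.abs(freqs - raf)
    dist[~ok] = np.inf
    best = float(dist.min())
    if best > tolerance:
        raise DataError(
            f"no variant within {tolerance:.3f} of target RAF {raf:.3f} "
            f"(closest at {best:.3f})")
    cand = np.where(dist <= best + 1e-6)[0]
    if rng is not None and len(cand) > 1:
        return int(rng.choice(cand))
    return int(cand[0])


def build_disease_model(panel: HaplotypePanel, causal_spec,
                        prevalence: float) -> DiseaseModel:
    """Solve the penetrance model for the stated prevalence.

    ``causal_spec`` is a list of ``(variant, OR)`` pairs where ``variant`` is
    either a variant id (str) or a target RAF (float, matched to the nearest
    panel variant within 0.5 percentage points). ``f0`` is found by 1-d root
    finding so that the HWE-expected prevalence matches ``prevalence`` to
    better than 1e-10.
    """
    if not (0.0 < prevalence < 1.0):
        raise ConfigError("prevalence must be in (0, 1)")
    indices, ors = [], []
    for variant, or_ in causal_spec:
        if isinstance(variant, str):
            idx = panel.index_of(variant)
        else:
            idx = find_variant_by_raf(panel, float(variant))
        indices.append(idx)
        ors.append(float(or_))
    indices = np.asarray(indices, dtype=np.int64)
    ors = np.asarray(ors, dtype=float)
    freqs = panel.alt_freqs[indices]

    combos = np.array(list(itertools.product([0, 1, 2], repeat=len(indices))))
    probs = np.ones(len(combos))
    for i, p in enumerate(freqs):
        locus = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        probs *= locus[combos[:, i]]
    relative = np.prod(ors[None, :] ** combos, axis=1)

    def excess(f0: float) -> float:
        return float(np.sum(probs * f0 * relative) - prevalence)

    f0 = brentq(excess, 1e-15, 1.0 - 1e-12, xtol=1e-14, rtol=1e-13)
    if abs(excess(f0)) >= 1e-10:
        raise DataError("prevalence constraint not solvable to 1e-10")
    if np.max(f0 * relative) >= 1.0:
        raise DataError("penetrance f2 >= 1 under this model; lower the OR "
                        "or the prevalence")
    return DiseaseModel(
        causal_ids=[panel.variants[i].id for i in indices],
        causal_indices=indices, odds_ratios=ors, prevalence=prevalence,
        f0=float(f0), allele_freqs=freqs,
    )


# ----------------------------------------------------------------------
# retrospective sampling
# ----------------------------------------------------------------------

def _split_genotype_to_haplotypes(genos: np.ndarray,
                                  rng: np.random.Generator) -> np.ndarray:
    """(n, c) genotypes -> (2n, c) per-haplotype required alleles.

    Heterozygotes assign the alternate allele to a random haplotype.
    """
    n, c = genos.shape
    alleles = np.zeros((2 * n, c), dtype=np.uint8)
    for j in range(c):
        g = genos[:, j]
        first = np.zeros(n, dtype=np.uint8)
        first[g == 2] = 1
        het = g == 1
        coin = rng.random(n) < 0.5
        first[het & coin] = 1
        second = (g - first).astype(np.uint8)
        alleles[0::2, j] = first
        alleles[1::2, j] = second
    return alleles


def _mosaic_fill_py(hap_mat, var_pos, sw_pos, sw_count, donors, cond_donors,
                    causal_cols, out, seg_of_causal, shared_flag):
    """Copy donor segments into ``out`` haplotype by haplotype.

    Segment s of haplotype i covers positions [sw_pos[i,s-1], sw_pos[i,s]);
    its donor is ``donors[i, s]`` unless it contains a causal column, in
    which case the pre-drawn conditional donor ``cond_donors[i, ci]`` is
    used. Haplotypes where two causal columns share a segment are flagged
    for a joint redraw by the caller.
    """
    n, m = out.shape
    c = causal_cols.shape[0]
    for i in range(n):
        k = sw_count[i]
        v = 0
        for ci in range(c):
            seg_of_causal[i, ci] = -1
        for s in range(k + 1):
            hi = sw_pos[i, s] if s < k else np.inf
            start = v
            while v < m and var_pos[v] < hi:
                v += 1
            d = donors[i, s]
            for ci in range(c):
                cc = causal_cols[ci]
                if start <= cc < v:
                    seg_of_causal[i, ci] = s
                    d = cond_donors[i, ci]
            for j in range(start, v):
                out[i, j] = hap_mat[d, j]
            if v == m:
                break
        for a in range(c):
            for b in range(a + 1, c):
                if seg_of_causal[i, a] == seg_of_causal[i, b]:
                    shared_flag[i] = True


try:  # pragma: no cover - compiled twin of the python loop
    import numba as _numba

    _mosaic_fill = _numba.njit(cache=True)(_mosaic_fill_py)
except Exception:  # pragma: no cover
    _mosaic_fill = _mosaic_fill_py


def _class_indices(hap_mat: np.ndarray, cols: np.ndarray,
                   alleles: tuple) -> np.ndarray:
    mask = np.ones(hap_mat.shape[0], dtype=bool)
    for c, a in zip(cols, alleles):
        mask &= hap_mat[:, c] == a
    return np.where(mask)[0]


def _mosaic_haplotypes(panel: HaplotypePanel, required_alleles: np.ndarray,
                       causal_cols: np.ndarray, rng: np.random.Generator,
                       switch_rate: float) -> np.ndarray:
    """Assemble mosaic haplotypes conditional on causal alleles.

    ``required_alleles``: (n_hap, n_causal) alleles each new haplotype must
    carry at the panel columns ``causal_cols``. Donor switch points follow a
    Poisson process of rate ``switch_rate`` per bp along the region; the
    donor of any segment containing causal columns is drawn from the panel
    class carrying the required alleles (jointly, if several causal variants
    share a segment).
    """
    hap_mat = panel.haplotypes
    h, m = hap_mat.shape
    n = required_alleles.shape[0]
    pos = panel.positions.astype(np.float64)
    span_lo, span_hi = float(pos[0]), float(pos[-1]) + 1.0

    lam = switch_rate * (span_hi - span_lo)
    counts = rng.poisson(lam, size=n).astype(np.int64)
    max_k = int(counts.max()) if n else 0
    sw_pos = np.full((n, max(max_k, 1)), np.inf)
    if max_k:
        draws = rng.uniform(span_lo, span_hi, size=(n, max_k))
        col = np.arange(max_k)[None, :]
        sw_pos[:, :max_k] = np.where(col < counts[:, None], draws, np.inf)
        sw_pos.sort(axis=1)
    donors = rng.integers(0, h, size=(n, max_k + 1), dtype=np.int64)

    # pre-draw conditional donors satisfying each causal allele marginally
    n_causal = len(causal_cols)
    cond_donors = np.zeros((n, max(n_causal, 1)), dtype=np.int64)
    classes: dict = {}
    for ci, cc in enumerate(causal_cols):
        for a in (0, 1):
            cls = _class_indices(hap_mat, np.array([cc]), (a,))
            classes[(ci, a)] = cls
            rows = np.where(required_alleles[:, ci] == a)[0]
            if len(rows) == 0:
                continue
            if len(cls) == 0:
                raise SimulationError(
                    f"no panel haplotype carries allele {a} at column {cc}")
            cond_donors[rows, ci] = cls[rng.integers(0, len(cls),
                                                     size=len(rows))]

    out = np.empty((n, m), dtype=np.uint8)
    seg_of_causal = np.zeros((n, max(n_causal, 1)), dtype=np.int64)
    shared = np.zeros(n, dtype=np.bool_)
    _mosaic_fill(hap_mat, pos, sw_pos, counts, donors, cond_donors,
                 np.asarray(causal_cols, dtype=np.int64), out,
                 seg_of_causal, shared)

    # joint redraw where several causal variants landed in one segment
    for i in np.where(shared)[0]:
        segs = seg_of_causal[i, :n_causal]
        for s in np.unique(segs):
            members = np.where(segs == s)[0]
            if len(members) < 2:
                continue
            cols = causal_cols[members]
            alleles = tuple(int(required_alleles[i, j]) for j in members)
            cls = _class_indices(hap_mat, cols, alleles)
            if len(cls) == 0:
                raise SimulationError(
                    f"required causal-allele haplotype class {alleles} at "
                    f"columns {list(cols)} is empty in the panel")
            donor = int(cls[rng.integers(0, len(cls))])
            k = counts[i]
            lo_bp = sw_pos[i, s - 1] if s > 0 else -np.inf
            hi_bp = sw_pos[i, s] if s < k else np.inf
            in_seg = (pos >= lo_bp) & (pos < hi_bp)
            out[i, in_seg] = hap_mat[donor, in_seg]
    return out


def simulate_case_control(panel: HaplotypePanel, model: DiseaseModel,
                          n_cases: int, n_controls: int, seed,
                          study_id: str = "study",
                          switch_rate: float = DEFAULT_SWITCH_RATE) -> StudyGenotypes:
    """Simulate one case-control cohort by retrospective haplotype mosaics."""
    rng = np.random.default_rng(seed)
    combos, p_case, p_ctrl = model.case_control_genotype_dists()
    gi_case = rng.choice(len(combos), size=n_cases, p=p_case)
    gi_ctrl = rng.choice(len(combos), size=n_controls, p=p_ctrl)
    genos = combos[np.concatenate([gi_case, gi_ctrl])]  # (N, c)
    required = _split_genotype_to_haplotypes(genos, rng)
    haps = _mosaic_haplotypes(panel, required, model.causal_indices, rng,
                              switch_rate)
    dosages = (haps[0::2] + haps[1::2]).astype(np.float32)
    n = n_cases + n_controls
    phenotype = np.zeros(n, dtype=np.int8)
    phenotype[:n_cases] = 1
    return StudyGenotypes(
        dosages=dosages, phenotype=phenotype,
        missing_mask=np.zeros(dosages.shape, dtype=bool),
        study_id=study_id, population=panel.population,
        variant_ids=panel.ids, positions=panel.positions,
        ref=np.array([v.ref for v in panel.variants], dtype=object),
        alt=np.array([v.alt for v in panel.variants], dtype=object),
    )


# ----------------------------------------------------------------------
# scenario transforms
# ----------------------------------------------------------------------

def apply_scenario(study: StudyGenotypes, scenario: ScenarioSpec) -> StudyGenotypes:
    """Apply a study-design scenario; ``gold`` is the identity."""
    scenario.validate()
    if scenario.name == "gold":
        return study
    out = study.copy()
    on_array = np.isin(out.variant_ids.astype(str),
                       np.asarray(scenario.array_mask, dtype=str))
    if not on_array.any():
        raise DataError("array mask shares no variants with this study")
    out.typed = on_array.copy()
    if scenario.name == "gwas_failure":
        rng = np.random.default_rng([scenario.seed,
                                     zlib.crc32(study.study_id.encode())])
        array_idx = np.where(on_array)[0]
        fail = array_idx[rng.random(len(array_idx)) < scenario.failure_fraction]
        out.failed[fail] = True
        out.typed[fail] = False
        out.missing_mask[:, fail] = True
    # untyped variants carry no observed genotypes until imputation
    out.missing_mask[:, ~out.typed & ~out.failed] = True
    return out


def select_array_mask(panel: HaplotypePanel, density_per_mb: float,
                      seed) -> np.ndarray:
    """Array content: variants sampled at a target density with probability
    proportional to MAF (commercial arrays favor common variants)."""
    m = panel.n_variants
    n_target = int(round(density_per_mb * panel.region_length / 1e6))
    if n_target > m:
        raise DataError(f"array density {density_per_mb}/Mb exceeds panel "
                        "density")
    if n_target == m:
        return panel.ids.copy()
    rng = np.random.default_rng(seed)
    maf = panel.mafs
    w = maf / maf.sum()
    chosen = rng.choice(m, size=n_target, replace=False, p=w)
    return panel.ids[np.sort(chosen)]


def select_multi_causal_pair(panel: HaplotypePanel, maf_target: float = 0.10,
                             max_r2: float = 0.05,
                             central_fraction: float = 0.75,
                             maf_tolerance: float = 0.02,
                             rng: np.random.Generator | None = None
                             ) -> tuple[str, str]:
    """Two weakly linked causal variants of similar frequency.

    Both within ``maf_tolerance`` of ``maf_target``, pairwise r^2 below
    ``max_r2``, both inside the central ``central_fraction`` of the region.
    Raises :class:`DataError` when no qualifying pair exists (callers resample
    the region).
    """
    rng = rng or np.random.default_rng(0)
    maf = panel.mafs
    pos = panel.positions
    margin = (1.0 - central_fraction) / 2.0 * panel.region_length
    cand = np.where((np.abs(maf - maf_target) <= maf_tolerance)
                    & (pos >= margin)
                    & (pos < panel.region_length - margin))[0]
    if len(cand) < 2:
        raise DataError("fewer than two candidate variants for a multi-causal "
                        "pair")
    cand = rng.permutation(cand)
    limit = 2000
    tried = 0
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            tried += 1
            if tried > limit:
                raise DataError("no weakly linked multi-causal pair found "
                                "within the search budget")
            if compute_r2(panel, int(cand[i]), int(cand[j])) < max_r2:
                a, b = sorted((int(cand[i]), int(cand[j])))
                return panel.variants[a].id, panel.variants[b].id
    raise DataError("no multi-causal pair with r^2 below threshold")
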
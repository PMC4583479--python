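"""Synthetic phased haplotype panels with block-structured linkage disequilibrium.

The generator stands in for a small sequenced reference panel (on the order of
85-90 individuals per population, as in 1000 Genomes Phase 1 CEU/YRI). Instead
of a coalescent simulation it uses an explicit haplotype-block model that gives
direct control over the two LD features that matter for fine-mapping
experiments: the length of strongly correlated blocks and the number of
distinct "proxy" haplotype backgrounds per block.

Model
-----
A region of length ``L`` bp is partitioned into blocks with exponentially
distributed lengths (mean ``block_length_mean``). Each block carries ``K``
distinct *block-haplotypes* whose frequencies are drawn from a symmetric
Dirichlet. Every panel haplotype owns one latent uniform per block; adjacent
blocks share the same uniform with probability ``inter_block_correlation`` and
redraw it otherwise. The block-haplotype carried in a block is the inverse-CDF
(comonotone) transform of that uniform under the block's frequency vector, so
each block's marginal frequencies are exact while correlation between blocks
decays geometrically with block distance.

Variants are placed uniformly, their folded minor allele frequencies drawn
from a density proportional to 1/p on [0.01, 0.5] (the standard neutral-like
common-variant spectrum), and each variant's alternate allele is painted onto
the clade of a random per-block genealogy whose frequency is nearest the
target. Variants on the same clade are perfect proxies (r^2 = 1); variants on
nested clades are strong but imperfect proxies — together they reproduce the
within-block proxy continuum of real sequence panels.

A diverged second population is obtained by redrawing block-haplotype
frequencies under the Balding-Nichols model (Dirichlet concentration
``(1-F)/F`` times the source frequencies) and subdividing blocks to shorten
LD, emulating e.g. an African-ancestry panel relative to a European one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, MonomorphicVariantError, PanelError

__all__ = [
    "VariantRecord",
    "PanelModelParams",
    "PanelBlockModel",
    "HaplotypePanel",
    "synthesize_panel",
    "derive_diverged_panel",
    "compute_r2",
    "r2_matrix",
    "write_vcf",
    "read_vcf",
]


@dataclass
class VariantRecord:
    """A biallelic SNV within a region.

    ``position`` is 0-based within the region (VCF I/O converts to 1-based).
    ``ancestral_freq`` is the target alternate-allele frequency the variant was
    generated at; ``alt_freq`` is the realized frequency in this panel's
    haplotype matrix.
    """

    id: str
    position: int
    ref: str
    alt: str
    ancestral_freq: float
    alt_freq: float
    is_coding: bool = False

    @property
    def maf(self) -> float:
        return min(self.alt_freq, 1.0 - self.alt_freq)


@dataclass
class PanelModelParams:
    """Parameters of the block-haplotype panel generator.

    target_density
        MAF>=1% variants per Mb (default 3000, the order of the 1000 Genomes
        common-variant density).
    block_length_mean
        Mean LD-block length in bp.
    haplotypes_per_block
        Number of distinct block-haplotypes (proxy backgrounds) per block.
    inter_block_correlation
        Probability that adjacent blocks share the latent uniform.
    fst
        Balding-Nichols drift parameter used by :func:`derive_diverged_panel`.
    recomb_scale
        Block-shortening factor for the diverged population (2 = blocks half
        as long, i.e. visibly shorter LD).
    private_flip_rate
        Mean number (Poisson) of individual panel haplotypes whose allele at
        a variant is flipped after clade painting. Emulates recent private
        mutations and gene-conversion events, turning families of exact
        proxies into near-perfect proxies (r^2 just below 1) — the stratum
        of LD that makes fine-mapping resolution non-trivial.
    exon_count_per_mb / exon_length_bp
        Synthetic "exon" intervals marking variants as coding, the stand-in
        annotation used by the functional-prior scenario.
    """

    n_haplotypes: int = 200
    target_density: float = 3000.0
    block_length_mean: float = 40_000.0
    haplotypes_per_block: int = 6
    inter_block_correlation: float = 0.9
    fst: float = 0.15
    recomb_scale: float = 2.0
    private_flip_rate: float = 0.3
    exon_count_per_mb: float = 10.0
    exon_length_bp: int = 300
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ConfigError(f"fst must be in [0, 1), got {self.fst}")
        if self.block_length_mean <= 0:
            raise ConfigError("block_length_mean must be positive")
        if self.target_density <= 0:
            raise ConfigError("target_density must be positive")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ConfigError("n_haplotypes must be even and >= 2")
        if not (0.0 <= self.inter_block_correlation <= 1.0):
            raise ConfigError("inter_block_correlation must be in [0, 1]")
        if self.haplotypes_per_block < 2:
            raise ConfigError("haplotypes_per_block must be >= 2")
        if self.recomb_scale <= 0:
            raise ConfigError("recomb_scale must be positive")


@dataclass
class PanelBlockModel:
    """Latent block structure retained for divergence and diagnostics.

    ``boundaries``: block start positions plus the region end (length B+1).
    ``hap_freqs``: realized block-haplotype frequencies per block (B x K).
    ``alleles``: per block, K x m_b matrix of block-haplotype alleles at the
    block's variants. ``var_block`` maps variant index -> block index.
    """

    boundaries: np.ndarray
    hap_freqs: np.ndarray
    alleles: list
    var_block: np.ndarray
    rho: float
    k: int
    flip_rate: float = 0.0

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries) - 1


@dataclass
class HaplotypePanel:
    """Phased haplotype panel: H x M binary matrix plus variant metadata."""

    population: str
    variants: list
    haplotypes: np.ndarray  # (H, M) uint8, entries in {0, 1}
    region_length: int
    block_model: PanelBlockModel | None = field(default=None, repr=False)

    # -- derived views (cached; panels are treated as immutable) -------
    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def _cache(self, key, builder):
        store = self.__dict__.setdefault("_views", {})
        if key not in store:
            store[key] = builder()
        return store[key]

    @property
    def positions(self) -> np.ndarray:
        return self._cache("pos", lambda: np.array(
            [v.position for v in self.variants], dtype=np.int64))

    @property
    def ids(self) -> np.ndarray:
        return self._cache("ids", lambda: np.array(
            [v.id for v in self.variants], dtype=object))

    @property
    def alt_freqs(self) -> np.ndarray:
        return self._cache("freq", lambda: np.array(
            [v.alt_freq for v in self.variants]))

    @property
    def mafs(self) -> np.ndarray:
        p = self.alt_freqs
        return np.minimum(p, 1.0 - p)

    @property
    def coding_mask(self) -> np.ndarray:
        return self._cache("coding", lambda: np.array(
            [v.is_coding for v in self.variants], dtype=bool))

    def index_of(self, variant_id: str) -> int:
        try:
            return self._id_index[variant_id]
        except AttributeError:
            self._id_index = {v.id: i for i, v in enumerate(self.variants)}
            return self._id_index[variant_id]

    def validate(self) -> None:
        h, m = self.haplotypes.shape
        if h % 2:
            raise PanelError("haplotype count must be even (phased diploids)")
        if m != len(self.variants):
            raise PanelError("variant list length does not match matrix")
        vals = np.unique(self.haplotypes)
        if not np.all(np.isin(vals, [0, 1])):
            raise PanelError("haplotype matrix entries must be 0/1")
        pos = self.positions
        if m and (np.any(np.diff(pos) <= 0)):
            raise PanelError("variant positions must be strictly increasing")
        if m and self.region_length < int(pos[-1]) + 1:
            raise PanelError("region_length smaller than max position")
        freqs = self.haplotypes.mean(axis=0)
        stored = self.alt_freqs
        if m and np.max(np.abs(freqs - stored)) > 1e-12:
            raise PanelError("stored alt_freq disagrees with haplotype matrix")


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _draw_block_boundaries(rng, region_length: float, mean_len: float) -> np.ndarray:
    bounds = [0.0]
    while bounds[-1] < region_length:
        bounds.append(bounds[-1] + rng.exponential(mean_len))
    bounds[-1] = float(region_length)
    if len(bounds) < 2:
        raise PanelError("region too short for a single block")
    return np.asarray(bounds)


def _chain_uniforms(rng, n_hap: int, n_blocks: int, rho: float) -> np.ndarray:
    """Latent uniforms per (haplotype, block) under the shared-uniform chain."""
    u = np.empty((n_hap, n_blocks))
    u[:, 0] = rng.random(n_hap)
    for b in range(1, n_blocks):
        keep = rng.random(n_hap) < rho
        u[:, b] = np.where(keep, u[:, b - 1], rng.random(n_hap))
    return u


def _states_from_uniforms(u: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Comonotone inverse-CDF map of uniforms to block-haplotype indices.

    ``u``: (H, B); ``freqs``: (B, K). Returns (H, B) int8 states.
    """
    k = freqs.shape[1]
    states = np.empty(u.shape, dtype=np.int16)
    for b in range(freqs.shape[0]):
        cum = np.cumsum(freqs[b])
        cum[-1] = 1.0 + 1e-12
        states[:, b] = np.searchsorted(cum, u[:, b], side="right")
    return np.minimum(states, k - 1)


def _sample_folded_maf(rng, n: int, lo: float = 0.01, hi: float = 0.5) -> np.ndarray:
    # inverse CDF of density proportional to 1/p on [lo, hi]
    return lo * (hi / lo) ** rng.random(n)


def _genealogy_clades(rng, k: int) -> np.ndarray:
    """Proper clades of a random binary genealogy over k block-haplotypes.

    Random pairwise merging produces the 2k-2 non-root clades (singletons
    plus internal nodes); complements are added so every clade can carry
    either allele orientation. Variants assigned to nested clades become
    partially correlated (high but imperfect r^2), variants on the same
    clade perfect proxies — the within-block proxy continuum of sequence
    panels.
    """
    masks = [np.eye(k, dtype=bool)[i] for i in range(k)]
    active = list(range(k))
    clades = list(masks)
    while len(active) > 2:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        merged = clades[a] | clades[b]
        clades.append(merged)
        active = [x for x in active if x not in (a, b)]
        active.append(len(clades) - 1)
    out = np.stack(clades)
    return np.concatenate([out, ~out], axis=0)


def _assign_clade(rng, clade_freqs: np.ndarray, target: float) -> int:
    """Clade whose frequency is nearest the target, random among near-ties."""
    dist = np.abs(clade_freqs - target)
    best = dist.min()
    cand = np.where(dist <= best + 1e-9)[0]
    return int(rng.choice(cand))


def _mark_coding(rng, positions: np.ndarray, region_length: int,
                 count_per_mb: float, exon_len: int) -> tuple[np.ndarray, np.ndarray]:
    n_exons = int(round(count_per_mb * region_length / 1e6))
    coding = np.zeros(len(positions), dtype=bool)
    if n_exons <= 0 or region_length <= exon_len:
        return coding, np.empty((0, 2), dtype=np.int64)
    starts = rng.integers(0, region_length - exon_len, size=n_exons)
    exons = np.stack([starts, starts + exon_len], axis=1)
    for s, e in exons:
        coding |= (positions >= s) & (positions < e)
    return coding, exons


def synthesize_panel(params: PanelModelParams, region_length: int,
                     population: str = "EUR-like") -> HaplotypePanel:
    """Generate a phased haplotype panel under the block-haplotype model.

    The panel's MAF>=1% variant count per Mb approximates
    ``params.target_density``; bit-identical output under identical
    ``params`` (including seed) and ``region_length``.
    """
    params.validate()
    if region_length <= 1:
        raise PanelError("region too short for one block")
    rng = np.random.default_rng(params.seed)
    h, k = params.n_haplotypes, params.haplotypes_per_block
    rho = params.inter_block_correlation

    bounds = _draw_block_boundaries(rng, region_length, params.block_length_mean)
    n_blocks = len(bounds) - 1
    block_freq_draw = rng.dirichlet(np.ones(k), size=n_blocks)
    u = _chain_uniforms(rng, h, n_blocks, rho)
    states = _states_from_uniforms(u, block_freq_draw)
    # realized block-haplotype frequencies (what drift should act on)
    hap_freqs = np.stack(
        [np.bincount(states[:, b], minlength=k) / h for b in range(n_blocks)]
    )

    # variant positions and target frequencies
    n_target = int(round(params.target_density * region_length / 1e6))
    if n_target < 1:
        raise PanelError("target_density infeasible for this region length")
    n_draw = int(np.ceil(1.1 * n_target))
    positions = np.unique(rng.integers(0, region_length, size=n_draw))
    n_var = len(positions)
    maf = _sample_folded_maf(rng, n_var)
    alt_target = np.where(rng.random(n_var) < 0.5, maf, 1.0 - maf)
    var_block = np.clip(np.searchsorted(bounds, positions, side="right") - 1,
                        0, n_blocks - 1)

    # paint alternate alleles onto genealogy clades of block-haplotypes
    alleles = [np.zeros((k, 0), dtype=np.uint8) for _ in range(n_blocks)]
    per_block_members: list[list[np.ndarray]] = [[] for _ in range(n_blocks)]
    block_clades = [_genealogy_clades(rng, k) for _ in range(n_blocks)]
    block_clade_freqs = [c @ hap_freqs[b] for b, c in enumerate(block_clades)]
    for j in range(n_var):
        b = var_block[j]
        ci = _assign_clade(rng, block_clade_freqs[b], alt_target[j])
        per_block_members[b].append(block_clades[b][ci].astype(np.uint8))
    hap = np.empty((h, n_var), dtype=np.uint8)
    col = 0
    block_cols = []
    for b in range(n_blocks):
        members = per_block_members[b]
        m_b = len(members)
        block_cols.append((col, col + m_b))
        if m_b:
            mat = np.stack(members, axis=1)  # (K, m_b)
            alleles[b] = mat
            hap[:, col:col + m_b] = mat[states[:, b], :]
        col += m_b

    # private carrier noise: flip the allele of a few individual haplotypes
    if params.private_flip_rate > 0:
        n_flip = rng.poisson(params.private_flip_rate, size=n_var)
        for j in np.where(n_flip > 0)[0]:
            rows = rng.integers(0, h, size=n_flip[j])
            hap[rows, j] ^= 1

    # drop variants monomorphic in the realized matrix
    realized = hap.mean(axis=0)
    keep = (realized > 0.0) & (realized < 1.0)
    hap = hap[:, keep]
    positions = positions[keep]
    alt_target = alt_target[keep]
    var_block = var_block[keep]
    realized = realized[keep]
    for b in range(n_blocks):
        lo, hi = block_cols[b]
        alleles[b] = alleles[b][:, keep[lo:hi]] if hi > lo else alleles[b]

    coding, _ = _mark_coding(rng, positions, region_length,
                             params.exon_count_per_mb, params.exon_length_bp)

    variants = [
        VariantRecord(
            id=f"v{int(p):07d}", position=int(p), ref="A", alt="G",
            ancestral_freq=float(alt_target[j]), alt_freq=float(realized[j]),
            is_coding=bool(coding[j]),
        )
        for j, p in enumerate(positions)
    ]
    model = PanelBlockModel(boundaries=bounds, hap_freqs=hap_freqs,
                            alleles=alleles, var_block=var_block, rho=rho,
                            k=k, flip_rate=params.private_flip_rate)
    panel = HaplotypePanel(population=population, variants=variants,
                           haplotypes=hap, region_length=int(region_length),
                           block_model=model)

    n_common = int(np.sum(np.minimum(realized, 1 - realized) >= 0.01))
    achieved = n_common / (region_length / 1e6)
    if not (0.7 * params.target_density <= achieved <= 1.4 * params.target_density):
        raise PanelError(
            f"achieved common-variant density {achieved:.0f}/Mb infeasible for "
            f"target {params.target_density:.0f}/Mb with this block configuration"
        )
    return panel


def derive_diverged_panel(panel: HaplotypePanel, fst: float,
                          recomb_scale: float, seed: int,
                          population: str = "AFR-like") -> HaplotypePanel:
    """Second-population panel over the same variant list.

    Block-haplotype frequencies are redrawn per block under Balding-Nichols
    drift (Dirichlet with concentration ``(1-F)/F`` times the source
    frequencies, so Var(p' - p) = F p (1-p) for any aggregate of
    block-haplotypes). Blocks are subdivided by ``recomb_scale`` so the chain
    redraws its latent uniform more often, shortening LD. Every variant of the
    source panel remains present, possibly at a very different (even
    near-zero) frequency.
    """
    if panel.block_model is None:
        raise PanelError("source panel lacks block structure "
                         "(must come from synthesize_panel)")
    if not (0.0 <= fst < 1.0):
        raise ConfigError(f"fst must be in [0, 1), got {fst}")
    if recomb_scale <= 0:
        raise ConfigError("recomb_scale must be positive")
    rng = np.random.default_rng(seed)
    bm = panel.block_model
    h = panel.n_haplotypes
    k = bm.k
    n_blocks = bm.n_blocks

    # Balding-Nichols redraw of block-haplotype frequencies
    if fst == 0.0:
        new_freqs = bm.hap_freqs.copy()
        _ = rng.random()  # keep stream position deterministic
    else:
        conc = (1.0 - fst) / fst
        gammas = rng.gamma(np.maximum(bm.hap_freqs * conc, 0.0))
        totals = gammas.sum(axis=1, keepdims=True)
        bad = (totals[:, 0] <= 0)
        new_freqs = np.where(bad[:, None], bm.hap_freqs,
                             gammas / np.where(totals > 0, totals, 1.0))

    # subdivide blocks: expected sub-block count per block = recomb_scale
    base = int(np.floor(recomb_scale))
    frac = recomb_scale - base
    sub_counts = base + (rng.random(n_blocks) < frac).astype(int)
    sub_counts = np.maximum(sub_counts, 1)
    sub_parent = np.repeat(np.arange(n_blocks), sub_counts)
    n_sub = len(sub_parent)

    u = _chain_uniforms(rng, h, n_sub, bm.rho)
    states = _states_from_uniforms(u, new_freqs[sub_parent])

    # map each variant to a sub-block of its parent block
    positions = panel.positions
    hap = np.empty((h, panel.n_variants), dtype=np.uint8)
    sub_of_block: list[np.ndarray] = []
    start = 0
    for b in range(n_blocks):
        sub_of_block.append(np.arange(start, start + sub_counts[b]))
        start += sub_counts[b]
    for b in range(n_blocks):
        cols = np.where(bm.var_block == b)[0]
        if len(cols) == 0:
            continue
        lo, hi = bm.boundaries[b], bm.boundaries[b + 1]
        edges = np.linspace(lo, hi, sub_counts[b] + 1)
        sub_idx = np.clip(np.searchsorted(edges, positions[cols], side="right") - 1,
                          0, sub_counts[b] - 1)
        mat = bm.alleles[b]  # (K, m_b)
        for s_local in np.unique(sub_idx):
            sub_global = sub_of_block[b][s_local]
            vcols = cols[sub_idx == s_local]
            local = np.searchsorted(cols, vcols)
            hap[:, vcols] = mat[states[:, sub_global], :][:, local]

    # the diverged population carries its own private-mutation noise
    if bm.flip_rate > 0:
        n_flip = rng.poisson(bm.flip_rate, size=panel.n_variants)
        for j in np.where(n_flip > 0)[0]:
            rows = rng.integers(0, h, size=n_flip[j])
            hap[rows, j] ^= 1

    realized = hap.mean(axis=0)
    variants = [
        dataclasses.replace(v, alt_freq=float(realized[j]))
        for j, v in enumerate(panel.variants)
    ]
    return HaplotypePanel(population=population, variants=variants,
                          haplotypes=hap, region_length=panel.region_length,
                          block_model=None)


# ----------------------------------------------------------------------
# LD utilities
# ----------------------------------------------------------------------

def compute_r2(panel: HaplotypePanel, a: int, b: int) -> float:
    """Squared haplotype correlation r^2 = D^2 / (pA(1-pA) pB(1-pB)).

    Raises :class:`MonomorphicVariantError` if either variant is monomorphic
    (r^2 undefined, distinct from 0).
    """
    xa = panel.haplotypes[:, a].astype(float)
    xb = panel.haplotypes[:, b].astype(float)
    pa, pb = xa.mean(), xb.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va <= 0 or vb <= 0:
        raise MonomorphicVariantError(
            f"r^2 undefined: variant index {a if va <= 0 else b} is monomorphic")
    d = (xa * xb).mean() - pa * pb
    return float(d * d / (va * vb))


def r2_matrix(panel: HaplotypePanel, anchor: int,
              columns: np.ndarray | None = None) -> np.ndarray:
    """r^2 of one anchor variant against a set of columns (vectorized).

    Monomorphic columns get NaN; a monomorphic anchor raises.
    """
    x = panel.haplotypes[:, anchor].astype(np.float64)
    pa = x.mean()
    va = pa * (1 - pa)
    if va <= 0:
        raise MonomorphicVariantError("anchor variant is monomorphic")
    cols = panel.haplotypes if columns is None else panel.haplotypes[:, columns]
    cols = cols.astype(np.float64)
    p = cols.mean(axis=0)
    v = p * (1 - p)
    d = (cols * x[:, None]).mean(axis=0) - p * pa
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(v > 0, d * d / (v * va), np.nan)
    return r2


# ----------------------------------------------------------------------
# VCF I/O (pysam)
# ----------------------------------------------------------------------

_CONTIG = "1"


def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write the panel as a phased biallelic VCF (GT like ``0|1``).

    Ancestral frequency and the coding flag travel in INFO (``ANC_AF``,
    ``CODING``); the population label in a ``##population`` header line.
    Round trips through :func:`read_vcf` preserve the matrix exactly.
    """
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(_CONTIG, length=max(panel.region_length, 1))
    header.add_meta("population", value=panel.population)
    header.add_meta("region_length", value=str(panel.region_length))
    header.info.add("ANC_AF", number=1, type="Float",
                    description="Generating (ancestral) alternate allele frequency")
    header.info.add("CODING", number=0, type="Flag",
                    description="Variant lies in a synthetic exon interval")
    header.formats.add("GT", 1, "String", "Genotype")
    n_samples = panel.n_haplotypes // 2
    samples = [f"S{i:04d}" for i in range(n_samples)]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(panel.variants):
            rec = out.new_record(contig=_CONTIG, start=v.position,
                                 alleles=(v.ref, v.alt), id=v.id)
            rec.qual = None
            rec.info["ANC_AF"] = float(v.ancestral_freq)
            if v.is_coding:
                rec.info["CODING"] = True
            col = panel.haplotypes[:, j]
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(col[2 * i]), int(col[2 * i + 1]))
                rec.samples[s].phased = True
            out.write(rec)


def read_vcf(path: str, population: str | None = None) -> HaplotypePanel:
    """Read a phased biallelic VCF into a :class:`HaplotypePanel`.

    Unphased or multiallelic records are rejected with the offending position
    reported. The block model is not recoverable from a VCF.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        pop = population
        region_length = 0
        for line in str(vf.header).splitlines():
            if line.startswith("##population=") and pop is None:
                pop = line.split("=", 1)[1]
            if line.startswith("##region_length="):
                region_length = int(line.split("=", 1)[1])
        if not region_length:
            for c in vf.header.contigs.values():
                region_length = max(region_length, c.length or 0)
        variants: list[VariantRecord] = []
        columns: list[np.ndarray] = []
        for rec in vf:
            if len(rec.alleles) != 2:
                raise PanelError(
                    f"multiallelic record at {rec.contig}:{rec.pos} not supported")
            alleles = []
            for s in rec.samples.values():
                gt = s["GT"]
                if len(gt) != 2 or any(a is None for a in gt):
                    raise PanelError(
                        f"missing genotype at {rec.contig}:{rec.pos}")
                if not s.phased:
                    raise PanelError(
                        f"unphased genotype at {rec.contig}:{rec.pos}; "
                        "phased haplotypes (0|1) required")
                alleles.extend(gt)
            col = np.asarray(alleles, dtype=np.uint8)
            columns.append(col)
            anc = float(rec.info.get("ANC_AF", col.mean()))
            variants.append(VariantRecord(
                id=rec.id or f"v{rec.start:07d}", position=rec.start,
                ref=rec.alleles[0], alt=rec.alleles[1],
                ancestral_freq=anc, alt_freq=float(col.mean()),
                is_coding=bool(rec.info.get("CODING", False)),
            ))
    if not columns:
        raise PanelError(f"no records in {path}")
    hap = np.stack(columns, axis=1)
    if not region_length:
        region_length = int(variants[-1].position) + 1
    return HaplotypePanel(population=pop or "panel", variants=variants,
                          haplotypes=hap, region_length=region_length)
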
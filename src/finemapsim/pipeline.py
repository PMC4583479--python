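"""End-to-end simulation grid: scenario x RAF x OR x ancestry mix x prior.

One *replicate* = one freshly synthesized 1 Mb region with an assigned causal
variant (or pair), ten simulated case-control cohorts, scenario transforms
(array downsampling, failure, imputation, QC), meta-analysis, ABF
fine-mapping, and scoring. Every replicate's random stream derives
deterministically from (master seed, setting index, replicate index), so runs
are reproducible and resumable record by record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, evaluate, finemap, impute, panel as panel_mod, simulate
from .errors import ConfigError, DataError

__all__ = ["GridConfig", "run_grid", "run_replicate", "finemap_summary_file"]

log = logging.getLogger("finemapsim")


@dataclass
class GridConfig:
    """Full configuration of a simulation grid.

    Defaults follow the reference study design: ten cohorts of 1,000 cases
    and 1,000 controls, RAF levels {5, 10, 20, 50}%, OR levels
    {1.0, 1.1, 1.2, 1.5}, prevalence 0.55%, prior variance W = 0.04,
    INFO > 0.4 / MAF >= 1% QC, credible levels 95% and 99%.
    """

    replicates: int = 1000
    raf_levels: tuple = (0.05, 0.10, 0.20, 0.50)
    or_levels: tuple = (1.0, 1.1, 1.2, 1.5)
    scenarios: tuple = ("gold",)
    population_mixes: tuple = (0,)      # AFR-like studies out of n_studies
    n_studies: int = 10
    n_cases: int = 1000
    n_controls: int = 1000
    prevalence: float = 0.0055

    region_length: int = 1_000_000
    panel_density: float = 3000.0
    n_haplotypes: int = 200
    block_length_mean: float = 40_000.0
    haplotypes_per_block: int = 6
    inter_block_correlation: float = 0.9
    fst: float = 0.15
    recomb_scale: float = 2.0
    private_flip_rate: float = 0.3
    exon_count_per_mb: float = 10.0
    exon_length_bp: int = 300
    switch_rate: float = simulate.DEFAULT_SWITCH_RATE

    array_fraction: float = 0.27        # fraction of panel variants on array
    failure_fraction: float = 0.05
    k_neighbors: int = 30
    ridge: float = 1e-3
    n_augment: int = 1000

    w: float = 0.04
    credible_levels: tuple = (0.95, 0.99)
    min_n_fraction: float = 0.7
    info_min: float = 0.4
    maf_min: float = 0.01
    r2_thresholds: tuple = (0.5, 0.8, 0.9)
    alpha: float = 5e-8

    raf_tolerance: float = 0.005
    central_fraction: float = 0.5
    causal_coding: bool = False
    coding_prior_weight: float = 1.0
    multi_causal: bool = False
    multi_causal_maf: float = 0.10
    multi_causal_max_r2: float = 0.05

    seed: int = 0
    outdir: str | None = None
    # region redraws happen before any cohort simulation, so a generous cap
    # costs little; thin parts of the frequency spectrum (RAF ~ 0.5) redraw
    # the region about half the time
    retry_cap: int = 60

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicate count must be >= 1")
        for s in self.scenarios:
            if s not in ("gold", "gwas", "gwas_failure"):
                raise ConfigError(f"unknown scenario {s!r}")
        for mx in self.population_mixes:
            if not (0 <= mx <= self.n_studies):
                raise ConfigError("population mix exceeds study count")
        if not (0 < self.array_fraction <= 1):
            raise ConfigError("array_fraction must be in (0, 1]")
        if self.coding_prior_weight <= 0:
            raise ConfigError("coding_prior_weight must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "GridConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError("unknown config key(s): "
                              + ", ".join(sorted(unknown)))
        for key in ("raf_levels", "or_levels", "scenarios",
                    "population_mixes", "credible_levels", "r2_thresholds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def panel_params(self, seed: int) -> panel_mod.PanelModelParams:
        return panel_mod.PanelModelParams(
            n_haplotypes=self.n_haplotypes, target_density=self.panel_density,
            block_length_mean=self.block_length_mean,
            haplotypes_per_block=self.haplotypes_per_block,
            inter_block_correlation=self.inter_block_correlation,
            fst=self.fst, recomb_scale=self.recomb_scale,
            private_flip_rate=self.private_flip_rate,
            exon_count_per_mb=self.exon_count_per_mb,
            exon_length_bp=self.exon_length_bp, seed=seed,
        )

    def settings(self) -> list[dict]:
        out = []
        for mix in self.population_mixes:
            for raf in self.raf_levels:
                for or_ in self.or_levels:
                    out.append({"raf": float(raf), "odds_ratio": float(or_),
                                "mix": int(mix)})
        return out


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _prepare_region(config: GridConfig, setting: dict,
                    ss: np.random.SeedSequence, attempt: int = 0):
    """Synthesize panels and the causal assignment for one replicate.

    The causal variant is placed centrally; because realized frequencies are
    quantized by the block-haplotype clades, some RAF targets (notably 50%,
    where the 1/p spectrum is thin) have no central match within the 0.5 pp
    tolerance in a sizable fraction of regions. Later redraw attempts widen
    the positional window (never the frequency tolerance) so replicates
    terminate.
    """
    kids = ss.spawn(4)
    rng = np.random.default_rng(kids[3])
    eur = panel_mod.synthesize_panel(
        config.panel_params(_seed_int(kids[0])), config.region_length)
    if config.multi_causal:
        id1, id2 = simulate.select_multi_causal_pair(
            eur, maf_target=config.multi_causal_maf,
            max_r2=config.multi_causal_max_r2, rng=rng)
        causal_spec = [(id1, setting["odds_ratio"]),
                       (id2, setting["odds_ratio"])]
    else:
        if attempt >= 16:
            central = None
        elif attempt >= 8:
            central = min(1.0, config.central_fraction + 0.25)
        else:
            central = config.central_fraction
        idx = simulate.find_variant_by_raf(
            eur, setting["raf"], tolerance=config.raf_tolerance,
            central_fraction=central, rng=rng)
        causal_spec = [(eur.variants[idx].id, setting["odds_ratio"])]
        if config.causal_coding:
            # condition on an exonic causal variant: place one exon interval
            # over it (the scenario draws regions whose causal is coding)
            lo = eur.variants[idx].position - config.exon_length_bp // 2
            hi = lo + config.exon_length_bp
            for v in eur.variants:
                if lo <= v.position < hi:
                    v.is_coding = True
            eur.__dict__.pop("_views", None)
    model_eur = simulate.build_disease_model(eur, causal_spec,
                                             config.prevalence)
    afr = model_afr = None
    if setting["mix"] > 0:
        afr = panel_mod.derive_diverged_panel(
            eur, config.fst, config.recomb_scale, _seed_int(kids[1]))
        freqs = afr.alt_freqs[model_eur.causal_indices]
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            raise DataError("causal variant monomorphic in the diverged panel")
        model_afr = simulate.build_disease_model(
            afr, [(vid, o) for vid, o in
                  zip(model_eur.causal_ids, model_eur.odds_ratios)],
            config.prevalence)
    return eur, afr, model_eur, model_afr, _seed_int(kids[2])


def _study_population(i: int, mix: int) -> str:
    return "afr" if i < mix else "eur"


def run_replicate(config: GridConfig, setting: dict, rep: int,
                  setting_index: int) -> list[evaluate.ReplicateOutcome]:
    """All scenario/prior outcomes for one replicate of one grid setting."""
    last_err = None
    for attempt in range(config.retry_cap):
        ss = np.random.SeedSequence(
            (config.seed, setting_index, rep, attempt))
        try:
            return _run_replicate_once(config, setting, ss, attempt)
        except DataError as err:
            last_err = err
            log.info("replicate %s/%d attempt %d redrawn: %s",
                     setting, rep, attempt, err)
    raise DataError(f"replicate failed after {config.retry_cap} redraws: "
                    f"{last_err}")


def _run_replicate_once(config: GridConfig, setting: dict,
                        ss: np.random.SeedSequence, attempt: int = 0):
    eur, afr, model_eur, model_afr, mask_seed = _prepare_region(
        config, setting, ss, attempt)
    mix = setting["mix"]
    study_seeds = ss.spawn(config.n_studies + 1)
    studies = []
    for i in range(config.n_studies):
        pop = _study_population(i, mix)
        pnl = afr if pop == "afr" else eur
        mdl = model_afr if pop == "afr" else model_eur
        studies.append(simulate.simulate_case_control(
            pnl, mdl, config.n_cases, config.n_controls,
            study_seeds[i], study_id=f"{pop}{i:02d}",
            switch_rate=config.switch_rate))

    majority_panel = afr if (afr is not None and mix > config.n_studies // 2) \
        else eur
    coding = eur.coding_mask
    coding_by_id = dict(zip(eur.ids.astype(str), coding))
    thresholds = impute.QCThresholds(info_min=config.info_min,
                                     maf_min=config.maf_min)

    needs_array = any(s != "gold" for s in config.scenarios)
    array_mask = imp_models = None
    if needs_array:
        density = (config.array_fraction * eur.n_variants
                   / (config.region_length / 1e6))
        array_mask = simulate.select_array_mask(eur, density, mask_seed)
        imp_models = {"eur": impute.fit_imputation_model(
            eur, array_mask, config.k_neighbors, config.ridge,
            n_augment=config.n_augment, switch_rate=config.switch_rate,
            seed=mask_seed)}
        if afr is not None:
            imp_models["afr"] = impute.fit_imputation_model(
                afr, array_mask, config.k_neighbors, config.ridge,
                n_augment=config.n_augment, switch_rate=config.switch_rate,
                seed=mask_seed + 1)

    outcomes = []
    for scen_name in config.scenarios:
        results = []
        for i, study in enumerate(studies):
            pop = _study_population(i, mix)
            if scen_name == "gold":
                prepared = study
            else:
                spec = simulate.ScenarioSpec(
                    name=scen_name, array_mask=array_mask,
                    failure_fraction=(config.failure_fraction
                                      if scen_name == "gwas_failure" else 0.0),
                    seed=mask_seed)
                masked = simulate.apply_scenario(study, spec)
                pnl = afr if pop == "afr" else eur
                prepared = impute.impute_study(
                    masked, imp_models[pop], panel=pnl,
                    k_neighbors=config.k_neighbors, ridge=config.ridge)
            res = assoc.association_scan(prepared)
            # per-study INFO filter: a variant leaves a study, not the region
            res.include = (res.status == assoc.STATUS_OK) \
                & (res.info > config.info_min)
            results.append(res)
        meta = assoc.meta_analyze(results)
        retain = impute.qc_filter(
            meta, None if scen_name == "gold" else meta.info_min, thresholds)
        if not retain.any():
            raise DataError("no variants survived QC")
        prior_modes = ["uniform"]
        if config.coding_prior_weight != 1.0:
            prior_modes.append("coding")
        for mode in prior_modes:
            weights = None
            if mode == "coding":
                weights = np.array(
                    [config.coding_prior_weight
                     if coding_by_id.get(str(v), False) else 1.0
                     for v in meta.ids])
            params = finemap.ABFParams(
                w=config.w, levels=config.credible_levels,
                min_n_fraction=config.min_n_fraction)
            fm = finemap.finemap_meta(meta, params, retain=retain,
                                      prior_weights=weights)
            outcomes.append(_score(config, setting, scen_name, mode, meta,
                                   retain, fm, model_eur.causal_ids,
                                   majority_panel))
    return outcomes


def _score(config, setting, scen_name, prior_mode, meta, retain, fm,
           causal_ids, majority_panel) -> evaluate.ReplicateOutcome:
    causal_set = {str(c) for c in causal_ids}
    ranks = [evaluate.causal_rank(meta, c, retain) for c in causal_ids]
    ranks = [r for r in ranks if r is not None]
    set_sizes, causal_in = {}, {}
    for lv in config.credible_levels:
        cs = fm.credible_set(lv)
        set_sizes[lv] = cs.size
        causal_in[lv] = bool(causal_set & {str(i) for i in cs.ids})
    r2_sizes, r2_contains = {}, {}
    for thr in config.r2_thresholds:
        try:
            ids = finemap.r2_proxy_set(meta, majority_panel, thr, retain)
        except DataError:
            continue
        r2_sizes[thr] = len(ids)
        r2_contains[thr] = bool(causal_set & {str(i) for i in ids})
    out_setting = dict(setting)
    out_setting["scenario"] = scen_name
    out_setting["prior"] = prior_mode
    return evaluate.ReplicateOutcome(
        setting=out_setting, causal_ids=list(causal_ids),
        rank=(min(ranks) if ranks else None), censored=not ranks,
        set_sizes=set_sizes, causal_in_set=causal_in,
        r2_sizes=r2_sizes, r2_contains=r2_contains,
        n_variants_retained=int(retain.sum()),
    )


# ----------------------------------------------------------------------
# grid driver
# ----------------------------------------------------------------------

def run_grid(config: GridConfig):
    """Run the whole grid; returns (EvalSummary, list of outcomes).

    With ``config.outdir`` set, per-replicate records stream to
    ``outcomes.jsonl`` and completed replicates are skipped on rerun, so a
    partial run resumes without recomputation.
    """
    config.validate()
    settings = config.settings()
    records_path = None
    done: set = set()
    outcomes: list[evaluate.ReplicateOutcome] = []
    if config.outdir:
        os.makedirs(config.outdir, exist_ok=True)
        records_path = os.path.join(config.outdir, "outcomes.jsonl")
        if os.path.exists(records_path):
            with open(records_path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    done.add((rec["setting_index"], rec["rep"]))
                    outcomes.append(
                        evaluate.ReplicateOutcome.from_record(rec))
    sink = open(records_path, "a") if records_path else None
    try:
        for s_idx, setting in enumerate(settings):
            for rep in range(config.replicates):
                if (s_idx, rep) in done:
                    continue
                for out in run_replicate(config, setting, rep, s_idx):
                    rec = out.to_record()
                    rec["setting_index"] = s_idx
                    rec["rep"] = rep
                    if sink:
                        sink.write(json.dumps(rec, sort_keys=True) + "\n")
                    outcomes.append(out)
                if sink:
                    sink.flush()
                log.info("setting %d/%d rep %d done", s_idx + 1,
                         len(settings), rep)
    finally:
        if sink:
            sink.close()
    summary = evaluate.summarize_replicates(
        outcomes, levels=config.credible_levels,
        power_kwargs={"n_cases": config.n_cases * config.n_studies,
                      "n_controls": config.n_controls * config.n_studies,
                      "prevalence": config.prevalence,
                      "alpha": config.alpha})
    if config.outdir:
        summary.write(os.path.join(config.outdir, "summary.tsv"))
    return summary, outcomes


# ----------------------------------------------------------------------
# fine-mapping real summary statistics
# ----------------------------------------------------------------------

def finemap_summary_file(summary_path: str, panel_path: str | None = None,
                         w: float = 0.04, levels=(0.95, 0.99),
                         min_n_fraction: float = 0.7,
                         weights_column: str | None = None,
                         r2_thresholds=(), out_path: str | None = None):
    """Fine-map a single-locus summary-statistics file.

    Runs rescaling (when N_EFF is present) -> ABF -> posteriors -> credible
    sets; with a phased panel VCF, also r^2 comparator sets. This is the
    entry point for published GWAS summary statistics.
    Returns (FinemapResult, {level: CredibleSet}, table DataFrame).
    """
    df = assoc.read_summary(summary_path)
    meta = assoc.MetaResult(
        ids=df["SNPID"].to_numpy(dtype=object),
        positions=df["POS"].to_numpy(dtype=np.int64) - 1,
        ea=df["EA"].to_numpy(dtype=object),
        nea=df["NEA"].to_numpy(dtype=object),
        eaf=df.get("EAF", pd.Series(np.nan, index=df.index)).to_numpy(float),
        beta=df["BETA"].to_numpy(float), se=df["SE"].to_numpy(float),
        z=df["Z"].to_numpy(float), n_eff=df["N_EFF"].to_numpy(float),
        n_studies=df.get("N_STUDIES",
                         pd.Series(1, index=df.index)).to_numpy(int),
        presence=np.zeros((0, len(df)), dtype=bool),
        info_min=df.get("INFO",
                        pd.Series(np.nan, index=df.index)).to_numpy(float),
    )
    weights = None
    if weights_column:
        if weights_column not in df.columns:
            raise DataError(f"summary file missing required column(s): "
                            f"{weights_column}")
        weights = df[weights_column].to_numpy(float)
    params = finemap.ABFParams(w=w, levels=tuple(levels),
                               min_n_fraction=min_n_fraction)
    do_rescale = bool(np.all(np.isfinite(meta.n_eff)) and np.all(meta.n_eff > 0))
    fm = finemap.finemap_meta(meta, params, prior_weights=weights,
                              rescale=do_rescale)
    sets = {lv: fm.credible_set(lv) for lv in levels}
    table = fm.to_frame(levels=levels)
    if panel_path and r2_thresholds:
        pnl = panel_mod.read_vcf(panel_path)
        for thr in r2_thresholds:
            ids = finemap.r2_proxy_set(meta, pnl, thr)
            table[f"IN_R2_{thr}"] = table["SNPID"].isin(
                [str(i) for i in ids]).to_numpy()
    if out_path:
        table.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return fm, sets, table
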
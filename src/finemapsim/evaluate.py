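"""Scoring of fine-mapping outcomes across replicates, and analytic power.

Per replicate we record whether each credible set contains a causal variant
(coverage), the rank of the causal variant by |z|, the set sizes, and a
success category using the "fewer than ten variants" criterion. Replicates
where the causal variant is removed by QC are *censored*: counted as
non-covered for coverage (conservative) and excluded from rank statistics.

Analytic power follows the classic unmatched case-control computation on
allele counts: genotype frequencies under HWE, penetrances from prevalence
and odds ratio, expected case/control allele frequencies, and the power of
the two-sample allele-frequency z-test at a two-sided genome-wide alpha
(default 5e-8) with the standard error evaluated under the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataError

__all__ = [
    "ReplicateOutcome",
    "EvalSummary",
    "PowerParams",
    "causal_rank",
    "coverage_rate",
    "classify_fine_mapping",
    "summarize_replicates",
    "power_case_control",
    "nearest_rank_quantile",
    "CATEGORIES",
]

CATEGORIES = ("causal_singleton", "causal_lt10", "lt10_no_causal", "ge10")


@dataclass
class ReplicateOutcome:
    """Fine-mapping result of one replicate region under one setting."""

    setting: dict                     # raf, odds_ratio, scenario, mix, prior...
    causal_ids: list
    rank: int | None                  # 1-based by |z|; None when censored
    censored: bool
    set_sizes: dict                   # level -> size
    causal_in_set: dict               # level -> bool
    r2_sizes: dict = field(default_factory=dict)      # threshold -> size
    r2_contains: dict = field(default_factory=dict)   # threshold -> bool
    n_variants_retained: int = 0

    def to_record(self) -> dict:
        return {
            "setting": self.setting, "causal_ids": list(self.causal_ids),
            "rank": self.rank, "censored": self.censored,
            "set_sizes": {str(k): int(v) for k, v in self.set_sizes.items()},
            "causal_in_set": {str(k): bool(v)
                              for k, v in self.causal_in_set.items()},
            "r2_sizes": {str(k): int(v) for k, v in self.r2_sizes.items()},
            "r2_contains": {str(k): bool(v)
                            for k, v in self.r2_contains.items()},
            "n_variants_retained": int(self.n_variants_retained),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ReplicateOutcome":
        return cls(
            setting=rec["setting"], causal_ids=rec["causal_ids"],
            rank=rec["rank"], censored=rec["censored"],
            set_sizes={float(k): v for k, v in rec["set_sizes"].items()},
            causal_in_set={float(k): v
                           for k, v in rec["causal_in_set"].items()},
            r2_sizes={float(k): v for k, v in rec.get("r2_sizes", {}).items()},
            r2_contains={float(k): v
                         for k, v in rec.get("r2_contains", {}).items()},
            n_variants_retained=rec.get("n_variants_retained", 0),
        )


@dataclass
class PowerParams:
    """Inputs of the analytic case-control power computation."""

    n_cases: int
    n_controls: int
    raf: float
    odds_ratio: float
    prevalence: float = 0.0055
    alpha: float = 5e-8

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("sample sizes must be positive")
        if not (0 < self.raf < 1):
            raise ConfigError("RAF must be in (0, 1)")
        if not (0 < self.prevalence < 1):
            raise ConfigError("prevalence must be in (0, 1)")


# ----------------------------------------------------------------------
# per-replicate scoring
# ----------------------------------------------------------------------

def causal_rank(meta, causal_id, retain: np.ndarray | None = None):
    """1-based rank of the causal variant by descending |z| (ties by
    ascending position). ``None`` when the causal variant is not retained
    (censored)."""
    if retain is None:
        retain = np.isfinite(meta.z)
    idx = np.where(retain & np.isfinite(meta.z))[0]
    id_arr = meta.ids[idx].astype(str)
    where = np.where(id_arr == str(causal_id))[0]
    if len(where) == 0:
        return None
    order = np.lexsort((meta.positions[idx], -np.abs(meta.z[idx])))
    return int(np.where(idx[order] == idx[where[0]])[0][0]) + 1


def coverage_rate(outcomes: list, level: float) -> float:
    """Fraction of replicates whose level-set contains any causal variant.

    Censored replicates count as non-covered.
    """
    if not outcomes:
        raise DataError("no outcomes")
    hits = sum(bool(o.causal_in_set.get(level, False)) for o in outcomes)
    return hits / len(outcomes)


def classify_fine_mapping(outcome: ReplicateOutcome, level: float,
                          success_threshold: int = 10) -> str:
    """Fig-3-style category: singleton with causal / <10 with causal /
    <10 without causal / >=10 ("fewer than ten" is strict)."""
    size = outcome.set_sizes[level]
    has = bool(outcome.causal_in_set.get(level, False))
    if size == 1 and has:
        return "causal_singleton"
    if size < success_threshold:
        return "causal_lt10" if has else "lt10_no_causal"
    return "ge10"


def nearest_rank_quantile(values, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th order statistic."""
    arr = np.sort(np.asarray(values))
    if len(arr) == 0:
        raise DataError("empty sample")
    k = max(int(np.ceil(q * len(arr))), 1)
    return float(arr[k - 1])


def summarize_replicates(outcomes: list, levels=(0.95, 0.99),
                         success_threshold: int = 10,
                         power_kwargs: dict | None = None) -> "EvalSummary":
    """Aggregate outcomes into per-setting, per-level summary rows."""
    if not outcomes:
        raise DataError("no outcomes to summarize")
    groups: dict = {}
    for o in outcomes:
        key = tuple(sorted(o.setting.items()))
        groups.setdefault(key, []).append(o)
    rows = []
    for key, outs in groups.items():
        setting = dict(key)
        ranks = [o.rank for o in outs if not o.censored and o.rank is not None]
        n_censored = sum(o.censored for o in outs)
        power = np.nan
        if power_kwargs is not None and "raf" in setting \
                and "odds_ratio" in setting:
            pp = PowerParams(raf=setting["raf"],
                             odds_ratio=setting["odds_ratio"], **power_kwargs)
            power = power_case_control(pp)
        for lv in levels:
            sizes = [o.set_sizes[lv] for o in outs if lv in o.set_sizes]
            cats = [classify_fine_mapping(o, lv, success_threshold)
                    for o in outs if lv in o.set_sizes]
            row = dict(setting)
            row.update({
                "level": lv,
                "n_replicates": len(outs),
                "n_censored": n_censored,
                "coverage": coverage_rate(outs, lv),
                "median_size": nearest_rank_quantile(sizes, 0.5),
                "p90_size": nearest_rank_quantile(sizes, 0.9),
                "success_rate": float(np.mean([s < success_threshold
                                               for s in sizes])),
                "rank1_rate": (float(np.mean([r == 1 for r in ranks]))
                               if ranks else np.nan),
                "power": power,
            })
            for cat in CATEGORIES:
                row[f"frac_{cat}"] = float(np.mean([c == cat for c in cats]))
            rows.append(row)
    table = pd.DataFrame(rows)
    return EvalSummary(table=table)


@dataclass
class EvalSummary:
    """Tidy per-setting evaluation table plus grid-level summaries."""

    table: pd.DataFrame

    def median_coverage(self, level: float, **setting_filter) -> float:
        """Median over settings of the per-setting coverage rate."""
        sub = self._filter(level, **setting_filter)
        return float(sub["coverage"].median())

    def _filter(self, level: float, **setting_filter) -> pd.DataFrame:
        sub = self.table[np.isclose(self.table["level"], level)]
        for k, v in setting_filter.items():
            sub = sub[sub[k] == v]
        if sub.empty:
            raise DataError("no summary rows match the filter")
        return sub

    def power_size_regression(self, level: float) -> tuple[float, float]:
        """(slope, R^2) of log median set size on analytic power."""
        sub = self._filter(level).dropna(subset=["power"])
        x = sub["power"].to_numpy(dtype=float)
        y = np.log(sub["median_size"].to_numpy(dtype=float))
        if len(x) < 3 or np.ptp(x) == 0:
            raise DataError("not enough settings for the regression")
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return float(slope), float(r2)

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ----------------------------------------------------------------------
# analytic power
# ----------------------------------------------------------------------

def power_case_control(params: PowerParams) -> float:
    """Power of the allele-count z-test for an additive disease model.

    HWE genotype frequencies at the risk allele frequency, penetrances
    ``f_g = f0 OR^g`` solved for the prevalence, expected case and
    (unaffected) control allele frequencies, then
    ``power = Phi(-z_{alpha/2} + |p_case - p_ctrl| / SE_alt)`` with 2n
    alleles per group and the SE under the alternative.
    """
    params.validate()
    p = params.raf
    or_ = params.odds_ratio
    k = params.prevalence
    geno_p = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    rel = or_ ** np.arange(3)
    f0 = k / float(geno_p @ rel)
    f = f0 * rel
    if np.any(f >= 1):
        raise DataError("penetrance >= 1; model degenerate")
    p_case = float((geno_p * f) @ np.array([0, 0.5, 1.0])) / k
    p_ctrl = float((geno_p * (1 - f)) @ np.array([0, 0.5, 1.0])) / (1 - k)
    if min(p_case, p_ctrl) <= 0 or max(p_case, p_ctrl) >= 1:
        raise DataError("degenerate allele frequencies")
    se_alt = np.sqrt(p_case * (1 - p_case) / (2 * params.n_cases)
                     + p_ctrl * (1 - p_ctrl) / (2 * params.n_controls))
    z_crit = norm.isf(params.alpha / 2.0)
    d = abs(p_case - p_ctrl) / se_alt
    # both rejection tails, so the null model recovers exactly alpha
    return float(norm.cdf(-z_crit + d) + norm.cdf(-z_crit - d))
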
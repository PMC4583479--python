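"""Wakefield approximate Bayes factors, posteriors, and credible sets.

For a variant with estimated log-OR ``beta``, standard error ``se``
(``V = se^2``), and a normal prior N(0, W) on the log-OR under association,
the approximate Bayes factor in favor of association is the marginal
likelihood ratio

    BF = N(beta; 0, V + W) / N(beta; 0, V)
       = sqrt(1 - r) * exp(z^2 r / 2),      r = W / (V + W),  z = beta / se.

This is the association-positive orientation (larger = more evidence), the
reciprocal of Wakefield's null-favoring form; external comparisons against
the null-favoring convention must invert. All arithmetic is in log space.

The default prior variance W = 0.04 corresponds to a 95% belief that the
odds ratio is below 1.5 (prior SD of the log-OR = log(1.5)/1.96 ≈ 0.21).

Posteriors over the variants of a locus assume a single causal variant:
``posterior_j = w_j BF_j / sum_k w_k BF_k`` with per-variant prior weights
``w`` (uniform by default; functional annotation can upweight classes such
as coding variants). A level-alpha credible set is the smallest
descending-posterior prefix whose cumulative posterior reaches alpha.

Variants measured in fewer samples (missingness, failed cohorts) have their
variance rescaled to the maximum observed effective sample size before the
ABF is computed, provided their sample size is within 30% of that maximum;
variants below the cutoff are excluded from the posterior normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DataError
from .panel import HaplotypePanel, r2_matrix

__all__ = [
    "ABFParams",
    "FinemapResult",
    "CredibleSet",
    "log_abf",
    "rescale_to_max_n",
    "posterior_probabilities",
    "credible_set",
    "finemap_meta",
    "r2_proxy_set",
]


@dataclass
class ABFParams:
    """Prior settings for ABF fine-mapping."""

    w: float = 0.04
    levels: tuple = (0.95, 0.99)
    min_n_fraction: float = 0.7
    prior_weights: np.ndarray | None = None

    def validate(self) -> None:
        if self.w <= 0:
            raise DataError("prior variance W must be positive")
        if any(not (0 < lv < 1) for lv in self.levels):
            raise DataError("credible levels must be in (0, 1)")


@dataclass
class CredibleSet:
    """Smallest descending-posterior prefix reaching the stated level."""

    level: float
    ids: list
    indices: np.ndarray          # into the FinemapResult arrays
    cumulative: float
    size: int = 0

    def __post_init__(self):
        self.size = len(self.ids)

    def __contains__(self, variant_id) -> bool:
        return variant_id in set(self.ids)


@dataclass
class FinemapResult:
    """Per-variant fine-mapping state for one locus."""

    ids: np.ndarray
    positions: np.ndarray
    z: np.ndarray
    v: np.ndarray                  # (possibly rescaled) squared SE
    r: np.ndarray                  # shrinkage W/(V+W)
    log_abf_: np.ndarray
    prior: np.ndarray
    posterior: np.ndarray
    rescaled: np.ndarray           # bool, V adjusted for sample size
    excluded_low_n: np.ndarray     # bool, dropped from normalization
    w: float = 0.04

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded_low_n

    def credible_set(self, level: float) -> CredibleSet:
        return credible_set(self.posterior, level, z=self.z,
                            positions=self.positions, ids=self.ids)

    def to_frame(self, levels=(0.95, 0.99)) -> pd.DataFrame:
        order = _credible_order(self.posterior, self.z, self.positions)
        cum = np.cumsum(self.posterior[order])
        df = pd.DataFrame({
            "SNPID": self.ids[order].astype(str),
            "POS": self.positions[order] + 1,
            "Z": self.z[order],
            "LOG10_ABF": self.log_abf_[order] / np.log(10.0),
            "PRIOR": self.prior[order],
            "POSTERIOR": self.posterior[order],
            "CUMULATIVE": cum,
        })
        for lv in levels:
            size = self.credible_set(lv).size
            df[f"IN_{int(round(lv * 100))}"] = np.arange(len(df)) < size
        return df


# ----------------------------------------------------------------------
# core formulas
# ----------------------------------------------------------------------

def log_abf(beta, se, w: float = 0.04):
    """Log approximate Bayes factor in favor of association.

    ``log BF = 0.5 log(1 - r) + z^2 r / 2`` with ``r = W/(V+W)``; equals the
    log ratio of normal marginal likelihoods N(beta; 0, V+W) / N(beta; 0, V).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DataError("standard errors must be positive")
    if w <= 0:
        raise DataError("prior variance W must be positive")
    v = se ** 2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z * z * r
    return out if out.shape else float(out)


def rescale_to_max_n(v: np.ndarray, n_eff: np.ndarray, n_max: float,
                     min_fraction: float = 0.7):
    """Rescale variances to the maximum observed effective sample size.

    Variance scales inversely with sample size, so a variant measured in
    ``n_eff`` of ``n_max`` samples gets ``V' = V * n_eff / n_max``. Variants
    with ``n_eff`` below ``min_fraction * n_max`` are flagged for exclusion
    instead. Returns (V', rescaled flags, excluded flags).
    """
    if n_max <= 0:
        raise DataError("n_max must be positive")
    v = np.asarray(v, dtype=float)
    n_eff = np.asarray(n_eff, dtype=float)
    if np.any(n_eff > n_max * (1 + 1e-9)):
        raise DataError("n_eff exceeds n_max")
    frac = n_eff / n_max
    excluded = frac < min_fraction
    rescale = (~excluded) & (frac < 1.0 - 1e-12)
    v_out = np.where(rescale, v * frac, v)
    return v_out, rescale, excluded


def posterior_probabilities(log_bfs: np.ndarray,
                            prior_weights: np.ndarray | None = None,
                            include: np.ndarray | None = None) -> np.ndarray:
    """Normalized posteriors over included variants, via log-sum-exp.

    ``posterior_j = w_j BF_j / sum_k w_k BF_k``; excluded variants get 0.
    Weights are scale-invariant.
    """
    log_bfs = np.asarray(log_bfs, dtype=float)
    m = len(log_bfs)
    if prior_weights is None:
        logw = np.zeros(m)
    else:
        prior_weights = np.asarray(prior_weights, dtype=float)
        if np.any(prior_weights <= 0):
            raise DataError("prior weights must be positive")
        logw = np.log(prior_weights)
    if include is None:
        include = np.ones(m, dtype=bool)
    if not include.any():
        raise DataError("all variants excluded from posterior normalization")
    score = logw + log_bfs
    denom = logsumexp(score[include])
    post = np.zeros(m)
    post[include] = np.exp(score[include] - denom)
    return post


def _credible_order(posterior, z=None, positions=None) -> np.ndarray:
    m = len(posterior)
    absz = np.abs(z) if z is not None else np.zeros(m)
    absz = np.where(np.isfinite(absz), absz, 0.0)
    pos = positions if positions is not None else np.arange(m)
    # descending posterior, ties by descending |z|, then ascending position
    return np.lexsort((pos, -absz, -np.asarray(posterior)))


def credible_set(posterior: np.ndarray, level: float, z=None, positions=None,
                 ids=None) -> CredibleSet:
    """Smallest prefix of descending-posterior variants reaching ``level``."""
    if not (0 < level < 1):
        raise DataError("credible level must be in (0, 1)")
    posterior = np.asarray(posterior, dtype=float)
    order = _credible_order(posterior, z, positions)
    cum = np.cumsum(posterior[order])
    k = int(np.searchsorted(cum, level - 1e-12) + 1)
    k = min(k, len(order))
    chosen = order[:k]
    idlist = (list(np.asarray(ids, dtype=object)[chosen]) if ids is not None
              else list(chosen))
    return CredibleSet(level=level, ids=idlist, indices=chosen,
                       cumulative=float(cum[k - 1]))


# ----------------------------------------------------------------------
# locus-level driver
# ----------------------------------------------------------------------

def finemap_meta(meta, params: ABFParams = None,
                 retain: np.ndarray | None = None,
                 prior_weights: np.ndarray | None = None,
                 rescale: bool = True) -> FinemapResult:
    """Fine-map a locus from meta-analysis summary statistics.

    ``retain`` restricts to QC-passing variants; ``prior_weights`` aligns
    with the retained subset of ``meta`` (or the full array). Variance
    rescaling to the maximum observed effective sample size is applied
    before the ABF unless ``rescale`` is False.
    """
    params = params or ABFParams()
    params.validate()
    if retain is None:
        retain = np.isfinite(meta.se) & (meta.se > 0)
    idx = np.where(retain)[0]
    if len(idx) == 0:
        raise DataError("no variants retained for fine-mapping")
    beta = meta.beta[idx]
    v = meta.se[idx] ** 2
    n_eff = meta.n_eff[idx]
    if rescale and np.all(n_eff > 0):
        n_max = float(n_eff.max())
        v, resc, excl = rescale_to_max_n(v, n_eff, n_max,
                                         params.min_n_fraction)
    else:
        resc = np.zeros(len(idx), dtype=bool)
        excl = np.zeros(len(idx), dtype=bool)
    se_adj = np.sqrt(v)
    z = beta / se_adj
    labf = log_abf(beta, se_adj, params.w)
    if prior_weights is None:
        weights = np.ones(len(idx))
    else:
        prior_weights = np.asarray(prior_weights, dtype=float)
        weights = (prior_weights[idx] if len(prior_weights) == len(meta.ids)
                   else prior_weights)
    post = posterior_probabilities(labf, weights, include=~excl)
    prior = weights / weights.sum()
    r = params.w / (v + params.w)
    return FinemapResult(
        ids=meta.ids[idx], positions=meta.positions[idx], z=z, v=v, r=r,
        log_abf_=labf, prior=prior, posterior=post, rescaled=resc,
        excluded_low_n=excl, w=params.w,
    )


def r2_proxy_set(meta, panel: HaplotypePanel, threshold: float,
                 retain: np.ndarray | None = None) -> list:
    """r^2-threshold comparator set around the lead variant.

    Lead = maximum |z| among retained variants; the set contains every
    retained variant with panel r^2 to the lead strictly exceeding the
    threshold (the lead itself always qualifies).
    """
    if retain is None:
        retain = np.isfinite(meta.z)
    idx = np.where(retain & np.isfinite(meta.z))[0]
    if len(idx) == 0:
        raise DataError("no variants available for the r^2 set")
    absz = np.abs(meta.z[idx])
    best = absz.max()
    tied = idx[absz >= best - 1e-12]
    lead = tied[np.argmin(meta.positions[tied])]
    try:
        lead_col = panel.index_of(meta.ids[lead])
    except KeyError:
        raise DataError(f"lead variant {meta.ids[lead]} absent from panel")
    cols = []
    keep_idx = []
    for i in idx:
        try:
            cols.append(panel.index_of(meta.ids[i]))
            keep_idx.append(i)
        except KeyError:
            continue
    r2 = r2_matrix(panel, lead_col, np.asarray(cols))
    chosen = [meta.ids[i] for i, rr in zip(keep_idx, r2)
              if np.isfinite(rr) and rr > threshold]
    lead_id = meta.ids[lead]
    if lead_id not in chosen:
        chosen.append(lead_id)
    return chosen
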
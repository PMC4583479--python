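"""Per-variant additive logistic association and fixed-effects meta-analysis.

Each variant is tested by maximum-likelihood logistic regression of the
binary phenotype on dosage (intercept + additive dosage term), Newton-Raphson
to a parameter tolerance of 1e-8, at most 25 iterations. Wald beta/se/z are
reported. Two kernels share the same likelihood:

* hard-call variants (all dosages in {0,1,2}, no missingness) collapse to
  2 x 3 sufficient-statistic tables, so Newton iterates on per-variant
  3-vectors regardless of sample size;
* continuous (imputed) dosages run a per-variant Newton over individuals,
  JIT-compiled with numba when available.

Studies are aggregated by inverse-variance fixed-effects meta-analysis:
``w_i = 1/se_i^2``, ``beta = sum(w_i b_i)/sum(w_i)``, ``se = sum(w_i)^-1/2``.
Effective sample size ``n_eff = 4/(1/n_cases + 1/n_controls)`` accumulates
over contributing studies and drives the missing-data variance rescaling
during fine-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import StudyGenotypes

__all__ = [
    "AssocResult",
    "MetaResult",
    "association_scan",
    "meta_analyze",
    "write_summary",
    "read_summary",
    "STATUS_OK",
    "STATUS_MONOMORPHIC",
    "STATUS_UNSTABLE",
]

STATUS_OK = 0
STATUS_MONOMORPHIC = 1
STATUS_UNSTABLE = 2

_TOL = 1e-8
_MAX_ITER = 25
_BETA_CAP = 15.0  # |log-OR| beyond this flags (quasi-)separation


@dataclass
class AssocResult:
    """Per-variant association statistics for one cohort."""

    study_id: str
    ids: np.ndarray
    positions: np.ndarray
    ea: np.ndarray            # effect allele (alt)
    nea: np.ndarray
    eaf: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    n_eff: np.ndarray
    status: np.ndarray        # int8 STATUS_* codes
    info: np.ndarray = field(default=None)
    include: np.ndarray = field(default=None)  # contributes to meta

    def __post_init__(self):
        if self.info is None:
            self.info = np.ones(len(self.ids))
        if self.include is None:
            self.include = self.status == STATUS_OK


@dataclass
class MetaResult:
    """Fixed-effects meta-analysis across cohorts."""

    ids: np.ndarray
    positions: np.ndarray
    ea: np.ndarray
    nea: np.ndarray
    eaf: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    n_eff: np.ndarray
    n_studies: np.ndarray
    presence: np.ndarray       # (n_studies_total, M) bool
    info_min: np.ndarray       # min INFO over contributing studies

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.eaf, 1.0 - self.eaf)


# ----------------------------------------------------------------------
# logistic kernels
# ----------------------------------------------------------------------

def _logistic_tables(counts1: np.ndarray, counts0: np.ndarray):
    """Vectorized Newton on 2 x 3 genotype tables.

    ``counts1``/``counts0``: (3, M) case/control counts per dosage level.
    Returns beta, se, converged (each (M,)).
    """
    g = np.array([0.0, 1.0, 2.0])[:, None]
    n_g = counts1 + counts0
    tot1 = counts1.sum(axis=0)
    tot = n_g.sum(axis=0)
    frac = np.clip(tot1 / np.maximum(tot, 1), 1e-12, 1 - 1e-12)
    b0 = np.log(frac / (1 - frac))
    b1 = np.zeros_like(b0)
    active = np.ones(b0.shape, dtype=bool)
    h00 = h01 = h11 = det = np.ones_like(b0)
    for _ in range(_MAX_ITER):
        eta = b0[None, :] + b1[None, :] * g
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n_g * mu * (1.0 - mu)
        resid = counts1 - n_g * mu
        g0 = resid.sum(axis=0)
        g1 = (g * resid).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (g * w).sum(axis=0)
        h11 = (g * g * w).sum(axis=0)
        det = h00 * h11 - h01 * h01
        safe = det > 1e-300
        d0 = np.where(safe, (h11 * g0 - h01 * g1) / np.where(safe, det, 1), 0)
        d1 = np.where(safe, (h00 * g1 - h01 * g0) / np.where(safe, det, 1), 0)
        d0 = np.clip(d0, -5, 5)
        d1 = np.clip(d1, -5, 5)
        b0 = b0 + np.where(active, d0, 0)
        b1 = b1 + np.where(active, d1, 0)
        step = np.maximum(np.abs(d0), np.abs(d1))
        active = active & (step >= _TOL) & safe
        if not active.any():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, h00 / np.where(det > 0, det, 1), np.inf))
    return b1, se, ~active


def _logreg_loop_py(x: np.ndarray, y: np.ndarray):
    """Per-variant Newton over individuals; NaN dosages are excluded."""
    n, m = x.shape
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    conv = np.zeros(m, dtype=np.bool_)
    for j in range(m):
        xj = x[:, j]
        usable = ~np.isnan(xj)
        xv = xj[usable].astype(np.float64)
        yv = y[usable].astype(np.float64)
        if len(xv) == 0 or xv.std() == 0:
            continue
        frac = min(max(yv.mean(), 1e-12), 1 - 1e-12)
        b0 = np.log(frac / (1 - frac))
        b1 = 0.0
        ok = False
        h00 = h01 = h11 = det = 1.0
        for _ in range(_MAX_ITER):
            eta = b0 + b1 * xv
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            r = yv - mu
            g0 = r.sum()
            g1 = (r * xv).sum()
            h00 = w.sum()
            h01 = (w * xv).sum()
            h11 = (w * xv * xv).sum()
            det = h00 * h11 - h01 * h01
            if det <= 1e-300:
                break
            d0 = min(max((h11 * g0 - h01 * g1) / det, -5), 5)
            d1 = min(max((h00 * g1 - h01 * g0) / det, -5), 5)
            b0 += d0
            b1 += d1
            if max(abs(d0), abs(d1)) < _TOL:
                ok = True
                break
        beta[j] = b1
        se[j] = np.sqrt(h00 / det) if det > 0 else np.inf
        conv[j] = ok
    return beta, se, conv


try:  # pragma: no cover - identical semantics to the python loop
    import numba

    # no fastmath: the kernel relies on NaN propagation for missing dosages
    _logreg_loop = numba.njit(cache=True)(_logreg_loop_py)
except Exception:  # pragma: no cover
    _logreg_loop = _logreg_loop_py


def _unique_columns(dos: np.ndarray, miss: np.ndarray | None):
    """Indices of first occurrences of identical (dosage, missingness)
    columns, and the inverse map. Perfect LD proxies share one model fit."""
    m = dos.shape[1]
    seen: dict = {}
    uniq: list[int] = []
    inverse = np.empty(m, dtype=np.int64)
    for j in range(m):
        key = dos[:, j].tobytes()
        if miss is not None:
            key = key + miss[:, j].tobytes()
        hit = seen.get(key)
        if hit is None:
            seen[key] = len(uniq)
            inverse[j] = len(uniq)
            uniq.append(j)
        else:
            inverse[j] = hit
    return np.asarray(uniq, dtype=np.int64), inverse


def association_scan(study: StudyGenotypes) -> AssocResult:
    """Additive logistic association for every variant of one cohort."""
    y = study.phenotype.astype(np.float64)
    if study.n_cases == 0 or study.n_controls == 0:
        raise DataError("both phenotype classes must be present")
    full_dos = study.dosages
    full_miss = study.missing_mask
    n, m = full_dos.shape
    has_missing = bool(full_miss.any())

    beta = np.zeros(m)
    se = np.full(m, np.inf)
    status = np.full(m, STATUS_OK, dtype=np.int8)
    eaf = np.full(m, np.nan)

    dosi = full_dos.astype(np.int8)
    is_int = ~np.any(full_dos != dosi, axis=0)
    is_int &= (dosi.min(axis=0) >= 0) & (dosi.max(axis=0) <= 2)
    if has_missing:
        any_missing = full_miss.any(axis=0)
        hard = is_int & ~any_missing
        n_case_used = (~full_miss[y == 1]).sum(axis=0).astype(float)
        n_ctrl_used = (~full_miss[y == 0]).sum(axis=0).astype(float)
    else:
        hard = is_int
        n_case_used = np.full(m, float((y == 1).sum()))
        n_ctrl_used = np.full(m, float((y == 0).sum()))
    soft = ~hard
    with np.errstate(divide="ignore"):
        n_eff = 4.0 / (1.0 / np.maximum(n_case_used, 1e-12)
                       + 1.0 / np.maximum(n_ctrl_used, 1e-12))
    n_eff[(n_case_used == 0) | (n_ctrl_used == 0)] = 0.0

    if hard.any():
        # 2x3 sufficient-statistic tables in one bincount pass
        d = dosi[:, hard].astype(np.int32)
        mh = d.shape[1]
        d += 3 * y.astype(np.int32)[:, None]
        d += 6 * np.arange(mh, dtype=np.int32)[None, :]
        counts = np.bincount(d.reshape(-1), minlength=6 * mh)
        counts = counts.reshape(mh, 6).T.astype(float)  # (6, mh): g within y
        c0 = counts[0:3]
        c1 = counts[3:6]
        b, s, conv = _logistic_tables(c1, c0)
        beta[hard] = b
        se[hard] = s
        tot = c0 + c1
        eaf[hard] = (tot[1] + 2.0 * tot[2]) / (2.0 * tot.sum(axis=0))
        mono = (tot > 0).sum(axis=0) <= 1
        sub = status[hard]
        sub[~conv | (np.abs(b) > _BETA_CAP) | ~np.isfinite(s)] = STATUS_UNSTABLE
        sub[mono] = STATUS_MONOMORPHIC
        status[hard] = sub

    if soft.any():
        # deduplicate identical columns; perfect proxies share one fit
        soft_idx = np.where(soft)[0]
        sub_dos = full_dos[:, soft_idx]
        sub_miss = full_miss[:, soft_idx] if has_missing else None
        uniq, inverse_s = _unique_columns(sub_dos, sub_miss)
        if has_missing:
            x = np.where(sub_miss[:, uniq], np.nan,
                         sub_dos[:, uniq].astype(np.float64))
        else:
            x = np.ascontiguousarray(sub_dos[:, uniq], dtype=np.float64)
        b, s, conv = _logreg_loop(x, y)
        with np.errstate(invalid="ignore"):
            var0 = np.nanstd(x, axis=0)
            eaf_u = np.nanmean(x, axis=0) / 2.0
        st = np.full(len(uniq), STATUS_OK, dtype=np.int8)
        st[~conv | (np.abs(b) > _BETA_CAP) | ~np.isfinite(s)] = STATUS_UNSTABLE
        st[var0 == 0] = STATUS_MONOMORPHIC
        beta[soft_idx] = b[inverse_s]
        se[soft_idx] = s[inverse_s]
        status[soft_idx] = st[inverse_s]
        eaf[soft_idx] = eaf_u[inverse_s]

    bad = status != STATUS_OK
    beta[bad] = np.nan
    se[bad] = np.nan
    with np.errstate(invalid="ignore"):
        z = beta / se
    return AssocResult(
        study_id=study.study_id, ids=study.variant_ids,
        positions=study.positions, ea=study.alt, nea=study.ref,
        eaf=eaf, beta=beta, se=se, z=z, n_eff=n_eff, status=status,
        info=study.info.copy(),
    )


# ----------------------------------------------------------------------
# meta-analysis
# ----------------------------------------------------------------------

def meta_analyze(results: list[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis, matching by variant id.

    A variant simply omits studies where it is absent or flagged; effect
    alleles are aligned across studies (a swapped EA/NEA flips the sign,
    anything else is an error naming the variant).
    """
    if not results:
        raise DataError("no studies to meta-analyze")
    ref = results[0]
    union_ids = list(ref.ids)
    seen = set(union_ids)
    for r in results[1:]:
        for vid in r.ids:
            if vid not in seen:
                union_ids.append(vid)
                seen.add(vid)
    index = {vid: i for i, vid in enumerate(union_ids)}
    m = len(union_ids)
    s = len(results)

    pos = np.zeros(m, dtype=np.int64)
    ea = np.empty(m, dtype=object)
    nea = np.empty(m, dtype=object)
    have_allele = np.zeros(m, dtype=bool)

    wsum = np.zeros(m)
    wbsum = np.zeros(m)
    wfsum = np.zeros(m)
    neff = np.zeros(m)
    nst = np.zeros(m, dtype=np.int64)
    presence = np.zeros((s, m), dtype=bool)
    info_min = np.full(m, np.inf)

    for si, r in enumerate(results):
        idx = np.array([index[v] for v in r.ids], dtype=np.int64)
        flip = np.zeros(len(idx), dtype=bool)
        newly = ~have_allele[idx]
        ea[idx[newly]] = r.ea[newly]
        nea[idx[newly]] = r.nea[newly]
        pos[idx[newly]] = r.positions[newly]
        have_allele[idx[newly]] = True
        est = ~newly
        if est.any():
            same = (ea[idx[est]] == r.ea[est]) & (nea[idx[est]] == r.nea[est])
            swapped = (ea[idx[est]] == r.nea[est]) & (nea[idx[est]] == r.ea[est])
            bad = ~(same | swapped)
            if bad.any():
                vid = r.ids[est][np.argmax(bad)]
                raise DataError(f"allele mismatch between studies at variant "
                                f"{vid}")
            flip[est] = swapped
        use = r.include & (r.status == STATUS_OK) & np.isfinite(r.se) \
            & (r.se > 0)
        uidx = idx[use]
        w = 1.0 / (r.se[use] ** 2)
        b = np.where(flip[use], -r.beta[use], r.beta[use])
        f = np.where(flip[use], 1.0 - r.eaf[use], r.eaf[use])
        np.add.at(wsum, uidx, w)
        np.add.at(wbsum, uidx, w * b)
        np.add.at(wfsum, uidx, w * f)
        np.add.at(neff, uidx, r.n_eff[use])
        np.add.at(nst, uidx, 1)
        presence[si, uidx] = True
        np.minimum.at(info_min, uidx, r.info[use])

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(wsum > 0, wbsum / np.where(wsum > 0, wsum, 1), np.nan)
        se = np.where(wsum > 0, 1.0 / np.sqrt(np.where(wsum > 0, wsum, 1)),
                      np.nan)
        eaf = np.where(wsum > 0, wfsum / np.where(wsum > 0, wsum, 1), np.nan)
        z = beta / se
    info_min[~np.isfinite(info_min)] = np.nan
    return MetaResult(
        ids=np.array(union_ids, dtype=object), positions=pos, ea=ea, nea=nea,
        eaf=eaf, beta=beta, se=se, z=z, n_eff=neff, n_studies=nst,
        presence=presence, info_min=info_min,
    )


# ----------------------------------------------------------------------
# summary-statistics interchange format
# ----------------------------------------------------------------------

_REQUIRED_COLS = ["SNPID", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE",
                  "Z", "N_EFF", "N_STUDIES"]


def write_summary(meta: MetaResult, path: str, chrom: str = "1") -> None:
    """Tab-delimited summary statistics (the fine-mapping input format)."""
    df = pd.DataFrame({
        "SNPID": meta.ids.astype(str), "CHR": chrom,
        "POS": meta.positions + 1,  # 1-based in text output
        "EA": meta.ea.astype(str), "NEA": meta.nea.astype(str),
        "EAF": meta.eaf, "BETA": meta.beta, "SE": meta.se, "Z": meta.z,
        "N_EFF": meta.n_eff, "N_STUDIES": meta.n_studies,
        "INFO": meta.info_min,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_summary(path: str) -> pd.DataFrame:
    """Read and validate a tab-delimited summary-statistics file."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("SNPID", "POS", "EA", "NEA", "BETA", "SE")
               if c not in df.columns]
    if missing:
        raise DataError("summary file missing required column(s): "
                        + ", ".join(missing))
    if "Z" not in df.columns:
        df["Z"] = df["BETA"] / df["SE"]
    if "N_EFF" not in df.columns:
        df["N_EFF"] = np.nan
    return df
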
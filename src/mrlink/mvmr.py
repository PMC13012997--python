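"""Multivariable IVW: joint direct effects of several exposures.

Given k SNPs instrumenting p exposures (k > p), the direct-effect vector is
the no-intercept weighted least-squares solution

    theta = (B' W B)^{-1} B' W beta_y,   W = diag(1 / se_y^2)

where B is the k x p matrix of harmonized exposure effects.  SEs come from
(B'WB)^{-1} scaled multiplicatively by max(1, Q_mv/(k-p)); Q_mv is the
weighted residual sum of squares.  Instrument strength per exposure is
reported as the mean per-SNP F statistic (the simple, marginal statistic —
not the conditional Sanderson-Windmeijer F — and labelled as such).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import CollinearityError, InsufficientInstrumentsError
from .mr import HeterogeneityResult, Z95, q_pvalue
from .sumstats import SummaryStatRecord, harmonize, kept_pairs


@dataclass
class MVInstrumentSet:
    """Effects of k SNPs on p exposures and one outcome, on a shared allele."""

    snp_ids: list[str]
    bx: np.ndarray      # (k, p)
    sx: np.ndarray      # (k, p)
    by: np.ndarray      # (k,)
    sy: np.ndarray      # (k,)
    labels: list[str]

    def __post_init__(self):
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)

    @property
    def k(self) -> int:
        return self.bx.shape[0]

    @property
    def p(self) -> int:
        return self.bx.shape[1]


def build_mv_set(exposures: dict[str, list[SummaryStatRecord]],
                 outcome: list[SummaryStatRecord],
                 snp_ids: list[str] | None = None,
                 pooling: str = "intersection") -> MVInstrumentSet:
    """Assemble an MV set from per-exposure record lists.

    Every exposure and the outcome are harmonized to the first exposure's
    allele coding.  ``pooling='intersection'`` (default, conservative) keeps
    SNPs present in every exposure; ``'union'`` keeps SNPs present in any
    exposure, imputing absent exposure effects as 0 with the largest observed
    SE for that exposure.
    """
    labels = list(exposures)
    ref = exposures[labels[0]]
    per_exp: dict[str, dict[str, tuple]] = {}
    for lab in labels:
        if lab == labels[0]:
            per_exp[lab] = {r.snp_id: (r.beta, r.se) for r in ref}
        else:
            pairs = kept_pairs(harmonize(ref, exposures[lab]))
            per_exp[lab] = {p.snp_id: (p.beta_y, p.se_y) for p in pairs}
    out_pairs = {p.snp_id: (p.beta_y, p.se_y)
                 for p in kept_pairs(harmonize(ref, outcome))}
    if snp_ids is None:
        ids = [s for s in per_exp[labels[0]] if s in out_pairs]
        if pooling == "intersection":
            ids = [s for s in ids if all(s in per_exp[lab] for lab in labels)]
        elif pooling != "union":
            raise ValueError(f"unknown pooling {pooling!r}")
    else:
        ids = [s for s in snp_ids if s in out_pairs]
    bx = np.zeros((len(ids), len(labels)))
    sx = np.zeros_like(bx)
    for j, lab in enumerate(labels):
        fallback_se = max((v[1] for v in per_exp[lab].values()), default=1.0)
        for i, s in enumerate(ids):
            b, se = per_exp[lab].get(s, (0.0, fallback_se))
            bx[i, j], sx[i, j] = b, se
    by = np.array([out_pairs[s][0] for s in ids])
    sy = np.array([out_pairs[s][1] for s in ids])
    return MVInstrumentSet(ids, bx, sx, by, sy, labels)


def mv_ivw(mvset: MVInstrumentSet) -> tuple[pd.DataFrame, HeterogeneityResult]:
    """Multivariable IVW direct effects, one row per exposure, plus the
    multivariable Cochran Q (df = k - p)."""
    k, p = mvset.k, mvset.p
    if k <= p:
        raise InsufficientInstrumentsError(f"need k > p instruments (k={k}, p={p})")
    B, by, sy = mvset.bx, mvset.by, mvset.sy
    rank = np.linalg.matrix_rank(B)
    if rank < p:
        corr = np.corrcoef(B, rowvar=False)
        offenders = set()
        for i in range(p):
            for j in range(i + 1, p):
                if abs(corr[i, j]) > 1.0 - 1e-10:
                    offenders.update((mvset.labels[i], mvset.labels[j]))
        if not offenders:
            offenders = set(mvset.labels)
        raise CollinearityError(
            f"exposure effect matrix rank deficient; check: {sorted(offenders)}",
            exposures=sorted(offenders))
    w = 1.0 / sy ** 2
    BtWB = B.T @ (w[:, None] * B)
    coef = np.linalg.solve(BtWB, B.T @ (w * by))
    resid = by - B @ coef
    q = float(np.sum(w * resid ** 2))
    phi = max(1.0, q / (k - p))
    cov = np.linalg.inv(BtWB) * phi
    ses = np.sqrt(np.diag(cov))
    rows = []
    for j, lab in enumerate(mvset.labels):
        b, s = float(coef[j]), float(ses[j])
        pv = float(2.0 * sps.norm.sf(abs(b) / s)) if s > 0 else 1.0
        rows.append({"exposure": lab, "nsnp": k, "beta": b, "se": s, "pval": pv,
                     "ci_low": b - Z95 * s, "ci_high": b + Z95 * s})
    het = HeterogeneityResult(q, k - p, q_pvalue(q, k - p))
    return pd.DataFrame(rows), het


def mv_instrument_strength(mvset: MVInstrumentSet,
                           f_min: float = 10.0) -> pd.DataFrame:
    """Mean marginal per-SNP F per exposure (labelled ``mean_f``); exposures
    at or below ``f_min`` are flagged weak."""
    f = (mvset.bx / mvset.sx) ** 2
    mean_f = f.mean(axis=0)
    return pd.DataFrame({
        "exposure": mvset.labels,
        "mean_f": mean_f,
        "weak": mean_f <= f_min,
        "statistic": ["mean_marginal_f"] * mvset.p,
    })
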
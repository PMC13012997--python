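"""Univariable two-sample MR estimators and sensitivity analyses.

All estimators consume an :class:`~mrlink.sumstats.InstrumentSet` of
harmonized pairs (per-SNP exposure effect ``beta_x`` with SE ``se_x`` and
outcome effect ``beta_y`` with SE ``se_y``) and return an
:class:`MREstimate`.  The inverse-variance weighted (IVW) estimator is the
primary method:

    theta_hat = sum(beta_x * beta_y / se_y^2) / sum(beta_x^2 / se_y^2)

which is the no-intercept weighted regression of outcome on exposure effects
with first-order weights.  MR-Egger adds an intercept (directional
pleiotropy), dIVW debiases the denominator for exposure sampling error, and
RAPS maximizes a profile likelihood accounting for error in both effects.
Cochran's Q, leave-one-out, and the Steiger directionality test are the
standard sensitivity companions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .exceptions import (DomainError, EstimationError,
                         InsufficientInstrumentsError, WeakInstrumentError)
from .sumstats import InstrumentSet

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pval: float
    ci_low: float
    ci_high: float
    k: int
    phi: float = 1.0  # overdispersion / heterogeneity scale applied to the SE


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    pval: float


def _normal_estimate(method: str, beta: float, se: float, k: int,
                     phi: float = 1.0) -> MREstimate:
    if se > 0:
        pval = float(2.0 * sps.norm.sf(abs(beta) / se))
    else:
        pval = 1.0 if beta == 0 else 0.0
    return MREstimate(method, float(beta), float(se), pval,
                      float(beta - Z95 * se), float(beta + Z95 * se), k, phi)


def _arrays(instruments):
    if isinstance(instruments, InstrumentSet):
        return instruments.arrays()
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in instruments)
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def wald_ratio(pair, se_order: str = "first") -> MREstimate:
    """Single-SNP causal estimate beta_y / beta_x.

    ``se_order='first'`` gives |se_y/beta_x|; ``'second'`` adds the exposure
    sampling term beta_y^2 se_x^2 / beta_x^4 under the square root.
    """
    bx, sx, by, sy = pair.beta_x, pair.se_x, pair.beta_y, pair.se_y
    if bx == 0:
        raise DomainError("wald_ratio undefined for beta_x = 0")
    beta = by / bx
    var = (sy / bx) ** 2
    if se_order == "second":
        var += by ** 2 * sx ** 2 / bx ** 4
    elif se_order != "first":
        raise DomainError(f"unknown se_order {se_order!r}")
    return _normal_estimate("wald", beta, np.sqrt(var), 1)


def ivw(instruments, mode: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate with first-order weights.

    ``mode='fixed'`` uses se = (sum beta_x^2/se_y^2)^{-1/2}; ``'random'``
    inflates it by sqrt(max(1, Q/(k-1))) (multiplicative random effects).
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 2:
        raise InsufficientInstrumentsError(
            "IVW requires >= 2 instruments; use wald_ratio for a single SNP")
    w = 1.0 / sy ** 2
    denom = np.sum(bx ** 2 * w)
    beta = np.sum(bx * by * w) / denom
    se = denom ** -0.5
    phi = 1.0
    if mode == "random":
        q = _cochran_q_value(bx, by, sy, beta)
        phi = max(1.0, q / (k - 1))
        se *= np.sqrt(phi)
    elif mode != "fixed":
        raise DomainError(f"unknown IVW mode {mode!r}")
    return _normal_estimate(f"ivw_{'re' if mode == 'random' else 'fe'}",
                            beta, se, k, phi)


def egger(instruments) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    Exposure effects are oriented positive (pair signs flipped) before the
    fit.  SEs are scaled by sqrt(max(1, RSS_w/(k-2))) and inference uses the
    t distribution with k-2 df.  Returns (slope, intercept) estimates.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(k), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    phi = max(1.0, rss_w / (k - 2))
    cov = np.linalg.inv(XtWX) * phi
    ses = np.sqrt(np.diag(cov))
    tq = sps.t.ppf(0.975, k - 2)
    out = []
    for name, b, s in (("egger_slope", coef[1], ses[1]),
                       ("egger_intercept", coef[0], ses[0])):
        p = float(2.0 * sps.t.sf(abs(b) / s, k - 2)) if s > 0 else (1.0 if b == 0 else 0.0)
        out.append(MREstimate(name, float(b), float(s), p,
                              float(b - tq * s), float(b + tq * s), k, phi))
    return out[0], out[1]


def divw(instruments, n_boot: int = 2000, seed: int = 0) -> MREstimate:
    """Debiased IVW: subtracts exposure sampling variance from the IVW
    denominator, correcting weak-instrument attenuation.

    The SE comes from a seeded nonparametric bootstrap over instruments
    (resamples with a nonpositive debiased denominator are discarded).
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 2:
        raise InsufficientInstrumentsError("dIVW requires >= 2 instruments")
    w = 1.0 / sy ** 2
    num_terms = bx * by * w
    den_terms = (bx ** 2 - sx ** 2) * w
    den = float(np.sum(den_terms))
    if den <= 0:
        raise WeakInstrumentError("nonpositive debiased denominator")
    beta = float(np.sum(num_terms)) / den
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, k, size=(n_boot, k))
    boot_num = num_terms[idx].sum(axis=1)
    boot_den = den_terms[idx].sum(axis=1)
    valid = boot_den > 0
    if valid.sum() < max(10, n_boot // 10):
        raise WeakInstrumentError("bootstrap denominators predominantly nonpositive")
    # k/(k-1) corrects the plug-in downward bias of the bootstrap variance
    se = float(np.std(boot_num[valid] / boot_den[valid], ddof=1)
               * np.sqrt(k / (k - 1)))
    return _normal_estimate("divw", beta, se, k)


def _raps_objective(theta, bx, sx, by, sy, tau2=0.0):
    v = sy ** 2 + theta ** 2 * sx ** 2 + tau2
    return -0.5 * np.sum((by - theta * bx) ** 2 / v)


def raps(instruments, overdispersion: bool = False) -> MREstimate:
    """Robust adjusted profile score estimator (plain profile likelihood).

    The base variant maximizes -0.5 * sum((by - theta*bx)^2/(sy^2 +
    theta^2*sx^2)) in theta; the overdispersion variant profiles an additive
    variance tau^2 >= 0 jointly using the full Gaussian log-likelihood (the
    normalization term is required for tau^2 to be identified).  The SE comes
    from the numerical curvature at the optimum.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("RAPS requires >= 3 instruments")
    start = ivw((bx, sx, by, sy), mode="fixed")
    span = max(1.0, 30.0 * start.se)
    lo, hi = start.beta - span, start.beta + span

    if not overdispersion:
        res = optimize.minimize_scalar(
            lambda t: -_raps_objective(t, bx, sx, by, sy),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        if not res.success:
            raise EstimationError(f"RAPS optimizer failed: {res.message}")
        theta = float(res.x)
        h = 1e-5 * (1.0 + abs(theta))
        curv = (_raps_objective(theta + h, bx, sx, by, sy)
                - 2.0 * _raps_objective(theta, bx, sx, by, sy)
                + _raps_objective(theta - h, bx, sx, by, sy)) / h ** 2
        if curv >= 0:
            raise EstimationError("RAPS curvature nonnegative at optimum")
        return _normal_estimate("raps", theta, (-curv) ** -0.5, k)

    def negll(params):
        theta, s = params
        v = sy ** 2 + theta ** 2 * sx ** 2 + s ** 2
        return 0.5 * np.sum(np.log(v) + (by - theta * bx) ** 2 / v)

    res = optimize.minimize(negll, x0=[start.beta, 0.01], method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000})
    if not res.success:
        raise EstimationError(f"RAPS optimizer failed: {res.message}")
    theta, s = res.x
    tau2 = s ** 2
    h = 1e-5 * (1.0 + abs(theta))
    ll = lambda t: _raps_objective(t, bx, sx, by, sy, tau2) \
        - 0.5 * np.sum(np.log(sy ** 2 + t ** 2 * sx ** 2 + tau2))
    curv = (ll(theta + h) - 2.0 * ll(theta) + ll(theta - h)) / h ** 2
    if curv >= 0:
        raise EstimationError("RAPS curvature nonnegative at optimum")
    est = _normal_estimate("raps", theta, (-curv) ** -0.5, k)
    est.phi = 1.0 + tau2
    return est


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def _cochran_q_value(bx, by, sy, beta_hat):
    ratios = by / bx
    w = bx ** 2 / sy ** 2
    return float(np.sum(w * (ratios - beta_hat) ** 2))


def q_pvalue(Q: float, df: int) -> float:
    """Upper-tail chi-square p for a heterogeneity statistic."""
    return float(sps.chi2.sf(Q, df))


def cochran_q(instruments, beta_hat: float | None = None) -> HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios with first-order weights
    w_j = beta_x_j^2 / se_y_j^2; df = k-1.  ``beta_hat`` defaults to the
    fixed-effects IVW estimate."""
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    if beta_hat is None:
        beta_hat = ivw((bx, sx, by, sy), mode="fixed").beta
    q = _cochran_q_value(bx, by, sy, beta_hat)
    return HeterogeneityResult(q, k - 1, q_pvalue(q, k - 1))


def leave_one_out(instruments) -> "pd.DataFrame":
    """Random-effects IVW re-estimated excluding each SNP in turn.

    Flags SNPs whose removal flips the sign of the estimate or its
    significance at 0.05 relative to the full-set estimate.
    """
    import pandas as pd

    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    snp_ids = instruments.snp_ids if isinstance(instruments, InstrumentSet) \
        else [f"snp{i}" for i in range(k)]
    full = ivw((bx, sx, by, sy))
    rows = []
    mask = np.ones(k, dtype=bool)
    for i in range(k):
        mask[i] = False
        est = ivw((bx[mask], sx[mask], by[mask], sy[mask]))
        mask[i] = True
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or \
            ((est.pval < 0.05) != (full.pval < 0.05))
        rows.append({"snp_id": snp_ids[i], "beta": est.beta, "se": est.se,
                     "pval": est.pval, "flagged": bool(flagged)})
    return pd.DataFrame(rows)


def steiger(instruments, n_x: float, n_y: float) -> SteigerResult:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-trait variance explained is summed over instruments as
    r² = sum_j F_j / (F_j + n - 2) using that trait's effects and SEs.  The
    one-sided p compares Fisher-transformed correlations:
    Z = (atanh r_x - atanh r_y) / sqrt(1/(n_x-3) + 1/(n_y-3)).
    """
    if n_x <= 3 or n_y <= 3:
        raise DomainError("sample sizes must exceed 3")
    bx, sx, by, sy = _arrays(instruments)

    def r2_sum(b, s, n):
        f = (b / s) ** 2
        r2 = float(np.sum(f / (f + n - 2.0)))
        if r2 >= 1.0:
            import warnings
            warnings.warn("summed r2 >= 1; capped", stacklevel=3)
            r2 = 1.0 - 1e-12
        return r2

    r2x = r2_sum(bx, sx, n_x)
    r2y = r2_sum(by, sy, n_y)
    z = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / \
        np.sqrt(1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0))
    return SteigerResult(r2x, r2y, r2x > r2y, float(sps.norm.sf(z)))


def steiger_filter(pairs, n_x: float, n_y: float, alpha: float = 0.05):
    """Per-SNP Steiger screen: keep instruments that explain significantly
    more variance in the exposure than the outcome (one-sided p < alpha);
    SNPs failing the test are removed from the instrument set."""
    if n_x <= 3 or n_y <= 3:
        raise DomainError("sample sizes must exceed 3")
    denom = np.sqrt(1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0))
    kept = []
    for p in pairs:
        fx = (p.beta_x / p.se_x) ** 2
        fy = (p.beta_y / p.se_y) ** 2
        r2x = fx / (fx + n_x - 2.0)
        r2y = fy / (fy + n_y - 2.0)
        z = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / denom
        if sps.norm.sf(z) < alpha:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Odds-ratio arithmetic
# ---------------------------------------------------------------------------

def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% CI low, 95% CI high) from a log-odds effect and its SE."""
    if se < 0:
        raise DomainError("se must be nonnegative")
    return (float(np.exp(beta)), float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


def or_from_ci(ci_low: float, ci_high: float) -> float:
    """Reconstruct a point OR as the geometric mean of its CI bounds."""
    if ci_low <= 0 or ci_high <= 0:
        raise DomainError("CI bounds must be positive")
    return float(np.sqrt(ci_low * ci_high))


def percent_excess_risk(odds_ratio: float) -> float:
    """OR expressed as percentage excess risk, 100*(OR - 1)."""
    return 100.0 * (odds_ratio - 1.0)
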
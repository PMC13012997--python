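"""Two-step mediation MR and phenome-wide MR screening.

The two-step framework estimates, with independent instrument sets,

    a : exposure -> mediator      b : mediator -> outcome
    c : exposure -> outcome (total effect)

and decomposes c into the indirect (mediated) path a·b and the direct
remainder c - a·b (difference method, so indirect + direct = total by
construction).  The Sobel normal approximation gives the indirect SE
sqrt(a²·se_b² + b²·se_a²); the proportion mediated a·b/c is reported as-is
(it may exceed 1 or be negative) with a delta-method CI assuming zero
covariance between the total and indirect estimates.

The PheWAS screen applies Wald/IVW MR of one exposure (here a circulating
protein instrumented by cis variants) against a panel of outcomes with
Benjamini-Hochberg FDR control across the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, PipelineError
from .mr import Z95, ivw, to_odds_ratio, wald_ratio
from .mvmr import build_mv_set, mv_ivw
from .sumstats import (InstrumentSet, LDMatrix, SummaryStatRecord, clump,
                       harmonize, kept_pairs, select_instruments)


@dataclass
class MediationResult:
    a: float
    se_a: float
    b: float
    se_b: float
    total: float
    se_total: float
    indirect: float
    se_indirect: float
    direct: float
    se_direct: float
    proportion: float            # NaN when total == 0
    se_proportion: float
    sobel_p: float

    def ci(self, which: str) -> tuple[float, float]:
        est = getattr(self, which)
        se = getattr(self, f"se_{which}")
        return est - Z95 * se, est + Z95 * se

    def odds_ratio(self, which: str) -> tuple[float, float, float]:
        return to_odds_ratio(getattr(self, which), getattr(self, f"se_{which}"))

    def to_dict(self) -> dict:
        out = {}
        for which in ("total", "indirect", "direct"):
            lo, hi = self.ci(which)
            orr, orl, oru = self.odds_ratio(which)
            out[which] = {"beta": getattr(self, which),
                          "se": getattr(self, f"se_{which}"),
                          "ci": [lo, hi], "or": orr, "or_ci": [orl, oru]}
        lo, hi = self.ci("proportion")
        out["proportion_mediated"] = {"estimate": self.proportion,
                                      "ci": [lo, hi],
                                      "ci_method": "delta, zero covariance"}
        out["sobel_p"] = self.sobel_p
        return out


def mediate(a: float, se_a: float, b: float, se_b: float,
            total_c: float, se_c: float) -> MediationResult:
    """Product-of-coefficients decomposition with Sobel inference.

    The direct-effect SE assumes independence of the total and indirect
    estimates (covariance 0) — an approximation, flagged as such."""
    for se in (se_a, se_b, se_c):
        if se <= 0:
            raise DomainError("standard errors must be positive")
    indirect = a * b
    se_ind = float(np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2))
    if se_ind > 0:
        sobel_p = float(2.0 * sps.norm.sf(abs(indirect) / se_ind))
    else:
        sobel_p = 1.0
    direct = total_c - indirect
    se_dir = float(np.sqrt(se_c ** 2 + se_ind ** 2))
    if total_c == 0:
        prop, se_prop = float("nan"), float("nan")
    else:
        prop = indirect / total_c
        # numpy arithmetic: near-zero totals overflow to inf, not an error
        with np.errstate(over="ignore"):
            t = np.float64(total_c)
            se_prop = float(np.hypot(np.float64(se_ind) / t,
                                     np.float64(prop) * se_c / t))
    return MediationResult(a, se_a, b, se_b, total_c, se_c, indirect, se_ind,
                           direct, se_dir, prop, se_prop, sobel_p)


def proportion_mediated(indirect: float, total: float) -> float:
    """Share of the total effect carried by the indirect path (unbounded)."""
    if total == 0:
        return float("nan")
    return indirect / total


def two_step_pipeline(exposure: list[SummaryStatRecord],
                      mediator: list[SummaryStatRecord],
                      outcome: list[SummaryStatRecord],
                      ld: LDMatrix | None = None, p_threshold: float = 5e-8,
                      r2_threshold: float = 0.001, window_kb: float = 10_000,
                      conditioned_b: bool = False
                      ) -> tuple[MediationResult, dict]:
    """Run the three MR steps from summary statistics and decompose.

    a and the total effect use the exposure's genome-wide significant
    instruments; b uses the mediator's.  ``conditioned_b=True`` instead takes
    the mediator's direct effect from a multivariable IVW of (mediator,
    exposure) on the outcome.  Returns (result, provenance) where provenance
    records instrument counts and SNP ids per step.
    """
    if {r.snp_id for r in exposure} == {r.snp_id for r in mediator} and \
            all(abs(e.beta - m.beta) < 1e-12 for e, m in
                zip(sorted(exposure, key=lambda r: r.snp_id),
                    sorted(mediator, key=lambda r: r.snp_id))):
        warnings.warn("mediator summary statistics are identical to the "
                      "exposure's; degenerate instruments", stacklevel=2)
    steps = {}
    provenance = {}

    def step(name, exp, out):
        iset = select_instruments(exp, out, ld, p_threshold, r2_threshold,
                                  window_kb)
        if len(iset) == 0:
            raise PipelineError(f"zero instruments in step {name!r}", stage=name)
        est = ivw(iset) if len(iset) > 1 else wald_ratio(iset.pairs[0])
        provenance[name] = {"nsnp": len(iset), "snps": iset.snp_ids,
                            "mean_f": iset.mean_f}
        return est

    est_a = step("exposure->mediator", exposure, mediator)
    est_c = step("exposure->outcome", exposure, outcome)
    if conditioned_b:
        mvset = build_mv_set({"mediator": mediator, "exposure": exposure},
                             outcome)
        table, _ = mv_ivw(mvset)
        row = table.set_index("exposure").loc["mediator"]
        b, se_b = float(row["beta"]), float(row["se"])
        provenance["mediator->outcome"] = {"nsnp": mvset.k,
                                           "snps": mvset.snp_ids,
                                           "conditioned": True}
    else:
        est_b = step("mediator->outcome", mediator, outcome)
        b, se_b = est_b.beta, est_b.se
    result = mediate(est_a.beta, est_a.se, b, se_b, est_c.beta, est_c.se)
    return result, provenance


# ---------------------------------------------------------------------------
# FDR control and PheWAS
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, q_(i) = min_{j>=i} p_(j)·m/j,
    returned in input order.  Empty input gives an empty array."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def phewas_screen(protein_instruments: list[SummaryStatRecord],
                  outcomes: dict[str, list[SummaryStatRecord]],
                  ld: LDMatrix | None = None, clump_r2: float = 0.1,
                  clump_kb: float = 10_000, p_threshold: float = 5e-8,
                  fdr: float = 0.05) -> pd.DataFrame:
    """Phenome-wide MR of one protein across an outcome panel.

    Instruments are clumped at the screen's looser independence threshold
    (r²=0.1, 10,000 kb).  Outcomes without overlapping SNPs get a missing
    estimate and are excluded from the FDR denominator.  Rows are sorted by
    -log10 p (Manhattan order).
    """
    iset = clump(protein_instruments, ld, p_threshold, clump_r2, clump_kb)
    instruments = iset.pairs
    rows = []
    for label, records in outcomes.items():
        pairs = kept_pairs(harmonize(instruments, records))
        if not pairs:
            rows.append({"outcome": label, "method": None, "nsnp": 0,
                         "beta": np.nan, "se": np.nan, "pval": np.nan})
            continue
        sub = InstrumentSet(pairs, p_threshold, clump_r2, clump_kb)
        est = ivw(sub) if len(pairs) > 1 else wald_ratio(pairs[0])
        rows.append({"outcome": label, "method": est.method,
                     "nsnp": len(pairs), "beta": est.beta, "se": est.se,
                     "pval": est.pval})
    df = pd.DataFrame(rows)
    estimable = df["pval"].notna()
    df["q_value"] = np.nan
    df.loc[estimable, "q_value"] = bh_fdr(df.loc[estimable, "pval"].to_numpy())
    df["significant"] = df["q_value"] < fdr
    df = df.sort_values("pval", na_position="last").reset_index(drop=True)
    return df
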
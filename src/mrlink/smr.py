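"""Summary-data-based MR (SMR) with HEIDI heterogeneity filtering.

SMR tests whether a molecular QTL's top variant carries a consistent effect
through to the outcome GWAS: the effect of expression/protein on outcome is
the Wald ratio b_xy = b_gwas/b_qtl at the top cis-QTL SNP, with test
statistic

    T_smr = z_qtl² z_gwas² / (z_qtl² + z_gwas²)  ~  chi²(1) under the null.

HEIDI (heterogeneity in dependent instruments) asks whether nearby SNPs in
LD with the top SNP imply the *same* b_xy — a single shared causal variant —
or different ones, which indicates linkage of distinct causal variants.
Differences d_i = b_xy(i) - b_xy(top) get a delta-method covariance using
the LD correlations, and the sum of squared standardized differences is
referred to a seeded Monte-Carlo null of correlated squared normals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, InputError, WeakInstrumentError
from .mediation import bh_fdr
from .sumstats import LDMatrix

HEIDI_PASS_P = 0.05


@dataclass
class CisRegion:
    """Per-SNP QTL and outcome-GWAS effects over one cis region, plus LD."""

    probe_id: str
    snp_ids: list[str]
    b_qtl: np.ndarray
    se_qtl: np.ndarray
    b_gwas: np.ndarray
    se_gwas: np.ndarray
    ld: LDMatrix | np.ndarray

    def __post_init__(self):
        self.b_qtl = np.asarray(self.b_qtl, dtype=float)
        self.se_qtl = np.asarray(self.se_qtl, dtype=float)
        self.b_gwas = np.asarray(self.b_gwas, dtype=float)
        self.se_gwas = np.asarray(self.se_gwas, dtype=float)
        m = len(self.snp_ids)
        for a in (self.b_qtl, self.se_qtl, self.b_gwas, self.se_gwas):
            if a.shape != (m,):
                raise InputError("arrays must match the SNP list")
        r = self.ld.r if isinstance(self.ld, LDMatrix) else np.asarray(self.ld)
        if r.shape != (m, m):
            raise InputError("LD matrix must cover all region SNPs")
        self._r = r

    @property
    def top_index(self) -> int:
        return int(np.argmax((self.b_qtl / self.se_qtl) ** 2))


@dataclass
class SMRResult:
    probe_id: str
    top_snp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float          # NaN when not evaluable
    n_heidi_snps: int
    q_value: float = float("nan")
    passes: bool = False
    heidi_reason: str | None = None


def smr_test(region: CisRegion) -> tuple[float, float, float]:
    """(b_xy, se_xy, p_smr) at the region's top QTL SNP.

    Requires top-SNP QTL F >= 10 (weak-instrument guard)."""
    t = region.top_index
    bq, sq = region.b_qtl[t], region.se_qtl[t]
    bg, sg = region.b_gwas[t], region.se_gwas[t]
    if bq == 0:
        raise DomainError("top-SNP QTL effect is zero")
    zq2 = (bq / sq) ** 2
    if zq2 < 10.0:
        raise WeakInstrumentError(f"top-SNP QTL F={zq2:.2f} < 10")
    zg2 = (bg / sg) ** 2
    b_xy = bg / bq
    t_smr = zq2 * zg2 / (zq2 + zg2)
    p_smr = float(sps.chi2.sf(t_smr, 1))
    se_xy = abs(b_xy) / np.sqrt(t_smr) if t_smr > 0 else float("inf")
    return float(b_xy), float(se_xy), p_smr


def heidi_test(region: CisRegion, include_p_qtl_max: float = 1.57e-3,
               r2_top_max: float = 0.9, r2_top_min: float = 0.05,
               max_snps: int = 20, mc_draws: int = 10_000,
               seed: int = 0) -> tuple[float, int, str | None]:
    """(p_heidi, n_used, reason).  ``p_heidi`` is NaN with a reason when
    fewer than 3 eligible non-top SNPs survive the filters.

    Eligibility mirrors the conventional settings of the method: QTL
    chi² > 10 (p below ~1.57e-3), r² with the top SNP in
    [r2_top_min, r2_top_max], capped at the ``max_snps`` most significant.
    """
    t = region.top_index
    r = region._r
    z_qtl2 = (region.b_qtl / region.se_qtl) ** 2
    p_qtl = sps.chi2.sf(z_qtl2, 1)
    r2_top = r[:, t] ** 2
    eligible = np.flatnonzero(
        (np.arange(len(region.snp_ids)) != t)
        & (p_qtl < include_p_qtl_max)
        & (r2_top >= r2_top_min) & (r2_top <= r2_top_max))
    if len(eligible) > max_snps:
        eligible = eligible[np.argsort(p_qtl[eligible])[:max_snps]]
    m = len(eligible)
    if m < 3:
        return float("nan"), m, "insufficient SNPs"

    idx = np.concatenate(([t], eligible))
    bq, sq = region.b_qtl[idx], region.se_qtl[idx]
    bg, sg = region.b_gwas[idx], region.se_gwas[idx]
    rr = r[np.ix_(idx, idx)]
    b_xy = bg / bq
    # delta-method covariance of the per-SNP ratios (QTL and GWAS samples
    # independent; effect covariances approx r_ij * se_i * se_j per study)
    cov_ratio = (rr * np.outer(sg, sg)) / np.outer(bq, bq) \
        + (rr * np.outer(sq, sq)) * np.outer(bg / bq ** 2, bg / bq ** 2)
    # d_i = b_xy(i) - b_xy(top): contrast against row/col 0
    cov_d = cov_ratio[1:, 1:] - cov_ratio[1:, :1] - cov_ratio[:1, 1:] \
        + cov_ratio[0, 0]
    d = b_xy[1:] - b_xy[0]
    sd = np.sqrt(np.diag(cov_d))
    t_obs = float(np.sum((d / sd) ** 2))
    corr = cov_d / np.outer(sd, sd)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-8:
        warnings.warn("singular HEIDI correlation matrix; ridge applied",
                      stacklevel=2)
        corr = corr + 1e-6 * np.eye(m)
        eigvals = np.linalg.eigvalsh(corr)
    eigvals = np.clip(eigvals, 0.0, None)
    rng = np.random.default_rng(seed)
    null = rng.chisquare(1, size=(mc_draws, m)) @ eigvals
    p = float((1 + np.sum(null >= t_obs)) / (1 + mc_draws))
    return p, m, None


def smr_screen(regions: list[CisRegion], fdr: float = 0.05, heidi: bool = True,
               mc_draws: int = 10_000, seed: int = 0,
               heidi_kwargs: dict | None = None) -> pd.DataFrame:
    """SMR + HEIDI over many probes with BH FDR control across probes.

    ``passes`` requires both p_heidi > 0.05 and q < ``fdr``; probes without
    an evaluable HEIDI p never pass and carry the reason.
    """
    if not regions:
        raise InputError("need at least one region")
    heidi_kwargs = dict(heidi_kwargs or {})
    rows = []
    for i, region in enumerate(regions):
        b_xy, se_xy, p_smr = smr_test(region)
        if heidi:
            p_h, n_h, reason = heidi_test(region, mc_draws=mc_draws,
                                          seed=seed + i, **heidi_kwargs)
        else:
            p_h, n_h, reason = float("nan"), 0, "not requested"
        rows.append({"probe": region.probe_id,
                     "top_snp": region.snp_ids[region.top_index],
                     "b_xy": b_xy, "se_xy": se_xy, "p_smr": p_smr,
                     "p_heidi": p_h, "nsnp_heidi": n_h,
                     "heidi_reason": reason})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_smr"].to_numpy())
    df["passes"] = (df["p_heidi"] > HEIDI_PASS_P) & (df["q_value"] < fdr)
    return df


def join_discovery_replication(discovery: pd.DataFrame,
                               replication: pd.DataFrame) -> pd.DataFrame:
    """Join two screen tables on probe id with a sign-concordance column."""
    merged = discovery.merge(replication, on="probe",
                             suffixes=("_disc", "_repl"))
    merged["concordant"] = np.sign(merged["b_xy_disc"]) == \
        np.sign(merged["b_xy_repl"])
    return merged
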
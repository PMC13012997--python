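"""Seeded generators for every input the analysis chain consumes.

All generators are pure functions of (config, seed) and produce data with
the statistical structure the estimators assume:

* two-sample GWAS pairs obey the instrumental-variable generating model
  beta_x_j = gamma_j + e_xj, beta_y_j = theta*gamma_j + alpha_j + e_yj with
  e ~ N(0, se²) and se = 1/sqrt(2·n·eaf·(1-eaf)) (continuous-trait
  convention; binary log-odds effects are emulated by supplying the same
  SE form);
* regional z-vectors are multivariate normal with mean R·lambda and
  covariance R under an AR(1) LD model, with causal indices placed per the
  five colocalization hypotheses;
* LDSC z-pairs are bivariate normal per SNP with the variances and
  covariance the LD score regression model implies;
* the mediation chain wires three traits so that the exposure's instruments
  carry slope a onto the mediator, the mediator's instruments carry slope b
  onto the outcome, and the exposure->outcome total equals direct + a·b by
  construction.

Simulated variants are deliberately non-palindromic, common (MAF >= 0.05)
and spaced beyond the clumping window, so default QC retains them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coloc import RegionPair
from .exceptions import ConfigurationError
from .ldsc import LdscInput
from .smr import CisRegion
from .sumstats import LDMatrix, SummaryStatRecord

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_CHROM_SPACING_BP = 50_000_000  # beyond any default clumping window


def analytic_se(n, eaf):
    """Standard error of a per-allele effect on a standardized continuous
    trait: se = 1/sqrt(2·n·eaf·(1-eaf))."""
    return 1.0 / np.sqrt(2.0 * np.asarray(n, dtype=float)
                         * np.asarray(eaf) * (1.0 - np.asarray(eaf)))


def _records(snp_ids, chroms, poss, eas, oas, eafs, betas, ses, ns):
    zs = betas / ses
    pvals = 2.0 * sps.norm.sf(np.abs(zs))
    pvals = np.clip(pvals, 5e-324, 1.0)
    return [SummaryStatRecord(snp_ids[j], chroms[j], int(poss[j]), eas[j],
                              oas[j], float(eafs[j]), float(betas[j]),
                              float(ses[j]), float(pvals[j]), float(ns[j]))
            for j in range(len(snp_ids))]


def _layout(k, rng, eaf_low, eaf_high, prefix="rs"):
    snp_ids = [f"{prefix}{j + 1}" for j in range(k)]
    chroms = [str(1 + j % 22) for j in range(k)]
    poss = [1_000_000 + (j // 22 + 1) * _CHROM_SPACING_BP for j in range(k)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(k)]
    eas = [a for a, _ in alleles]
    oas = [b for _, b in alleles]
    eafs = rng.uniform(eaf_low, eaf_high, size=k)
    return snp_ids, chroms, np.array(poss), eas, oas, eafs


# ---------------------------------------------------------------------------
# Two-sample GWAS pair
# ---------------------------------------------------------------------------

@dataclass
class Pleiotropy:
    kind: str = "none"          # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    def draw(self, rng, gamma):
        """Pleiotropic outcome effects, expressed relative to the
        exposure-increasing allele (the orientation MR-Egger fits under),
        so a directional mean is identifiable as the Egger intercept."""
        k = len(gamma)
        if self.kind == "none":
            return np.zeros(k)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sd, size=k)
        if self.kind == "directional":
            return np.sign(gamma) * rng.normal(self.mean, self.sd, size=k)
        raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")


@dataclass
class TwoSampleSimConfig:
    k: int = 50
    gamma_sd: float = 0.05
    theta: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    n_x: float = 100_000
    n_y: float = 100_000
    eaf_low: float = 0.1
    eaf_high: float = 0.9
    seed: int = 0


def simulate_two_sample(config: TwoSampleSimConfig
                        ) -> tuple[list[SummaryStatRecord],
                                   list[SummaryStatRecord]]:
    """Exposure and outcome summary statistics over ``k`` independent
    instruments under a true causal effect ``theta``."""
    rng = np.random.default_rng(config.seed)
    k = config.k
    snp_ids, chroms, poss, eas, oas, eafs = _layout(
        k, rng, config.eaf_low, config.eaf_high)
    gamma = rng.normal(0.0, config.gamma_sd, size=k)
    se_x = analytic_se(config.n_x, eafs)
    se_y = analytic_se(config.n_y, eafs)
    alpha = config.pleiotropy.draw(rng, gamma)
    beta_x = gamma + rng.normal(0.0, se_x)
    beta_y = config.theta * gamma + alpha + rng.normal(0.0, se_y)
    exp_recs = _records(snp_ids, chroms, poss, eas, oas, eafs, beta_x, se_x,
                        np.full(k, config.n_x))
    out_recs = _records(snp_ids, chroms, poss, eas, oas, eafs, beta_y, se_y,
                        np.full(k, config.n_y))
    return exp_recs, out_recs


# ---------------------------------------------------------------------------
# Regional z-vectors (colocalization / SMR scenarios)
# ---------------------------------------------------------------------------

def ar1_ld(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class RegionSimConfig:
    m: int = 100
    rho: float = 0.9
    scenario: str = "H4"        # H0 | H1 | H2 | H3 | H4
    z_causal: float = 8.0
    z_causal2: float | None = None   # trait-2 causal z (defaults to z_causal)
    n1: float = 10_000
    n2: float = 10_000
    seed: int = 0


def _causal_indices(scenario: str, m: int) -> tuple[list[int], list[int]]:
    mid, q1, q3 = m // 2, m // 4, (3 * m) // 4
    return {
        "H0": ([], []),
        "H1": ([mid], []),
        "H2": ([], [mid]),
        "H3": ([q1], [q3]),
        "H4": ([mid], [mid]),
    }[scenario]


def simulate_region_pair(config: RegionSimConfig
                         ) -> tuple[RegionPair, LDMatrix]:
    """Draw z ~ MVN(R·lambda, R) for two traits over an AR(1) LD region,
    with causal indices placed per the H0-H4 scenario; betas are z·se with
    se = 1/sqrt(n)."""
    rng = np.random.default_rng(config.seed)
    m = config.m
    R = ar1_ld(m, config.rho)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        import warnings
        warnings.warn("non-positive-definite LD matrix; ridge applied",
                      stacklevel=2)
        L = np.linalg.cholesky(R + 1e-8 * np.eye(m))
    idx1, idx2 = _causal_indices(config.scenario, m)
    z2c = config.z_causal if config.z_causal2 is None else config.z_causal2
    lam1, lam2 = np.zeros(m), np.zeros(m)
    lam1[idx1] = config.z_causal
    lam2[idx2] = z2c
    z1 = R @ lam1 + L @ rng.standard_normal(m)
    z2 = R @ lam2 + L @ rng.standard_normal(m)
    se1 = np.full(m, 1.0 / np.sqrt(config.n1))
    se2 = np.full(m, 1.0 / np.sqrt(config.n2))
    snp_ids = [f"rs{j + 1}" for j in range(m)]
    region = RegionPair(snp_ids, z1 * se1, se1, z2 * se2, se2,
                        label=config.scenario)
    return region, LDMatrix(snp_ids, R)


def simulate_cis_region(m: int = 100, rho: float = 0.9,
                        mode: str = "shared", z_qtl: float = 10.0,
                        b_xy: float = 0.25, linkage_gap: int = 3,
                        probe_id: str = "probe", n: float = 10_000,
                        seed: int = 0) -> CisRegion:
    """A cis-QTL region paired with an outcome GWAS.

    ``mode='shared'``: one causal variant drives both the QTL (top z ~
    ``z_qtl``) and the GWAS (through effect ``b_xy``) — the SMR/HEIDI null.
    ``mode='linkage'``: the GWAS causal variant sits ``linkage_gap`` SNPs
    away (r² = rho^(2·gap)), the HEIDI alternative.  ``mode='null'``: no
    GWAS signal.  Betas are z·se with se = 1/sqrt(n): the SMR and HEIDI
    statistics are scale invariant, but a realistic SE scale matters for
    the effect-size prior in colocalization.
    """
    rng = np.random.default_rng(seed)
    R = ar1_ld(m, rho)
    L = np.linalg.cholesky(R)
    cq = m // 2
    lam_q = np.zeros(m)
    lam_q[cq] = z_qtl
    lam_g = np.zeros(m)
    if mode == "shared":
        lam_g[cq] = b_xy * z_qtl
    elif mode == "linkage":
        lam_g[cq + linkage_gap] = b_xy * z_qtl
    elif mode != "null":
        raise ConfigurationError(f"unknown mode {mode!r}")
    z_q = R @ lam_q + L @ rng.standard_normal(m)
    z_g = R @ lam_g + L @ rng.standard_normal(m)
    se = np.full(m, 1.0 / np.sqrt(n))
    return CisRegion(probe_id, [f"rs{j + 1}" for j in range(m)],
                     z_q * se, se, z_g * se, se.copy(), R)


# ---------------------------------------------------------------------------
# LDSC inputs
# ---------------------------------------------------------------------------

@dataclass
class LdscSimConfig:
    M: int = 20_000
    h2_1: float = 0.2
    h2_2: float = 0.1
    rg: float = 0.22
    N1: float = 50_000
    N2: float = 50_000
    ell_shape: float = 2.0
    ell_scale: float = 20.0
    overlap: float = 0.0        # shared-sample noise correlation (biv intercept)
    seed: int = 0


def simulate_ldsc(config: LdscSimConfig) -> LdscInput:
    """Per-SNP z pairs whose first two moments follow the LD score
    regression model: Var(z_t) = 1 + N_t·h2_t·ℓ/M,
    Cov(z1,z2) = sqrt(N1·N2)·rg·sqrt(h2_1·h2_2)·ℓ/M + overlap."""
    if abs(config.rg) > 1:
        raise ConfigurationError("|rg| must not exceed 1")
    rng = np.random.default_rng(config.seed)
    ell = 1.0 + rng.gamma(config.ell_shape, config.ell_scale, size=config.M)
    a1 = config.N1 * config.h2_1 * ell / config.M
    a2 = config.N2 * config.h2_2 * ell / config.M
    var1, var2 = 1.0 + a1, 1.0 + a2
    cov = (np.sqrt(config.N1 * config.N2) * config.rg
           * np.sqrt(config.h2_1 * config.h2_2) * ell / config.M
           + config.overlap)
    u = rng.standard_normal(config.M)
    v = rng.standard_normal(config.M)
    z1 = np.sqrt(var1) * u
    resid_var = np.clip(var2 - cov ** 2 / var1, 1e-12, None)
    z2 = cov / np.sqrt(var1) * u + np.sqrt(resid_var) * v
    return LdscInput(ell, z1, z2, config.N1, config.N2, config.M)


# ---------------------------------------------------------------------------
# Mediation chain
# ---------------------------------------------------------------------------

@dataclass
class MediationChainConfig:
    a: float = 0.4
    b: float = 0.25
    direct: float = 0.05
    k_exposure: int = 30
    k_mediator: int = 30
    gamma_low: float = 0.04
    gamma_high: float = 0.08
    gamma2_low: float = 0.12
    gamma2_high: float = 0.2
    n_exposure: float = 200_000
    n_mediator: float = 30_000
    n_outcome: float = 200_000
    seed: int = 0

    @property
    def true_total(self) -> float:
        return self.direct + self.a * self.b

    @property
    def true_proportion(self) -> float:
        return self.a * self.b / self.true_total


def simulate_mediation_chain(config: MediationChainConfig
                             ) -> dict[str, list[SummaryStatRecord]]:
    """Summary statistics for exposure, mediator and outcome GWAS over the
    union of both instrument sets.

    Exposure instruments G1 act on the mediator with slope ``a`` and on the
    outcome with slope ``direct + a·b`` (total); mediator instruments G2 act
    on the outcome with slope ``b`` and not on the exposure.  Scales and
    sample sizes are chosen so each trait's genome-wide significant set is
    exactly its own instruments (G1's mediator effects stay sub-threshold
    in the mediator GWAS).
    """
    rng = np.random.default_rng(config.seed)
    k1, k2 = config.k_exposure, config.k_mediator
    k = k1 + k2
    snp_ids, chroms, poss, eas, oas, eafs = _layout(k, rng, 0.2, 0.8)
    sign1 = rng.choice([-1.0, 1.0], size=k1)
    sign2 = rng.choice([-1.0, 1.0], size=k2)
    gamma1 = sign1 * rng.uniform(config.gamma_low, config.gamma_high, size=k1)
    gamma2 = sign2 * rng.uniform(config.gamma2_low, config.gamma2_high, size=k2)
    true_x = np.concatenate([gamma1, np.zeros(k2)])
    true_m = np.concatenate([config.a * gamma1, gamma2])
    true_y = np.concatenate([config.true_total * gamma1, config.b * gamma2])
    out = {}
    for name, true, n in (("exposure", true_x, config.n_exposure),
                          ("mediator", true_m, config.n_mediator),
                          ("outcome", true_y, config.n_outcome)):
        se = analytic_se(n, eafs)
        beta = true + rng.normal(0.0, se)
        out[name] = _records(snp_ids, chroms, poss, eas, oas, eafs, beta, se,
                             np.full(k, n))
    return out
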
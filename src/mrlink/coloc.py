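"""Bayesian colocalization of two traits over a genomic region.

Under the single-causal-variant assumption, each SNP's evidence of
association with a trait is summarized by Wakefield's approximate Bayes
factor.  With per-SNP prior probabilities p1 (causal for trait 1 only), p2
(trait 2 only) and p12 (shared causal variant), the five region hypotheses

    H0: no association; H1/H2: one trait only; H3: two distinct causal
    variants; H4: one shared causal variant

get posterior probabilities by summing ABFs over SNP configurations.  A
posterior PP.H4 above 0.8 is the conventional threshold for a shared causal
variant; PP.H3+PP.H4 >= 0.8 is the relaxed criterion that admits loci where
the data cannot separate sharing from tight linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import DomainError, InputError

DEFAULT_PRIOR_SD = {"quant": 0.15, "cc": 0.2}


def wakefield_labf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for one variant:

        labf = 0.5 * [ln(se²/(se²+W)) + z²·W/(se²+W)],  W = prior_sd², z = beta/se

    Vectorized over beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be positive")
    if prior_sd <= 0:
        raise DomainError("prior_sd must be positive")
    W = prior_sd ** 2
    z2 = (beta / se) ** 2
    r = W / (se ** 2 + W)
    labf = 0.5 * (np.log(se ** 2 / (se ** 2 + W)) + z2 * r)
    return float(labf) if labf.ndim == 0 else labf


@dataclass
class RegionPair:
    """Per-SNP summary effects for two traits over one region (same SNP
    order for both).  ``type*`` is 'quant' or 'cc' (log-odds effects)."""

    snp_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    type1: str = "quant"
    type2: str = "quant"
    label: str = ""

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        n = len(self.snp_ids)
        for a in (self.beta1, self.se1, self.beta2, self.se2):
            if a.shape != (n,):
                raise InputError("trait arrays must match the SNP list")


@dataclass
class ColocResult:
    pp: dict[str, float]           # keys h0..h4
    priors: tuple[float, float, float]
    n_snps: int
    classification: str = "unresolved"
    thresholds: tuple[float, float] = (0.8, 0.8)

    def __post_init__(self):
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-10:
            raise InputError("posterior probabilities must sum to 1")


def coloc_abf(region: RegionPair, p1: float = 1e-4, p2: float = 1e-4,
              p12: float = 1e-5, prior_sd_quant: float = 0.15,
              prior_sd_cc: float = 0.2) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Hypothesis sums are assembled in log space (log-sum-exp); the H3 sum of
    ABF products over distinct SNP pairs is computed as
    (sum e^l1)(sum e^l2) - sum e^(l1+l2) in log space.
    """
    n = len(region.snp_ids)
    if n < 2:
        raise InputError("colocalization needs at least 2 SNPs")
    if n < 10:
        warnings.warn(f"only {n} SNPs in region; results may be unstable",
                      stacklevel=2)
    sd1 = prior_sd_quant if region.type1 == "quant" else prior_sd_cc
    sd2 = prior_sd_quant if region.type2 == "quant" else prior_sd_cc
    l1 = wakefield_labf(region.beta1, region.se1, sd1)
    l2 = wakefield_labf(region.beta2, region.se2, sd2)

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + ls1
    lh[2] = np.log(p2) + ls2
    # sum_{i != j} e^{l1_i + l2_j} = (sum e^l1)(sum e^l2) - sum e^{l1+l2}
    diag_ratio = np.exp(ls12 - ls1 - ls2)
    with np.errstate(divide="ignore"):
        cross = ls1 + ls2 + np.log1p(-min(diag_ratio, 1.0)) \
            if diag_ratio < 1.0 else -np.inf
    lh[3] = np.log(p1) + np.log(p2) + cross
    lh[4] = np.log(p12) + ls12

    lh -= logsumexp(lh)
    pp = np.exp(lh)
    pp /= pp.sum()
    result = ColocResult({f"h{i}": float(pp[i]) for i in range(5)},
                         (p1, p2, p12), n)
    result.classification = classify_coloc(result)
    return result


def classify_coloc(result: ColocResult, h4_threshold: float = 0.8,
                   combined_threshold: float = 0.8) -> str:
    """'shared_causal' iff PP.H4 > h4_threshold; else 'distinct_or_shared'
    iff PP.H3+PP.H4 >= combined_threshold; else 'unresolved'."""
    result.thresholds = (h4_threshold, combined_threshold)
    if result.pp["h4"] > h4_threshold:
        return "shared_causal"
    if result.pp["h3"] + result.pp["h4"] >= combined_threshold:
        return "distinct_or_shared"
    return "unresolved"
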
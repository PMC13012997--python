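"""LD score regression: SNP heritability and cross-trait genetic correlation.

For a polygenic trait with SNP heritability h² measured on N individuals,
the expected association chi-square at a SNP with LD score ℓ (the sum of r²
with all SNPs) is E[z²] = 1 + N·h²·ℓ/M, so regressing z² on N·ℓ/M gives h²
as the slope and confounding/stratification as the intercept (near 1 in its
absence).  Regressing the cross-trait product z1·z2 on sqrt(N1·N2)·ℓ/M gives
the genetic covariance; the genetic correlation is

    rg = gencov / sqrt(h2_1 · h2_2)

with its SE from a delete-one-block jackknife over contiguous SNP blocks
run through the whole pipeline.  Heteroskedasticity weights use a one-step
scheme (1/(1+N·ĥ²·ℓ/M)² per trait, the product of unsquared factors for the
cross regression) fixed from a full-sample pass — a simplification of the
reference two-step estimator, labelled "simplified-LDSC" in output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import EstimationError, InputError

METHOD_LABEL = "simplified-LDSC"


@dataclass
class LdscInput:
    """Per-SNP LD scores and z statistics for two traits (genome order)."""

    ell: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    n1: float
    n2: float
    M: int

    def __post_init__(self):
        self.ell = np.asarray(self.ell, dtype=float)
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        if not (len(self.ell) == len(self.z1) == len(self.z2)):
            raise InputError("ell, z1, z2 must have equal length")
        if np.any(self.ell < 0):
            raise InputError("LD scores must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"L2": self.ell, "Z1": self.z1, "Z2": self.z2,
                             "N1": self.n1, "N2": self.n2})


@dataclass
class H2Result:
    h2: float
    intercept: float
    se_h2: float
    n_blocks: int
    method: str = METHOD_LABEL


@dataclass
class RgResult:
    h2_1: float
    h2_2: float
    gencov: float
    rg: float
    se_rg: float
    pval: float
    intercept1: float
    intercept2: float
    intercept_biv: float
    n_blocks: int
    method: str = METHOD_LABEL


def _block_bounds(n_snps: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, n_snps, n_blocks + 1).astype(int)


def _wls_sums(x, y, w, bounds):
    """Per-block weighted sufficient statistics for a 1-predictor +
    intercept regression: columns [Σw, Σwx, Σwx², Σwy, Σwxy]."""
    stats = np.column_stack([w, w * x, w * x * x, w * y, w * x * y])
    blocks = np.add.reduceat(stats, bounds[:-1], axis=0)
    return blocks


def _solve_wls(s):
    """Slope and intercept from summed sufficient statistics."""
    sw, swx, swx2, swy, swxy = s
    det = sw * swx2 - swx ** 2
    if det <= 0 or not np.isfinite(det):
        raise EstimationError("degenerate design: LD scores carry no variation")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    return slope, intercept


def _weights(ell, n, h2, M):
    a = n * max(h2, 0.0) * ell / M
    return 1.0 / (1.0 + a)


def h2_regression(ld_scores, z, n: float, M: int,
                  n_blocks: int = 200) -> H2Result:
    """SNP heritability from the regression of z² on N·ℓ/M.

    SEs by delete-one-block jackknife over contiguous blocks (block count is
    reduced with a warning when there are fewer SNPs than blocks).
    """
    ell = np.asarray(ld_scores, dtype=float)
    z = np.asarray(z, dtype=float)
    n_snps = len(ell)
    if n_snps < n_blocks:
        warnings.warn(f"only {n_snps} SNPs; reducing jackknife blocks",
                      stacklevel=2)
        n_blocks = max(2, n_snps // 2)
    x = n * ell / M
    y = z ** 2
    # step 1: unweighted pass for the heteroskedasticity weights
    bounds = _block_bounds(n_snps, n_blocks)
    h2_0, _ = _solve_wls(_wls_sums(x, y, np.ones(n_snps), bounds).sum(axis=0))
    w = _weights(ell, n, h2_0, M) ** 2
    blocks = _wls_sums(x, y, w, bounds)
    total = blocks.sum(axis=0)
    h2, intercept = _solve_wls(total)
    jack = np.array([_solve_wls(total - blocks[b])[0] for b in range(n_blocks)])
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((jack - jack.mean()) ** 2))
    return H2Result(float(h2), float(intercept), float(se), n_blocks)


def rg_regression(inp: LdscInput, n_blocks: int = 200) -> RgResult:
    """Cross-trait genetic correlation with jackknife SE over the full
    pipeline (both heritabilities, the genetic covariance, and their ratio
    recomputed per delete-block; weights fixed from the full-sample pass)."""
    n_snps = len(inp.ell)
    if n_snps < n_blocks:
        warnings.warn(f"only {n_snps} SNPs; reducing jackknife blocks",
                      stacklevel=2)
        n_blocks = max(2, n_snps // 2)
    bounds = _block_bounds(n_snps, n_blocks)
    x1 = inp.n1 * inp.ell / inp.M
    x2 = inp.n2 * inp.ell / inp.M
    xg = np.sqrt(inp.n1 * inp.n2) * inp.ell / inp.M
    y1, y2, yg = inp.z1 ** 2, inp.z2 ** 2, inp.z1 * inp.z2
    ones = np.ones(n_snps)
    h2_1_0, _ = _solve_wls(_wls_sums(x1, y1, ones, bounds).sum(axis=0))
    h2_2_0, _ = _solve_wls(_wls_sums(x2, y2, ones, bounds).sum(axis=0))
    w1 = _weights(inp.ell, inp.n1, h2_1_0, inp.M)
    w2 = _weights(inp.ell, inp.n2, h2_2_0, inp.M)
    blocks1 = _wls_sums(x1, y1, w1 ** 2, bounds)
    blocks2 = _wls_sums(x2, y2, w2 ** 2, bounds)
    blocksg = _wls_sums(xg, yg, w1 * w2, bounds)
    t1, t2, tg = (b.sum(axis=0) for b in (blocks1, blocks2, blocksg))
    h2_1, int1 = _solve_wls(t1)
    h2_2, int2 = _solve_wls(t2)
    gencov, int_biv = _solve_wls(tg)
    if h2_1 <= 0 or h2_2 <= 0:
        raise EstimationError(
            f"nonpositive heritability (h2_1={h2_1:.4g}, h2_2={h2_2:.4g}); "
            "rg undefined")
    rg = gencov / np.sqrt(h2_1 * h2_2)

    jack = np.empty(n_blocks)
    for b in range(n_blocks):
        a1, _ = _solve_wls(t1 - blocks1[b])
        a2, _ = _solve_wls(t2 - blocks2[b])
        g, _ = _solve_wls(tg - blocksg[b])
        denom = np.sqrt(max(a1, 1e-12) * max(a2, 1e-12))
        jack[b] = g / denom
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * np.sum((jack - jack.mean()) ** 2)))
    if se > 0:
        pval = float(2.0 * sps.norm.sf(abs(rg) / se))
    else:
        pval = 1.0 if rg == 0 else 0.0
    if abs(rg) > 1:
        warnings.warn(f"|rg|={abs(rg):.3f} exceeds 1", stacklevel=2)
    return RgResult(float(h2_1), float(h2_2), float(gencov), float(rg), se,
                    pval, float(int1), float(int2), float(int_biv), n_blocks)
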
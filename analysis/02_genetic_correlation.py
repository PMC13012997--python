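#!/usr/bin/env python
"""Stage 1 — shared genetic background.

Cross-trait LD score regression on the simulated exposure/outcome z pairs:
the slope of z1·z2 on sqrt(N1·N2)·ℓ/M gives the genetic covariance, and
rg = gencov/sqrt(h2_1·h2_2).  The generating model plants rg = 0.22 with
heritabilities 0.2 and 0.1 — the regime the estimator must recover before
any causal claim is worth making.
"""

from pathlib import Path

import pandas as pd

from mrlink.ldsc import rg_regression
from mrlink.simulate import LdscSimConfig, simulate_ldsc

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main():
    RESULTS.mkdir(exist_ok=True)
    res = rg_regression(simulate_ldsc(LdscSimConfig(seed=SEED + 2)))
    table = pd.DataFrame([{
        "h2_exposure": res.h2_1, "h2_outcome": res.h2_2,
        "gencov": res.gencov, "rg": res.rg, "se_rg": res.se_rg,
        "pval": res.pval, "intercept_exposure": res.intercept1,
        "intercept_outcome": res.intercept2,
        "intercept_bivariate": res.intercept_biv, "method": res.method,
    }])
    table.to_csv(RESULTS / "ldsc_rg.tsv", sep="\t", index=False)
    print(f"rg = {res.rg:.3f} (SE {res.se_rg:.3f}, p = {res.pval:.2e}); "
          f"true value 0.22 lies within the jackknife band: "
          f"{abs(res.rg - 0.22) < 3 * res.se_rg}")
    print(f"univariate intercepts {res.intercept1:.3f}/{res.intercept2:.3f} "
          "(no confounding planted, so both should sit near 1)")
    print(f"wrote {RESULTS / 'ldsc_rg.tsv'}")


if __name__ == "__main__":
    main()
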
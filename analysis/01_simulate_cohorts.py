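#!/usr/bin/env python
"""Generate the synthetic study inputs once, in the file dialects every
downstream command reads.

Emulated are the study's data sources: an exposure GWAS (gestational
diabetes liability, FinnGen-scale), an outcome GWAS (carpal tunnel
syndrome), a correlated metabolic covariate, a cis-pQTL region for the
candidate mediator protein (CCS, copper chaperone for superoxide
dismutase), LD-score inputs for the trait pair, and the three-trait
mediation chain.  Files land under scratch/data/ (regenerated
deterministically; nothing here is a stored fixture).
"""

from pathlib import Path

from mrlink.simulate import (LdscSimConfig, MediationChainConfig,
                             TwoSampleSimConfig, simulate_cis_region,
                             simulate_ldsc, simulate_mediation_chain,
                             simulate_two_sample)
from mrlink.sumstats import LDMatrix, write_sumstats

import pandas as pd

SEED = 2026
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main():
    DATA.mkdir(parents=True, exist_ok=True)

    # exposure -> outcome pair with a true log-odds effect of 0.15
    gdm, cts = simulate_two_sample(TwoSampleSimConfig(
        k=40, theta=0.15, gamma_sd=0.06, seed=SEED))
    write_sumstats(gdm, DATA / "gdm.tsv")
    write_sumstats(cts, DATA / "cts.tsv")

    # a metabolically correlated covariate with no direct outcome effect
    t2d, _ = simulate_two_sample(TwoSampleSimConfig(
        k=40, theta=0.0, gamma_sd=0.06, seed=SEED + 1))
    write_sumstats(t2d, DATA / "t2d.tsv")

    # LDSC inputs in the study's regime (h2 0.2 / 0.1, rg 0.22)
    simulate_ldsc(LdscSimConfig(seed=SEED + 2)).to_frame().to_csv(
        DATA / "ldsc_input.tsv", sep="\t", index=False)

    # shared-causal cis region: protein QTL vs outcome GWAS
    region = simulate_cis_region(mode="shared", b_xy=0.4, m=100,
                                 seed=SEED + 3, probe_id="CCS")
    pd.DataFrame({"SNP": region.snp_ids, "BETA": region.b_qtl,
                  "SE": region.se_qtl}).to_csv(DATA / "ccs_qtl.tsv",
                                               sep="\t", index=False)
    pd.DataFrame({"SNP": region.snp_ids, "BETA": region.b_gwas,
                  "SE": region.se_gwas}).to_csv(DATA / "cts_region.tsv",
                                                sep="\t", index=False)
    LDMatrix(region.snp_ids, region._r).to_tsv(DATA / "region_ld.tsv")

    # the full mediation chain (a=0.4, b=0.25, direct=0.05)
    for name, recs in simulate_mediation_chain(
            MediationChainConfig(seed=SEED + 4)).items():
        write_sumstats(recs, DATA / f"chain_{name}.tsv")

    print(f"wrote synthetic cohort inputs to {DATA}")
    for p in sorted(DATA.iterdir()):
        print(f"  {p.name}")


if __name__ == "__main__":
    main()
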
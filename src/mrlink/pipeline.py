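"""End-to-end orchestration of the multi-stage causal-inference framework.

The chain mirrors the standard study design for dissecting an
exposure-outcome relationship from summary statistics: genetic correlation
(LDSC) -> bidirectional MR -> a univariable MR panel of candidate traits ->
multivariable MR adjustment -> SMR + colocalization of molecular QTL ->
protein MR/colocalization -> phenome-wide screen of the prioritised protein
-> two-step mediation MR.  Stages are independent unless declared otherwise;
a failing stage halts its dependents but not the rest, and every stage is
seeded from the master seed plus its index so the whole report is a pure
function of (config, input files, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import ldsc as ldsc_mod
from . import mediation as med_mod
from . import mr as mr_mod
from . import mvmr as mvmr_mod
from . import smr as smr_mod
from .exceptions import ConfigurationError, PipelineError
from .sumstats import LDMatrix, read_sumstats, select_instruments

STAGES = ["ldsc", "bidirectional_mr", "uvmr", "mvmr", "smr_coloc", "pqtl",
          "phewas", "mediation"]
#: stage -> stages that must have succeeded first
DEPENDENCIES = {"mediation": ["bidirectional_mr"]}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    thresholds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    DEFAULT_THRESHOLDS = {
        "p_instrument": 5e-8, "clump_r2": 0.001, "clump_kb": 10_000,
        "f_min": 10.0, "pph4": 0.8, "pph3_pph4": 0.8, "p_heidi": 0.05,
        "fdr": 0.05,
    }

    def __post_init__(self):
        merged = dict(self.DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = {k: raw[k] for k in STAGES if k in raw}
        return cls(seed=int(raw.get("seed", 0)),
                   out_dir=str(raw.get("out_dir", "results")),
                   thresholds=raw.get("thresholds", {}),
                   stages=stages)

    def validate(self) -> list[str]:
        """Itemized config errors (missing files, unknown stages)."""
        errors = []
        for stage, spec in self.stages.items():
            if stage not in STAGES:
                errors.append(f"unknown stage {stage!r}")
                continue
            for key, value in (spec or {}).items():
                if isinstance(value, str) and (
                        key.endswith("file") or key in
                        {"exposure", "outcome", "mediator", "qtl", "gwas",
                         "ld", "instruments", "ldsc_input"}):
                    if not Path(value).exists():
                        errors.append(f"{stage}.{key}: missing file {value}")
                if isinstance(value, dict) and key in ("exposures", "outcomes"):
                    for lab, p in value.items():
                        if not Path(p).exists():
                            errors.append(f"{stage}.{key}.{lab}: missing file {p}")
        return errors


@dataclass
class Report:
    stages: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        return json.dumps({"metadata": self.metadata, "stages": self.stages,
                           "errors": self.errors}, default=default, indent=2)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        lines = [f"pipeline report (seed={self.metadata.get('seed')})", ""]
        for stage in STAGES:
            status = ("ok" if stage in self.stages
                      else f"FAILED: {self.errors[stage]}" if stage in self.errors
                      else "skipped")
            lines.append(f"  {stage:16s} {status}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")


def _read(path):
    return read_sumstats(path).records


def _ld(spec):
    path = (spec or {}).get("ld")
    return LDMatrix.from_tsv(path) if path else None


def _mr_table(iset, n_x=None, n_y=None) -> dict:
    """Standard univariable results block: IVW + sensitivity battery."""
    rows = []
    est_ivw = mr_mod.ivw(iset)
    ests = [est_ivw]
    for fn in (mr_mod.divw, mr_mod.raps):
        try:
            ests.append(fn(iset))
        except Exception as exc:      # report the methods that do run
            warnings.warn(f"{fn.__name__} failed: {exc}", stacklevel=2)
    het = mr_mod.cochran_q(iset)
    try:
        slope, intercept = mr_mod.egger(iset)
        ests.append(slope)
        egger_int = {"beta": intercept.beta, "pval": intercept.pval}
    except Exception as exc:
        warnings.warn(f"egger failed: {exc}", stacklevel=2)
        egger_int = {"beta": float("nan"), "pval": float("nan")}
    for est in ests:
        orr, orl, oru = mr_mod.to_odds_ratio(est.beta, est.se)
        rows.append({"method": est.method, "nsnp": est.k, "beta": est.beta,
                     "se": est.se, "pval": est.pval, "or": orr,
                     "or_lci": orl, "or_uci": oru})
    block = {"estimates": rows, "Q": het.Q, "Q_pval": het.pval,
             "egger_intercept": egger_int, "mean_f": iset.mean_f}
    if n_x and n_y:
        st = mr_mod.steiger(iset, n_x, n_y)
        block["steiger"] = {"direction_ok": st.direction_ok, "pval": st.pval,
                            "r2_exposure": st.r2_exposure,
                            "r2_outcome": st.r2_outcome}
    return block


def bidirectional_mr(exposure, outcome, ld=None, p_threshold=5e-8,
                     r2_threshold=0.001, window_kb=10_000,
                     alpha=0.05, steiger_alpha=0.05) -> dict:
    """Forward and reverse MR with Steiger screening and a direction call.

    Instruments in each direction are screened per SNP with the Steiger
    directionality test (SNPs failing at one-sided p >= ``steiger_alpha``
    are removed), which strips reverse-direction instruments that primarily
    act on the other trait.  Verdict: 'forward' when the forward IVW is
    significant, the reverse is not, and Steiger supports exposure->outcome;
    'reverse' symmetric; 'ambiguous' when both survive; 'none' otherwise.
    """
    from .sumstats import InstrumentSet

    def n_of(records):
        ns = [r.n for r in records if r.n]
        return float(np.median(ns)) if ns else None

    result = {}
    for direction, (exp, out) in (("forward", (exposure, outcome)),
                                  ("reverse", (outcome, exposure))):
        iset = select_instruments(exp, out, ld, p_threshold, r2_threshold,
                                  window_kb)
        n_x, n_y = n_of(exp), n_of(out)
        if len(iset) and n_x and n_y:
            kept = mr_mod.steiger_filter(iset.pairs, n_x, n_y, steiger_alpha)
            iset = InstrumentSet(kept, iset.p_threshold, iset.r2_threshold,
                                 iset.window_kb,
                                 np.array([p.f_stat for p in kept]))
        if len(iset) < 2:
            result[direction] = {"estimable": False,
                                 "reason": f"{len(iset)} instrument(s) after "
                                           "selection and Steiger screening"}
            continue
        block = _mr_table(iset, n_x, n_y)
        block["estimable"] = True
        result[direction] = block

    def sig(block):
        if not block.get("estimable"):
            return False
        return block["estimates"][0]["pval"] < alpha

    fwd, rev = sig(result["forward"]), sig(result["reverse"])
    if fwd and not rev:
        verdict = "forward"
        if not result["forward"].get("steiger", {}).get("direction_ok", True):
            verdict = "ambiguous"
    elif rev and not fwd:
        verdict = "reverse"
    elif fwd and rev:
        verdict = "ambiguous"
    else:
        verdict = "none"
    result["verdict"] = verdict
    return result


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute configured stages in dependency order.

    Config validation failures raise :class:`ConfigurationError` before any
    computation.  A stage failure is logged and halts its dependents only.
    """
    errors = config.validate()
    if errors:
        raise ConfigurationError("config invalid:\n  " + "\n  ".join(errors))
    report = Report(metadata={"seed": config.seed,
                              "thresholds": config.thresholds})
    th = config.thresholds

    def stage_seed(stage):
        return config.seed + STAGES.index(stage)

    for stage in STAGES:
        spec = config.stages.get(stage)
        if spec is None:
            continue
        blocked = [d for d in DEPENDENCIES.get(stage, [])
                   if d in config.stages and d not in report.stages]
        if blocked:
            report.errors[stage] = f"dependency failed: {blocked}"
            continue
        try:
            report.stages[stage] = _run_stage(stage, spec, th,
                                              stage_seed(stage))
        except Exception as exc:
            report.errors[stage] = str(exc)
    return report


def _run_stage(stage, spec, th, seed):
    if stage == "ldsc":
        df = pd.read_csv(spec["ldsc_input"], sep="\t")
        inp = ldsc_mod.LdscInput(df["L2"].to_numpy(), df["Z1"].to_numpy(),
                                 df["Z2"].to_numpy(),
                                 float(df["N1"].iloc[0]),
                                 float(df["N2"].iloc[0]), int(spec["M"]))
        res = ldsc_mod.rg_regression(inp, n_blocks=int(spec.get("n_blocks", 200)))
        return {"rg": res.rg, "se_rg": res.se_rg, "pval": res.pval,
                "h2_1": res.h2_1, "h2_2": res.h2_2,
                "intercepts": [res.intercept1, res.intercept2,
                               res.intercept_biv], "method": res.method}
    if stage == "bidirectional_mr":
        return bidirectional_mr(_read(spec["exposure"]), _read(spec["outcome"]),
                                _ld(spec), th["p_instrument"], th["clump_r2"],
                                th["clump_kb"])
    if stage == "uvmr":
        outcome = _read(spec["outcome"])
        block = {}
        for label, path in spec["exposures"].items():
            iset = select_instruments(_read(path), outcome, _ld(spec),
                                      th["p_instrument"], th["clump_r2"],
                                      th["clump_kb"])
            if len(iset) < 2:
                block[label] = {"estimable": False}
                continue
            est = mr_mod.ivw(iset)
            orr, orl, oru = mr_mod.to_odds_ratio(est.beta, est.se)
            block[label] = {"estimable": True, "nsnp": est.k,
                            "beta": est.beta, "se": est.se, "pval": est.pval,
                            "or": orr, "or_lci": orl, "or_uci": oru}
        return block
    if stage == "mvmr":
        exposures = {lab: _read(p) for lab, p in spec["exposures"].items()}
        mvset = mvmr_mod.build_mv_set(exposures, _read(spec["outcome"]),
                                      pooling=spec.get("pooling", "intersection"))
        table, het = mvmr_mod.mv_ivw(mvset)
        strength = mvmr_mod.mv_instrument_strength(mvset, th["f_min"])
        return {"estimates": table.to_dict(orient="records"),
                "Q": het.Q, "Q_df": het.df, "Q_pval": het.pval,
                "strength": strength.to_dict(orient="records")}
    if stage in ("smr_coloc", "pqtl"):
        return _molecular_stage(spec, th, seed)
    if stage == "phewas":
        instruments = _read(spec["instruments"])
        outcomes = {lab: _read(p) for lab, p in spec["outcomes"].items()}
        df = med_mod.phewas_screen(instruments, outcomes, _ld(spec),
                                   clump_r2=spec.get("clump_r2", 0.1),
                                   clump_kb=spec.get("clump_kb", 10_000),
                                   fdr=th["fdr"])
        return {"table": df.to_dict(orient="records"),
                "n_significant": int(df["significant"].sum())}
    if stage == "mediation":
        result, provenance = med_mod.two_step_pipeline(
            _read(spec["exposure"]), _read(spec["mediator"]),
            _read(spec["outcome"]), _ld(spec), th["p_instrument"],
            th["clump_r2"], th["clump_kb"],
            conditioned_b=bool(spec.get("conditioned_b", False)))
        return {"decomposition": result.to_dict(), "provenance": provenance}
    raise PipelineError(f"unknown stage {stage!r}", stage=stage)


def _molecular_stage(spec, th, seed):
    """Shared SMR + colocalization logic for the eQTL and pQTL stages."""
    qtl = pd.read_csv(spec["qtl"], sep="\t")
    gwas = pd.read_csv(spec["gwas"], sep="\t")
    ld = LDMatrix.from_tsv(spec["ld"])
    merged = qtl.merge(gwas, on="SNP", suffixes=("_qtl", "_gwas"))
    order = [s for s in ld.snp_ids if s in set(merged["SNP"])]
    merged = merged.set_index("SNP").loc[order].reset_index()
    sub = ld if list(merged["SNP"]) == ld.snp_ids else LDMatrix(
        order, ld.r[np.ix_([ld.snp_ids.index(s) for s in order],
                           [ld.snp_ids.index(s) for s in order])])
    region = smr_mod.CisRegion(
        spec.get("probe", "probe"), list(merged["SNP"]),
        merged["BETA_qtl"].to_numpy(), merged["SE_qtl"].to_numpy(),
        merged["BETA_gwas"].to_numpy(), merged["SE_gwas"].to_numpy(), sub)
    b_xy, se_xy, p_smr = smr_mod.smr_test(region)
    p_heidi, n_heidi, reason = smr_mod.heidi_test(region, seed=seed)
    pair = coloc_mod.RegionPair(list(merged["SNP"]),
                                merged["BETA_qtl"].to_numpy(),
                                merged["SE_qtl"].to_numpy(),
                                merged["BETA_gwas"].to_numpy(),
                                merged["SE_gwas"].to_numpy())
    cres = coloc_mod.coloc_abf(pair)
    cres.classification = coloc_mod.classify_coloc(cres, th["pph4"],
                                                   th["pph3_pph4"])
    return {"smr": {"b_xy": b_xy, "se_xy": se_xy, "p_smr": p_smr,
                    "p_heidi": p_heidi, "nsnp_heidi": n_heidi,
                    "heidi_reason": reason},
            "coloc": {"pp": cres.pp, "classification": cres.classification,
                      "n_snps": cres.n_snps}}
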
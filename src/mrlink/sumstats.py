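"""GWAS/QTL summary-statistic data model, I/O, QC, harmonization and clumping.

The unit of data is one SNP's association with one trait: effect allele,
other allele, effect-allele frequency, effect size (log-odds for binary
traits), its standard error, p-value and sample size.  Files are plain
tab/whitespace-delimited text with the canonical header

    SNP CHR POS EA OA EAF BETA SE P N

(``CHR POS EAF N`` optional).  Two-sample analyses require the exposure and
outcome effects to be expressed relative to the same effect allele; the
:func:`harmonize` routine aligns them, flipping signs where the allele labels
are swapped and resolving strand-ambiguous (palindromic) SNPs by allele
frequency.  Instrument selection follows the conventional greedy p-value
clumping under pairwise r² and distance constraints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DomainError, InputError

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_BASES = set("ACGT")

#: tolerance for the |z| -> p consistency check on input rows
PZ_RELATIVE_TOL = 0.10


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


@dataclass
class SummaryStatRecord:
    """One SNP-trait association."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def validation_errors(self, check_pz: bool = True) -> list[str]:
        errs: list[str] = []
        if not np.isfinite(self.se) or self.se <= 0:
            errs.append("nonpositive SE")
        if not np.isfinite(self.beta):
            errs.append("nonfinite beta")
        if self.effect_allele == self.other_allele:
            errs.append("identical alleles")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            errs.append("EAF outside (0,1)")
        if not (0.0 < self.pval <= 1.0):
            errs.append("pval outside (0,1]")
        elif check_pz and not errs:
            z = abs(self.beta / self.se)
            expected = 2.0 * sps.norm.sf(z)
            if expected > 1e-300 or self.pval > 1e-300:
                ref = max(expected, 1e-300)
                if abs(self.pval - expected) > PZ_RELATIVE_TOL * ref:
                    errs.append("pval inconsistent with beta/se")
        if self.n is not None and self.n < 1:
            errs.append("sample size < 1")
        return errs

    @property
    def is_palindromic(self) -> bool:
        return _complement(self.effect_allele) == self.other_allele

    @property
    def is_indel(self) -> bool:
        a, b = self.effect_allele, self.other_allele
        return len(a) != 1 or len(b) != 1 or a not in _BASES or b not in _BASES

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class ReadResult:
    """Validated records plus rejected rows with reasons, in file order."""

    records: list[SummaryStatRecord]
    rejects: list[tuple[int, str]]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  check_pz: bool = True) -> ReadResult:
    """Read a whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps canonical names (``SNP``, ``EA``, ...) to the names
    used in the file's header.  Missing mandatory columns raise
    :class:`ConfigurationError`; a file with zero valid rows raises
    :class:`InputError`.  Malformed rows are collected (0-based data row
    index, reason) rather than raised.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    rename = {}
    if column_map:
        for canonical, actual in column_map.items():
            if canonical not in CANONICAL_COLUMNS:
                raise ConfigurationError(f"unknown canonical column {canonical!r}")
            rename[actual] = canonical
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[SummaryStatRecord] = []
    rejects: list[tuple[int, str]] = []
    has = {c: c in df.columns for c in CANONICAL_COLUMNS}
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            rec = SummaryStatRecord(
                snp_id=str(row["SNP"]),
                chrom=str(row["CHR"]) if has["CHR"] else "0",
                pos=int(float(row["POS"])) if has["POS"] else 0,
                effect_allele=str(row["EA"]).upper(),
                other_allele=str(row["OA"]).upper(),
                eaf=float(row["EAF"]) if has["EAF"] and row["EAF"] not in (None, "NA") else None,
                beta=float(row["BETA"]),
                se=float(row["SE"]),
                pval=float(row["P"]),
                n=float(row["N"]) if has["N"] and row["N"] not in (None, "NA") else None,
            )
        except (TypeError, ValueError) as exc:
            rejects.append((i, f"unparseable row: {exc}"))
            continue
        errs = rec.validation_errors(check_pz=check_pz)
        if errs:
            rejects.append((i, "; ".join(errs)))
        else:
            records.append(rec)
    if not records:
        raise InputError(f"{path}: zero valid rows")
    return ReadResult(records, rejects)


def write_sumstats(records: Iterable[SummaryStatRecord], path) -> None:
    """Write records in the canonical tab-delimited dialect (lossless)."""
    rows = []
    for r in records:
        rows.append({
            "SNP": r.snp_id, "CHR": r.chrom, "POS": r.pos,
            "EA": r.effect_allele, "OA": r.other_allele,
            "EAF": "NA" if r.eaf is None else repr(float(r.eaf)),
            "BETA": repr(float(r.beta)), "SE": repr(float(r.se)),
            "P": repr(float(r.pval)),
            "N": "NA" if r.n is None else repr(float(r.n)),
        })
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int = 0
    n_indel: int = 0
    n_ambiguous: int = 0
    n_duplicate: int = 0
    n_low_maf: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_indel + self.n_ambiguous + self.n_duplicate + self.n_low_maf

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rule": ["indel", "strand_ambiguous", "duplicate", "low_maf"],
            "removed": [self.n_indel, self.n_ambiguous, self.n_duplicate, self.n_low_maf],
        })


def qc_filter(records: Sequence[SummaryStatRecord], maf_min: float = 0.01,
              drop_ambiguous: bool = True, drop_duplicates: bool = True,
              drop_indels: bool = True) -> tuple[list[SummaryStatRecord], QCReport]:
    """Apply the standard summary-statistics filters, in order: non-SNP
    variants (indels), strand-ambiguous SNPs, duplicate SNP ids, MAF below
    ``maf_min``.  Records with unknown EAF survive the MAF filter."""
    report = QCReport(n_input=len(records))
    kept = list(records)
    if drop_indels:
        nxt = [r for r in kept if not r.is_indel]
        report.n_indel = len(kept) - len(nxt)
        kept = nxt
    if drop_ambiguous:
        nxt = [r for r in kept if not r.is_palindromic]
        report.n_ambiguous = len(kept) - len(nxt)
        kept = nxt
    if drop_duplicates:
        seen: set[str] = set()
        nxt = []
        for r in kept:
            if r.snp_id in seen:
                continue
            seen.add(r.snp_id)
            nxt.append(r)
        report.n_duplicate = len(kept) - len(nxt)
        kept = nxt
    nxt = [r for r in kept if r.maf is None or r.maf >= maf_min]
    report.n_low_maf = len(kept) - len(nxt)
    kept = nxt
    if not kept:
        warnings.warn("qc_filter removed every record", stacklevel=2)
    return kept, report


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPair:
    """Exposure and outcome effects for one SNP, aligned to one effect allele."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None
    eaf_y: float | None
    pval_x: float
    pval_y: float
    n_x: float | None = None
    n_y: float | None = None
    action: str = "kept"  # kept | allele_flipped | palindromic_inferred | dropped
    reason: str | None = None

    @property
    def f_stat(self) -> float:
        return (self.beta_x / self.se_x) ** 2


def harmonize(exposure: Sequence[SummaryStatRecord],
              outcome: Sequence[SummaryStatRecord],
              palindrome_eaf_window: float = 0.08) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele.

    Shared SNPs only.  Swapped allele labels flip the outcome sign and EAF;
    strand (complement) flips are recognised for non-palindromic SNPs.
    Palindromic SNPs are kept only when both EAFs lie outside
    ``0.5 ± palindrome_eaf_window`` and fall on the same side of 0.5 after
    label alignment; otherwise they are dropped.  Dropped pairs are returned
    with ``action='dropped'`` and a reason code.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    for ex in exposure:
        oy = out_by_id.get(ex.snp_id)
        if oy is None:
            continue
        pair = HarmonizedPair(
            snp_id=ex.snp_id, chrom=ex.chrom, pos=ex.pos,
            effect_allele=ex.effect_allele, other_allele=ex.other_allele,
            beta_x=ex.beta, se_x=ex.se, beta_y=oy.beta, se_y=oy.se,
            eaf_x=ex.eaf, eaf_y=oy.eaf, pval_x=ex.pval, pval_y=oy.pval,
            n_x=ex.n, n_y=oy.n,
        )
        ea, oa = ex.effect_allele, ex.other_allele
        if ex.is_palindromic:
            # Allele labels cannot distinguish strands here; align labels,
            # then infer strand agreement from allele frequency.
            if (oy.effect_allele, oy.other_allele) == (ea, oa):
                pass
            elif (oy.effect_allele, oy.other_allele) == (oa, ea):
                pair.beta_y = -oy.beta
                pair.eaf_y = None if oy.eaf is None else 1.0 - oy.eaf
            else:
                pair.action, pair.reason = "dropped", "allele mismatch"
                pairs.append(pair)
                continue
            lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
            if pair.eaf_x is None or pair.eaf_y is None:
                pair.action, pair.reason = "dropped", "palindromic missing EAF"
            elif not (pair.eaf_x < lo or pair.eaf_x > hi) or \
                    not (pair.eaf_y < lo or pair.eaf_y > hi):
                pair.action, pair.reason = "dropped", "palindromic EAF near 0.5"
            elif (pair.eaf_x < 0.5) != (pair.eaf_y < 0.5):
                pair.action, pair.reason = "dropped", "palindromic EAF side mismatch"
            else:
                pair.action = "palindromic_inferred"
            pairs.append(pair)
            continue
        cea, coa = _complement(oy.effect_allele), _complement(oy.other_allele)
        if (oy.effect_allele, oy.other_allele) == (ea, oa) or (cea, coa) == (ea, oa):
            pair.action = "kept"
        elif (oy.effect_allele, oy.other_allele) == (oa, ea) or (cea, coa) == (oa, ea):
            pair.beta_y = -oy.beta
            pair.eaf_y = None if oy.eaf is None else 1.0 - oy.eaf
            pair.action = "allele_flipped"
        else:
            pair.action, pair.reason = "dropped", "allele mismatch"
        pairs.append(pair)
    return pairs


def kept_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.action != "dropped"]


def pairs_to_records(pairs: Iterable[HarmonizedPair], side: str = "outcome"
                     ) -> list[SummaryStatRecord]:
    """Re-express one side of harmonized pairs as plain records (aligned to
    the shared effect allele); used for idempotence checks and chaining."""
    recs = []
    for p in pairs:
        if p.action == "dropped":
            continue
        if side == "exposure":
            beta, se, eaf, pval, n = p.beta_x, p.se_x, p.eaf_x, p.pval_x, p.n_x
        else:
            beta, se, eaf, pval, n = p.beta_y, p.se_y, p.eaf_y, p.pval_y, p.n_y
        recs.append(SummaryStatRecord(p.snp_id, p.chrom, p.pos, p.effect_allele,
                                      p.other_allele, eaf, beta, se, pval, n))
    return recs


# ---------------------------------------------------------------------------
# F statistics
# ---------------------------------------------------------------------------

WEAK_F_THRESHOLD = 10.0


def f_statistic(beta, se):
    """Instrument strength F = (beta/se)²; values below 10 flag a weak
    instrument.  Accepts scalars or arrays; ``se <= 0`` is a domain error."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be positive")
    f = (beta / se) ** 2
    return float(f) if f.ndim == 0 else f


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Square signed-correlation (r) matrix indexed by SNP id."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise InputError("LD matrix shape does not match SNP ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise InputError("|r| exceeds 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        """Pairwise r², or None when either SNP is absent."""
        ia, ib = self._index.get(snp_a), self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t")


# ---------------------------------------------------------------------------
# Clumping and instrument selection
# ---------------------------------------------------------------------------

def _item_fields(item):
    """(snp_id, chrom, pos, pval) from a record or a harmonized pair."""
    pval = getattr(item, "pval_x", None)
    if pval is None:
        pval = item.pval
    return item.snp_id, item.chrom, item.pos, pval


@dataclass
class InstrumentSet:
    """Ordered, approximately independent instruments with strength metadata.

    ``pairs`` holds the selected items (harmonized pairs for two-sample
    analyses; plain exposure records when clumping a single trait).
    """

    pairs: list
    p_threshold: float
    r2_threshold: float
    window_kb: float
    fstats: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self):
        return len(self.pairs)

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.fstats)) if len(self.fstats) else math.nan

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self):
        """(beta_x, se_x, beta_y, se_y) for harmonized pairs."""
        bx = np.array([p.beta_x for p in self.pairs])
        sx = np.array([p.se_x for p in self.pairs])
        by = np.array([p.beta_y for p in self.pairs])
        sy = np.array([p.se_y for p in self.pairs])
        return bx, sx, by, sy


def clump(items: Sequence, ld: LDMatrix | None = None, p_threshold: float = 5e-8,
          r2_threshold: float = 0.001, window_kb: float = 10_000) -> InstrumentSet:
    """Greedy p-value clumping.

    Items are sorted by ascending p (ties broken by chrom, pos, snp_id); an
    item is accepted iff its r² with every previously accepted item on the
    same chromosome within ``window_kb`` kb is below ``r2_threshold``.  When
    an :class:`LDMatrix` is supplied, pairs within the window missing from it
    count as r²=1 (conservatively blocking co-selection); ``ld=None`` assumes
    all items are mutually independent.  No item below the p threshold yields
    an empty set with a warning, not an error.
    """
    candidates = [it for it in items if _item_fields(it)[3] < p_threshold]
    if not candidates:
        warnings.warn("no SNP passes the p-value threshold; empty instrument set",
                      stacklevel=2)
    def sort_key(it):
        sid, chrom, pos, pval = _item_fields(it)
        return (pval, chrom, pos, sid)

    candidates.sort(key=sort_key)
    accepted: list = []
    window_bp = window_kb * 1000.0
    for it in candidates:
        sid, chrom, pos, _ = _item_fields(it)
        ok = True
        for acc in accepted:
            aid, achrom, apos, _ = _item_fields(acc)
            if chrom != achrom:
                continue  # cross-chromosome pairs count as r²=0
            if abs(pos - apos) > window_bp:
                continue
            if ld is None:
                r2 = 0.0
            else:
                r2 = ld.r2(sid, aid)
                if r2 is None:
                    r2 = 1.0  # missing in-window entry: block conservatively
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(it)
    fstats = []
    for it in accepted:
        beta = getattr(it, "beta_x", None)
        se = getattr(it, "se_x", None)
        if beta is None:
            beta, se = it.beta, it.se
        fstats.append(f_statistic(beta, se))
    return InstrumentSet(accepted, p_threshold, r2_threshold, window_kb,
                         np.asarray(fstats, dtype=float))


def select_instruments(exposure: Sequence[SummaryStatRecord],
                       outcome: Sequence[SummaryStatRecord],
                       ld: LDMatrix | None = None, p_threshold: float = 5e-8,
                       r2_threshold: float = 0.001, window_kb: float = 10_000,
                       f_min: float = WEAK_F_THRESHOLD,
                       palindrome_eaf_window: float = 0.08) -> InstrumentSet:
    """Harmonize, clump, and drop weak instruments (F < ``f_min``)."""
    pairs = kept_pairs(harmonize(exposure, outcome, palindrome_eaf_window))
    iset = clump(pairs, ld, p_threshold, r2_threshold, window_kb)
    keep = iset.fstats >= f_min
    return InstrumentSet([p for p, k in zip(iset.pairs, keep) if k],
                         p_threshold, r2_threshold, window_kb,
                         iset.fstats[keep])
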
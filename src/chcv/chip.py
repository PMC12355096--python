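"""CHIP post-calling filter cascade.

Candidate somatic variants with read evidence are judged by, in order:
whitelist match, sequencing-depth rules (DP >= 20, alt AD >= 5, at least one
alt-supporting read pair in each of the F1R2/F2R1 orientations),
a homopolymer rule (sites inside or immediately adjacent to a run of five
identical reference bases are removed when AD < 10 or VAF < 0.08), removal
of three named recurrent artifacts, an exact binomial test excluding
germline-like missense variants in CBL/TET2/DNMT3A/TP53 (removed when the
two-sided p against VAF = 0.5 is >= 0.01, with three catalytic TET2 sites
exempt), and finally a cohort-recurrence filter: variants carried by more
than 20 individuals are kept only if associated with age or with TERT
rs7705526 dosage at p <= 0.1.

Every per-variant rule depends only on the variant record itself, so the
verdicts commute and the audit trail lists all failed rules, not just the
first.  The cohort-recurrence rule is the single cohort-level step and is
applied to the survivors of the per-variant rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import PANEL_GENES
from .whitelist import Whitelist, load_default_whitelist

RULE_WHITELIST = "whitelist"
RULE_DEPTH_DP = "depth_dp"
RULE_DEPTH_AD = "depth_ad"
RULE_DEPTH_F1R2 = "depth_f1r2"
RULE_DEPTH_F2R1 = "depth_f2r1"
RULE_HOMOPOLYMER = "homopolymer"
RULE_ARTIFACT = "named_artifact"
RULE_BINOMIAL = "binomial_vaf"
RULE_RECURRENCE = "recurrence"

BINOMIAL_TEST_GENES = frozenset({"CBL", "TET2", "DNMT3A", "TP53"})


@dataclass
class FilterVerdict:
    """Outcome of one filter rule (or of the whole cascade) for a variant."""

    kept: bool
    failed_rules: List[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kept != (len(self.failed_rules) == 0):
            raise ValueError("kept must be equivalent to an empty failed_rules")


def _get(v, key):
    if isinstance(v, pd.Series) or isinstance(v, dict):
        return v[key]
    return getattr(v, key)


# ----------------------------------------------------------------------
# per-variant rules
# ----------------------------------------------------------------------
def match_whitelist(v, wl: Whitelist) -> bool:
    """True iff the variant matches a whitelist site entry or gene rule."""
    return wl.matches(_get(v, "gene"), _get(v, "hgvs_p"), _get(v, "consequence"))


def depth_filter(v, dp_min: int = 20, ad_min: int = 5,
                 orient_min: int = 1) -> FilterVerdict:
    """Sequencing-depth rules: DP >= 20, AD >= 5, F1R2 >= 1 and F2R1 >= 1."""
    dp, ad = int(_get(v, "dp")), int(_get(v, "ad"))
    f1, f2 = int(_get(v, "f1r2")), int(_get(v, "f2r1"))
    if ad > dp:
        raise ValueError(f"alt depth {ad} exceeds total depth {dp}")
    if f1 + f2 > ad:
        raise ValueError("orientation depths exceed alt depth")
    failed = []
    if dp < dp_min:
        failed.append(RULE_DEPTH_DP)
    if ad < ad_min:
        failed.append(RULE_DEPTH_AD)
    if f1 < orient_min:
        failed.append(RULE_DEPTH_F1R2)
    if f2 < orient_min:
        failed.append(RULE_DEPTH_F2R1)
    return FilterVerdict(kept=not failed, failed_rules=failed,
                         details={"dp": dp, "ad": ad, "f1r2": f1, "f2r1": f2})


def _homopolymer_applicable(context: str, min_run: int) -> bool:
    """Whether the center base sits inside or adjacent to a >=min_run run."""
    if context is None or len(context) < 11 or len(context) % 2 == 0:
        raise ValueError("context must cover the position +/-5 bases "
                         "(odd length >= 11)")
    c = len(context) // 2
    i = 0
    while i < len(context):
        j = i
        while j < len(context) and context[j] == context[i]:
            j += 1
        if j - i >= min_run and (i - 1) <= c <= j:
            return True
        i = j
    return False


def homopolymer_filter(v, min_run: int = 5, ad_min: int = 10,
                       vaf_min: float = 0.08) -> FilterVerdict:
    """Remove homopolymer-run sites with AD < 10 or VAF < 0.08."""
    context = _get(v, "context")
    applicable = _homopolymer_applicable(context, min_run)
    details = {"homopolymer": applicable}
    if not applicable:
        return FilterVerdict(kept=True, details=details)
    ad, vaf = int(_get(v, "ad")), float(_get(v, "vaf"))
    removed = ad < ad_min or vaf < vaf_min
    return FilterVerdict(kept=not removed,
                         failed_rules=[RULE_HOMOPOLYMER] if removed else [],
                         details=details)


def named_artifact_filter(v, wl: Optional[Whitelist] = None,
                          scope: str = "g646fs") -> FilterVerdict:
    """Remove recurrent technical artifacts.

    ``scope='g646fs'`` (default): TP53 p.P72R and ASXL1 p.P815L removed
    unconditionally, ASXL1 p.G646Wfs*12 only when VAF < 0.1 (it is a genuine
    hotspot at larger clone sizes).  ``scope='all'``: the VAF < 0.1 clause
    applies to all three.
    """
    wl = wl or load_default_whitelist()
    key = (_get(v, "gene"), _get(v, "hgvs_p"))
    vaf = float(_get(v, "vaf"))
    removed = False
    if key in wl.artifacts_unconditional:
        removed = True if scope == "g646fs" else vaf < 0.1
    elif key in wl.artifacts_vaf_conditional:
        removed = vaf < 0.1
    return FilterVerdict(kept=not removed,
                         failed_rules=[RULE_ARTIFACT] if removed else [],
                         details={"artifact": removed})


def binomial_p_half(ad: int, dp: int) -> float:
    """Exact two-sided binomial p-value of ad/dp against VAF = 0.5.

    The null is symmetric, so the two-sided p equals twice the smaller tail,
    capped at 1.
    """
    if dp <= 0:
        raise ValueError("dp must be positive for the binomial test")
    m = min(ad, dp - ad)
    return float(min(1.0, 2.0 * stats.binom.cdf(m, dp, 0.5)))


def binomial_somatic_test(v, wl: Optional[Whitelist] = None,
                          alpha: float = 0.01) -> FilterVerdict:
    """Exclude germline-like missense variants in CBL/TET2/DNMT3A/TP53.

    Applies only to non-exempt missense variants in those genes; removed
    when the exact two-sided p against VAF = 0.5 is >= alpha (default 0.01),
    i.e. when the read support is indistinguishable from a heterozygous
    germline variant.
    """
    wl = wl or load_default_whitelist()
    gene, hgvs = _get(v, "gene"), _get(v, "hgvs_p")
    tested = (_get(v, "consequence") == "missense"
              and gene in BINOMIAL_TEST_GENES
              and (gene, hgvs) not in wl.binomial_exempt)
    if not tested:
        return FilterVerdict(kept=True, details={"tested": False})
    p = binomial_p_half(int(_get(v, "ad")), int(_get(v, "dp")))
    removed = p >= alpha
    return FilterVerdict(kept=not removed,
                         failed_rules=[RULE_BINOMIAL] if removed else [],
                         details={"tested": True, "p": p})


# ----------------------------------------------------------------------
# cohort-level recurrence rule
# ----------------------------------------------------------------------
def _assoc_p(y: np.ndarray, x: np.ndarray) -> Tuple[float, str]:
    """Wald p for the slope of a univariate logistic fit, with a Fisher
    fallback on dichotomized x when the fit separates or fails."""
    import statsmodels.api as sm
    X = sm.add_constant(np.asarray(x, dtype=float))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        p = float(res.pvalues[1])
        if np.isfinite(p) and np.isfinite(res.bse[1]):
            return p, "logistic"
    except Exception:
        pass
    hi = x > np.median(x)
    table = np.array([[int(((y == 1) & hi).sum()), int(((y == 1) & ~hi).sum())],
                      [int(((y == 0) & hi).sum()), int(((y == 0) & ~hi).sum())]])
    return float(stats.fisher_exact(table)[1]), "fisher"


def recurrence_filter(variant_key, carriers: Iterable[str],
                      phenotypes: pd.DataFrame,
                      combine: str = "either", threshold: int = 20,
                      p_cut: float = 0.1) -> FilterVerdict:
    """Test recurrent variants (> threshold carriers) for age/TERT association.

    Kept without testing when carried by <= threshold individuals; otherwise
    kept iff associated with age or with TERT rs7705526 dosage at
    p <= p_cut (``combine='either'``; ``'both'`` requires both tests).
    """
    carriers = set(carriers)
    details = {"key": variant_key, "n_carriers": len(carriers), "tested": False}
    if len(carriers) <= threshold:
        return FilterVerdict(kept=True, details=details)
    y = phenotypes["participant_id"].isin(carriers).to_numpy(dtype=int)
    p_age, m_age = _assoc_p(y, phenotypes["age_baseline"].to_numpy(float))
    p_tert, m_tert = _assoc_p(y, phenotypes["tert_dosage"].to_numpy(float))
    details.update(tested=True, p_age=p_age, p_tert=p_tert,
                   method_age=m_age, method_tert=m_tert)
    if combine == "either":
        kept = min(p_age, p_tert) <= p_cut
    elif combine == "both":
        kept = max(p_age, p_tert) <= p_cut
    else:
        raise ValueError("combine must be 'either' or 'both'")
    return FilterVerdict(kept=kept,
                         failed_rules=[] if kept else [RULE_RECURRENCE],
                         details=details)


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------
class ChipCaller(BaseEstimator):
    """Apply the CHIP filter cascade and aggregate per-participant status.

    ``fit(X, phenotypes)`` evaluates every rule on the candidate variant
    table ``X``, learns which recurrent variants the cohort-level rule
    drops, and exposes ``calls_`` (surviving variants), ``status_``
    (per-participant ChipStatus rows for every phenotype participant),
    ``audit_`` (one row per removed variant listing all failed rules) and
    ``dropped_recurrent_``.  ``transform(X)`` applies the per-variant rules
    plus the learned recurrent drop set to new records.
    """

    def __init__(self, whitelist: Optional[Whitelist] = None,
                 artifact_vaf_scope: str = "g646fs",
                 recurrence_combine: str = "either",
                 binomial_alpha: float = 0.01,
                 recurrence_threshold: int = 20,
                 recurrence_p: float = 0.1,
                 expanded_vaf: float = 0.10,
                 dp_min: int = 20, ad_min: int = 5, orient_min: int = 1,
                 homopolymer_run: int = 5, homopolymer_ad: int = 10,
                 homopolymer_vaf: float = 0.08,
                 fasta: Optional[str] = None):
        self.whitelist = whitelist
        self.artifact_vaf_scope = artifact_vaf_scope
        self.recurrence_combine = recurrence_combine
        self.binomial_alpha = binomial_alpha
        self.recurrence_threshold = recurrence_threshold
        self.recurrence_p = recurrence_p
        self.expanded_vaf = expanded_vaf
        self.dp_min = dp_min
        self.ad_min = ad_min
        self.orient_min = orient_min
        self.homopolymer_run = homopolymer_run
        self.homopolymer_ad = homopolymer_ad
        self.homopolymer_vaf = homopolymer_vaf
        self.fasta = fasta

    # -----------------------------------------------------------------
    def _wl(self) -> Whitelist:
        return self.whitelist if self.whitelist is not None \
            else load_default_whitelist()

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.copy()
        dup = X.duplicated(subset=["participant_id", "gene", "hgvs_p"])
        if dup.any():
            raise ValueError(
                f"duplicate (participant, variant) records: "
                f"{X.loc[dup, ['participant_id', 'gene', 'hgvs_p']].values[:5]}")
        bad_gene = ~X["gene"].isin(PANEL_GENES)
        if bad_gene.any():
            raise ValueError(
                f"genes outside the 11-gene panel: "
                f"{sorted(X.loc[bad_gene, 'gene'].unique())}")
        if (X["ad"] > X["dp"]).any():
            raise ValueError("alt depth exceeds total depth in input records")
        if ((X["f1r2"] + X["f2r1"]) > X["ad"]).any():
            raise ValueError("orientation depths exceed alt depth")
        if "vaf" not in X.columns or X["vaf"].isna().any():
            X["vaf"] = X["ad"] / X["dp"]
        if (X["context"].isna().any()) and self.fasta is not None:
            import pyfaidx
            fa = pyfaidx.Fasta(str(self.fasta))
            need = X["context"].isna()
            X.loc[need, "context"] = [
                str(fa[c][p - 6:p + 5]).upper()
                for c, p in zip(X.loc[need, "chrom"], X.loc[need, "pos"])]
        return X

    def _rule_matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        """Boolean failure matrix, one column per per-variant rule."""
        wl = self._wl()
        n = len(X)
        fails = pd.DataFrame(index=X.index)

        key = list(zip(X["gene"], X["hgvs_p"], X["consequence"]))
        wl_cache = {k: not wl.matches(*k) for k in set(key)}
        fails[RULE_WHITELIST] = [wl_cache[k] for k in key]

        fails[RULE_DEPTH_DP] = X["dp"] < self.dp_min
        fails[RULE_DEPTH_AD] = X["ad"] < self.ad_min
        fails[RULE_DEPTH_F1R2] = X["f1r2"] < self.orient_min
        fails[RULE_DEPTH_F2R1] = X["f2r1"] < self.orient_min

        ctx_cache = {c: _homopolymer_applicable(c, self.homopolymer_run)
                     for c in X["context"].unique()}
        applicable = X["context"].map(ctx_cache)
        fails[RULE_HOMOPOLYMER] = applicable & (
            (X["ad"] < self.homopolymer_ad) | (X["vaf"] < self.homopolymer_vaf))

        site = list(zip(X["gene"], X["hgvs_p"]))
        uncond = pd.Series([s in wl.artifacts_unconditional for s in site],
                           index=X.index)
        cond = pd.Series([s in wl.artifacts_vaf_conditional for s in site],
                         index=X.index)
        if self.artifact_vaf_scope == "g646fs":
            fails[RULE_ARTIFACT] = uncond | (cond & (X["vaf"] < 0.1))
        elif self.artifact_vaf_scope == "all":
            fails[RULE_ARTIFACT] = (uncond | cond) & (X["vaf"] < 0.1)
        else:
            raise ValueError("artifact_vaf_scope must be 'g646fs' or 'all'")

        exempt = pd.Series([s in wl.binomial_exempt for s in site], index=X.index)
        tested = (X["consequence"].eq("missense")
                  & X["gene"].isin(BINOMIAL_TEST_GENES) & ~exempt)
        p = pd.Series(np.nan, index=X.index)
        if tested.any():
            m = np.minimum(X.loc[tested, "ad"], X.loc[tested, "dp"] - X.loc[tested, "ad"])
            p[tested] = np.minimum(
                1.0, 2.0 * stats.binom.cdf(m, X.loc[tested, "dp"], 0.5))
        fails[RULE_BINOMIAL] = tested & (p >= self.binomial_alpha)
        fails.attrs["binomial_p"] = p
        assert len(fails) == n
        return fails

    # -----------------------------------------------------------------
    def fit(self, X: pd.DataFrame, phenotypes: pd.DataFrame) -> "ChipCaller":
        X = self._validate(X)
        fails = self._rule_matrix(X)
        per_variant_kept = ~fails.any(axis=1)
        surv = X[per_variant_kept]

        dropped_recurrent = set()
        recurrence_details = {}
        for k, grp in surv.groupby(["gene", "hgvs_p"], sort=True):
            verdict = recurrence_filter(
                k, grp["participant_id"], phenotypes,
                combine=self.recurrence_combine,
                threshold=self.recurrence_threshold, p_cut=self.recurrence_p)
            recurrence_details[k] = verdict.details
            if not verdict.kept:
                dropped_recurrent.add(k)

        rec_fail = pd.Series(
            [(g, h) in dropped_recurrent for g, h in zip(X["gene"], X["hgvs_p"])],
            index=X.index) & per_variant_kept
        fails[RULE_RECURRENCE] = rec_fail
        kept = per_variant_kept & ~rec_fail

        self.dropped_recurrent_ = dropped_recurrent
        self.recurrence_details_ = recurrence_details
        self.calls_ = X[kept].reset_index(drop=True)
        audit = X.loc[~kept, ["participant_id", "gene", "hgvs_p", "vaf"]].copy()
        audit["failed_rules"] = [
            ";".join(c for c in fails.columns if fails.at[i, c])
            for i in audit.index]
        bp = fails.attrs["binomial_p"]
        audit["binomial_p"] = bp[audit.index]
        self.audit_ = audit.reset_index(drop=True)
        self.rule_failures_ = fails
        self.status_ = self._aggregate(self.calls_, phenotypes)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Kept calls for new records, using the learned recurrent drop set."""
        X = self._validate(X)
        fails = self._rule_matrix(X)
        kept = ~fails.any(axis=1)
        dropped = getattr(self, "dropped_recurrent_", set())
        rec = pd.Series([(g, h) in dropped
                         for g, h in zip(X["gene"], X["hgvs_p"])], index=X.index)
        return X[kept & ~rec].reset_index(drop=True)

    def fit_transform(self, X: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X, phenotypes).calls_

    def _aggregate(self, calls: pd.DataFrame,
                   phenotypes: pd.DataFrame) -> pd.DataFrame:
        pids = phenotypes["participant_id"]
        if len(calls):
            g = calls.groupby("participant_id")
            agg = pd.DataFrame({
                "n_mutations": g.size(),
                "genes": g["gene"].apply(lambda s: ",".join(sorted(set(s)))),
                "max_vaf": g["vaf"].max(),
            })
        else:
            agg = pd.DataFrame(columns=["n_mutations", "genes", "max_vaf"])
        status = pd.DataFrame({"participant_id": pids}).set_index("participant_id")
        status = status.join(agg)
        status["n_mutations"] = pd.to_numeric(
            status["n_mutations"], errors="coerce").fillna(0).astype(int)
        status["genes"] = status["genes"].fillna("")
        status["max_vaf"] = pd.to_numeric(
            status["max_vaf"], errors="coerce").fillna(0.0)
        status["carrier"] = status["n_mutations"] >= 1
        status["expanded"] = status["carrier"] & (status["max_vaf"] >= self.expanded_vaf)
        status["mutation_count_class"] = np.select(
            [status["n_mutations"] == 0, status["n_mutations"] == 1,
             status["n_mutations"] == 2],
            ["0", "1", "2"], default="3+")
        return status.reset_index()


def call_chip(evidence: pd.DataFrame, wl: Optional[Whitelist] = None,
              phenotypes: Optional[pd.DataFrame] = None, **params):
    """Run the full cascade; returns (status, calls, audit) DataFrames."""
    if phenotypes is None:
        raise ValueError("phenotypes table (age, TERT dosage) is required "
                         "for the recurrence filter")
    caller = ChipCaller(whitelist=wl, **params).fit(evidence, phenotypes)
    return caller.status_, caller.calls_, caller.audit_
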
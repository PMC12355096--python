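"""Logistic-regression prevalence analyses.

Who carries CHIP and mCAs: maximum-likelihood logistic fits with Wald
confidence intervals, adjusted for age at baseline and sex — except for
LOY/LOX models, which run on the sex-restricted subset (men for LOY, women
for LOX) with no sex covariate.  Also provides gene-level carrier
proportion comparisons between strata (e.g. PPM1D among chemotherapy-
exposed vs unexposed carriers) by Pearson chi-squared with continuity
correction, falling back to Fisher's exact test for sparse tables.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .design import expand_terms

SEX_RESTRICTED = {"loy": "M", "lox": "F"}
Z95 = stats.norm.ppf(0.975)


class PrevalenceLogit(BaseEstimator):
    """Logistic prevalence model with odds-ratio reporting.

    Parameters name the binary outcome column, the predictor terms of
    interest, and the adjustment covariates.  After ``fit(df)``,
    ``or_table_`` holds one row per non-intercept term with the point OR,
    Wald CI, p-value and the sample size used.
    """

    def __init__(self, outcome: str = "chip",
                 predictors: Sequence[str] = ("age_baseline",),
                 adjust: Sequence[str] = ("age_baseline", "sex"),
                 level: float = 0.95, min_rows: int = 50):
        self.outcome = outcome
        self.predictors = predictors
        self.adjust = adjust
        self.level = level
        self.min_rows = min_rows

    def fit(self, df: pd.DataFrame, y=None) -> "PrevalenceLogit":
        outcome = self.outcome
        terms = list(dict.fromkeys(list(self.predictors) + list(self.adjust)))

        work = df
        restricted = None
        for t in [outcome] + terms:
            if t in SEX_RESTRICTED:
                restricted = SEX_RESTRICTED[t]
        if restricted is not None:
            work = work[work["sex"] == restricted]
            terms = [t for t in terms if t != "sex"]
        self.sex_restricted_to_ = restricted

        X, names = expand_terms(work, terms)
        yv = work.loc[X.index, outcome].astype(float)
        keep = yv.notna()
        X, yv = X[keep], yv[keep]
        if len(X) < self.min_rows:
            raise ValueError(
                f"only {len(X)} complete-case rows (< {self.min_rows})")
        if yv.nunique() < 2:
            raise ValueError(f"outcome {outcome!r} has an empty cell")

        Xc = sm.add_constant(X, prepend=True)
        flag = ""
        with np.errstate(all="ignore"):
            try:
                res = sm.Logit(yv, Xc).fit(disp=0, maxiter=200)
            except Exception as exc:  # separation / non-convergence
                raise ValueError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.bse)):
            flag = "separation"

        z = stats.norm.ppf(0.5 + self.level / 2)
        rows = []
        for name in names:
            b, se, p = res.params[name], res.bse[name], res.pvalues[name]
            rows.append({
                "term": name,
                "or_point": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "p": float(p),
                "n_used": int(len(X)),
                "covariates": ",".join(n for n in names if n != name),
                "flag": flag,
            })
        self.result_ = res
        self.or_table_ = pd.DataFrame(rows)
        self.n_used_ = int(len(X))
        return self


def fit_prevalence_model(table: pd.DataFrame, outcome: str,
                         predictors: Sequence[str],
                         adjust: Sequence[str] = ("age_baseline", "sex"),
                         level: float = 0.95) -> pd.DataFrame:
    """Fit a prevalence model and return the odds-ratio table."""
    model = PrevalenceLogit(outcome=outcome, predictors=predictors,
                            adjust=adjust, level=level)
    return model.fit(table).or_table_


def compare_gene_proportions(chip_calls: pd.DataFrame,
                             stratifier: pd.Series,
                             gene: str) -> Tuple[float, float, float]:
    """Compare the share of CHIP carriers mutated in ``gene`` across strata.

    ``stratifier`` is a binary series indexed by participant_id (e.g.
    chemotherapy exposure).  Returns (proportion in stratum 1, proportion in
    stratum 0, p).  Pearson chi-squared with continuity correction; Fisher's
    exact test when any expected cell is < 5 or a stratum is degenerate.
    """
    carriers = chip_calls.groupby("participant_id")["gene"] \
        .apply(lambda g: gene in set(g))
    strat = stratifier.reindex(carriers.index)
    ok = strat.notna()
    carriers, strat = carriers[ok], strat[ok].astype(int)
    n1, n0 = int((strat == 1).sum()), int((strat == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("a stratum contains no CHIP carriers")
    k1 = int(carriers[strat == 1].sum())
    k0 = int(carriers[strat == 0].sum())
    table = np.array([[k1, n1 - k1], [k0, n0 - k0]])
    expected = stats.contingency.expected_freq(table) \
        if table.min() >= 0 else None
    if expected is None or (expected < 5).any() or (table.sum(axis=1) == 0).any():
        p = float(stats.fisher_exact(table)[1])
    else:
        p = float(stats.chi2_contingency(table, correction=True)[1])
    return k1 / n1, k0 / n0, p
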
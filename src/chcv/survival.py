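"""Cox proportional-hazards models and CHIP-by-mCA interaction metrics.

The four-category clonal hematopoiesis exposure (no CH / CHIP & mCA /
CHIP only / mCA only) enters a Cox partial-likelihood fit with Breslow tie
handling; from the three adjusted hazard ratios (h11 for both exposures,
h10 for CHIP only, h01 for mCA only, each vs no CH) the interaction
metrics are:

    RERI = h11 - h10 - h01 + 1        (relative excess risk due to interaction)
    AP   = RERI / h11                 (attributable proportion)
    ratio = h11 / (h10 * h01)         (multiplicative interaction; this is
                                       the quantity reported as "SI" in the
                                       source tables and it equals
                                       exp(beta) of the product-term Cox
                                       parameterization)
    classical SI = (h11 - 1) / ((h10 - 1) + (h01 - 1))
                                      (Rothman's synergy index, provided
                                       separately because the conventional
                                       meaning of "SI" differs from the
                                       multiplicative ratio)

Confidence intervals propagate the coefficient covariance through each
metric's gradient (delta method, on the natural scale, matching the
symmetric intervals of the source tables) or bootstrap participants with
replacement.  The product-term coefficient is computed as the exact linear
contrast b11 - b10 - b01 of the four-category fit: both parameterizations
span the same column space, so this is an exact reparameterization rather
than a refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.duration.hazard_regression import PHReg

from .config import ENDPOINTS
from .design import expand_terms

DEFAULT_COVARIATES = (
    "age_baseline", "sex", "smoking", "chemo", "radio", "prevalent_cvd",
    "delay_days", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "pc7", "pc8",
    "pc9", "pc10",
)

PAIRS = {
    "chip_x_mca": ("chip", "any_mca", None),
    "chip_x_loy": ("chip", "loy", "M"),
    "chip_x_lox": ("chip", "lox", "F"),
    "expanded_chip_x_mca": ("chip_expanded", "any_mca", None),
    "chip_x_expanded_mca": ("chip", "mca_expanded", None),
}


class NotReportableError(ValueError):
    """An exposure cell has no events; metrics are not reportable."""


@dataclass
class CoxResult:
    terms: List[str]
    beta: np.ndarray
    vcov: np.ndarray
    summary: pd.DataFrame
    n: int
    n_events: int
    exposure_terms: List[str] = field(default_factory=list)

    def beta_of(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def sub_vcov(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.terms.index(t) for t in names]
        return self.vcov[np.ix_(idx, idx)]


@dataclass
class InteractionMetrics:
    h11: float
    h10: float
    h01: float
    reri: float
    ap: float
    mult_ratio: float
    classical_si: Optional[float]
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    ci_method: str = "delta"
    not_reportable: List[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# interaction arithmetic
# ----------------------------------------------------------------------
def _check_hrs(*hrs: float) -> None:
    for h in hrs:
        if not h > 0:
            raise ValueError(f"hazard ratios must be positive, got {h}")


def compute_reri(h11: float, h10: float, h01: float) -> float:
    """Relative excess risk due to interaction: h11 - h10 - h01 + 1."""
    _check_hrs(h11, h10, h01)
    return h11 - h10 - h01 + 1.0


def compute_ap(reri: float, h11: float) -> float:
    """Attributable proportion: the share of the joint-exposure risk that
    is due to interaction, RERI / h11."""
    if not h11 > 0:
        raise ValueError(f"h11 must be positive, got {h11}")
    return reri / h11


def compute_mult_ratio(h11: float, h10: float, h01: float) -> float:
    """Multiplicative interaction ratio h11 / (h10 * h01).

    Equals exp(beta) of the interaction term in the product-term Cox
    parameterization; reported as "SI" in the source tables.
    """
    _check_hrs(h11, h10, h01)
    return h11 / (h10 * h01)


def compute_classical_si(h11: float, h10: float, h01: float) -> Optional[float]:
    """Rothman's synergy index (h11-1)/((h10-1)+(h01-1)); None when the
    denominator is zero (both single-exposure excesses vanish)."""
    _check_hrs(h11, h10, h01)
    denom = (h10 - 1.0) + (h01 - 1.0)
    if denom == 0.0:
        return None
    return (h11 - 1.0) / denom


# ----------------------------------------------------------------------
# Cox fitting
# ----------------------------------------------------------------------
def _exposure_design(df: pd.DataFrame, exposure) -> Tuple[pd.DataFrame, List[str]]:
    if exposure == "chip":
        return df[["chip"]].astype(float), ["chip"]
    if exposure == "ch4":
        cols = pd.DataFrame({
            "ch_both": (df["exposure4"] == "both").astype(float),
            "ch_chip_only": (df["exposure4"] == "chip_only").astype(float),
            "ch_mca_only": (df["exposure4"] == "mca_only").astype(float),
        }, index=df.index)
        return cols, list(cols.columns)
    if exposure == "mutation_count":
        cols = pd.DataFrame({
            f"chip_muts_{lvl}": (df["mutation_count_class"] == lvl).astype(float)
            for lvl in ("1", "2", "3+")
        }, index=df.index)
        return cols, list(cols.columns)
    if exposure == "expanded_chip":
        return df[["chip_expanded"]].astype(float), ["chip_expanded"]
    if isinstance(exposure, tuple) and exposure[0] == "pair":
        _, a, b = exposure
        av, bv = df[a].astype(bool), df[b].astype(bool)
        cols = pd.DataFrame({
            "ch_both": (av & bv).astype(float),
            f"{a}_only": (av & ~bv).astype(float),
            f"{b}_only": (~av & bv).astype(float),
        }, index=df.index)
        return cols, list(cols.columns)
    if isinstance(exposure, (list, tuple)):
        return df[list(exposure)].astype(float), list(exposure)
    raise ValueError(f"unknown exposure spec {exposure!r}")


def fit_cox(table: pd.DataFrame, endpoint: str,
            exposure: Union[str, tuple, Sequence[str]] = "chip",
            covariates: Sequence[str] = DEFAULT_COVARIATES,
            min_events: int = 10) -> CoxResult:
    """Cox partial-likelihood fit (Breslow ties) for one endpoint.

    ``exposure`` is one of ``'chip'``, ``'ch4'``, ``'mutation_count'``,
    ``'expanded_chip'``, ``('pair', a_col, b_col)`` (four categories from
    two binary exposures) or an explicit list of numeric columns.  Raises
    :class:`NotReportableError` naming the category when an exposure cell
    has no events, and ``ValueError`` when there are fewer than
    ``min_events`` events overall.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"

    expo, expo_names = _exposure_design(table, exposure)
    cov, cov_names = expand_terms(table, covariates) if covariates else \
        (pd.DataFrame(index=table.index), [])
    idx = expo.index.intersection(cov.index) if covariates else expo.index
    X = pd.concat([expo.loc[idx], cov.loc[idx]], axis=1)
    y = table.loc[idx, tcol].astype(float)
    status = table.loc[idx, ecol].astype(int)
    ok = y.notna() & (y > 0)
    X, y, status = X[ok], y[ok], status[ok]

    n_events = int(status.sum())
    if n_events < min_events:
        raise ValueError(f"only {n_events} events for {endpoint} "
                         f"(< {min_events})")
    for name in expo_names:
        cell = X[name] == 1.0
        if cell.any() and status[cell].sum() == 0:
            raise NotReportableError(
                f"no {endpoint} events in exposure category {name!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(y.to_numpy(), X.to_numpy(), status=status.to_numpy(),
                      ties="breslow")
        res = model.fit(disp=0)
    beta = np.asarray(res.params)
    vcov = np.asarray(res.cov_params())
    se = np.sqrt(np.diag(vcov))
    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame({
        "term": list(X.columns),
        "beta": beta,
        "se": se,
        "hr": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "p": 2 * stats.norm.sf(np.abs(beta / se)),
    })
    return CoxResult(terms=list(X.columns), beta=beta, vcov=vcov,
                     summary=summary, n=int(len(X)), n_events=n_events,
                     exposure_terms=expo_names)


# ----------------------------------------------------------------------
# confidence intervals for the interaction metrics
# ----------------------------------------------------------------------
def _metric_and_gradient(metric: str, b: np.ndarray) -> Tuple[float, np.ndarray]:
    """Value and gradient in beta-space; b = (b11, b10, b01)."""
    e11, e10, e01 = np.exp(b)
    if metric == "reri":
        return e11 - e10 - e01 + 1.0, np.array([e11, -e10, -e01])
    if metric == "ap":
        val = (e11 - e10 - e01 + 1.0) / e11
        grad = np.array([(e10 + e01 - 1.0) / e11, -e10 / e11, -e01 / e11])
        return val, grad
    if metric == "mult_ratio":
        r = e11 / (e10 * e01)
        return r, r * np.array([1.0, -1.0, -1.0])
    if metric == "classical_si":
        denom = (e10 - 1.0) + (e01 - 1.0)
        if denom == 0.0:
            raise ZeroDivisionError("classical SI undefined: zero denominator")
        val = (e11 - 1.0) / denom
        grad = np.array([e11 / denom,
                         -(e11 - 1.0) * e10 / denom ** 2,
                         -(e11 - 1.0) * e01 / denom ** 2])
        return val, grad
    raise ValueError(f"unknown metric {metric!r}")


def interaction_ci(cox: CoxResult, metric: str, method: str = "delta",
                   level: float = 0.95,
                   data: Optional[pd.DataFrame] = None,
                   refit: Optional[Callable[[pd.DataFrame], CoxResult]] = None,
                   n_boot: int = 1000, seed: int = 0) -> Tuple[float, float]:
    """CI for an interaction metric from the Cox fit.

    ``method='delta'`` propagates the coefficient covariance through the
    metric's gradient; ``method='bootstrap'`` resamples participants with
    replacement (requires ``data`` and a ``refit`` callable).  A singular
    covariance falls back to the bootstrap with a warning when possible.
    """
    names = cox.exposure_terms
    if len(names) != 3:
        raise ValueError("interaction CIs need the three-category exposure fit")
    b = np.array([cox.beta_of(t) for t in names])
    V = cox.sub_vcov(names)
    z = stats.norm.ppf(0.5 + level / 2)

    if method == "delta":
        eig = np.linalg.eigvalsh(V)
        if not np.all(np.isfinite(V)) or eig.min() < -1e-10:
            if data is not None and refit is not None:
                warnings.warn("singular covariance; falling back to bootstrap")
                method = "bootstrap"
            else:
                raise np.linalg.LinAlgError(
                    "singular coefficient covariance and no bootstrap fallback")
        if method == "delta":
            val, grad = _metric_and_gradient(metric, b)
            var = float(grad @ V @ grad)
            half = z * np.sqrt(max(var, 0.0))
            return val - half, val + half

    if method == "bootstrap":
        if data is None or refit is None:
            raise ValueError("bootstrap CIs need data and a refit callable")
        rng = np.random.default_rng(seed)
        vals = []
        n = len(data)
        for _ in range(n_boot):
            sample = data.iloc[rng.integers(0, n, n)]
            try:
                bres = refit(sample)
                bb = np.array([bres.beta_of(t) for t in bres.exposure_terms])
                vals.append(_metric_and_gradient(metric, bb)[0])
            except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
                continue
        if len(vals) < max(50, n_boot // 4):
            raise RuntimeError("too few successful bootstrap replicates")
        lo, hi = np.quantile(vals, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi)

    raise ValueError("method must be 'delta' or 'bootstrap'")


def interaction_term(cox: CoxResult) -> Dict[str, float]:
    """Product-term interaction coefficient as an exact linear contrast.

    In the product parameterization (a, b, a*b) the interaction coefficient
    equals b11 - b10 - b01 of the four-category fit; its variance follows
    from the same contrast of the covariance.
    """
    names = cox.exposure_terms
    b = np.array([cox.beta_of(t) for t in names])
    V = cox.sub_vcov(names)
    c = np.array([1.0, -1.0, -1.0])
    beta_int = float(c @ b)
    se = float(np.sqrt(c @ V @ c))
    z95 = stats.norm.ppf(0.975)
    return {
        "beta": beta_int,
        "se": se,
        "hr": float(np.exp(beta_int)),
        "ci_low": float(np.exp(beta_int - z95 * se)),
        "ci_high": float(np.exp(beta_int + z95 * se)),
        "p": float(2 * stats.norm.sf(abs(beta_int / se))),
    }


# ----------------------------------------------------------------------
# estimator and report
# ----------------------------------------------------------------------
class CoxInteraction(BaseEstimator):
    """Four-category CH exposure Cox fit with interaction metrics.

    ``pair`` picks the exposure pairing: CHIP x any mCA, CHIP x LOY (fit in
    men only), CHIP x LOX (women only), expanded CHIP x mCA (non-expanded
    CHIP carriers excluded) or CHIP x expanded mCA (non-expanded mCA
    carriers excluded).  After ``fit(table)``, ``cox_`` holds the
    :class:`CoxResult`, ``metrics_`` the :class:`InteractionMetrics` with
    CIs, and ``interaction_`` the product-term contrast.
    """

    def __init__(self, endpoint: str = "any_death", pair: str = "chip_x_mca",
                 covariates: Optional[Sequence[str]] = None,
                 ci_method: str = "delta", level: float = 0.95,
                 n_boot: int = 1000, seed: int = 0):
        self.endpoint = endpoint
        self.pair = pair
        self.covariates = covariates
        self.ci_method = ci_method
        self.level = level
        self.n_boot = n_boot
        self.seed = seed

    def _subset_and_exposure(self, table: pd.DataFrame):
        if self.pair not in PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}; "
                             f"choose from {sorted(PAIRS)}")
        a, b, sex = PAIRS[self.pair]
        df = table
        covs = list(self.covariates) if self.covariates is not None \
            else list(DEFAULT_COVARIATES)
        if sex is not None:
            df = df[df["sex"] == sex]
            covs = [c for c in covs if c != "sex"]
        if a == "chip_expanded":
            df = df[~(df["chip"] & ~df["chip_expanded"])]
        if b == "mca_expanded":
            df = df[~(df["any_mca"] & ~df["mca_expanded"])]
        return df, ("pair", a, b), covs

    def fit(self, table: pd.DataFrame, y=None) -> "CoxInteraction":
        df, exposure, covs = self._subset_and_exposure(table)
        self.n_input_ = len(df)
        self.cox_ = fit_cox(df, self.endpoint, exposure=exposure,
                            covariates=covs)
        names = self.cox_.exposure_terms
        h11, h10, h01 = (float(np.exp(self.cox_.beta_of(t))) for t in names)
        reri = compute_reri(h11, h10, h01)
        ap = compute_ap(reri, h11)
        ratio = compute_mult_ratio(h11, h10, h01)
        si = compute_classical_si(h11, h10, h01)

        def refit(sample: pd.DataFrame) -> CoxResult:
            return fit_cox(sample, self.endpoint, exposure=exposure,
                           covariates=covs)

        ci = {}
        nr = []
        for metric in ("reri", "ap", "mult_ratio", "classical_si"):
            if metric == "classical_si" and si is None:
                nr.append(metric)
                continue
            try:
                ci[metric] = interaction_ci(
                    self.cox_, metric, method=self.ci_method, level=self.level,
                    data=df, refit=refit, n_boot=self.n_boot, seed=self.seed)
            except (ZeroDivisionError, np.linalg.LinAlgError, RuntimeError):
                nr.append(metric)
        self.metrics_ = InteractionMetrics(
            h11=h11, h10=h10, h01=h01, reri=reri, ap=ap, mult_ratio=ratio,
            classical_si=si, ci=ci, ci_method=self.ci_method,
            not_reportable=nr)
        self.interaction_ = interaction_term(self.cox_)
        return self


def run_interaction_analysis(table: pd.DataFrame,
                             endpoints: Sequence[str] = ENDPOINTS,
                             pair: str = "chip_x_mca",
                             covariates: Optional[Sequence[str]] = None,
                             ci_method: str = "delta", level: float = 0.95,
                             n_boot: int = 1000, seed: int = 0) -> dict:
    """Interaction analysis across endpoints; one report entry per endpoint.

    Endpoints whose four-category fit has an exposure cell with zero events
    are marked not reportable rather than raising.
    """
    report: dict = {"pair": pair, "endpoints": {}}
    for ep in endpoints:
        model = CoxInteraction(endpoint=ep, pair=pair, covariates=covariates,
                               ci_method=ci_method, level=level,
                               n_boot=n_boot, seed=seed)
        try:
            model.fit(table)
        except NotReportableError as exc:
            report["endpoints"][ep] = {"not_reportable": True,
                                       "reason": str(exc)}
            continue
        except ValueError as exc:
            report["endpoints"][ep] = {"not_reportable": True,
                                       "reason": str(exc)}
            continue
        m = model.metrics_
        hr_rows = model.cox_.summary.set_index("term")
        entry = {
            "not_reportable": False,
            "n": model.cox_.n,
            "n_events": model.cox_.n_events,
            "hr": {t: {"hr": float(hr_rows.loc[t, "hr"]),
                       "ci_low": float(hr_rows.loc[t, "ci_low"]),
                       "ci_high": float(hr_rows.loc[t, "ci_high"]),
                       "p": float(hr_rows.loc[t, "p"])}
                   for t in model.cox_.exposure_terms},
            "interaction_term": model.interaction_,
            "metrics": {
                "h11": m.h11, "h10": m.h10, "h01": m.h01,
                "reri": m.reri, "ap": m.ap, "mult_ratio": m.mult_ratio,
                "classical_si": m.classical_si,
            },
            "ci": {k: list(v) for k, v in m.ci.items()},
            "ci_method": m.ci_method,
            "metrics_not_reportable": m.not_reportable,
        }
        report["endpoints"][ep] = entry
    return report
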
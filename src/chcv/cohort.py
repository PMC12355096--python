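"""Cohort eligibility rules and per-endpoint time-to-event construction.

Exclusions: hematologic cancers diagnosed within +/-6 months (182 days) of
study entry, genotypic-phenotypic sex discordance, and one member of each
first/second-degree relative pair, chosen by a seeded RNG on a canonically
sorted pair list so the retained set is independent of the order in which
the three rules are applied.

Time origins: for cancers diagnosed before baseline the clock starts at the
assessment visit; for cancers diagnosed after baseline it starts at the
diagnosis date.  The delay covariate is the number of days between a
prevalent cancer diagnosis and recruitment, set to 0 for incident cancers.
Follow-up for event-free participants ends at the last registered death
date in the dataset (a single administrative censoring date shared by the
whole cohort).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import ENDPOINTS

DAYS_PER_YEAR = 365.25
HEMA_WINDOW_DAYS = 182

EXCL_HEMATOLOGIC = "hematologic_cancer_within_6mo"
EXCL_SEX = "sex_discordance"
EXCL_RELATIVE = "relative_pair"


def apply_exclusions(roster: pd.DataFrame, seed: int = 0,
                     window_days: int = HEMA_WINDOW_DAYS
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three eligibility rules; returns (kept, exclusion_log).

    Relative pruning removes exactly one member per related group, chosen by
    an RNG seeded from the global seed and the group label (so the choice
    does not depend on the other exclusion rules or on row order); groups
    larger than two are pruned iteratively until no related pair remains,
    i.e. one member survives.
    """
    log_rows = []
    excluded = set()

    if "hematologic_dx_date" in roster.columns:
        delta = (roster["hematologic_dx_date"] - roster["recruit_date"]).dt.days
        hema = delta.abs() <= window_days
        for pid in roster.loc[hema.fillna(False), "participant_id"]:
            excluded.add(pid)
            log_rows.append((pid, EXCL_HEMATOLOGIC))

    if "sex_concordant" in roster.columns:
        disc = roster["sex_concordant"].astype(bool) == False  # noqa: E712
        for pid in roster.loc[disc, "participant_id"]:
            if pid not in excluded:
                excluded.add(pid)
            log_rows.append((pid, EXCL_SEX))

    if "relative_group" in roster.columns:
        groups = roster.loc[roster["relative_group"].astype(str) != "", :]
        for gid, grp in groups.groupby("relative_group"):
            members = sorted(grp["participant_id"])
            if len(members) < 2:
                continue
            rng = np.random.default_rng(
                (seed + zlib.crc32(str(gid).encode())) % (2 ** 31))
            # iterative pruning: drop random members until one remains
            while len(members) > 1:
                victim = members.pop(int(rng.integers(0, len(members))))
                if victim not in excluded:
                    excluded.add(victim)
                log_rows.append((victim, EXCL_RELATIVE))

    kept = roster[~roster["participant_id"].isin(excluded)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return kept, log


@dataclass
class EndpointRecord:
    endpoint: str
    time_years: float
    event: bool
    origin_date: pd.Timestamp


def derive_time_to_event(recruit_date, cancer_dx_date, event_date,
                         censor_date, endpoint: str = "") -> EndpointRecord:
    """Per-endpoint (time, event) from the origin rule.

    Origin is the recruitment date for prevalent cancers (dx on or before
    baseline) and the diagnosis date for incident cancers.  Raises
    ``ValueError`` when the event predates the origin (data error; callers
    drop and log such rows).
    """
    recruit = pd.Timestamp(recruit_date)
    dx = pd.Timestamp(cancer_dx_date)
    censor = pd.Timestamp(censor_date)
    origin = recruit if dx <= recruit else dx
    has_event = event_date is not None and not pd.isna(event_date)
    if has_event:
        ev = pd.Timestamp(event_date)
        if ev < origin:
            raise ValueError(
                f"event on {ev.date()} predates time origin {origin.date()}")
        event = ev <= censor
        end = min(ev, censor)
    else:
        event = False
        end = censor
    time_years = (end - origin).days / DAYS_PER_YEAR
    if time_years < 0:
        raise ValueError("censoring date precedes the time origin")
    return EndpointRecord(endpoint=endpoint, time_years=time_years,
                          event=bool(event), origin_date=origin)


def last_registered_death(pheno: pd.DataFrame) -> pd.Timestamp:
    """Administrative censoring date: the last death date in the dataset."""
    death_cols = [c for c in ("any_death_date", "cv_death_date",
                              "cad_death_date") if c in pheno.columns]
    dates = pd.concat([pheno[c] for c in death_cols]) if death_cols \
        else pd.Series(dtype="datetime64[ns]")
    dates = dates.dropna()
    if len(dates):
        return dates.max()
    # degenerate cohorts without any death: censor at the last recorded
    # event or, failing that, the last recruitment date
    all_cols = [c for c in pheno.columns if c.endswith("_date")]
    alles = pd.concat([pheno[c] for c in all_cols]).dropna()
    return alles.max()


def build_analysis_table(roster: pd.DataFrame, chip_status: pd.DataFrame,
                         mca_status: pd.DataFrame,
                         censor_date=None) -> pd.DataFrame:
    """Join exposures and covariates and derive per-endpoint (time, event).

    Returns one row per retained participant with the four-category CH
    exposure, the delay covariate, and ``time_<endpoint>`` /
    ``event_<endpoint>`` columns.  Rows whose event predates the time
    origin are dropped and recorded in ``df.attrs['dropped']``.
    """
    chip = chip_status.set_index("participant_id")
    mca = mca_status.set_index("participant_id")
    missing_chip = ~roster["participant_id"].isin(chip.index)
    missing_mca = ~roster["participant_id"].isin(mca.index)
    if missing_chip.any() or missing_mca.any():
        raise ValueError("retained participants missing CHIP or mCA status")

    df = roster.copy().set_index("participant_id")
    df["chip"] = chip["carrier"].astype(bool)
    df["chip_expanded"] = chip["expanded"].astype(bool)
    df["n_chip_mutations"] = chip["n_mutations"]
    df["mutation_count_class"] = chip["mutation_count_class"]
    df["chip_max_vaf"] = chip["max_vaf"]
    for c in ("any_mca", "loy", "lox", "autosomal"):
        df[c] = mca[c].astype(bool)
    df["mca_expanded"] = mca["expanded"].astype(bool)

    df["exposure4"] = np.select(
        [df["chip"] & df["any_mca"], df["chip"], df["any_mca"]],
        ["both", "chip_only", "mca_only"], default="no_ch")

    delay = (df["recruit_date"] - df["cancer_dx_date"]).dt.days
    df["delay_days"] = delay.clip(lower=0).fillna(0).astype(int)

    if censor_date is None:
        censor_date = last_registered_death(roster)
    censor_date = pd.Timestamp(censor_date)
    origin = df["recruit_date"].where(df["cancer_dx_date"] <= df["recruit_date"],
                                      df["cancer_dx_date"])

    bad = pd.Series(False, index=df.index)
    for ep in ENDPOINTS:
        col = f"{ep}_date"
        ev_date = df[col] if col in df.columns else pd.Series(pd.NaT, index=df.index)
        has_event = ev_date.notna() & (ev_date <= censor_date)
        end = ev_date.where(has_event, censor_date)
        t = (end - origin).dt.days / DAYS_PER_YEAR
        df[f"time_{ep}"] = t
        df[f"event_{ep}"] = has_event.astype(int)
        bad |= (ev_date.notna() & (ev_date < origin)) | (t < 0)

    dropped = df[bad].index.tolist()
    out = df[~bad].reset_index()
    out.attrs["dropped"] = dropped
    out.attrs["censor_date"] = censor_date
    return out


class CohortAssembler(BaseEstimator, TransformerMixin):
    """Exclusions + analysis-table construction as a transformer.

    ``fit`` applies the eligibility rules and derives the administrative
    censoring date; ``transform`` joins CHIP/mCA status onto the retained
    roster and emits the analysis rows.
    """

    def __init__(self, seed: int = 0, hema_window_days: int = HEMA_WINDOW_DAYS,
                 censor_date=None):
        self.seed = seed
        self.hema_window_days = hema_window_days
        self.censor_date = censor_date

    def fit(self, X: pd.DataFrame, y=None) -> "CohortAssembler":
        kept, log = apply_exclusions(X, seed=self.seed,
                                     window_days=self.hema_window_days)
        self.kept_ = kept
        self.exclusion_log_ = log
        self.censor_date_ = (pd.Timestamp(self.censor_date)
                             if self.censor_date is not None
                             else last_registered_death(kept))
        return self

    def transform(self, X=None, chip_status: Optional[pd.DataFrame] = None,
                  mca_status: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        if chip_status is None or mca_status is None:
            raise ValueError("chip_status and mca_status tables are required")
        return build_analysis_table(self.kept_, chip_status, mca_status,
                                    censor_date=self.censor_date_)
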
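"""Mosaic chromosomal alteration (mCA) classification.

Per-participant mCA call tables (chromosome, event type, cell fraction) are
collapsed into the exposure categories used throughout the analysis: any
mCA, LOY (chrY loss, evaluated in men only), LOX (chrX loss, evaluated in
women only), autosomal mCA, and expanded mCA (maximum cell fraction at or
above 10%; a strict > 10% reading is available via ``strict_expansion``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

AUTOSOMES = {str(i) for i in range(1, 23)}
EVENT_TYPES = {"loss", "gain", "cnloh"}


@dataclass
class McaStatus:
    participant_id: str
    any_mca: bool
    loy: bool
    lox: bool
    autosomal: bool
    expanded: bool
    max_cell_fraction: float


def _check_call(chrom: str, event_type: str, cell_fraction: float,
                sex: str) -> None:
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown mCA event type {event_type!r}")
    if not 0.0 < cell_fraction <= 1.0:
        raise ValueError(f"cell fraction {cell_fraction} outside (0, 1]")
    if chrom == "Y" and sex == "F":
        raise ValueError("chrY mCA call in a female participant")
    if chrom == "X" and event_type == "loss" and sex == "M":
        raise ValueError("chrX loss call in a male participant")


def classify_mca(calls, sex: str, participant_id: Optional[str] = None,
                 expansion_threshold: float = 0.10,
                 strict_expansion: bool = False) -> McaStatus:
    """Classify one participant's mCA calls.

    ``calls`` is an iterable of (chrom, event_type, cell_fraction) tuples or
    a DataFrame with those columns; the output is a pure function of
    (calls, sex) and invariant to call order.
    """
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    if isinstance(calls, pd.DataFrame):
        rows = list(zip(calls["chrom"].astype(str), calls["event_type"],
                        calls["cell_fraction"]))
    else:
        rows = [tuple(c) for c in calls]
    loy = lox = autosomal = False
    max_cf = 0.0
    for chrom, event_type, cf in rows:
        chrom = str(chrom).removeprefix("chr")
        _check_call(chrom, event_type, float(cf), sex)
        if chrom == "Y" and event_type == "loss" and sex == "M":
            loy = True
        if chrom == "X" and event_type == "loss" and sex == "F":
            lox = True
        if chrom in AUTOSOMES:
            autosomal = True
        max_cf = max(max_cf, float(cf))
    any_mca = len(rows) > 0
    expanded = any_mca and (max_cf > expansion_threshold if strict_expansion
                            else max_cf >= expansion_threshold)
    return McaStatus(participant_id=participant_id or "", any_mca=any_mca,
                     loy=loy, lox=lox, autosomal=autosomal,
                     expanded=expanded, max_cell_fraction=max_cf)


class McaClassifier(BaseEstimator, TransformerMixin):
    """Vectorized classifier from an mCA call table to per-participant status.

    ``transform(calls, phenotypes)`` (or passing phenotypes at ``fit``)
    returns one status row per phenotype participant, including those with
    no calls.
    """

    def __init__(self, expansion_threshold: float = 0.10,
                 strict_expansion: bool = False):
        self.expansion_threshold = expansion_threshold
        self.strict_expansion = strict_expansion

    def fit(self, X: pd.DataFrame, y=None) -> "McaClassifier":
        return self

    def transform(self, X: pd.DataFrame,
                  phenotypes: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        if phenotypes is None:
            raise ValueError("phenotypes table with participant sex is required")
        return classify_mca_table(
            X, phenotypes, expansion_threshold=self.expansion_threshold,
            strict_expansion=self.strict_expansion)


def classify_mca_table(calls: pd.DataFrame, phenotypes: pd.DataFrame,
                       expansion_threshold: float = 0.10,
                       strict_expansion: bool = False) -> pd.DataFrame:
    """Classify a whole cohort's mCA calls against the phenotype roster."""
    sex = phenotypes.set_index("participant_id")["sex"]
    calls = calls.copy()
    if len(calls):
        unknown = ~calls["participant_id"].isin(sex.index)
        if unknown.any():
            raise ValueError("mCA calls reference participants missing from "
                             "the phenotype table")
        calls["chrom"] = calls["chrom"].astype(str).str.removeprefix("chr")
        call_sex = calls["participant_id"].map(sex)
        bad_et = ~calls["event_type"].isin(EVENT_TYPES)
        if bad_et.any():
            raise ValueError(
                f"unknown event types: {sorted(calls.loc[bad_et, 'event_type'])}")
        bad_cf = ~((calls["cell_fraction"] > 0) & (calls["cell_fraction"] <= 1))
        if bad_cf.any():
            raise ValueError("cell fractions outside (0, 1]")
        if ((calls["chrom"] == "Y") & (call_sex == "F")).any():
            raise ValueError("chrY mCA call in a female participant")
        if ((calls["chrom"] == "X") & (calls["event_type"] == "loss")
                & (call_sex == "M")).any():
            raise ValueError("chrX loss call in a male participant")
        loss = calls["event_type"] == "loss"
        flags = pd.DataFrame({
            "participant_id": calls["participant_id"],
            "cell_fraction": calls["cell_fraction"],
            "loy": (calls["chrom"] == "Y") & loss,
            "lox": (calls["chrom"] == "X") & loss,
            "autosomal": calls["chrom"].isin(AUTOSOMES),
        })
        g = flags.groupby("participant_id")
        agg = g[["loy", "lox", "autosomal"]].any()
        agg["n_calls"] = g.size()
        agg["max_cell_fraction"] = g["cell_fraction"].max()
    else:
        agg = pd.DataFrame(columns=["n_calls", "max_cell_fraction", "loy",
                                    "lox", "autosomal"])

    status = pd.DataFrame({"participant_id": phenotypes["participant_id"]})
    status = status.set_index("participant_id").join(agg)
    status["n_calls"] = status["n_calls"].fillna(0).astype(int)
    status["max_cell_fraction"] = status["max_cell_fraction"].fillna(0.0)
    for c in ("loy", "lox", "autosomal"):
        status[c] = status[c].astype("boolean").fillna(False).astype(bool)
    status["any_mca"] = status["n_calls"] > 0
    cf = status["max_cell_fraction"]
    status["expanded"] = status["any_mca"] & (
        cf > expansion_threshold if strict_expansion
        else cf >= expansion_threshold)
    # LOY/LOX are evaluated sex-restrictedly downstream; the flags here are
    # guaranteed sex-consistent by the validation above
    return status.reset_index()[["participant_id", "any_mca", "loy", "lox",
                                 "autosomal", "expanded", "max_cell_fraction"]]
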
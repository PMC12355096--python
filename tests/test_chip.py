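"""CHIP filter cascade: rule behavior, oracles, invariants."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import chcv
from chcv.chip import (
    RULE_ARTIFACT, RULE_BINOMIAL, RULE_HOMOPOLYMER, ChipCaller,
    binomial_p_half, binomial_somatic_test, depth_filter, homopolymer_filter,
    match_whitelist, named_artifact_filter, recurrence_filter,
)
from tests.conftest import make_variant


# ----------------------------------------------------------------------
# whitelist
# ----------------------------------------------------------------------
def test_whitelist_matching(default_whitelist):
    wl = default_whitelist
    assert match_whitelist(make_variant(), wl)  # DNMT3A p.R882H
    assert match_whitelist(
        make_variant(gene="TET2", hgvs_p="p.Q1000*", consequence="nonsense"), wl)
    assert not match_whitelist(
        make_variant(gene="GNAS", hgvs_p="p.X999X", consequence="other"), wl)
    with pytest.raises(ValueError, match="panel"):
        match_whitelist(make_variant(gene="EGFR", hgvs_p="p.L858R"), wl)


# ----------------------------------------------------------------------
# depth rules
# ----------------------------------------------------------------------
@pytest.mark.parametrize("dp,ad,f1,f2,kept,rule", [
    (20, 5, 2, 3, True, None),           # all thresholds at boundary
    (19, 10, 5, 5, False, "depth_dp"),
    (100, 4, 2, 2, False, "depth_ad"),
    (100, 6, 6, 0, False, "depth_f2r1"),
    (100, 6, 0, 6, False, "depth_f1r2"),
])
def test_depth_filter_boundaries(dp, ad, f1, f2, kept, rule):
    v = make_variant(dp=dp, ad=ad, f1r2=f1, f2r1=f2)
    verdict = depth_filter(v)
    assert verdict.kept is kept
    if rule:
        assert rule in verdict.failed_rules


def test_depth_filter_rejects_ad_above_dp():
    with pytest.raises(ValueError):
        depth_filter(make_variant(dp=10, ad=11, f1r2=5, f2r1=5))


# ----------------------------------------------------------------------
# homopolymer rule
# ----------------------------------------------------------------------
@pytest.mark.parametrize("context,ad,vaf,kept", [
    ("CGAAAAAGTCT", 8, 0.20, False),   # run spans center, AD<10 branch
    ("CGAAAAAGTCT", 12, 0.15, True),   # both sub-conditions pass
    ("CGAAAAAGTCT", 15, 0.05, False),  # VAF<0.08 branch
    ("ACGTACGTACG", 5, 0.05, True),    # no run >=5: rule not applicable
    ("AAAAACGTCGT", 6, 0.05, False),   # run ends adjacent to center
    ("ACGCGTAAAAA", 6, 0.05, False),   # run starts adjacent to center
    ("AAAAACGCGTCGT", 6, 0.05, True),  # 13-mer: run not adjacent to center
])
def test_homopolymer_filter(context, ad, vaf, kept):
    v = make_variant(context=context, ad=ad, dp=int(ad / vaf), vaf=vaf,
                     f1r2=1, f2r1=1)
    assert homopolymer_filter(v).kept is kept


def test_homopolymer_requires_full_context():
    with pytest.raises(ValueError, match="context"):
        homopolymer_filter(make_variant(context="ACGTA"))


# ----------------------------------------------------------------------
# named artifacts
# ----------------------------------------------------------------------
def test_named_artifacts_default_scope(default_whitelist):
    wl = default_whitelist
    p72r = make_variant(gene="TP53", hgvs_p="p.P72R", ad=27, dp=60)
    assert not named_artifact_filter(p72r, wl).kept  # removed at any VAF
    p815l = make_variant(gene="ASXL1", hgvs_p="p.P815L", ad=30, dp=60)
    assert not named_artifact_filter(p815l, wl).kept
    g646_small = make_variant(gene="ASXL1", hgvs_p="p.G646Wfs*12",
                              consequence="frameshift", ad=5, dp=100)
    assert not named_artifact_filter(g646_small, wl).kept  # VAF<0.1
    g646_big = make_variant(gene="ASXL1", hgvs_p="p.G646Wfs*12",
                            consequence="frameshift", ad=20, dp=100)
    assert named_artifact_filter(g646_big, wl).kept  # VAF 0.2: genuine clone


def test_named_artifacts_all_scope(default_whitelist):
    # alternative reading: the VAF<0.1 clause covers all three artifacts
    wl = default_whitelist
    p72r_big = make_variant(gene="TP53", hgvs_p="p.P72R", ad=27, dp=60)
    assert named_artifact_filter(p72r_big, wl, scope="all").kept
    p72r_small = make_variant(gene="TP53", hgvs_p="p.P72R", ad=5, dp=100)
    assert not named_artifact_filter(p72r_small, wl, scope="all").kept


# ----------------------------------------------------------------------
# binomial somatic test
# ----------------------------------------------------------------------
def test_binomial_examples(default_whitelist):
    wl = default_whitelist
    # ad=5, dp=20: exact two-sided p = 2*sum_{k<=5} C(20,k)/2^20 = 0.0414
    v = make_variant(ad=5, dp=20, f1r2=2, f2r1=3)
    verdict = binomial_somatic_test(v, wl)
    assert not verdict.kept
    assert verdict.details["p"] == pytest.approx(0.041389465, rel=1e-6)
    # VAF exactly 0.5 -> p = 1 -> removed
    v = make_variant(gene="TET2", hgvs_p="p.C1135Y", ad=30, dp=60,
                     f1r2=15, f2r1=15)
    assert not binomial_somatic_test(v, wl).kept
    # exempt TET2 site kept despite germline-like VAF
    v = make_variant(gene="TET2", hgvs_p="p.H1904R", ad=30, dp=60,
                     f1r2=15, f2r1=15)
    verdict = binomial_somatic_test(v, wl)
    assert verdict.kept and verdict.details["tested"] is False
    # non-missense and out-of-scope genes are not tested
    v = make_variant(gene="ASXL1", hgvs_p="p.Q800*", consequence="nonsense",
                     ad=30, dp=60, f1r2=15, f2r1=15)
    assert binomial_somatic_test(v, wl).kept


def test_binomial_p_matches_exact_summation_oracle():
    # oracle: exact rational two-tail summation, independent of scipy
    def oracle(ad, dp):
        m = min(ad, dp - ad)
        s = sum(comb(dp, k) for k in range(m + 1))
        return float(min(Fraction(1), 2 * Fraction(s, 2 ** dp)))

    rng = np.random.default_rng(0)
    cases = [(5, 20), (30, 60), (0, 7), (250, 500), (100, 500)]
    cases += [(int(rng.integers(0, dp + 1)), int(dp))
              for dp in rng.integers(1, 501, 40)]
    for ad, dp in cases:
        expected = oracle(ad, dp)
        got = binomial_p_half(ad, dp)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)


def test_binomial_rejects_zero_depth(default_whitelist):
    with pytest.raises(ValueError):
        binomial_somatic_test(make_variant(ad=0, dp=0, f1r2=0, f2r1=0, vaf=0),
                              default_whitelist)


# ----------------------------------------------------------------------
# recurrence filter
# ----------------------------------------------------------------------
def _pheno(n, rng):
    return pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "age_baseline": rng.normal(60, 7, n),
        "tert_dosage": rng.binomial(2, 0.3, n),
    })


def test_recurrence_below_threshold_untested():
    rng = np.random.default_rng(1)
    pheno = _pheno(2000, rng)
    v = recurrence_filter(("DNMT3A", "p.R882H"),
                          pheno["participant_id"].iloc[:15], pheno)
    assert v.kept and v.details["tested"] is False


def test_recurrence_keeps_age_associated_variant():
    # simulation oracle: with 200 carriers drawn under a strong positive
    # age effect (log-OR 0.1/year) the power of the age test is ~1
    rng = np.random.default_rng(2)
    pheno = _pheno(20_000, rng)
    eta = 0.1 * (pheno["age_baseline"] - 60)
    p = 200 / 20_000 * np.exp(eta) / np.mean(np.exp(eta))
    carriers = pheno.loc[rng.random(20_000) < p, "participant_id"]
    assert len(carriers) > 100
    v = recurrence_filter(("JAK2", "p.V617F"), carriers, pheno)
    assert v.kept and v.details["p_age"] <= 0.1


def test_recurrence_removal_rate_under_null():
    # carriers independent of age and TERT: under the either-test rule the
    # variant is removed when both p-values exceed 0.1, i.e. ~81% of the
    # time (1 - 0.19 for two independent near-uniform p-values)
    rng = np.random.default_rng(3)
    removed = 0
    reps = 120
    for _ in range(reps):
        pheno = _pheno(6000, rng)
        carriers = pheno["participant_id"].sample(
            30, random_state=int(rng.integers(2 ** 31)))
        removed += not recurrence_filter(("GNAS", "p.R201C"),
                                         carriers, pheno).kept
    assert 0.70 <= removed / reps <= 0.90


def test_recurrence_both_rule_is_stricter():
    rng = np.random.default_rng(4)
    stricter = 0
    for _ in range(30):
        pheno = _pheno(4000, rng)
        carriers = pheno["participant_id"].sample(
            30, random_state=int(rng.integers(2 ** 31)))
        either = recurrence_filter(("G", "h"), carriers, pheno,
                                   combine="either").kept
        both = recurrence_filter(("G", "h"), carriers, pheno,
                                 combine="both").kept
        assert either or not both  # both => either
        stricter += either and not both
    assert stricter > 0


# ----------------------------------------------------------------------
# cascade invariants
# ----------------------------------------------------------------------
variant_strategy = st.builds(
    make_variant,
    gene=st.sampled_from(["DNMT3A", "TET2", "ASXL1", "TP53"]),
    hgvs_p=st.sampled_from(["p.R882H", "p.P72R", "p.P815L", "p.G646Wfs*12",
                            "p.Q555*", "p.A123T"]),
    consequence=st.sampled_from(["missense", "nonsense", "frameshift"]),
    dp=st.integers(10, 200),
    ad=st.integers(0, 60),
    context=st.sampled_from(["ACGTACGTACG", "CGAAAAAGTCT", "TTTTTTTTTTT"]),
).filter(lambda v: v["ad"] <= v["dp"]).map(
    lambda v: {**v, "f1r2": min(2, v["ad"]), "f2r1": max(0, min(2, v["ad"] - 2)),
               "vaf": v["ad"] / v["dp"]})


@settings(max_examples=60, deadline=None, derandomize=True)
@given(v=variant_strategy)
def test_per_variant_rules_commute(v, default_whitelist):
    """Each per-variant verdict depends only on the record, so the rules
    commute and the audit lists every failed rule."""
    wl = default_whitelist
    verdicts = {
        "whitelist": not match_whitelist(v, wl),
        "depth": not depth_filter(v).kept,
        "homopolymer": not homopolymer_filter(v).kept,
        "artifact": not named_artifact_filter(v, wl).kept,
        "binomial": not binomial_somatic_test(v, wl).kept,
    }
    caller = ChipCaller()
    X = pd.DataFrame([v])
    pheno = pd.DataFrame({"participant_id": [v["participant_id"]],
                          "age_baseline": [60.0], "tert_dosage": [0]})
    caller.fit(X, pheno)
    kept = len(caller.calls_) == 1
    assert kept == (not any(verdicts.values()))
    if not kept:
        failed = caller.audit_.loc[0, "failed_rules"].split(";")
        if verdicts["homopolymer"]:
            assert RULE_HOMOPOLYMER in failed
        if verdicts["artifact"]:
            assert RULE_ARTIFACT in failed
        if verdicts["binomial"]:
            assert RULE_BINOMIAL in failed


def test_cascade_idempotent(small_bundle):
    caller = ChipCaller().fit(small_bundle.variant_evidence,
                              small_bundle.participants)
    again = ChipCaller().fit(caller.calls_, small_bundle.participants)
    pd.testing.assert_frame_equal(caller.calls_.reset_index(drop=True),
                                  again.calls_.reset_index(drop=True))


def test_lower_dp_threshold_is_monotone(small_bundle):
    strict = ChipCaller(dp_min=20).fit(small_bundle.variant_evidence,
                                       small_bundle.participants)
    loose = ChipCaller(dp_min=10).fit(small_bundle.variant_evidence,
                                      small_bundle.participants)
    key = ["participant_id", "gene", "hgvs_p"]
    strict_keys = set(map(tuple, strict.calls_[key].values))
    loose_keys = set(map(tuple, loose.calls_[key].values))
    assert strict_keys <= loose_keys


def test_duplicate_records_rejected(small_bundle):
    dup = pd.concat([small_bundle.variant_evidence.iloc[:5]] * 2)
    with pytest.raises(ValueError, match="duplicate"):
        ChipCaller().fit(dup, small_bundle.participants)


def test_status_aggregation():
    pheno = pd.DataFrame({"participant_id": ["A", "B", "C"],
                          "age_baseline": [55.0, 60.0, 65.0],
                          "tert_dosage": [0, 1, 2]})
    X = pd.DataFrame([
        make_variant(participant_id="A", ad=7, dp=58, f1r2=4, f2r1=3),  # VAF 0.121
        make_variant(participant_id="A", gene="TET2", hgvs_p="p.Q555*",
                     consequence="nonsense", ad=5, dp=60, f1r2=2, f2r1=3),
        make_variant(participant_id="B", ad=5, dp=62, f1r2=2, f2r1=3),
    ])
    status = ChipCaller().fit(X, pheno).status_.set_index("participant_id")
    assert status.loc["A", "n_mutations"] == 2
    assert status.loc["A", "genes"] == "DNMT3A,TET2"
    assert status.loc["A", "expanded"]          # max VAF 7/58 >= 0.10
    assert not status.loc["B", "expanded"]      # 5/62 < 0.10
    assert not status.loc["C", "carrier"]
    assert status.loc["C", "mutation_count_class"] == "0"
    assert status.loc["A", "mutation_count_class"] == "2"
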
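"""Synthetic cohort generator: marginals, determinism, serialization."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chcv
from chcv.simulate import CohortSimulator, read_bundle, write_bundle
from chcv.io import read_vcf


def test_invalid_configs_rejected():
    with pytest.raises(chcv.ConfigError):
        chcv.SimulationConfig(n_participants=0).validate()
    with pytest.raises(chcv.ConfigError):
        chcv.SimulationConfig(chip_prevalence_at_mean_age=1.5).validate()
    with pytest.raises(chcv.ConfigError):
        chcv.SimulationConfig(age_range=(70, 40)).validate()
    with pytest.raises(chcv.ConfigError):
        chcv.SimulationConfig(vaf_floor=0.001).validate()


def test_zero_prevalence_yields_no_clones():
    cfg = chcv.SimulationConfig(n_participants=500, seed=1,
                                chip_prevalence_at_mean_age=0.0,
                                decoy_fraction=0.0,
                                recurrent_decoy_fraction=0.0)
    b = chcv.generate_cohort(cfg)
    assert not b.truth["chip_carrier"].any()
    assert len(b.variant_evidence) == 0


def test_realized_chip_prevalence_matches_target():
    # binomial sampling oracle: the realized carrier fraction at n=50,000
    # must lie within 3 Monte-Carlo standard errors of the 5.5% target
    cfg = chcv.SimulationConfig(n_participants=50_000, seed=20,
                                generate_read_evidence=False)
    b = chcv.generate_cohort(cfg)
    p, n = 0.055, 50_000
    se = np.sqrt(p * (1 - p) / n)
    assert abs(b.truth["chip_carrier"].mean() - p) < 3 * se


def test_chip_prevalence_increases_with_age():
    # pooled over replicates, CHIP prevalence is non-decreasing across age
    # deciles up to sampling noise (tested on decile halves)
    carriers, ages = [], []
    for seed in range(5):
        cfg = chcv.SimulationConfig(n_participants=8000, seed=30 + seed,
                                    generate_read_evidence=False)
        b = chcv.generate_cohort(cfg)
        carriers.append(b.truth["chip_carrier"])
        ages.append(b.participants["age_baseline"].to_numpy())
    carrier = np.concatenate(carriers)
    age = np.concatenate(ages)
    decile = pd.qcut(age, 10, labels=False)
    prev = pd.Series(carrier).groupby(decile).mean()
    assert prev.iloc[7:].mean() > prev.iloc[:3].mean()
    # monotone trend: adjacent deciles may wiggle, but Kendall tau is positive
    tau = stats.kendalltau(np.arange(10), prev.values)[0]
    assert tau > 0.5


def test_loy_lox_chip_correlations_have_configured_signs():
    cfg = chcv.SimulationConfig(n_participants=60_000, seed=4,
                                generate_read_evidence=False)
    b = chcv.generate_cohort(cfg)
    pheno, tr = b.participants, b.truth
    men = (pheno["sex"] == "M").to_numpy()
    women = ~men
    chip = tr["chip_carrier"]
    loy_or = _odds_ratio(tr["loy"][men], chip[men])
    lox_or = _odds_ratio(tr["lox"][women], chip[women])
    assert loy_or < 1.0 < lox_or


def _odds_ratio(a, b):
    t = pd.crosstab(a, b).to_numpy().astype(float)
    return (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])


def test_null_exposure_logrank_p_uniform():
    # with all exposure log-HRs zero, carriers and non-carriers have the
    # same survival; log-rank p-values across replicates look uniform
    from lifelines.statistics import logrank_test
    pvals = []
    for seed in range(40):
        cfg = chcv.SimulationConfig(n_participants=1200, seed=500 + seed,
                                    generate_read_evidence=False)
        for ep in cfg.hazard.exposure_log_hr:
            cfg.hazard.exposure_log_hr[ep] = {
                "chip_only": 0.0, "mca_only": 0.0, "both": 0.0}
        cfg.chip_prevalence_at_mean_age = 0.5
        cfg.chip_log_or_per_year_age = 0.0
        cfg.chip_log_or_current_smoker = 0.0
        cfg.chip_log_or_previous_smoker = 0.0
        cfg.chip_log_or_chemo = 0.0
        b = chcv.generate_cohort(cfg)
        pheno = b.participants
        origin = pheno["recruit_date"].where(
            pheno["cancer_dx_date"] <= pheno["recruit_date"],
            pheno["cancer_dx_date"])
        ev = pheno["any_death_date"].notna()
        end = pheno["any_death_date"].fillna(
            origin + pd.Timedelta(days=int(15 * 365.25)))
        t = (end - origin).dt.days / 365.25
        chip = b.truth["chip_carrier"]
        r = logrank_test(t[chip], t[~chip], ev[chip], ev[~chip])
        pvals.append(r.p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_vaf_floor_and_expansion_share(small_bundle):
    tv = small_bundle.truth["variants"]
    clones = tv[tv["kind"] == "clone"]
    ev = small_bundle.variant_evidence.merge(
        clones[["participant_id", "gene", "hgvs_p"]],
        on=["participant_id", "gene", "hgvs_p"])
    assert (ev["vaf"] >= 0.02).all()
    # clone-size skew: roughly 60% of clone VAFs at or above 10%
    assert 0.4 < (ev["vaf"] >= 0.10).mean() < 0.8


def test_bundle_round_trip_identity(tmp_path, small_bundle):
    write_bundle(small_bundle, tmp_path)
    back = read_bundle(tmp_path)
    ve = small_bundle.variant_evidence.reset_index(drop=True)
    pd.testing.assert_frame_equal(ve, back.variant_evidence, check_dtype=False)
    pd.testing.assert_frame_equal(small_bundle.mca_calls, back.mca_calls,
                                  check_dtype=False)
    orig = small_bundle.participants
    cols = [c for c in back.participants.columns if c in orig.columns]
    pd.testing.assert_frame_equal(orig[cols], back.participants[cols],
                                  check_dtype=False)


def test_reproducibility_byte_identical(tmp_path):
    cfg = chcv.SimulationConfig(n_participants=400, seed=9)
    for d in ("a", "b"):
        write_bundle(CohortSimulator(cfg).generate(), tmp_path / d)
    for name in ("phenotypes.tsv", "mca_calls.tsv", "variants.vcf",
                 "truth.json"):
        ha = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
        hb = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
        assert ha == hb, name


def test_empty_bundle_writes_valid_headers(tmp_path):
    cfg = chcv.SimulationConfig(n_participants=50, seed=2,
                                chip_prevalence_at_mean_age=0.0,
                                mca_prevalence_at_mean_age=0.0,
                                decoy_fraction=0.0,
                                recurrent_decoy_fraction=0.0)
    b = chcv.generate_cohort(cfg)
    assert len(b.variant_evidence) == 0 and len(b.mca_calls) == 0
    write_bundle(b, tmp_path)
    vcf_text = (tmp_path / "variants.vcf").read_text()
    assert vcf_text.startswith("##fileformat=VCF")
    assert "#CHROM" in vcf_text
    assert len(read_vcf(tmp_path / "variants.vcf")) == 0
    pheno = pd.read_csv(tmp_path / "phenotypes.tsv", sep="\t")
    assert len(pheno) == 50


def test_vcf_encodes_depths_as_ref_alt(tmp_path):
    # direct construction: one carrier with DP=40, AD=8 must serialize the
    # sample field with DP 40 and AD "32,8"
    from tests.conftest import make_variant
    df = pd.DataFrame([make_variant(dp=40, ad=8, f1r2=4, f2r1=4)])
    from chcv.io import write_vcf
    path = tmp_path / "one.vcf"
    write_vcf(df, path)
    body = [ln for ln in path.read_text().splitlines()
            if not ln.startswith("#")]
    assert len(body) == 1
    sample_field = body[0].split("\t")[-1]
    assert "40" in sample_field and "32,8" in sample_field
    back = read_vcf(path)
    assert back.loc[0, "dp"] == 40 and back.loc[0, "ad"] == 8
    assert back.loc[0, "vaf"] == pytest.approx(0.2)


def test_bundle_rejects_unknown_participants(small_bundle):
    import copy
    bad = copy.copy(small_bundle)
    bad.mca_calls = pd.concat([
        small_bundle.mca_calls,
        pd.DataFrame([{"participant_id": "PX", "chrom": "1",
                       "event_type": "loss", "cell_fraction": 0.2}])])
    with pytest.raises(ValueError):
        bad.validate()
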
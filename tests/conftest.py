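import numpy as np
import pandas as pd
import pytest

import chcv
from chcv.cohort import build_analysis_table
from chcv.mca import classify_mca_table


def make_variant(**overrides):
    """A well-formed whitelisted variant record; fields overridable."""
    v = {
        "participant_id": "P000001",
        "gene": "DNMT3A",
        "hgvs_p": "p.R882H",
        "chrom": "chr2",
        "pos": 25_234_373,
        "ref": "C",
        "alt": "T",
        "dp": 60,
        "ad": 12,
        "f1r2": 6,
        "f2r1": 6,
        "vaf": 0.2,
        "context": "ACGTACGTACG",
        "consequence": "missense",
    }
    v.update(overrides)
    if "vaf" not in overrides:
        v["vaf"] = v["ad"] / v["dp"]
    return v


def truth_analysis_table(bundle):
    """Analysis table built from the simulator's latent truth exposures
    (bypasses the filter cascade; used by model-recovery tests)."""
    pheno = bundle.participants
    carrier = bundle.truth["chip_carrier"]
    chip_status = pd.DataFrame({
        "participant_id": pheno["participant_id"],
        "carrier": carrier,
        "n_mutations": carrier.astype(int),
        "genes": "",
        "max_vaf": 0.0,
        "expanded": False,
        "mutation_count_class": np.where(carrier, "1", "0"),
    })
    mca_status = classify_mca_table(bundle.mca_calls, pheno)
    return build_analysis_table(pheno, chip_status, mca_status)


def null_interaction_config(seed, n=5000, endpoint_rate=0.035):
    """Scenario with zero exposure effects and independent CHIP/mCA at
    elevated prevalence, used for CI-coverage simulations."""
    cfg = chcv.SimulationConfig(n_participants=n, seed=seed,
                                generate_read_evidence=False)
    cfg.chip_prevalence_at_mean_age = 0.30
    cfg.mca_prevalence_at_mean_age = 0.30
    cfg.loy_chip_log_or = 0.0
    cfg.lox_chip_log_or = 0.0
    for ep in cfg.hazard.exposure_log_hr:
        cfg.hazard.exposure_log_hr[ep] = {
            "chip_only": 0.0, "mca_only": 0.0, "both": 0.0}
    cfg.hazard.baseline_rate["any_death"] = endpoint_rate
    return cfg


@pytest.fixture(scope="session")
def small_bundle():
    cfg = chcv.SimulationConfig(n_participants=2500, seed=7)
    return chcv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_bundle):
    caller = chcv.ChipCaller().fit(small_bundle.variant_evidence,
                                   small_bundle.participants)
    mca_status = classify_mca_table(small_bundle.mca_calls,
                                    small_bundle.participants)
    return build_analysis_table(small_bundle.participants, caller.status_,
                                mca_status)


@pytest.fixture(scope="session")
def default_whitelist():
    return chcv.load_default_whitelist()
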
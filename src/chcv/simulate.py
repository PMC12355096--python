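"""Synthetic cancer-cohort generator.

Generates a fully synthetic cohort — participants with demographics and
treatment history, per-variant read evidence for CHIP clones and labelled
decoy artifacts, mCA call tables, and proportional-hazards event times for
five cardiovascular endpoints — with the statistical structure the analysis
assumes, so every downstream stage is testable without any external data.

Latent CHIP carriage follows a logistic model in centered age, smoking and
chemotherapy; the intercept is calibrated numerically on the drawn linear
predictors so the realized marginal prevalence matches the configured one.
LOY (men), LOX (women) and autosomal mCA carriage are drawn analogously,
with LOY negatively and LOX positively coupled to CHIP carriage.  Event
times are exponential proportional hazards with administrative censoring;
Cox fits are baseline-agnostic, so the exponential baseline loses no
generality for parameter-recovery purposes.

The ``truth`` block records every latent assignment (carriage, per-variant
decoy labels with the rule each decoy violates, true log-hazard ratios) for
confusion-matrix and parameter-recovery tests.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .config import ENDPOINTS, ConfigError, SimulationConfig
from . import io as chcv_io

# gene -> (contig, offset for synthetic coordinates)
GENE_CONTIGS: Dict[str, tuple] = {
    "GNB1": ("chr1", 1_700_000),
    "DNMT3A": ("chr2", 25_200_000),
    "SF3B1": ("chr2", 197_400_000),
    "TET2": ("chr4", 105_100_000),
    "JAK2": ("chr9", 4_900_000),
    "CBL": ("chr11", 119_200_000),
    "TP53": ("chr17", 7_500_000),
    "PPM1D": ("chr17", 60_600_000),
    "SRSF2": ("chr17", 76_700_000),
    "ASXL1": ("chr20", 32_300_000),
    "GNAS": ("chr20", 58_800_000),
}

# mutation share per gene among CHIP clones (DNMT3A/TET2/ASXL1 dominate)
GENE_SHARES: Dict[str, float] = {
    "DNMT3A": 0.520, "TET2": 0.220, "ASXL1": 0.137, "JAK2": 0.030,
    "TP53": 0.025, "PPM1D": 0.022, "CBL": 0.015, "SF3B1": 0.012,
    "SRSF2": 0.012, "GNAS": 0.004, "GNB1": 0.003,
}

BINOMIAL_TEST_GENES = frozenset({"CBL", "TET2", "DNMT3A", "TP53"})
EXEMPT_SITES = (("TET2", "p.H1904R"), ("TET2", "p.I1873T"), ("TET2", "p.T1884A"))
RECURRENT_DECOY = ("GNAS", "p.R201C")  # reserved for the recurrence-filter decoy

_AA = list("ACDEFGHIKLMNPQRSTVWY")
_BASES = np.array(list("ACGT"))

DECOY_KINDS = (
    "not_whitelisted", "depth_dp", "depth_ad", "orientation",
    "homopolymer", "binomial", "artifact_p72r", "artifact_p815l",
    "artifact_g646",
)


@dataclass
class CohortBundle:
    """Everything the simulator emits for one cohort."""

    participants: pd.DataFrame
    variant_evidence: pd.DataFrame
    mca_calls: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        pids = set(self.participants["participant_id"])
        for name, df in (("variant_evidence", self.variant_evidence),
                         ("mca_calls", self.mca_calls)):
            if len(df) and not set(df["participant_id"]) <= pids:
                raise ValueError(f"{name} references unknown participant ids")


def _calibrated_bernoulli(rng, eta: np.ndarray, target: float) -> np.ndarray:
    """Draw Bernoulli with logistic mean calibrated to a marginal target.

    Solves for the intercept a such that mean(expit(a + eta)) == target on
    the realized linear predictors, then draws carriage indicators.
    """
    n = eta.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    if target <= 0.0:
        return np.zeros(n, dtype=bool)
    if target >= 1.0:
        return np.ones(n, dtype=bool)

    def gap(a):
        return expit(a + eta).mean() - target

    a = optimize.brentq(gap, -30.0, 30.0)
    return rng.random(n) < expit(a + eta)


def _trunc_beta(rng, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Beta(a, b) truncated to [lo, hi] by inverse-CDF sampling."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size)
    return stats.beta.ppf(u, a, b)


def _two_sided_half_binom_p(ad: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p-value against p=0.5 (symmetric null)."""
    m = np.minimum(ad, dp - ad)
    return np.minimum(1.0, 2.0 * stats.binom.cdf(m, dp, 0.5))


class CohortSimulator:
    """Generate synthetic cohorts under a :class:`SimulationConfig`."""

    def __init__(self, config: Optional[SimulationConfig] = None):
        self.config = config or SimulationConfig()

    # ------------------------------------------------------------------
    def generate(self, seed: Optional[int] = None) -> CohortBundle:
        cfg = self.config
        cfg.validate()
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        n = cfg.n_participants

        pheno = self._draw_participants(rng, n)
        chip = self._draw_chip(rng, pheno)
        loy, lox, autosomal = self._draw_mca(rng, pheno, chip)
        any_mca = loy | lox | autosomal
        exposure4 = np.where(chip & any_mca, "both",
                             np.where(chip, "chip_only",
                                      np.where(any_mca, "mca_only", "no_ch")))

        mca_calls, mca_cf = self._mca_call_table(rng, pheno, loy, lox, autosomal)
        if cfg.generate_read_evidence:
            variants = self._variant_evidence(rng, pheno, chip)
        else:
            variants = chcv_io.empty_variant_table()

        self._draw_events(rng, pheno, exposure4)

        truth = {
            "chip_carrier": chip,
            "loy": loy, "lox": lox, "autosomal_mca": autosomal,
            "any_mca": any_mca,
            "exposure4": exposure4,
            "max_cell_fraction": mca_cf,
            "variants": variants[["participant_id", "gene", "hgvs_p",
                                  "kind", "decoy_kind"]].copy()
            if len(variants) else pd.DataFrame(
                columns=["participant_id", "gene", "hgvs_p", "kind", "decoy_kind"]),
            "hazard": {
                "baseline_rate": dict(cfg.hazard.baseline_rate),
                "exposure_log_hr": {k: dict(v)
                                    for k, v in cfg.hazard.exposure_log_hr.items()},
                "covariate_log_hr": {k: dict(v)
                                     for k, v in cfg.hazard.covariate_log_hr.items()},
                "censoring_horizon_years": cfg.hazard.censoring_horizon_years,
            },
            "config": cfg.to_dict(),
        }
        evidence = variants.drop(columns=["kind", "decoy_kind"]) if len(variants) \
            else chcv_io.empty_variant_table(drop_truth=True)
        bundle = CohortBundle(participants=pheno, variant_evidence=evidence,
                              mca_calls=mca_calls, truth=truth)
        bundle.validate()
        return bundle

    # ------------------------------------------------------------------
    def _draw_participants(self, rng, n: int) -> pd.DataFrame:
        cfg = self.config
        lo, hi = cfg.age_range
        a, b = (lo - cfg.age_mean) / cfg.age_sd, (hi - cfg.age_mean) / cfg.age_sd
        age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                                  size=n, random_state=rng)
        sex = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
        smoking_levels = list(cfg.smoking_probs)
        smoking = rng.choice(smoking_levels, size=n, p=list(cfg.smoking_probs.values()))
        chemo = (rng.random(n) < cfg.chemo_prob).astype(int)
        radio = (rng.random(n) < cfg.radio_prob).astype(int)
        prevalent_cvd = (rng.random(n) < cfg.prevalent_cvd_prob).astype(int)
        tert = rng.binomial(2, cfg.tert_maf, size=n)
        pcs = rng.standard_normal((n, 10))

        recruit = (pd.Timestamp("2006-01-01")
                   + pd.to_timedelta(rng.integers(0, 4 * 365, n), unit="D"))
        prevalent = rng.random(n) < cfg.prevalent_cancer_fraction
        dx_offset = np.where(prevalent,
                             -rng.integers(30, 3650, n),
                             rng.integers(1, 1825, n))
        cancer_dx = recruit + pd.to_timedelta(dx_offset, unit="D")

        # cancer type, with sex-specific types drawn conditionally
        types = list(cfg.cancer_type_frequencies)
        probs = np.array(list(cfg.cancer_type_frequencies.values()))
        female_only = {"breast", "uterus"}
        male_only = {"prostate"}
        cancer_type = np.empty(n, dtype=object)
        for s, banned in (("F", male_only), ("M", female_only)):
            mask = sex == s
            p = np.array([0.0 if t in banned else w for t, w in zip(types, probs)])
            p = p / p.sum()
            cancer_type[mask] = rng.choice(types, size=mask.sum(), p=p)

        # exclusion-rule plumbing
        concordant = rng.random(n) >= cfg.sex_discordant_fraction
        hema = rng.random(n) < cfg.hematologic_fraction
        hema_date = pd.Series(pd.NaT, index=range(n))
        if hema.any():
            hema_date[hema] = (recruit[hema]
                               + pd.to_timedelta(rng.integers(-730, 730, hema.sum()),
                                                 unit="D"))
        relative_group = np.full(n, "", dtype=object)
        n_pairs = int(round(cfg.relative_pair_fraction * n / 2))
        if n_pairs:
            members = rng.choice(n, size=2 * n_pairs, replace=False)
            for k in range(n_pairs):
                gid = f"R{k:05d}"
                relative_group[members[2 * k]] = gid
                relative_group[members[2 * k + 1]] = gid

        pheno = pd.DataFrame({
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age_baseline": np.round(age, 1),
            "smoking": smoking,
            "chemo": chemo,
            "radio": radio,
            "prevalent_cvd": prevalent_cvd,
            "cancer_type": cancer_type,
            "cancer_dx_date": cancer_dx,
            "recruit_date": recruit,
            "tert_dosage": tert,
        })
        for j in range(10):
            pheno[f"pc{j + 1}"] = np.round(pcs[:, j], 4)
        pheno["hematologic_dx_date"] = pd.to_datetime(hema_date.values)
        pheno["sex_concordant"] = concordant.astype(int)
        pheno["relative_group"] = relative_group
        return pheno

    def _draw_chip(self, rng, pheno: pd.DataFrame) -> np.ndarray:
        cfg = self.config
        eta = (cfg.chip_log_or_per_year_age
               * (pheno["age_baseline"].to_numpy() - cfg.age_mean)
               + cfg.chip_log_or_current_smoker * (pheno["smoking"] == "current")
               + cfg.chip_log_or_previous_smoker * (pheno["smoking"] == "previous")
               + cfg.chip_log_or_chemo * pheno["chemo"].to_numpy())
        return _calibrated_bernoulli(rng, np.asarray(eta, dtype=float),
                                     cfg.chip_prevalence_at_mean_age)

    def _draw_mca(self, rng, pheno: pd.DataFrame, chip: np.ndarray):
        cfg = self.config
        n = len(pheno)
        age_c = pheno["age_baseline"].to_numpy() - cfg.age_mean
        base_eta = (cfg.mca_log_or_per_year_age * age_c
                    + cfg.mca_log_or_current_smoker * (pheno["smoking"] == "current")
                    + cfg.mca_log_or_chemo * pheno["chemo"].to_numpy())
        base_eta = np.asarray(base_eta, dtype=float)
        # scale component prevalences so the implied any-mCA marginal tracks
        # the configured target (defaults imply ~0.207)
        f = cfg.mca_prevalence_at_mean_age / 0.207

        male = (pheno["sex"] == "M").to_numpy()
        female = ~male
        loy = np.zeros(n, dtype=bool)
        lox = np.zeros(n, dtype=bool)
        loy[male] = _calibrated_bernoulli(
            rng, base_eta[male] + cfg.loy_chip_log_or * chip[male],
            min(1.0, cfg.loy_prevalence_males * f))
        lox[female] = _calibrated_bernoulli(
            rng, base_eta[female] + cfg.lox_chip_log_or * chip[female],
            min(1.0, cfg.lox_prevalence_females * f))
        autosomal = _calibrated_bernoulli(
            rng, base_eta, min(1.0, cfg.autosomal_mca_prevalence * f))
        return loy, lox, autosomal

    def _mca_call_table(self, rng, pheno, loy, lox, autosomal):
        cfg = self.config
        a, b = cfg.cell_fraction_beta
        pid = pheno["participant_id"].to_numpy()
        rows = []
        max_cf = np.zeros(len(pheno))

        def add(mask, chrom, event_type):
            idx = np.flatnonzero(mask)
            cf = np.clip(stats.beta.rvs(a, b, size=idx.size, random_state=rng),
                         1e-4, 1.0)
            for i, c in zip(idx, cf):
                ch = chrom if chrom is not None else str(rng.integers(1, 23))
                et = event_type if event_type is not None else \
                    ["loss", "gain", "cnloh"][rng.integers(0, 3)]
                rows.append((pid[i], ch, et, round(float(c), 4)))
                max_cf[i] = max(max_cf[i], c)

        add(loy, "Y", "loss")
        add(lox, "X", "loss")
        add(autosomal, None, None)
        calls = pd.DataFrame(rows, columns=["participant_id", "chrom",
                                            "event_type", "cell_fraction"])
        return calls.sort_values(["participant_id", "chrom"],
                                 kind="mergesort").reset_index(drop=True), max_cf

    # ------------------------------------------------------------------
    # variant evidence
    # ------------------------------------------------------------------
    def _variant_evidence(self, rng, pheno, chip) -> pd.DataFrame:
        cfg = self.config
        recs = []
        recs += self._clone_variants(rng, pheno, chip)
        recs += self._structural_decoys(rng, pheno)
        recs += self._recurrent_decoys(rng, pheno)
        if not recs:
            return chcv_io.empty_variant_table()
        df = pd.DataFrame(recs, columns=[
            "participant_id", "gene", "hgvs_p", "consequence",
            "dp", "ad", "f1r2", "f2r1", "kind", "decoy_kind",
        ])
        self._assign_sites(rng, df)
        df["vaf"] = df["ad"] / df["dp"]
        cols = ["participant_id", "gene", "hgvs_p", "chrom", "pos", "ref", "alt",
                "dp", "ad", "f1r2", "f2r1", "vaf", "context", "consequence",
                "kind", "decoy_kind"]
        return (df[cols]
                .sort_values(["chrom", "pos", "participant_id"], kind="mergesort")
                .reset_index(drop=True))

    def _sample_gene_entry(self, rng) -> tuple:
        """Draw (gene, hgvs_p, consequence) for one true CHIP mutation."""
        genes = list(GENE_SHARES)
        gene = rng.choice(genes, p=list(GENE_SHARES.values()))
        u = rng.random()
        if gene == "DNMT3A":
            if u < 0.25:
                return gene, "p.R882H", "missense"
            if u < 0.35:
                return gene, "p.R882C", "missense"
            return gene, self._missense_tail(rng, 30, 900), "missense"
        if gene == "TET2":
            if u < 0.024:
                g, h = EXEMPT_SITES[rng.integers(0, 3)]
                return g, h, "missense"
            return gene, *self._lof_tail(rng, 100, 1900)
        if gene == "ASXL1":
            while True:
                hgvs, cons = self._lof_tail(rng, 200, 1500)
                if "646" not in hgvs and "815" not in hgvs:
                    return gene, hgvs, cons
        if gene == "JAK2":
            return gene, "p.V617F", "missense"
        if gene == "TP53":
            if u < 0.3:
                return gene, ["p.R175H", "p.R248Q", "p.R273H",
                              "p.R282W"][rng.integers(0, 4)], "missense"
            while True:
                hgvs, cons = self._lof_tail(rng, 30, 390)
                if "72" not in hgvs:
                    return gene, hgvs, cons
        if gene == "PPM1D":
            return gene, *self._lof_tail(rng, 420, 605)
        if gene == "CBL":
            return gene, *self._lof_tail(rng, 50, 900)
        if gene == "SF3B1":
            return gene, ["p.K700E", "p.K666N", "p.G742D",
                          "p.E622D"][rng.integers(0, 4)], "missense"
        if gene == "SRSF2":
            return gene, ["p.P95H", "p.P95L", "p.P95R",
                          "p.P95T"][rng.integers(0, 4)], "missense"
        if gene == "GNAS":
            return gene, ["p.R201H", "p.R844H"][rng.integers(0, 2)], "missense"
        return gene, "p.K57E", "missense"  # GNB1

    def _missense_tail(self, rng, lo, hi) -> str:
        a1, a2 = rng.choice(len(_AA), size=2, replace=False)
        return f"p.{_AA[a1]}{rng.integers(lo, hi)}{_AA[a2]}"

    def _lof_tail(self, rng, lo, hi) -> tuple:
        pos = rng.integers(lo, hi)
        if rng.random() < 0.5:
            return f"p.{_AA[rng.integers(0, 20)]}{pos}*", "nonsense"
        return (f"p.{_AA[rng.integers(0, 20)]}{pos}"
                f"{_AA[rng.integers(0, 20)]}fs*{rng.integers(2, 30)}"), "frameshift"

    def _clone_variants(self, rng, pheno, chip) -> list:
        cfg = self.config
        carriers = np.flatnonzero(chip)
        if carriers.size == 0:
            return []
        counts = rng.choice(list(cfg.mutation_count_probs),
                            size=carriers.size,
                            p=list(cfg.mutation_count_probs.values()))
        pid = pheno["participant_id"].to_numpy()
        recs = []
        for i, k in zip(carriers, counts):
            seen = set()
            for _ in range(int(k)):
                gene, hgvs, cons = self._sample_gene_entry(rng)
                if (gene, hgvs) in seen:
                    continue
                seen.add((gene, hgvs))
                tested = cons == "missense" and gene in BINOMIAL_TEST_GENES \
                    and (gene, hgvs) not in EXEMPT_SITES
                dp, ad, f1, f2 = self._clone_evidence(rng, tested)
                recs.append((pid[i], gene, hgvs, cons, dp, ad, f1, f2, "clone", ""))
        return recs

    def _clone_evidence(self, rng, binomial_tested: bool) -> tuple:
        """Read support for a true clone, compliant with every depth rule.

        For variants subject to the germline binomial test the depth is
        escalated and the alt count resampled until the exact test rejects
        VAF = 0.5 at 0.01; the target VAF for such variants is capped at
        0.40 because clones nearer 0.5 are not separable from germline at
        realistic exome depth.
        """
        cfg = self.config
        a, b = cfg.vaf_beta
        hi = 0.40 if binomial_tested else 1.0
        v = float(_trunc_beta(rng, a, b, cfg.vaf_floor, hi, 1)[0])
        dp = 30 + int(rng.poisson(15))
        if binomial_tested:
            dp = max(dp, int(np.ceil((2.9 / (1.0 - 2.0 * v)) ** 2)))
        ad = 5
        for _ in range(300):
            ad = int(rng.binomial(dp, v))
            if ad < 5 or ad >= dp or ad / dp < cfg.vaf_floor:
                # small clones get deeper coverage rather than an inflated
                # alt count, preserving the target VAF distribution and the
                # detection floor on the realized VAF
                dp = int(dp * 1.3) + 10
                continue
            if not binomial_tested:
                break
            p = float(_two_sided_half_binom_p(np.array(ad), np.array(dp)))
            if p < 0.01:
                break
            dp = int(dp * 1.3) + 10
        ad = min(max(ad, 5), dp - 1)
        f1 = int(np.clip(rng.binomial(ad, 0.5), 1, ad - 1))
        return dp, ad, f1, ad - f1

    def _structural_decoys(self, rng, pheno) -> list:
        cfg = self.config
        n = len(pheno)
        idx = np.flatnonzero(rng.random(n) < cfg.decoy_fraction)
        pid = pheno["participant_id"].to_numpy()
        recs = []
        for i in idx:
            kind = DECOY_KINDS[int(rng.integers(0, len(DECOY_KINDS)))]
            recs.append(self._one_decoy(rng, pid[i], kind))
        return recs

    def _one_decoy(self, rng, pid: str, kind: str) -> tuple:
        if kind == "not_whitelisted":
            hgvs = self._missense_tail(rng, 100, 300)
            return (pid, "GNB1", hgvs, "missense", 60, 12, 6, 6, "decoy", kind)
        if kind == "depth_dp":
            return (pid, "DNMT3A", self._missense_tail(rng, 30, 900), "missense",
                    15, 5, 3, 2, "decoy", kind)
        if kind == "depth_ad":
            h, c = self._lof_tail(rng, 100, 1900)
            return (pid, "TET2", h, c, 40, 3, 2, 1, "decoy", kind)
        if kind == "orientation":
            h, c = self._lof_tail(rng, 200, 1500)
            return (pid, "ASXL1", h, c, 60, 9, 9, 0, "decoy", kind)
        if kind == "homopolymer":
            # reserved position range so these sites never collide with a
            # true-clone variant name (clone tails stop at 1900)
            h, c = self._lof_tail(rng, 1950, 2000)
            return (pid, "TET2", h, c, 120, 6, 3, 3, "decoy", kind)
        if kind == "binomial":
            dp = 50 + int(rng.poisson(15))
            for _ in range(200):
                ad = int(rng.binomial(dp, 0.5))
                p = float(_two_sided_half_binom_p(np.array(ad), np.array(dp)))
                if p >= 0.05 and ad >= 5 and ad < dp:
                    break
            f1 = int(np.clip(rng.binomial(ad, 0.5), 1, ad - 1))
            return (pid, "DNMT3A", self._missense_tail(rng, 30, 900), "missense",
                    dp, ad, f1, ad - f1, "decoy", kind)
        if kind == "artifact_p72r":
            return (pid, "TP53", "p.P72R", "missense", 80, 36, 18, 18, "decoy", kind)
        if kind == "artifact_p815l":
            return (pid, "ASXL1", "p.P815L", "missense", 70, 20, 10, 10, "decoy", kind)
        if kind == "artifact_g646":
            return (pid, "ASXL1", "p.G646Wfs*12", "frameshift",
                    80, 6, 3, 3, "decoy", kind)
        raise ValueError(f"unknown decoy kind {kind!r}")

    def _recurrent_decoys(self, rng, pheno) -> list:
        cfg = self.config
        n = len(pheno)
        k = int(round(cfg.recurrent_decoy_fraction * n))
        if k == 0:
            return []
        # drawn uniformly: carriage independent of age and TERT by design
        idx = rng.choice(n, size=k, replace=False)
        pid = pheno["participant_id"].to_numpy()
        gene, hgvs = RECURRENT_DECOY
        recs = []
        for i in idx:
            dp = 40 + int(rng.poisson(10))
            ad = max(5, int(rng.binomial(dp, 0.12)))
            f1 = int(np.clip(rng.binomial(ad, 0.5), 1, ad - 1))
            recs.append((pid[i], gene, hgvs, "missense",
                         dp, ad, f1, ad - f1, "decoy", "recurrent"))
        return recs

    def _assign_sites(self, rng, df: pd.DataFrame) -> None:
        """Assign per-site chrom/pos/ref/alt/context, identical across carriers."""
        keys = sorted(set(zip(df["gene"], df["hgvs_p"], df["consequence"],
                              df["decoy_kind"] == "homopolymer")))
        taken = set()
        site_info = {}
        for gene, hgvs, cons, homopoly in keys:
            contig, base = GENE_CONTIGS[gene]
            h = zlib.crc32(f"{gene}:{hgvs}".encode())
            pos = base + h % 150_000
            while (contig, pos) in taken:
                pos += 1
            taken.add((contig, pos))
            if homopoly:
                run_base = "ACGT"[h % 4]
                context = run_base * 11
            else:
                while True:
                    context = "".join(_BASES[rng.integers(0, 4, 11)])
                    if not _has_run(context, 5):
                        break
            ref = context[5]
            alt_choices = [x for x in "ACGT" if x != ref]
            alt = alt_choices[h % 3]
            if cons == "frameshift":
                alt = ref + "A"  # encoded as a 1-bp insertion
            site_info[(gene, hgvs)] = (contig, pos, ref, alt, context)
        info = df.apply(lambda r: site_info[(r["gene"], r["hgvs_p"])], axis=1)
        df["chrom"] = [t[0] for t in info]
        df["pos"] = [t[1] for t in info]
        df["ref"] = [t[2] for t in info]
        df["alt"] = [t[3] for t in info]
        df["context"] = [t[4] for t in info]

    # ------------------------------------------------------------------
    def _draw_events(self, rng, pheno: pd.DataFrame, exposure4: np.ndarray) -> None:
        cfg = self.config
        hz = cfg.hazard
        n = len(pheno)
        age_c = pheno["age_baseline"].to_numpy() - cfg.age_mean
        cov = {
            "age_baseline": age_c,
            "sex_M": (pheno["sex"] == "M").to_numpy(float),
            "smoking_current": (pheno["smoking"] == "current").to_numpy(float),
            "smoking_previous": (pheno["smoking"] == "previous").to_numpy(float),
            "chemo": pheno["chemo"].to_numpy(float),
            "radio": pheno["radio"].to_numpy(float),
            "prevalent_cvd": pheno["prevalent_cvd"].to_numpy(float),
        }
        origin = pheno["recruit_date"].where(
            pheno["cancer_dx_date"] <= pheno["recruit_date"],
            pheno["cancer_dx_date"])
        for ep in ENDPOINTS:
            lp = np.zeros(n)
            for name, beta in hz.covariate_log_hr[ep].items():
                if name in cov:
                    lp += beta * cov[name]
            for cat, beta in hz.exposure_log_hr[ep].items():
                lp += beta * (exposure4 == cat)
            rate = hz.baseline_rate[ep] * np.exp(lp)
            t = rng.exponential(1.0 / rate)
            event = t <= hz.censoring_horizon_years
            dates = pd.Series(pd.NaT, index=pheno.index)
            if event.any():
                dates[event] = origin[event] + pd.to_timedelta(
                    np.round(t[event] * 365.25).astype(int), unit="D")
            pheno[f"{ep}_date"] = pd.to_datetime(dates)


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a synthetic cohort bundle; deterministic given config.seed."""
    return CohortSimulator(config).generate()


def _has_run(s: str, k: int) -> bool:
    run, prev = 1, ""
    for c in s:
        run = run + 1 if c == prev else 1
        prev = c
        if run >= k:
            return True
    return False


# ----------------------------------------------------------------------
# bundle serialization
# ----------------------------------------------------------------------
def write_bundle(bundle: CohortBundle, out_dir) -> dict:
    """Write a bundle as VCF + TSVs + truth JSON; returns the file map.

    The variant evidence goes to a multi-sample VCF v4.2 whose samples are
    the participants carrying at least one candidate call (FORMAT
    GT:DP:AD:F1R2:F2R1, AD as ref,alt; INFO GENE/HGVSP/CONTEXT/CONSEQ);
    mCA calls and phenotypes go to TSV; truth to JSON.  Everything
    round-trips losslessly through :mod:`chcv.io` readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "phenotypes": out / "phenotypes.tsv",
        "mca_calls": out / "mca_calls.tsv",
        "variants": out / "variants.vcf",
        "truth": out / "truth.json",
    }
    chcv_io.write_phenotypes(bundle.participants, files["phenotypes"])
    chcv_io.write_mca_calls(bundle.mca_calls, files["mca_calls"])
    chcv_io.write_vcf(bundle.variant_evidence, files["variants"])
    with open(files["truth"], "w") as fh:
        json.dump(_truth_to_json(bundle.truth), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in files.items()}


def read_bundle(out_dir) -> CohortBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    out = Path(out_dir)
    pheno = chcv_io.read_phenotypes(out / "phenotypes.tsv")
    mca = chcv_io.read_mca_calls(out / "mca_calls.tsv")
    variants = chcv_io.read_vcf(out / "variants.vcf")
    truth_path = out / "truth.json"
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        if "variants" in truth:
            truth["variants"] = pd.DataFrame(
                truth["variants"],
                columns=["participant_id", "gene", "hgvs_p", "kind", "decoy_kind"])
        for key in ("chip_carrier", "loy", "lox", "autosomal_mca", "any_mca"):
            if key in truth:
                truth[key] = np.asarray(truth[key], dtype=bool)
        if "exposure4" in truth:
            truth["exposure4"] = np.asarray(truth["exposure4"], dtype=object)
        if "max_cell_fraction" in truth:
            truth["max_cell_fraction"] = np.asarray(truth["max_cell_fraction"])
    return CohortBundle(participants=pheno, variant_evidence=variants,
                        mca_calls=mca, truth=truth)


def _truth_to_json(truth: dict) -> dict:
    out = {}
    for k, v in truth.items():
        if isinstance(v, pd.DataFrame):
            out[k] = v.values.tolist()
        elif isinstance(v, np.ndarray):
            out[k] = [bool(x) if isinstance(x, (np.bool_, bool)) else
                      (float(x) if isinstance(x, (np.floating, float)) else str(x))
                      for x in v]
        else:
            out[k] = v
    return out
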
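"""Summary tables, rounding conventions, and pipeline orchestration.

Percents are computed as 100*numerator/denominator and rounded half-up to
one decimal; hazard ratios, odds ratios and interaction metrics are
rounded half-up to three decimals, matching the display precision of the
source tables.  ``run_pipeline`` chains simulate -> call-chip ->
classify-mca -> build-cohort -> prevalence -> survival -> report, writing
every intermediate file plus a manifest with seeds and SHA-256 hashes so a
run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as chcv_io
from .config import ENDPOINTS, SimulationConfig
from .chip import ChipCaller
from .cohort import CohortAssembler
from .mca import classify_mca_table
from .prevalence import fit_prevalence_model
from .simulate import CohortSimulator, write_bundle
from .survival import run_interaction_analysis


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """100*numerator/denominator, rounded half-up to ``digits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(100 * numerator / denominator)
                 .quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, digits: int = 3) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and percents per characteristic, overall and by CHIP status."""
    if len(table) == 0:
        raise ValueError("cannot summarize an empty analysis table")
    strata = {
        "overall": table,
        "no_chip": table[~table["chip"]],
        "chip": table[table["chip"]],
    }
    binaries = [
        ("sex_M", table["sex"] == "M"),
        ("sex_F", table["sex"] == "F"),
        ("smoking_current", table["smoking"] == "current"),
        ("smoking_never", table["smoking"] == "never"),
        ("smoking_previous", table["smoking"] == "previous"),
        ("smoking_unknown", table["smoking"] == "unknown"),
        ("chemo", table["chemo"] == 1),
        ("radio", table["radio"] == 1),
        ("prevalent_cvd", table["prevalent_cvd"] == 1),
        ("any_mca", table["any_mca"]),
        ("loy", table["loy"]),
        ("lox", table["lox"]),
        ("expanded_mca", table["mca_expanded"]),
        ("expanded_chip", table["chip_expanded"]),
    ]
    rows = []
    for label, mask in binaries:
        row = {"characteristic": label}
        for sname, sdf in strata.items():
            n = int(mask.loc[sdf.index].sum())
            row[f"{sname}_n"] = n
            row[f"{sname}_pct"] = percent(n, len(sdf)) if len(sdf) else 0.0
        rows.append(row)
    age_row = {"characteristic": "age_baseline"}
    for sname, sdf in strata.items():
        a = sdf["age_baseline"]
        age_row[f"{sname}_n"] = int(len(sdf))
        age_row[f"{sname}_pct"] = np.nan
        age_row[f"{sname}_mean"] = round_half_up(a.mean(), 1) if len(a) else np.nan
        age_row[f"{sname}_sd"] = round_half_up(a.std(), 1) if len(a) > 1 else np.nan
        age_row[f"{sname}_median"] = float(a.median()) if len(a) else np.nan
        age_row[f"{sname}_iqr_low"] = float(a.quantile(.25)) if len(a) else np.nan
        age_row[f"{sname}_iqr_high"] = float(a.quantile(.75)) if len(a) else np.nan
    rows.append(age_row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------
class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d").fillna("")
    tmp = path.with_suffix(path.suffix + ".partial")
    out.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def _write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
    os.replace(tmp, path)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, pd.Timestamp):
        return x.strftime("%Y-%m-%d")
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pipeline(config: Optional[SimulationConfig] = None,
                 out_dir="chcv_run", seed: Optional[int] = None,
                 pair: str = "chip_x_mca") -> dict:
    """Simulate a cohort and run every analysis stage end-to-end.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg.seed = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    manifest = {"seed": cfg.seed, "n_participants": cfg.n_participants,
                "stages": {}, "files": {}}

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            (out / "pipeline.log").write_text("\n".join(
                log_lines + [f"[{name}] FAILED: {exc}"]) + "\n")
            raise PipelineError(name, exc) from exc

    # 1. simulate
    def _simulate():
        bundle = CohortSimulator(cfg).generate()
        files = write_bundle(bundle, out / "sim")
        log("simulate", f"{len(bundle.participants)} participants, "
            f"{len(bundle.variant_evidence)} candidate variants, "
            f"{len(bundle.mca_calls)} mCA calls")
        manifest["stages"]["simulate"] = {
            "n_participants": len(bundle.participants),
            "n_variants": len(bundle.variant_evidence),
            "n_mca_calls": len(bundle.mca_calls)}
        return bundle, files
    bundle, sim_files = run_stage("simulate", _simulate)

    # 2. call-chip (reads the written VCF/TSV back: the pipeline is
    # exercised through its file formats, not in-memory shortcuts)
    def _chip():
        variants = chcv_io.read_vcf(sim_files["variants"])
        pheno = chcv_io.read_phenotypes(sim_files["phenotypes"])
        caller = ChipCaller().fit(variants, pheno)
        _write_table(caller.status_, out / "chip_status.tsv")
        _write_table(caller.calls_, out / "chip_calls.tsv")
        _write_table(caller.audit_, out / "chip_audit.tsv")
        log("call-chip", f"{len(variants)} candidates in, "
            f"{len(caller.calls_)} kept, {len(caller.audit_)} removed, "
            f"{int(caller.status_['carrier'].sum())} carriers")
        manifest["stages"]["call_chip"] = {
            "in": len(variants), "kept": len(caller.calls_),
            "removed": len(caller.audit_),
            "carriers": int(caller.status_["carrier"].sum())}
        return pheno, caller
    pheno, caller = run_stage("call-chip", _chip)

    # 3. classify-mca
    def _mca():
        calls = chcv_io.read_mca_calls(sim_files["mca_calls"])
        status = classify_mca_table(calls, pheno)
        _write_table(status, out / "mca_status.tsv")
        log("classify-mca", f"{len(calls)} calls -> "
            f"{int(status['any_mca'].sum())} carriers")
        manifest["stages"]["classify_mca"] = {
            "calls": len(calls), "carriers": int(status["any_mca"].sum())}
        return status
    mca_status = run_stage("classify-mca", _mca)

    # 4. build-cohort
    def _cohort():
        asm = CohortAssembler(seed=cfg.seed).fit(pheno)
        table = asm.transform(pheno, chip_status=caller.status_,
                              mca_status=mca_status)
        _write_table(table, out / "analysis_table.tsv")
        _write_table(asm.exclusion_log_, out / "exclusions.log")
        log("build-cohort", f"{len(pheno)} in, "
            f"{len(asm.exclusion_log_)} exclusions, {len(table)} rows out")
        manifest["stages"]["build_cohort"] = {
            "in": len(pheno), "excluded": len(asm.exclusion_log_),
            "rows": len(table),
            "censor_date": str(asm.censor_date_.date())}
        return table
    table = run_stage("build-cohort", _cohort)

    # 5. prevalence
    def _prevalence():
        results = {}
        for outcome in ("chip", "any_mca"):
            tab = fit_prevalence_model(
                table, outcome,
                predictors=["age_baseline", "sex", "smoking", "chemo"],
                adjust=[])
            results[outcome] = tab.to_dict(orient="records")
        _write_json(results, out / "prevalence.json")
        log("prevalence", f"fitted {len(results)} outcomes")
        manifest["stages"]["prevalence"] = {"outcomes": sorted(results)}
        return results
    run_stage("prevalence", _prevalence)

    # 6. survival + interaction
    def _survival():
        report = run_interaction_analysis(table, ENDPOINTS, pair=pair,
                                          seed=cfg.seed)
        _write_json(report, out / "survival.json")
        done = [ep for ep, e in report["endpoints"].items()
                if not e.get("not_reportable")]
        log("survival", f"{len(done)}/{len(ENDPOINTS)} endpoints reportable")
        manifest["stages"]["survival"] = {"reportable": done}
        return report
    run_stage("survival", _survival)

    # 7. descriptive report
    def _report():
        desc = summarize_descriptives(table)
        _write_table(desc, out / "table1.tsv")
        log("report", f"{len(desc)} characteristic rows")
        manifest["stages"]["report"] = {"rows": len(desc)}
    run_stage("report", _report)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json", "pipeline.log"):
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    _write_json(manifest, out / "manifest.json")
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return manifest
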
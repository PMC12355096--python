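"""Readers and writers for the pipeline's on-disk formats.

Variant evidence travels as VCF v4.2 (via pysam) with FORMAT
``GT:DP:AD:F1R2:F2R1`` (AD as ref,alt) and INFO tags ``GENE``, ``HGVSP``,
``CONTEXT`` (reference bases +/-5 bp around the site) and ``CONSEQ``.
Samples present in the file are participants with at least one candidate
call; participants absent from the VCF simply have no candidates.
Phenotypes and mCA calls travel as plain TSV with ISO-8601 dates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam

CONTIG_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr4": 190_214_555,
    "chr9": 138_394_717, "chr11": 135_086_622, "chr17": 83_257_441,
    "chr20": 64_444_167,
}

VARIANT_COLUMNS = [
    "participant_id", "gene", "hgvs_p", "chrom", "pos", "ref", "alt",
    "dp", "ad", "f1r2", "f2r1", "vaf", "context", "consequence",
]

PHENO_DATE_COLUMNS = [
    "cancer_dx_date", "recruit_date",
    "incident_cvd_date", "incident_cad_date", "cv_death_date",
    "cad_death_date", "any_death_date", "hematologic_dx_date",
]

PHENO_COLUMNS = (
    ["participant_id", "sex", "age_baseline", "smoking", "chemo", "radio",
     "prevalent_cvd", "cancer_type", "cancer_dx_date", "recruit_date",
     "tert_dosage"]
    + [f"pc{i}" for i in range(1, 11)]
    + ["incident_cvd_date", "incident_cad_date", "cv_death_date",
       "cad_death_date", "any_death_date"]
    + ["hematologic_dx_date", "sex_concordant", "relative_group"]
)


def empty_variant_table(drop_truth: bool = False) -> pd.DataFrame:
    cols = VARIANT_COLUMNS if drop_truth else VARIANT_COLUMNS + ["kind", "decoy_kind"]
    return pd.DataFrame(columns=cols)


# ----------------------------------------------------------------------
# TSV
# ----------------------------------------------------------------------
def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    df = pheno.copy()
    for c in PHENO_DATE_COLUMNS:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d").fillna("")
    cols = [c for c in PHENO_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str,
                                            "relative_group": str})
    for c in PHENO_DATE_COLUMNS:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
    if "relative_group" in df.columns:
        df["relative_group"] = df["relative_group"].fillna("")
    return df


def write_mca_calls(calls: pd.DataFrame, path) -> None:
    cols = ["participant_id", "chrom", "event_type", "cell_fraction"]
    calls[cols].to_csv(path, sep="\t", index=False)


def read_mca_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"participant_id": str, "chrom": str,
                              "event_type": str, "cell_fraction": float})


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def _vcf_header(samples: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in CONTIG_LENGTHS.items():
        header.contigs.add(contig, length=length)
    header.info.add("GENE", 1, "String", "CHIP panel gene symbol")
    header.info.add("HGVSP", 1, "String", "Protein change (HGVS p. notation)")
    header.info.add("CONTEXT", 1, "String",
                    "Reference bases +/-5bp around the variant position")
    header.info.add("CONSEQ", 1, "String", "Consequence class")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
    header.formats.add("F1R2", 1, "Integer", "Alt-supporting F1R2 read pairs")
    header.formats.add("F2R1", 1, "Integer", "Alt-supporting F2R1 read pairs")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(variants: pd.DataFrame, path) -> None:
    """Write the per-participant variant evidence as one multi-sample VCF."""
    path = str(path)
    if len(variants) == 0:
        vf = pysam.VariantFile(path, "w", header=_vcf_header([]))
        vf.close()
        return
    samples = sorted(variants["participant_id"].unique())
    header = _vcf_header(samples)
    vf = pysam.VariantFile(path, "w", header=header)
    site_cols = ["chrom", "pos", "ref", "alt", "gene", "hgvs_p",
                 "context", "consequence"]
    contig_order = {c: i for i, c in enumerate(CONTIG_LENGTHS)}
    grouped = variants.groupby(site_cols, sort=False)
    keys = sorted(grouped.groups, key=lambda k: (contig_order[k[0]], k[1], k[3]))
    for key in keys:
        chrom, pos, ref, alt, gene, hgvs, context, conseq = key
        grp = grouped.get_group(key)
        rec = vf.new_record(contig=chrom, start=int(pos) - 1,
                            alleles=(ref, alt))
        rec.info["GENE"] = gene
        rec.info["HGVSP"] = hgvs
        rec.info["CONTEXT"] = context
        rec.info["CONSEQ"] = conseq
        for row in grp.itertuples(index=False):
            s = rec.samples[row.participant_id]
            s["GT"] = (0, 1)
            s["DP"] = int(row.dp)
            s["AD"] = (int(row.dp) - int(row.ad), int(row.ad))
            s["F1R2"] = int(row.f1r2)
            s["F2R1"] = int(row.f2r1)
        vf.write(rec)
    vf.close()


def read_vcf(path, fasta: Optional[str] = None) -> pd.DataFrame:
    """Read a (multi-sample or per-sample) VCF into the variant table.

    If ``CONTEXT`` is absent and a FASTA path is given, the +/-5bp context
    is fetched from the indexed reference instead.
    """
    vf = pysam.VariantFile(str(path))
    fa = None
    if fasta is not None:
        import pyfaidx
        fa = pyfaidx.Fasta(str(fasta))
    rows = []
    for rec in vf.fetch() if vf.index is not None else vf:
        info = rec.info
        gene = info.get("GENE")
        hgvs = info.get("HGVSP")
        conseq = info.get("CONSEQ", "other")
        context = info.get("CONTEXT")
        if context is None and fa is not None:
            seq = fa[rec.contig][max(0, rec.pos - 6):rec.pos + 5]
            context = str(seq).upper()
        for name, sample in rec.samples.items():
            dp = sample.get("DP")
            if dp is None:
                continue
            ad_field = sample.get("AD")
            ad = int(ad_field[1]) if ad_field is not None and len(ad_field) > 1 else 0
            f1r2 = sample.get("F1R2") or 0
            f2r1 = sample.get("F2R1") or 0
            rows.append((name, gene, hgvs, rec.contig, rec.pos,
                         rec.ref, rec.alts[0], int(dp), ad,
                         int(f1r2), int(f2r1),
                         ad / int(dp) if dp else np.nan,
                         context, conseq))
    vf.close()
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return (df.sort_values(["chrom", "pos", "participant_id"], kind="mergesort")
            .reset_index(drop=True))


def write_variant_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str})
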
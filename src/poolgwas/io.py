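"""Tabular I/O for every pipeline stage.

All tables are tab-separated text with fixed, documented headers;
floats are written with ``%.10g`` so identical runs produce
byte-identical files.  Genotypes travel either as an individuals x
SNPs TSV (0/1/2/NA) or as a minimal GT-only VCF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "write_table",
    "read_table",
    "write_genotypes",
    "read_genotypes",
    "write_minimal_vcf",
    "read_minimal_vcf",
    "write_manifest",
]

FLOAT_FORMAT = "%.10g"

#: Required leading columns per table kind (extra columns are allowed
#: after them).
SCHEMAS = {
    "intensity": ["snp_id", "chrom", "pos", "probe_idx", "allele",
                  "PM", "MM", "pool_id"],
    "pool_freq": ["snp_id", "chrom", "pos", "pool_id", "f_A", "f_B",
                  "F_A", "callable"],
    "ratio": ["snp_id", "chrom", "pos", "subtype", "R1", "R2", "R3",
              "R4", "mean_R", "cv_R", "selected"],
    "candidate": ["snp_id", "chrom", "subtype", "mean_R", "cv_R",
                  "p_mc", "selected", "shortlist_rule"],
    "annotation": ["snp_id", "chrom", "pos", "gene_label"],
    "phenotype": ["individual_id", "group"],
    "reference_freq": ["snp_id", "F_ref"],
    "association": ["snp_id", "subtype", "chi2", "df", "p_geno",
                    "risk_allele", "OR", "ci_low", "ci_high",
                    "hwe_p_controls", "phet", "call_rate",
                    "significant"],
}


class DataError(ValueError):
    """A table failed schema validation."""


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a stage table as TSV after checking its schema."""
    _check_schema(df, kind, str(path))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              na_rep="NA")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a stage TSV and validate its header."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except Exception as exc:  # pragma: no cover - passthrough context
        raise DataError(f"{path}: cannot parse TSV ({exc})") from exc
    _check_schema(df, kind, str(path))
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df


def _check_schema(df: pd.DataFrame, kind: str, context: str) -> None:
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise DataError(
            f"{context}: {kind} table missing column(s) {missing}; "
            f"found {list(df.columns)}"
        )


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    """Write an individuals x SNPs genotype matrix (0/1/2, NA missing)."""
    out = df.copy()
    out.index.name = out.index.name or "individual_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a genotype matrix TSV written by :func:`write_genotypes`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    bad = df.apply(lambda c: ~(c.dropna().isin((0, 1, 2))).all())
    if bad.any():
        raise DataError(
            f"{path}: genotype values outside {{0,1,2,NA}} in column(s) "
            f"{list(df.columns[bad])[:5]}"
        )
    return df


def write_minimal_vcf(genotypes: pd.DataFrame, annotation: pd.DataFrame,
                      path: str | Path) -> None:
    """Write genotypes as a minimal GT-only VCF (text, uncompressed).

    REF/ALT are the array's A and B alleles reported as placeholder
    bases; genotype 0/1/2 counts ALT (B) copies; missing is ``./.``.
    """
    ann = annotation.set_index("snp_id")
    samples = list(genotypes.index)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in genotypes.columns:
            row = ann.loc[snp]
            calls = [
                gt_map.get(float(v), "./.") if pd.notna(v) else "./."
                for v in genotypes[snp]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tA\tC\t.\t.\t.\t"
                "GT\t" + "\t".join(calls) + "\n"
            )


def read_minimal_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GT-only VCF back into (genotypes, annotation) frames.

    Handles exactly the subset :func:`write_minimal_vcf` emits (plus
    phased separators); anything richer should be converted to the
    genotype-matrix TSV first.
    """
    samples: list[str] = []
    records: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise DataError(f"{path}: malformed VCF line: {line[:60]}")
            chrom, pos, snp_id = fields[0], int(fields[1]), fields[2]
            calls = []
            for cell in fields[9:]:
                gt = cell.split(":")[0].replace("|", "/")
                if "." in gt:
                    calls.append(np.nan)
                else:
                    calls.append(float(sum(int(x) for x in gt.split("/"))))
            records.append((chrom, pos, snp_id, calls))
    if not samples:
        raise DataError(f"{path}: no #CHROM header line")
    geno = pd.DataFrame(
        {snp: calls for _, _, snp, calls in records},
        index=pd.Index(samples, name="individual_id"),
    )
    ann = pd.DataFrame(
        [(snp, chrom, pos, "") for chrom, pos, snp, _ in records],
        columns=["snp_id", "chrom", "pos", "gene_label"],
    )
    return geno, ann


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (config hash, seed, stage row counts)."""
    payload = {}
    for key, value in entries.items():
        if isinstance(value, (np.integer,)):
            value = int(value)
        elif isinstance(value, (np.floating,)):
            value = float(value)
        payload[key] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
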
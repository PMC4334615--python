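"""Pool allelotyping: probe-level PM/MM intensities -> allele frequencies.

For each SNP and pool, each allele's background-corrected fluorescence
is ``f = PM - MM`` (clamped at zero) summed across its probes, and the
pool frequency of allele A is estimated as ``F_A = f_A / (f_A + f_B)``.
A SNP x pool with zero total fluorescence is marked non-callable rather
than raising: chip-level QC is assumed to have happened upstream, and
the per-SNP ``callable`` flag is the in-pipeline substitute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "corrected_fluorescence",
    "summarize_snp",
    "estimate_frequency",
    "allelotype_table",
]


def corrected_fluorescence(pm, mm):
    """Background-corrected allele signal ``max(PM - MM, 0)``.

    Real arrays can show MM > PM for dim probes; clamping at zero keeps
    downstream frequencies inside [0, 1].  Scalars or arrays accepted;
    negative inputs rejected.
    """
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if (pm < 0).any() or (mm < 0).any():
        raise ValueError("PM and MM intensities must be non-negative")
    out = np.maximum(pm - mm, 0.0)
    return float(out) if out.ndim == 0 else out


def summarize_snp(quartets: pd.DataFrame) -> tuple[float, float]:
    """Combine one SNP x pool's probe quartets into per-allele signals.

    ``quartets`` holds columns ``allele`` ('A'/'B'), ``PM``, ``MM`` for
    a single SNP x pool.  Signals are summed across probes per allele
    (ratio of sums, robust to a single dim probe).  Raises if either
    allele has no probes.
    """
    f = {}
    for allele, sub in quartets.groupby("allele", observed=True):
        f[allele] = float(corrected_fluorescence(sub["PM"].to_numpy(),
                                                 sub["MM"].to_numpy()).sum())
    missing = {"A", "B"} - set(f)
    if missing:
        ident = ""
        for col in ("snp_id", "pool_id"):
            if col in quartets.columns and len(quartets):
                ident += f" {col}={quartets[col].iloc[0]}"
        raise ValueError(
            f"no probes for allele(s) {sorted(missing)}{ident}"
        )
    return f["A"], f["B"]


def estimate_frequency(f_a: float, f_b: float) -> tuple[float, bool]:
    """Allele-A frequency estimate ``f_A / (f_A + f_B)``.

    Returns ``(F_A, callable)``; when both signals are zero the
    frequency is undefined and the SNP x pool is flagged non-callable
    (F_A reported as NaN).
    """
    if f_a < 0 or f_b < 0:
        raise ValueError("allele signals must be non-negative")
    total = f_a + f_b
    if total == 0:
        return float("nan"), False
    return f_a / total, True


def allelotype_table(intensities: pd.DataFrame) -> pd.DataFrame:
    """Vectorized allelotyping of a full probe-intensity table.

    Input columns: snp_id, chrom, pos, probe_idx, allele, PM, MM,
    pool_id.  Output: one row per SNP x pool with snp_id, chrom, pos,
    pool_id, f_A, f_B, F_A, callable.
    """
    required = {"snp_id", "allele", "PM", "MM", "pool_id"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing column(s): {sorted(missing)}")
    df = intensities.copy()
    df["f"] = corrected_fluorescence(df["PM"].to_numpy(), df["MM"].to_numpy())
    keys = ["snp_id", "pool_id"]
    meta_cols = [c for c in ("chrom", "pos") if c in df.columns]
    wide = (
        df.groupby(keys + meta_cols + ["allele"], observed=True)["f"]
        .sum()
        .unstack("allele")
    )
    for allele in ("A", "B"):
        if allele not in wide.columns or wide[allele].isna().any():
            bad = (wide.index[wide[allele].isna()].tolist()
                   if allele in wide.columns else wide.index.tolist())
            raise ValueError(
                f"missing allele-{allele} probes for SNP x pool(s): {bad[:5]}"
            )
    out = wide.reset_index().rename(columns={"A": "f_A", "B": "f_B"})
    total = out["f_A"] + out["f_B"]
    out["callable"] = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["F_A"] = np.where(out["callable"], out["f_A"] / total, np.nan)
    cols = ["snp_id"] + meta_cols + ["pool_id", "f_A", "f_B", "F_A",
                                     "callable"]
    return out[cols].sort_values(["snp_id", "pool_id"],
                                 kind="stable").reset_index(drop=True)
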
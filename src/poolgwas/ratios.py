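"""Case/control allele-frequency ratio statistics for pooled arrays.

With two pools per condition, each SNP and case subtype yields four
frequency ratios (each case pool over each control pool)::

    R1 = F_case1 / F_ctrl1    R2 = F_case1 / F_ctrl2
    R3 = F_case2 / F_ctrl1    R4 = F_case2 / F_ctrl2

The summary statistic is the arithmetic mean of the four ratios paired
with their coefficient of variation (CV = SD / mean): a large mean with
a small CV indicates a frequency shift reproduced across biological
replicates.  Pre-selection keeps SNPs whose mean ratio is at least a
threshold (default 20) in either direction (>= t or <= 1/t) — the
two-sided form is required because a depleted allele shows up as a
tiny mean rather than a large one.

Frequencies are clamped to ``[eps, 1 - eps]`` before any ratio so R is
always finite and positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["clamp_frequencies", "four_ratios", "mean_cv", "preselect",
           "ratio_table"]


def clamp_frequencies(freqs, epsilon: float = 1e-4):
    """Clamp frequencies to ``[epsilon, 1 - epsilon]``."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    return np.clip(np.asarray(freqs, dtype=float), epsilon, 1.0 - epsilon)


def four_ratios(f_case1, f_case2, f_ctrl1, f_ctrl2):
    """The four case/control frequency ratios (R1, R2, R3, R4).

    Inputs must already be clamped away from 0 and 1; scalars or
    broadcastable arrays accepted.
    """
    f_case1, f_case2, f_ctrl1, f_ctrl2 = (
        np.asarray(x, dtype=float) for x in (f_case1, f_case2,
                                             f_ctrl1, f_ctrl2)
    )
    if any((x <= 0).any() or (x >= 1).any()
           for x in (f_case1, f_case2, f_ctrl1, f_ctrl2)):
        raise ValueError("frequencies must lie in (0, 1); clamp first")
    return (f_case1 / f_ctrl1, f_case1 / f_ctrl2,
            f_case2 / f_ctrl1, f_case2 / f_ctrl2)


def mean_cv(r1, r2, r3, r4, ddof: int = 1):
    """Mean and coefficient of variation of the four ratios.

    CV = SD / mean with the sample (n-1) SD by default; ``ddof=0``
    selects the population convention.
    """
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    r = np.stack([np.asarray(x, dtype=float) for x in (r1, r2, r3, r4)])
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    mean = r.mean(axis=0)
    cv = r.std(axis=0, ddof=ddof) / mean
    if mean.ndim == 0:
        return float(mean), float(cv)
    return mean, cv


def preselect(mean_r, threshold: float = 20.0):
    """Two-sided pre-selection flag on the mean ratio.

    Selected iff ``mean_r >= threshold`` or ``mean_r <= 1/threshold``;
    symmetric so that swapping cases and controls (which maps the mean
    into the reciprocal regime) preserves selection.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    mean_r = np.asarray(mean_r, dtype=float)
    if (mean_r <= 0).any():
        raise ValueError("mean ratio must be positive")
    out = (mean_r >= threshold) | (mean_r <= 1.0 / threshold)
    return bool(out) if out.ndim == 0 else out


def ratio_table(pool_freqs: pd.DataFrame, case_groups, control_group: str,
                pools_per_group: int = 2, epsilon: float = 1e-4,
                cv_ddof: int = 1,
                preselect_threshold: float = 20.0) -> pd.DataFrame:
    """Per-SNP, per-subtype ratio statistics from a pool-frequency table.

    ``pool_freqs`` is the allelotyping output (snp_id, [chrom, pos],
    pool_id, F_A, callable); pool ids are ``<GROUP><k>`` (e.g. OMA1,
    OMA2, CTR1, CTR2).  SNPs with any non-callable pool among the four
    involved are skipped (dropped rows; counted by the pipeline log).

    Returns columns: snp_id, [chrom, pos], subtype, R1..R4, mean_R,
    cv_R, selected.
    """
    if pools_per_group != 2:
        raise ValueError(
            "ratio statistics are defined for two pools per condition"
        )
    meta_cols = [c for c in ("chrom", "pos") if c in pool_freqs.columns]
    wide_f = pool_freqs.pivot_table(index="snp_id", columns="pool_id",
                                    values="F_A", aggfunc="first")
    wide_call = pool_freqs.pivot_table(index="snp_id", columns="pool_id",
                                       values="callable", aggfunc="first")
    meta = (pool_freqs[["snp_id"] + meta_cols].drop_duplicates("snp_id")
            .set_index("snp_id")) if meta_cols else None

    ctrl_ids = [f"{control_group}{k + 1}" for k in range(2)]
    frames = []
    for subtype in case_groups:
        case_ids = [f"{subtype}{k + 1}" for k in range(2)]
        needed = case_ids + ctrl_ids
        missing = [c for c in needed if c not in wide_f.columns]
        if missing:
            raise ValueError(f"pool(s) {missing} absent from frequency table")
        ok = wide_call[needed].fillna(False).all(axis=1).to_numpy(bool)
        sub = wide_f.loc[ok, needed]
        fc1, fc2, fk1, fk2 = (
            clamp_frequencies(sub[c].to_numpy(), epsilon) for c in needed
        )
        r1, r2, r3, r4 = four_ratios(fc1, fc2, fk1, fk2)
        mean_r, cv_r = mean_cv(r1, r2, r3, r4, ddof=cv_ddof)
        frame = pd.DataFrame({
            "snp_id": sub.index,
            "subtype": subtype,
            "R1": r1, "R2": r2, "R3": r3, "R4": r4,
            "mean_R": mean_r, "cv_R": cv_r,
            "selected": preselect(mean_r, preselect_threshold),
        })
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if meta is not None:
        out = out.merge(meta.reset_index(), on="snp_id", how="left")
        out = out[["snp_id"] + meta_cols + ["subtype", "R1", "R2", "R3",
                                            "R4", "mean_R", "cv_R",
                                            "selected"]]
    return out.sort_values(["subtype", "snp_id"],
                           kind="stable").reset_index(drop=True)
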
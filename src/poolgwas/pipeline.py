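"""End-to-end orchestration of the discovery and replication stages.

``run_discovery`` chains allelotyping -> ratio statistics ->
pre-selection -> per-chromosome Monte-Carlo empirical p -> FDR cut ->
replication shortlist, and ``run_replication`` computes the
case-control association summary for every shortlisted SNP x subtype.
Both operate on in-memory DataFrames (the CLI wraps them with file
I/O), return a run manifest with stage row counts, and are
deterministic given the pipeline seed.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .allelotype import allelotype_table
from .assoc import associate
from .config import PipelineConfig
from .ranking import empirical_p, fdr_select, replication_shortlist, simulate_null
from .ratios import ratio_table

__all__ = ["run_discovery", "run_replication", "discovery_allele_table"]

log = logging.getLogger("poolgwas")


def _pool_groups(pool_ids) -> dict[str, list[str]]:
    """Group pool ids like CTR1/OMA2 by their condition prefix."""
    groups: dict[str, list[str]] = {}
    for pid in pool_ids:
        m = re.fullmatch(r"([A-Za-z_]+)(\d+)", str(pid))
        if not m:
            raise pio.DataError(
                f"pool id {pid!r} is not of the form <GROUP><k>"
            )
        groups.setdefault(m.group(1), []).append(str(pid))
    return {g: sorted(p) for g, p in groups.items()}


def _chrom_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(seed, spawn_key=(5, index))
    return int(state.generate_state(1)[0] % (2 ** 31))


def run_discovery(intensities: pd.DataFrame, annotation: pd.DataFrame,
                  config: PipelineConfig, *,
                  reference_freqs: pd.DataFrame | None = None,
                  control_group: str = "CTR",
                  out_dir: str | Path | None = None) -> dict:
    """Full discovery chain from probe intensities to a shortlist.

    Returns a dict with ``pool_freqs``, ``ratios``, ``candidates``
    (every pre-selected SNP x subtype with its empirical p and FDR
    flag), ``shortlist`` and ``manifest``.  When ``out_dir`` is given,
    every table, the per-chromosome null caches and the manifest are
    written there.
    """
    pool_freqs = allelotype_table(intensities)
    if "chrom" not in pool_freqs.columns:
        pool_freqs = pool_freqs.merge(
            annotation[["snp_id", "chrom", "pos"]], on="snp_id"
        )
    n_noncallable = int((~pool_freqs["callable"]).sum())

    groups = _pool_groups(pool_freqs["pool_id"].unique())
    if control_group not in groups:
        raise pio.DataError(
            f"control group {control_group!r} absent from pool ids"
        )
    case_groups = sorted(g for g in groups if g != control_group)
    ratios = ratio_table(
        pool_freqs, case_groups, control_group,
        epsilon=config.epsilon, cv_ddof=config.cv_ddof,
        preselect_threshold=config.preselect_threshold,
    )
    log.info("ratio stage: %d SNP x subtype rows, %d pre-selected",
             len(ratios), int(ratios["selected"].sum()))

    # mean control-pool frequency per SNP, for shortlist rule B
    ctrl_cols = groups[control_group]
    f_ctrl = (
        pool_freqs[pool_freqs["pool_id"].isin(ctrl_cols)]
        .groupby("snp_id")["F_A"].mean()
    )

    chrom_of = annotation.set_index("snp_id")["chrom"].astype(str)
    ratios["chrom"] = ratios["snp_id"].map(chrom_of)

    candidates = []
    nulls = {}
    chromosomes = sorted(ratios["chrom"].unique())
    for ci, chrom in enumerate(chromosomes):
        sub = ratios[ratios["chrom"] == chrom]
        n_chip = config.chip_profile.get(
            str(chrom), int(sub["snp_id"].nunique())
        )
        observed = None
        if config.null_mode == "empirical":
            # per-SNP quadruples (case1, case2, ctrl1, ctrl2), stacked
            # over subtypes, preserving within-SNP frequency coupling
            quads = []
            wide = pool_freqs[pool_freqs["chrom"] == chrom].pivot_table(
                index="snp_id", columns="pool_id", values="F_A",
                aggfunc="first",
            ).dropna()
            for g in case_groups:
                cols = groups[g] + ctrl_cols
                if all(c in wide.columns for c in cols):
                    quads.append(wide[cols].to_numpy())
            observed = np.concatenate(quads) if quads else None
        null = simulate_null(
            chrom, n_chip, config.n_reps,
            _chrom_seed(config.seed, ci),
            epsilon=config.epsilon, cv_ddof=config.cv_ddof,
            mode=config.null_mode, observed_freqs=observed,
        )
        nulls[chrom] = null
        sel = sub[sub["selected"]]
        if len(sel):
            p = empirical_p(sel["mean_R"].to_numpy(),
                            sel["cv_R"].to_numpy(), null,
                            mode=config.p_mode)
            cand = sel.copy()
            cand["p_mc"] = p
            candidates.append(cand)
        log.info("chromosome %s: null %d pairs, %d pre-selected SNPs",
                 chrom, null.n_pairs, len(sel))

    if candidates:
        candidates = pd.concat(candidates, ignore_index=True)
        candidates["fdr_selected"] = fdr_select(
            candidates["p_mc"].to_numpy(), config.fdr_alpha,
            config.fdr_mode,
        )
    else:
        candidates = pd.DataFrame(
            columns=["snp_id", "chrom", "subtype", "R1", "R2", "R3",
                     "R4", "mean_R", "cv_R", "selected", "p_mc",
                     "fdr_selected"]
        )

    fdr_hits = candidates[candidates["fdr_selected"]].copy()
    fdr_hits["F_ctrl"] = fdr_hits["snp_id"].map(f_ctrl)
    if len(fdr_hits):
        shortlist = replication_shortlist(
            fdr_hits, annotation, reference_freqs,
            stringent_p=config.stringent_p,
            reference_tolerance=config.reference_freq_tolerance,
        )
        if config.shortlist_rule != "both":
            tag = {"wide": "A", "stringent": "B"}[config.shortlist_rule]
            shortlist = shortlist[
                shortlist["shortlist_rule"].str.contains(tag)
            ].reset_index(drop=True)
    else:
        shortlist = fdr_hits.assign(shortlist_rule=pd.Series(dtype=str))

    candidates["shortlist_rule"] = candidates.set_index(
        ["snp_id", "subtype"]
    ).index.map(
        shortlist.set_index(["snp_id", "subtype"])["shortlist_rule"]
        .to_dict().get
    ).fillna("") if len(shortlist) else ""

    n_snps_total = int(ratios["snp_id"].nunique())
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_snp_pool_rows": int(len(pool_freqs)),
        "n_noncallable": n_noncallable,
        "n_snps": n_snps_total,
        "n_ratio_rows": int(len(ratios)),
        "n_preselected": int(ratios["selected"].sum()),
        "n_fdr_selected": int(len(fdr_hits)),
        "n_shortlisted": int(len(shortlist)),
        "null_mode": config.null_mode,
        "p_mode": config.p_mode,
    }
    # row-count accounting: every ratio row is either pre-selected or
    # rejected; skipped (non-callable) SNPs are counted separately
    assert (manifest["n_ratio_rows"]
            == manifest["n_preselected"]
            + int((~ratios["selected"]).sum()))

    result = {"pool_freqs": pool_freqs, "ratios": ratios,
              "candidates": candidates, "shortlist": shortlist,
              "nulls": nulls, "manifest": manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_table(pool_freqs, out / "pool_freqs.tsv", "pool_freq")
        pio.write_table(ratios.drop(columns=["shortlist_rule"],
                                    errors="ignore"),
                        out / "ratios.tsv", "ratio")
        cand_out = candidates[
            ["snp_id", "chrom", "subtype", "mean_R", "cv_R", "p_mc",
             "selected", "shortlist_rule", "fdr_selected"]
        ] if len(candidates) else candidates
        pio.write_table(cand_out, out / "candidates.tsv", "candidate")
        for chrom, null in nulls.items():
            null.save(out / f"null_chr{chrom}.npz")
        pio.write_manifest(out / "manifest.json", **manifest)
    return result


def discovery_allele_table(pool_freqs: pd.DataFrame, snp_id: str,
                           subtype: str, control_group: str = "CTR",
                           n_per_group: int = 20) -> np.ndarray:
    """Approximate discovery-stage 2x2 allele table for one SNP.

    Pooled designs never observe discovery allele *counts*; this
    reconstructs them as pool-frequency point estimates times the
    number of pooled chromosomes (``2 * n_per_group``), rounded — an
    approximation by construction, used only for the cross-stage
    heterogeneity test.  Rows are alleles A/B, columns case/control.
    """
    sub = pool_freqs[pool_freqs["snp_id"] == snp_id]
    groups = _pool_groups(sub["pool_id"].unique())
    table = np.zeros((2, 2))
    for j, g in enumerate((subtype, control_group)):
        if g not in groups:
            raise pio.DataError(f"no pools for group {g!r}")
        f_a = sub.loc[sub["pool_id"].isin(groups[g]), "F_A"].mean()
        n_chrom = 2 * n_per_group
        table[0, j] = round(f_a * n_chrom)
        table[1, j] = n_chrom - table[0, j]
    return table.astype(np.int64)


def run_replication(genotypes: pd.DataFrame, phenotypes: pd.Series,
                    shortlist: pd.DataFrame, config: PipelineConfig, *,
                    control_group: str = "CTR",
                    discovery_pool_freqs: pd.DataFrame | None = None,
                    n_per_discovery_group: int = 20,
                    out_dir: str | Path | None = None) -> dict:
    """Association statistics for every shortlisted SNP x subtype.

    ``shortlist`` needs columns snp_id and subtype.  SNPs absent from
    the genotype matrix are skipped with a warning; a subtype with no
    genotyped individuals raises.  When ``discovery_pool_freqs`` is
    given, the Breslow-Day heterogeneity p across the (approximate)
    discovery stratum and the replication stratum is reported.
    """
    pairs = (shortlist[["snp_id", "subtype"]].drop_duplicates()
             .itertuples(index=False))
    rows = []
    n_skipped = 0
    for snp_id, subtype in pairs:
        if snp_id not in genotypes.columns:
            warnings.warn(f"shortlisted SNP {snp_id!r} absent from "
                          "genotypes; skipped", stacklevel=2)
            n_skipped += 1
            continue
        stratum = None
        if discovery_pool_freqs is not None:
            stratum = discovery_allele_table(
                discovery_pool_freqs, snp_id, subtype, control_group,
                n_per_discovery_group,
            )
        res = associate(
            genotypes, phenotypes, snp_id, subtype, control_group,
            hwe_method=config.hwe_method, discovery_stratum=stratum,
            tarone=config.tarone,
        )
        rows.append({
            "snp_id": res.snp_id, "subtype": res.subtype,
            "chi2": res.chi2, "df": res.df, "p_geno": res.p_geno,
            "risk_allele": res.risk_allele, "OR": res.or_value,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "hwe_p_controls": res.hwe_p_controls, "phet": res.phet,
            "call_rate": res.call_rate,
            "significant": bool(res.p_geno < config.significance_alpha)
            if not np.isnan(res.p_geno) else False,
        })
    assoc = pd.DataFrame(rows, columns=pio.SCHEMAS["association"])
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_shortlisted": int(len(shortlist)),
        "n_tested": int(len(assoc)),
        "n_skipped": n_skipped,
        "n_significant": int(assoc["significant"].sum()) if len(assoc) else 0,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_table(assoc, out / "association.tsv", "association")
        pio.write_manifest(out / "replication_manifest.json", **manifest)
    return {"association": assoc, "manifest": manifest}
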
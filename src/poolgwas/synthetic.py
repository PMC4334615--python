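"""Synthetic pooled-GWAS cohorts: genotypes, DNA pools, probe intensities.

The generator emulates the statistical structure a pooled-array
discovery stage assumes:

* a population allele-frequency spectrum (uniform MAF by default);
* Hardy-Weinberg genotypes within each group, with case groups shifted
  at planted "effect" SNPs so that the allelic odds ratio versus the
  control group equals a configured value;
* non-overlapping DNA pools of equal size per group, in biological
  replicates (two 10-individual pools per condition by default);
* probe-level perfect-match / mismatch (PM/MM) fluorescence for each
  SNP x pool x probe x allele, with log-normal multiplicative noise, a
  constant MM leakage fraction and an additive floor.

Pool allele frequencies are exact functions of the genotypes: all
measurement noise enters through :func:`simulate_intensities`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, NoiseModel

__all__ = [
    "SyntheticCohort",
    "shifted_frequency",
    "generate_cohort",
    "build_pools",
    "simulate_intensities",
]

#: Genotype code for a missing call in the integer genotype matrix.
MISSING = -1


@dataclass
class SyntheticCohort:
    """A simulated case-control cohort with pool structure.

    Attributes
    ----------
    genotypes
        ``(n_individuals, n_snps)`` int8 matrix counting copies of
        allele B (0/1/2), with :data:`MISSING` (-1) for no-calls.
    phenotypes
        Series mapping individual id -> group label.
    pool_assignment
        Series mapping individual id -> pool id, NaN for unpooled
        individuals.
    true_pool_freqs
        ``(n_pools, n_snps)`` exact allele-B frequency per pool,
        computed from the un-masked genotypes (missingness never
        affects pool DNA).
    annotation
        Per-SNP table: snp_id, chrom, pos (1-based), gene_label.
    population_freqs
        ``(n_groups, n_snps)`` allele-B population frequency each
        group's genotypes were drawn from.
    truth
        The planted effect SNPs (indices, groups, odds ratios).
    """

    genotypes: np.ndarray
    phenotypes: pd.Series
    pool_assignment: pd.Series
    pool_ids: list[str]
    true_pool_freqs: np.ndarray
    annotation: pd.DataFrame
    population_freqs: pd.DataFrame
    truth: tuple
    config: CohortConfig
    #: per pool: (pool_size, n_snps) un-masked genotypes of its members,
    #: used only when simulating unequal DNA contributions
    pool_member_genotypes: dict | None = None

    @property
    def snp_ids(self) -> np.ndarray:
        return self.annotation["snp_id"].to_numpy()

    def genotype_frame(self) -> pd.DataFrame:
        """Genotypes as individuals x SNPs DataFrame (NA for missing)."""
        df = pd.DataFrame(
            self.genotypes.astype(float),
            index=self.phenotypes.index,
            columns=self.annotation["snp_id"],
        )
        return df.mask(df < 0)


def shifted_frequency(p: np.ndarray | float, odds_ratio: float) -> np.ndarray | float:
    """Case allele frequency under an allelic odds-ratio shift.

    Solves ``OR = [p_case/(1-p_case)] / [p/(1-p)]`` for ``p_case``:
    ``p_case = OR*p / (1 - p + OR*p)``.  ``OR = 1`` returns ``p``
    unchanged; the map is monotone in both arguments.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    p = np.asarray(p, dtype=float)
    out = odds_ratio * p / (1.0 - p + odds_ratio * p)
    return float(out) if out.ndim == 0 else out


def _spawn(seed: int, *path: int) -> np.random.Generator:
    """Derive an independent child stream from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate genotypes, phenotypes and pool structure for a cohort.

    Every group shares one population frequency per SNP except at
    planted effect SNPs, where the configured case groups are shifted
    by the allelic odds ratio before Hardy-Weinberg sampling.
    Deterministic given ``config.seed``.
    """
    n_snps = config.n_snps
    rng_freq = _spawn(config.seed, 0)
    base_freq = rng_freq.uniform(config.maf_low, config.maf_high, n_snps)
    if config.random_allele_labels:
        # the array's B allele is the minor allele for only ~half the
        # SNPs; planted effect SNPs keep B = minor so the configured OR
        # acts on the risk (minor) allele
        flip = rng_freq.random(n_snps) < 0.5
        flip[[e.snp_index for e in config.effect_snps]] = False
        base_freq = np.where(flip, 1.0 - base_freq, base_freq)

    group_freqs = {g: base_freq.copy() for g in config.groups}
    for eff in config.effect_snps:
        for g in eff.groups:
            group_freqs[g][eff.snp_index] = shifted_frequency(
                base_freq[eff.snp_index], eff.odds_ratio
            )

    # annotation: SNPs laid out consecutively along chromosomes,
    # 10 kb apart, with a gene label every 4 SNPs so that shortlist
    # rules based on shared gene regions are exercised.
    chroms = np.repeat(
        [str(i + 1) for i in range(config.n_chromosomes)],
        config.snps_per_chromosome,
    )
    pos = np.concatenate(
        [10_000 * (np.arange(n) + 1) for n in config.snps_per_chromosome]
    ).astype(np.int64)
    snp_ids = np.array([f"snp{i:06d}" for i in range(n_snps)])
    gene_labels = np.array(
        [f"GENE{c}_{p // 40_000}" for c, p in zip(chroms, pos)]
    )
    annotation = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": chroms, "pos": pos,
         "gene_label": gene_labels}
    )

    n_per_group = config.n_individuals_per_group
    individuals: list[str] = []
    groups_col: list[str] = []
    geno_blocks: list[np.ndarray] = []
    for gi, g in enumerate(config.groups):
        rng_g = _spawn(config.seed, 1, gi)
        p = group_freqs[g]
        # HWE within group: genotype = sum of two Bernoulli(p) alleles
        alleles = rng_g.random((n_per_group, 2, n_snps)) < p
        geno_blocks.append(alleles.sum(axis=1).astype(np.int8))
        individuals.extend(f"{g}_{i:03d}" for i in range(n_per_group))
        groups_col.extend([g] * n_per_group)
    genotypes = np.concatenate(geno_blocks, axis=0)

    phenotypes = pd.Series(groups_col, index=pd.Index(individuals,
                                                      name="individual_id"),
                           name="group")

    # pools: first pools_per_group * pool_size individuals of each group
    pool_assignment = pd.Series(pd.NA, index=phenotypes.index,
                                dtype="object", name="pool_id")
    pool_ids: list[str] = []
    for g in config.groups:
        members = phenotypes.index[phenotypes == g]
        for k in range(config.pools_per_group):
            pid = f"{g}{k + 1}"
            pool_ids.append(pid)
            sel = members[k * config.pool_size:(k + 1) * config.pool_size]
            pool_assignment.loc[sel] = pid

    true_pool_freqs = build_pools(genotypes, phenotypes.index,
                                  pool_assignment, pool_ids,
                                  config.pool_size)
    loc = {ind: i for i, ind in enumerate(phenotypes.index)}
    assigned = pool_assignment.dropna()
    pool_member_genotypes = {
        pid: genotypes[[loc[m] for m in assigned.index[assigned == pid]], :]
        for pid in pool_ids
    }

    # genotype missingness is applied after pooling: pooled DNA exists
    # regardless of whether the individual genotyping call succeeded
    if config.missing_rate > 0:
        rng_miss = _spawn(config.seed, 2)
        mask = rng_miss.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = MISSING

    population_freqs = pd.DataFrame(group_freqs, index=snp_ids).T
    return SyntheticCohort(
        genotypes=genotypes,
        phenotypes=phenotypes,
        pool_assignment=pool_assignment,
        pool_ids=pool_ids,
        true_pool_freqs=true_pool_freqs,
        annotation=annotation,
        population_freqs=population_freqs,
        truth=config.effect_snps,
        config=config,
        pool_member_genotypes=pool_member_genotypes,
    )


def build_pools(genotypes: np.ndarray, individuals: pd.Index,
                pool_assignment: pd.Series, pool_ids: list[str],
                pool_size: int) -> np.ndarray:
    """Exact pool allele frequencies from genotypes.

    Pool frequency = (sum of allele-B copies in the pool) / (2 *
    pool_size), so values lie on the grid ``k / (2 * pool_size)``.
    Raises if any pool is short, oversized, or shares an individual
    with another pool.
    """
    assigned = pool_assignment.dropna()
    if assigned.index.duplicated().any():
        raise ValueError("an individual is assigned to more than one pool")
    loc = {ind: i for i, ind in enumerate(individuals)}
    freqs = np.empty((len(pool_ids), genotypes.shape[1]))
    for pi, pid in enumerate(pool_ids):
        members = assigned.index[assigned == pid]
        if len(members) != pool_size:
            raise ValueError(
                f"pool {pid!r} has {len(members)} members, expected {pool_size}"
            )
        rows = genotypes[[loc[m] for m in members], :]
        if (rows < 0).any():
            raise ValueError(f"pool {pid!r} contains missing genotypes")
        freqs[pi] = rows.sum(axis=0) / (2.0 * pool_size)
    return freqs


def simulate_intensities(cohort: SyntheticCohort,
                         noise: NoiseModel | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Probe-level PM/MM intensities for every SNP x pool x probe x allele.

    For allele B with true pool frequency ``q`` (and A with ``1 - q``)::

        PM = signal_scale * freq * L + additive_floor
        MM = background_mm_fraction * signal_scale * freq * M + additive_floor

    where ``L, M`` are independent log-normal factors with unit mean and
    CV ``multiplicative_cv`` (degenerate at 1 when the CV is zero).  The
    additive floor enters both PM and MM, so the background-corrected
    signal ``PM - MM`` is exactly proportional to frequency in the
    noise-free limit.

    Returns the probe-intensity table (columns: snp_id, chrom, pos,
    probe_idx, allele, PM, MM, pool_id); deterministic given ``seed``.
    """
    cfg = cohort.config
    noise = noise if noise is not None else cfg.noise
    seed = cfg.seed if seed is None else seed
    rng = _spawn(seed, 3)

    freq_b = cohort.true_pool_freqs  # (n_pools, n_snps)
    if ((freq_b < 0) | (freq_b > 1)).any():
        raise ValueError("pool frequencies must lie in [0, 1]")
    n_pools, n_snps = freq_b.shape
    n_probes = noise.probes_per_snp_per_allele

    if cfg.pool_weight_jitter > 0 and cohort.pool_member_genotypes:
        # unequal DNA contributions within a pool (off by default): each
        # member's DNA quantity gets a log-normal weight, shifting the
        # effective hybridized frequency away from the exact pool count
        freq_b = freq_b.copy()
        for pi, pid in enumerate(cohort.pool_ids):
            g = cohort.pool_member_genotypes[pid].astype(float)
            w = rng.lognormal(0.0, cfg.pool_weight_jitter, size=(len(g), 1))
            freq_b[pi] = (w * g).sum(axis=0) / (2.0 * w.sum())

    # stack: allele A frequency is 1 - q, allele B frequency is q
    freq = np.stack([1.0 - freq_b, freq_b])  # (2, n_pools, n_snps)

    shape = (2, n_pools, n_snps, n_probes)
    if noise.multiplicative_cv > 0:
        sigma2 = np.log1p(noise.multiplicative_cv ** 2)
        mu = -0.5 * sigma2
        ln = rng.lognormal(mu, np.sqrt(sigma2), size=(2,) + shape)
        pm_noise, mm_noise = ln[0], ln[1]
    else:
        pm_noise = mm_noise = np.ones(shape)

    signal = noise.signal_scale * freq[..., None]  # noise-free allele signal
    pm = signal * pm_noise + noise.additive_floor
    mm = (noise.background_mm_fraction * signal * mm_noise
          + noise.additive_floor)

    ann = cohort.annotation
    idx = pd.MultiIndex.from_product(
        [["A", "B"], cohort.pool_ids, ann["snp_id"], range(n_probes)],
        names=["allele", "pool_id", "snp_id", "probe_idx"],
    )
    table = pd.DataFrame(
        {"PM": pm.ravel(), "MM": mm.ravel()}, index=idx
    ).reset_index()
    table = table.merge(ann[["snp_id", "chrom", "pos"]], on="snp_id")
    return table[["snp_id", "chrom", "pos", "probe_idx", "allele",
                  "PM", "MM", "pool_id"]].sort_values(
        ["snp_id", "pool_id", "allele", "probe_idx"], kind="stable",
    ).reset_index(drop=True)
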
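"""Monte-Carlo empirical null, FDR cut and replication-candidate rules.

The discovery statistic for a SNP is the pair (mean of four case/control
frequency ratios, their CV).  Its significance is judged against an
artificial chromosome: ``n_snps x n_reps`` simulated SNPs, each with
four random pool frequencies pushed through the identical ratio
machinery.  A pair is "at least as extreme" as an observation when its
mean is at least as far from 1 in the same direction and its CV is no
larger — large, replicate-consistent shifts are rewarded, noisy ones
penalized.

Two quantities derive from that ordering:

* the *dominance probability* ``(1 + #extreme) / (1 + N)`` — the raw
  chance of a random pair landing in the observation's rejection
  region (``mode="dominance"``);
* the *calibrated empirical p* — the rank of the observation's
  dominance probability within the null's own dominance probabilities
  (``mode="calibrated"``, the default).  The dominance probability of
  a random null pair is not itself uniform (it is a joint tail
  probability evaluated at a random point), so it is used as an
  ordering score and re-ranked against the null, which makes the
  resulting p uniform under the null by construction while preserving
  the add-one floor ``1 / (N + 1)``.

Both regimes (enriched, mean >= 1; depleted, mean < 1) are mirrored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ratios import clamp_frequencies, four_ratios, mean_cv

__all__ = [
    "NullDistribution",
    "simulate_null",
    "dominance_counts",
    "empirical_p",
    "fdr_select",
    "replication_shortlist",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(fn):
            return fn
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False)
def _bit_sweep(ins_key, ins_rank, q_key, q_rank, n_ranks):  # pragma: no cover
    """Offline 2D dominance counting with a Fenwick tree.

    Both streams sorted by key descending; for each query j, counts
    inserted items with ``key >= q_key[j]`` (ties inclusive) and
    ``rank <= q_rank[j]``.
    """
    tree = np.zeros(n_ranks + 1, dtype=np.int64)
    counts = np.empty(len(q_key), dtype=np.int64)
    i = 0
    n_ins = len(ins_key)
    for j in range(len(q_key)):
        while i < n_ins and ins_key[i] >= q_key[j]:
            r = ins_rank[i] + 1
            while r <= n_ranks:
                tree[r] += 1
                r += r & (-r)
            i += 1
        s = 0
        r = q_rank[j] + 1
        while r > 0:
            s += tree[r]
            r -= r & (-r)
        counts[j] = s
    return counts


def _sweep_counts(ins_key: np.ndarray, ins_cv: np.ndarray,
                  q_key: np.ndarray, q_cv: np.ndarray) -> np.ndarray:
    """#{i: ins_key >= q_key_j and ins_cv <= q_cv_j} for every query."""
    if len(q_key) == 0:
        return np.zeros(0, dtype=np.int64)
    all_cv = np.unique(np.concatenate([ins_cv, q_cv]))
    ins_rank = np.searchsorted(all_cv, ins_cv)
    q_rank = np.searchsorted(all_cv, q_cv)
    ins_order = np.argsort(-ins_key, kind="stable")
    q_order = np.argsort(-q_key, kind="stable")
    counts_sorted = _bit_sweep(
        np.ascontiguousarray(ins_key[ins_order]),
        np.ascontiguousarray(ins_rank[ins_order]),
        np.ascontiguousarray(q_key[q_order]),
        np.ascontiguousarray(q_rank[q_order]),
        len(all_cv),
    )
    counts = np.empty_like(counts_sorted)
    counts[q_order] = counts_sorted
    return counts


def dominance_counts(null_mean: np.ndarray, null_cv: np.ndarray,
                     obs_mean: np.ndarray, obs_cv: np.ndarray) -> np.ndarray:
    """Number of null pairs at least as extreme as each observation.

    Enriched regime (``obs_mean >= 1``): null mean >= obs mean and null
    CV <= obs CV.  Depleted regime (``obs_mean < 1``): null mean <= obs
    mean and null CV <= obs CV.  O((N+Q) log(N+Q)).
    """
    obs_mean = np.atleast_1d(np.asarray(obs_mean, dtype=float))
    obs_cv = np.atleast_1d(np.asarray(obs_cv, dtype=float))
    counts = np.empty(len(obs_mean), dtype=np.int64)
    high = obs_mean >= 1.0
    if high.any():
        counts[high] = _sweep_counts(null_mean, null_cv,
                                     obs_mean[high], obs_cv[high])
    if (~high).any():
        counts[~high] = _sweep_counts(-null_mean, null_cv,
                                      -obs_mean[~high], obs_cv[~high])
    return counts


@dataclass
class NullDistribution:
    """Cached Monte-Carlo null for one chromosome.

    ``mean``/``cv`` hold the simulated pairs; ``scores`` holds each
    null pair's own dominance probability (sorted), the reference
    distribution for calibrated empirical p-values.
    """

    chromosome: str
    n_snps: int
    n_reps: int
    seed: int
    mode: str
    mean: np.ndarray
    cv: np.ndarray
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean.shape != (self.n_snps * self.n_reps,):
            raise ValueError("null size must equal n_snps * n_reps")
        if (self.mean <= 0).any():
            raise ValueError("simulated means must be positive")
        if self.scores is None:
            n = len(self.mean)
            self_counts = dominance_counts(self.mean, self.cv,
                                           self.mean, self.cv)
            self.scores = np.sort((1.0 + self_counts) / (1.0 + n))

    @property
    def n_pairs(self) -> int:
        return len(self.mean)

    def save(self, path) -> None:
        np.savez_compressed(
            path, chromosome=self.chromosome, n_snps=self.n_snps,
            n_reps=self.n_reps, seed=self.seed, mode=self.mode,
            mean=self.mean, cv=self.cv, scores=self.scores,
        )

    @classmethod
    def load(cls, path) -> "NullDistribution":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                chromosome=str(z["chromosome"]), n_snps=int(z["n_snps"]),
                n_reps=int(z["n_reps"]), seed=int(z["seed"]),
                mode=str(z["mode"]), mean=z["mean"], cv=z["cv"],
                scores=z["scores"],
            )


def simulate_null(chromosome: str, n_snps: int, n_reps: int = 1000,
                  seed: int = 0, *, epsilon: float = 1e-4,
                  cv_ddof: int = 1, mode: str = "uniform",
                  observed_freqs: np.ndarray | None = None,
                  compute_scores: bool = True) -> NullDistribution:
    """Simulate the (mean, CV) null for one artificial chromosome.

    ``mode="uniform"`` draws each of the four pool frequencies
    independently Uniform(0, 1) and clamps with the pipeline's epsilon.
    ``mode="empirical"`` resamples observed per-SNP frequency quadruples
    (``observed_freqs``: rows of [case1, case2, ctrl1, ctrl2]) and
    randomly permutes each quadruple across the case/control slots — a
    permutation null that preserves the within-SNP coupling of the four
    frequencies.  Deterministic given ``seed``.
    """
    if n_snps < 1 or n_reps < 1:
        raise ValueError("n_snps and n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    n = n_snps * n_reps
    if mode == "uniform":
        freqs = rng.random((n, 4))
    elif mode == "empirical":
        if observed_freqs is None or len(observed_freqs) == 0:
            raise ValueError("empirical mode requires observed_freqs")
        obs = np.asarray(observed_freqs, dtype=float)
        rows = rng.integers(0, len(obs), size=n)
        perm = np.argsort(rng.random((n, 4)), axis=1)
        freqs = obs[rows[:, None], perm]
    else:
        raise ValueError("mode must be 'uniform' or 'empirical'")
    freqs = clamp_frequencies(freqs, epsilon)
    r = four_ratios(freqs[:, 0], freqs[:, 1], freqs[:, 2], freqs[:, 3])
    mean, cv = mean_cv(*r, ddof=cv_ddof)
    null = NullDistribution.__new__(NullDistribution)
    null.chromosome = str(chromosome)
    null.n_snps = n_snps
    null.n_reps = n_reps
    null.seed = seed
    null.mode = mode
    null.mean = mean
    null.cv = cv
    null.scores = None
    if compute_scores:
        null.__post_init__()
    else:
        if (mean <= 0).any():
            raise ValueError("simulated means must be positive")
    return null


def empirical_p(mean_obs, cv_obs, null: NullDistribution,
                mode: str = "calibrated") -> np.ndarray | float:
    """Empirical probability of a (mean, CV) pair under the null.

    ``mode="dominance"`` returns the raw dominance probability
    ``(1 + #extreme) / (1 + N)``; ``mode="calibrated"`` (default)
    returns its rank among the null's own dominance probabilities,
    ``(1 + #{null score <= obs score}) / (1 + N)``, which is uniform
    under the null.  Either way p is in ``(0, 1]`` with floor
    ``1 / (N + 1)``.
    """
    scalar = np.isscalar(mean_obs) or np.ndim(mean_obs) == 0
    mean_arr = np.atleast_1d(np.asarray(mean_obs, dtype=float))
    cv_arr = np.atleast_1d(np.asarray(cv_obs, dtype=float))
    if mean_arr.shape != cv_arr.shape:
        raise ValueError("mean_obs and cv_obs must have the same shape")
    n = null.n_pairs
    counts = dominance_counts(null.mean, null.cv, mean_arr, cv_arr)
    score = (1.0 + counts) / (1.0 + n)
    if mode == "dominance":
        p = score
    elif mode == "calibrated":
        if null.scores is None:
            raise ValueError("null distribution lacks cached scores")
        ranks = np.searchsorted(null.scores, score, side="right")
        p = (1.0 + ranks) / (1.0 + n)
    else:
        raise ValueError("mode must be 'calibrated' or 'dominance'")
    return float(p[0]) if scalar else p


def fdr_select(p_values, alpha: float = 0.05,
               mode: str = "paper") -> np.ndarray:
    """Significance mask over empirical p-values.

    ``mode="paper"`` keeps ``p < alpha`` (the original study equated
    the empirical p < 0.05 cut with a 5% FDR); ``mode="bh"`` applies
    Benjamini-Hochberg at level ``alpha``.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mode == "paper":
        return p < alpha
    if mode == "bh":
        return multipletests(p, alpha=alpha, method="fdr_bh")[0]
    raise ValueError("mode must be 'paper' or 'bh'")


def replication_shortlist(selected: pd.DataFrame,
                          annotation: pd.DataFrame,
                          reference_freqs: pd.DataFrame | None = None,
                          *, stringent_p: float = 0.001,
                          reference_tolerance: float = 0.1) -> pd.DataFrame:
    """Apply the replication-candidate rules to FDR-selected SNPs.

    Rule set A (wide): keep SNPs whose gene label carries >= 2 distinct
    selected SNPs, or that are selected in >= 2 case subtypes.  Rule
    set B (stringent): empirical p <= ``stringent_p`` and control pool
    frequency within ``reference_tolerance`` of the external reference
    frequency (a stand-in for a population panel); when no reference
    table is supplied only the p condition applies.

    ``selected`` needs columns snp_id, subtype, p_mc and, for rule B
    with a reference, F_ctrl (mean control pool frequency of the
    array's A allele).  Returns the input rows that pass either rule,
    with a ``shortlist_rule`` tag ("A", "B" or "A+B").
    """
    required = {"snp_id", "subtype", "p_mc"}
    if not required <= set(selected.columns):
        raise ValueError(f"selected needs columns {sorted(required)}")
    sel = selected.copy()
    ann = annotation.set_index("snp_id")["gene_label"] if len(annotation) else pd.Series(dtype=object)
    gene = sel["snp_id"].map(ann)
    missing_ann = sel.loc[gene.isna(), "snp_id"].unique()
    if len(missing_ann):
        warnings.warn(
            f"{len(missing_ann)} selected SNP(s) lack annotation "
            f"(e.g. {missing_ann[0]}); kept only under subtype sharing",
            stacklevel=2,
        )
    sel["gene_label"] = gene

    n_subtypes = sel.groupby("snp_id")["subtype"].transform("nunique")
    snps_in_gene = (
        sel.dropna(subset=["gene_label"])
        .groupby("gene_label")["snp_id"].nunique()
    )
    gene_share = sel["gene_label"].map(snps_in_gene).fillna(0) >= 2
    rule_a = gene_share | (n_subtypes >= 2)

    rule_b = sel["p_mc"] <= stringent_p
    if reference_freqs is not None:
        if "F_ctrl" not in sel.columns:
            raise ValueError("rule B with a reference table needs F_ctrl")
        ref = reference_freqs.set_index("snp_id")["F_ref"]
        diff = (sel["F_ctrl"] - sel["snp_id"].map(ref)).abs()
        rule_b &= diff <= reference_tolerance

    keep = rule_a | rule_b
    tag = np.where(rule_a & rule_b, "A+B", np.where(rule_a, "A", "B"))
    out = sel.loc[keep].copy()
    out["shortlist_rule"] = tag[keep.to_numpy()]
    return out.reset_index(drop=True)
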
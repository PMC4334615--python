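"""Case-control association statistics for individually genotyped SNPs.

The replication stage tests each candidate SNP in one case subtype
against the controls:

* genotypic association — Pearson chi-square on the 3x2 genotype table
  (AA/AB/BB x case/control), all-zero genotype rows dropped, no
  continuity correction;
* allelic odds ratio — cross-product ratio on the derived 2x2 allele
  table, oriented to the case-enriched allele so OR >= 1, with a 95%
  Woolf confidence interval
  ``exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells))``;
* Hardy-Weinberg equilibrium in controls — chi-square goodness of fit
  (1 df) by default, exact test optionally;
* Breslow-Day heterogeneity of the odds ratio across strata (e.g.
  discovery vs replication stage), with the Tarone correction on by
  default;
* per-SNP call rate from missing genotype calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "AssociationResult",
    "tabulate",
    "genotypic_chi2",
    "allelic_or",
    "hwe_test",
    "breslow_day",
    "mantel_haenszel_or",
    "associate",
]

MISSING = -1


@dataclass(frozen=True)
class GenotypeCounts:
    """3x2 genotype contingency table for one SNP (case vs control).

    ``case``/``control`` are (AA, AB, BB) counts — copies of allele B
    ascending.  Allele counts derive as 2*hom + het per allele.
    """

    snp_id: str
    case_label: str
    control_label: str
    case: tuple[int, int, int]
    control: tuple[int, int, int]
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        for counts in (self.case, self.control):
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValueError("genotype counts must be 3 non-negative ints")
        if not 0 <= self.call_rate <= 1:
            raise ValueError("call_rate must be in [0, 1]")

    @property
    def table(self) -> np.ndarray:
        """3x2 array, rows AA/AB/BB, columns case/control."""
        return np.array([self.case, self.control], dtype=np.int64).T

    @property
    def allele_table(self) -> np.ndarray:
        """2x2 allele counts, rows A/B, columns case/control."""
        ca, cb = self.case, self.control
        return np.array(
            [[2 * ca[0] + ca[1], 2 * cb[0] + cb[1]],
             [2 * ca[2] + ca[1], 2 * cb[2] + cb[1]]], dtype=np.int64
        )

    def allele_percent(self) -> dict[str, tuple[float, float]]:
        """Per-group allele percentages {(group): (%A, %B)}."""
        at = self.allele_table
        out = {}
        for j, label in enumerate((self.case_label, self.control_label)):
            tot = at[:, j].sum()
            out[label] = (100.0 * at[0, j] / tot, 100.0 * at[1, j] / tot)
        return out


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    subtype: str
    chi2: float
    df: int
    p_geno: float
    or_value: float
    ci_low: float
    ci_high: float
    risk_allele: str
    hwe_p_controls: float
    phet: float
    call_rate: float
    degenerate: bool = False
    haldane: bool = False


def tabulate(genotypes: pd.DataFrame, phenotypes: pd.Series, snp_id: str,
             subtype: str, control_label: str = "CTR") -> GenotypeCounts:
    """Genotype contingency table for one SNP, one subtype vs controls.

    ``genotypes`` is individuals x SNPs with values 0/1/2 (copies of
    allele B) and NaN or -1 for missing; missing calls are excluded
    listwise per SNP and reflected in the call rate.
    """
    if snp_id not in genotypes.columns:
        raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
    members = {}
    for label in (subtype, control_label):
        idx = phenotypes.index[phenotypes == label]
        if len(idx) == 0:
            raise ValueError(f"no individuals with phenotype {label!r}")
        members[label] = idx
    col = genotypes[snp_id]
    counts = {}
    n_total = n_called = 0
    for label, idx in members.items():
        g = pd.to_numeric(col.loc[idx], errors="coerce")
        g = g.where(g >= 0)  # -1 missing code -> NaN
        n_total += len(g)
        called = g.dropna().astype(int)
        n_called += len(called)
        counts[label] = tuple(int((called == k).sum()) for k in (0, 1, 2))
    if n_called == 0:
        raise ValueError(f"SNP {snp_id!r}: all genotypes missing")
    return GenotypeCounts(
        snp_id=snp_id, case_label=subtype, control_label=control_label,
        case=counts[subtype], control=counts[control_label],
        call_rate=n_called / n_total,
    )


def genotypic_chi2(counts: GenotypeCounts) -> tuple[float, int, float]:
    """Pearson chi-square on the 3x2 genotype table.

    All-zero genotype rows are dropped first; df = (r-1)(c-1) on the
    reduced table; no continuity correction.  A degenerate table (a
    single non-zero genotype row, or an empty group) yields
    ``(nan, 0, nan)``.
    """
    table = counts.table
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return float("nan"), 0, float("nan")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def allelic_or(counts: GenotypeCounts) -> tuple[float, float, float, str, bool]:
    """Oriented allelic odds ratio with 95% Woolf confidence interval.

    The 2x2 allele table is oriented to the case-enriched allele so
    that OR >= 1; the CI is
    ``exp(ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``.  A zero cell
    triggers the Haldane-Anscombe +0.5 correction on all cells (the
    returned flag reports it).
    """
    at = counts.allele_table.astype(float)  # rows A/B, cols case/control
    haldane = (at == 0).any()
    if haldane:
        at = at + 0.5
    # odds of allele B in cases over controls
    or_b = (at[1, 0] * at[0, 1]) / (at[0, 0] * at[1, 1])
    if or_b >= 1.0:
        or_value, risk_allele = or_b, "B"
    else:
        or_value, risk_allele = 1.0 / or_b, "A"
    se = math.sqrt((1.0 / at).sum())
    half = 1.96 * se
    ci_low = or_value * math.exp(-half)
    ci_high = or_value * math.exp(half)
    return float(or_value), float(ci_low), float(ci_high), risk_allele, bool(haldane)


def hwe_test(control_counts, method: str = "chisq") -> tuple[float, bool]:
    """Hardy-Weinberg equilibrium test on (AA, AB, BB) control counts.

    ``method="chisq"``: 1-df chi-square goodness of fit against
    p^2 / 2pq / q^2 expectations at the observed allele frequency.
    ``method="exact"``: conditional exact test (sum of probabilities of
    heterozygote counts no more likely than the observed one, given the
    allele counts).  Returns ``(p, monomorphic)``: a monomorphic SNP
    has no HWE departure to test and reports p = 1 with a flag.
    """
    n_aa, n_ab, n_bb = (int(c) for c in control_counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb == 0:
        raise ValueError("need non-negative counts with positive total")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0, True
    if method == "chisq":
        p = n_a / (2.0 * n)
        expected = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
        observed = np.array([n_aa, n_ab, n_bb], dtype=float)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        return float(stats.chi2.sf(chi2, df=1)), False
    if method == "exact":
        return _hwe_exact(n_ab, n_a, n_b), False
    raise ValueError("method must be 'chisq' or 'exact'")


def _hwe_exact(n_ab: int, n_a: int, n_b: int) -> float:
    """Exact HWE p: enumerate heterozygote counts given allele counts."""
    rare = min(n_a, n_b)
    n = (n_a + n_b) // 2
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant, via log-gammas
    lg = math.lgamma
    logp = np.array([
        h * math.log(2) - lg(h + 1) - lg((rare - h) // 2 + 1)
        - lg(n - (rare + h) // 2 + 1)
        for h in hets
    ])
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_ab)]
    return float(prob[prob <= obs + 1e-12].sum())


def mantel_haenszel_or(strata: list[np.ndarray]) -> float:
    """Mantel-Haenszel common odds ratio across 2x2 strata."""
    num = den = 0.0
    for t in strata:
        t = np.asarray(t, dtype=float)
        n = t.sum()
        num += t[0, 0] * t[1, 1] / n
        den += t[0, 1] * t[1, 0] / n
    if den == 0:
        raise ValueError("Mantel-Haenszel OR undefined (zero denominator)")
    return num / den


def breslow_day(strata: list[np.ndarray],
                tarone: bool = True) -> tuple[float, float]:
    """Breslow-Day test of odds-ratio homogeneity across 2x2 strata.

    For each stratum the expected count of cell (0, 0) under the
    Mantel-Haenszel common OR solves the usual quadratic; the statistic
    sums squared deviations over asymptotic variances, with Tarone's
    adjustment (subtracting the squared summed deviation over the
    summed variance) by default.  df = K - 1.  Strata with a zero
    margin carry no information about the OR and are dropped with a
    warning.
    """
    clean = []
    for t in strata:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn("dropping stratum with a zero margin",
                          stacklevel=2)
            continue
        clean.append(t)
    if len(clean) < 2:
        raise ValueError("Breslow-Day needs at least 2 informative strata")
    or_mh = mantel_haenszel_or(clean)
    stat = 0.0
    sum_dev = 0.0
    sum_var = 0.0
    for t in clean:
        a = t[0, 0]
        row1, row2 = t[0].sum(), t[1].sum()
        col1 = t[:, 0].sum()
        n = t.sum()
        if or_mh == 1.0:
            e = row1 * col1 / n
        else:
            # E[a] under the common OR solves
            # (psi-1) E^2 - [psi (row1+col1) + (N - row1 - col1)] E
            #   + psi row1 col1 = 0; keep the root with all four
            # expected cells positive
            coef_a = or_mh - 1.0
            coef_b = -((row1 + col1) * or_mh + (n - row1 - col1))
            coef_c = or_mh * row1 * col1
            disc = math.sqrt(coef_b * coef_b - 4 * coef_a * coef_c)
            lo = max(0.0, row1 + col1 - n)
            hi = min(row1, col1)
            e = None
            for root in ((-coef_b - disc) / (2 * coef_a),
                         (-coef_b + disc) / (2 * coef_a)):
                if lo < root < hi:
                    e = root
                    break
            if e is None:
                raise ValueError("no admissible Breslow-Day expected count")
        v = 1.0 / (1.0 / e + 1.0 / (row1 - e) + 1.0 / (col1 - e)
                   + 1.0 / (n - row1 - col1 + e))
        dev = a - e
        stat += dev * dev / v
        sum_dev += dev
        sum_var += v
    if tarone:
        stat -= sum_dev * sum_dev / sum_var
    df = len(clean) - 1
    return float(stat), float(stats.chi2.sf(stat, df=df))


def associate(genotypes: pd.DataFrame, phenotypes: pd.Series, snp_id: str,
              subtype: str, control_label: str = "CTR", *,
              hwe_method: str = "chisq",
              discovery_stratum: np.ndarray | None = None,
              tarone: bool = True) -> AssociationResult:
    """Full association summary for one SNP and subtype.

    ``discovery_stratum`` is an optional 2x2 allele table from the
    pooled discovery stage; when given, the Breslow-Day heterogeneity p
    across {discovery, replication} is reported, otherwise Phet is NaN.
    """
    counts = tabulate(genotypes, phenotypes, snp_id, subtype, control_label)
    chi2, df, p_geno = genotypic_chi2(counts)
    or_value, ci_low, ci_high, risk, haldane = allelic_or(counts)
    hwe_p, _mono = hwe_test(counts.control, method=hwe_method)
    if discovery_stratum is not None:
        try:
            _, phet = breslow_day(
                [np.asarray(discovery_stratum), counts.allele_table],
                tarone=tarone,
            )
        except ValueError:
            phet = float("nan")
    else:
        phet = float("nan")
    return AssociationResult(
        snp_id=snp_id, subtype=subtype, chi2=chi2, df=df, p_geno=p_geno,
        or_value=or_value, ci_low=ci_low, ci_high=ci_high,
        risk_allele=risk, hwe_p_controls=hwe_p, phet=phet,
        call_rate=counts.call_rate, degenerate=math.isnan(chi2),
        haldane=haldane,
    )
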
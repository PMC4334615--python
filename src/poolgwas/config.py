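"""Configuration objects for the pooled-GWAS pipeline.

Two families of settings live here:

* :class:`CohortConfig` / :class:`NoiseModel` describe a synthetic
  case-control population hybridized as DNA pools — group sizes, pool
  layout, the minor-allele-frequency spectrum, planted risk alleles and
  the array noise model.
* :class:`PipelineConfig` collects every analysis threshold (epsilon
  clamp, CV convention, pre-selection threshold, Monte-Carlo replicate
  count, FDR level and mode, shortlist rules) plus the chip profile, so
  that no stage hard-codes a tunable.

All configs validate eagerly on construction and reject unknown keys
when loaded from TOML/YAML, so a typo in a config file fails fast with
a message naming the offending key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

__all__ = [
    "NoiseModel",
    "EffectSnp",
    "CohortConfig",
    "PipelineConfig",
    "ConfigError",
    "load_pipeline_config",
]

#: Case-subtype labels: superficial peritoneal (SUP), ovarian
#: endometrioma (OMA), deep infiltrating (DIE) endometriosis; CTR are
#: surgically verified controls.
DEFAULT_GROUPS = ("CTR", "SUP", "OMA", "DIE")


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass(frozen=True)
class NoiseModel:
    """Array-noise model for simulated probe intensities.

    The signal model is linear in allele frequency: a perfect-match (PM)
    probe for an allele reads ``signal_scale * freq`` fluorescence units
    before noise, the paired mismatch (MM) probe sees a constant
    fraction of that signal as leakage, and both sit on a common
    additive floor.  Multiplicative noise is log-normal with unit mean
    and coefficient of variation ``multiplicative_cv`` per probe.
    """

    probes_per_snp_per_allele: int = 5
    signal_scale: float = 1000.0
    background_mm_fraction: float = 0.1
    multiplicative_cv: float = 0.1
    additive_floor: float = 20.0

    def __post_init__(self) -> None:
        if self.probes_per_snp_per_allele < 1:
            raise ConfigError("probes_per_snp_per_allele must be >= 1")
        for name in ("signal_scale", "background_mm_fraction",
                     "multiplicative_cv", "additive_floor"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.multiplicative_cv >= 1:
            raise ConfigError("multiplicative_cv must be < 1")


@dataclass(frozen=True)
class EffectSnp:
    """A planted risk allele: SNP index, affected case group(s), allelic OR."""

    snp_index: int
    groups: tuple[str, ...]
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ConfigError("effect odds ratio must be > 0")
        if isinstance(self.groups, str):
            object.__setattr__(self, "groups", (self.groups,))
        else:
            object.__setattr__(self, "groups", tuple(self.groups))


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic pooled-GWAS cohort.

    Defaults mirror the discovery design being emulated: four
    conditions (CTR, SUP, OMA, DIE), two 10-individual pools per
    condition in biological duplicate, and a uniform MAF spectrum on
    [0.05, 0.5].
    """

    n_snps: int = 2000
    snps_per_chromosome: tuple[int, ...] | None = None
    maf_low: float = 0.05
    maf_high: float = 0.5
    groups: tuple[str, ...] = DEFAULT_GROUPS
    control_group: str = "CTR"
    n_individuals_per_group: int = 20
    pools_per_group: int = 2
    pool_size: int = 10
    effect_snps: tuple[EffectSnp, ...] = ()
    #: arrays label alleles A/B arbitrarily, so for ~half the SNPs the
    #: array's B allele is the major allele; effect SNPs always keep B
    #: as the minor (risk) allele so the planted OR is well defined
    random_allele_labels: bool = True
    missing_rate: float = 0.025
    pool_weight_jitter: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.snps_per_chromosome is None:
            object.__setattr__(self, "snps_per_chromosome", (self.n_snps,))
        else:
            object.__setattr__(
                self, "snps_per_chromosome", tuple(self.snps_per_chromosome)
            )
        if sum(self.snps_per_chromosome) != self.n_snps:
            raise ConfigError("snps_per_chromosome must sum to n_snps")
        if not (0.0 < self.maf_low <= self.maf_high < 1.0):
            raise ConfigError("need 0 < maf_low <= maf_high < 1")
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.control_group not in self.groups:
            raise ConfigError(
                f"control_group {self.control_group!r} not in groups"
            )
        if self.pools_per_group * self.pool_size > self.n_individuals_per_group:
            raise ConfigError(
                "pools_per_group * pool_size exceeds n_individuals_per_group"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.pool_weight_jitter < 0:
            raise ConfigError("pool_weight_jitter must be >= 0")
        effects = tuple(
            e if isinstance(e, EffectSnp) else EffectSnp(*e)
            for e in self.effect_snps
        )
        object.__setattr__(self, "effect_snps", effects)
        for e in effects:
            if not (0 <= e.snp_index < self.n_snps):
                raise ConfigError(
                    f"effect SNP index {e.snp_index} out of range"
                )
            for g in e.groups:
                if g not in self.groups or g == self.control_group:
                    raise ConfigError(
                        f"effect group {g!r} must be a case group"
                    )

    @property
    def case_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.control_group)

    @property
    def n_chromosomes(self) -> int:
        return len(self.snps_per_chromosome)


@dataclass(frozen=True)
class PipelineConfig:
    """Every analysis threshold of the discovery/replication pipeline.

    ``chip_profile`` maps chromosome label -> number of array SNPs and
    drives the per-chromosome Monte-Carlo null size; the default holds
    the 250K-chip chromosome-1 figure of 19,865 SNPs, but any profile
    (including the small ones used in tests) is accepted.
    """

    epsilon: float = 1e-4
    cv_ddof: int = 1
    preselect_threshold: float = 20.0
    n_reps: int = 1000
    fdr_alpha: float = 0.05
    fdr_mode: str = "paper"
    p_mode: str = "calibrated"
    null_mode: str = "uniform"
    shortlist_rule: str = "both"
    reference_freq_tolerance: float = 0.1
    stringent_p: float = 0.001
    tarone: bool = True
    hwe_method: str = "chisq"
    significance_alpha: float = 0.05
    seed: int = 0
    chip_profile: dict[str, int] = field(
        default_factory=lambda: {"1": 19865}
    )

    def __post_init__(self) -> None:
        if not (0 < self.epsilon < 0.5):
            raise ConfigError("epsilon must be in (0, 0.5)")
        if self.cv_ddof not in (0, 1):
            raise ConfigError("cv_ddof must be 0 or 1")
        if self.preselect_threshold <= 1:
            raise ConfigError("preselect_threshold must be > 1")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        for name in ("fdr_alpha", "stringent_p", "significance_alpha"):
            if not (0 < getattr(self, name) < 1):
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.fdr_mode not in ("paper", "bh"):
            raise ConfigError("fdr_mode must be 'paper' or 'bh'")
        if self.p_mode not in ("calibrated", "dominance"):
            raise ConfigError("p_mode must be 'calibrated' or 'dominance'")
        if self.null_mode not in ("uniform", "empirical"):
            raise ConfigError("null_mode must be 'uniform' or 'empirical'")
        if self.shortlist_rule not in ("wide", "stringent", "both"):
            raise ConfigError(
                "shortlist_rule must be 'wide', 'stringent' or 'both'"
            )
        if self.reference_freq_tolerance < 0:
            raise ConfigError("reference_freq_tolerance must be >= 0")
        if self.hwe_method not in ("chisq", "exact"):
            raise ConfigError("hwe_method must be 'chisq' or 'exact'")
        for chrom, n in self.chip_profile.items():
            if n < 1:
                raise ConfigError(
                    f"chip_profile[{chrom!r}] must be >= 1"
                )

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls: type, data: dict[str, Any], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a TOML or YAML file.

    The file holds a flat mapping (optionally under a ``pipeline``
    table); unknown keys are rejected.
    """
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "pipeline" in data and isinstance(data["pipeline"], dict):
        data = data["pipeline"]
    if "chip_profile" in data:
        data["chip_profile"] = {
            str(k): int(v) for k, v in dict(data["chip_profile"]).items()
        }
    return _build(PipelineConfig, data, str(path))


def cohort_config_from_mapping(data: dict[str, Any],
                               context: str = "cohort") -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain mapping (TOML/YAML)."""
    data = dict(data)
    if "noise" in data and isinstance(data["noise"], dict):
        data["noise"] = _build(NoiseModel, data["noise"], f"{context}.noise")
    if "effect_snps" in data:
        data["effect_snps"] = tuple(
            EffectSnp(int(e[0]), tuple(e[1]) if not isinstance(e[1], str)
                      else (e[1],), float(e[2]))
            if not isinstance(e, dict)
            else _build(EffectSnp, e, f"{context}.effect_snps")
            for e in data["effect_snps"]
        )
    for key in ("snps_per_chromosome", "groups"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return _build(CohortConfig, data, context)
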
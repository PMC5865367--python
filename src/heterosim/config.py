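"""Configuration objects for the simulation study.

Defaults reproduce the study conditions: a 4 x 1 Morgan genome carrying
4000 SNPs and 400 QTL drawn from ~8800 candidate loci (MAF > 0.05 at the
end of 2000 historical generations at N = 2000 with recurrent mutation
2.5e-5), a trait with phenotypic variance 1, h2 = 0.3 and dominance
variance 0.1 or 0.05 depending on the genetic model, and a selection
program with 1000 candidates per breed from which the top 100 males and
200 females are selected each generation.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = [
    "GenomeConfig", "TraitConfig", "SelectionConfig", "ChainConfig",
    "StudyConfig", "load_study_config", "save_study_config",
]


@dataclass
class GenomeConfig:
    """Genome layout and historical-population settings."""
    n_chromosomes: int = 4
    chromosome_length: float = 1.0          # Morgans
    n_snps_target: int = 4000
    n_qtl_target: int = 400
    n_candidate_loci: int = 8800            # ~2x (snps + qtl)
    mutation_rate: float = 2.5e-5           # per locus per gamete, historical only
    historical_size: int = 2000
    historical_generations: int = 2000
    maf_threshold_arch: float = 0.05

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ConfigurationError("need at least one chromosome of positive length")
        if self.n_candidate_loci < self.n_snps_target + self.n_qtl_target:
            raise ConfigurationError(
                "n_candidate_loci must cover the SNP and QTL targets: "
                f"{self.n_candidate_loci} < {self.n_snps_target + self.n_qtl_target}")
        if self.historical_size <= 0 or self.n_candidate_loci <= 0:
            raise ConfigurationError("historical population and locus count must be positive")
        for name in ("mutation_rate", "maf_threshold_arch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_snps_target % self.n_chromosomes or self.n_qtl_target % self.n_chromosomes:
            raise ConfigurationError(
                "SNP and QTL targets must divide evenly over chromosomes")


@dataclass
class TraitConfig:
    """Trait variance targets.

    sigma2_e is derived as sigma2_p - sigma2_a - sigma2_d so that the
    phenotypic variance actually equals sigma2_p at the stated h2.  Set
    literal_unit_residual=True to add a N(0, 1) residual instead.
    """
    sigma2_p: float = 1.0
    h2: float = 0.3
    sigma2_d_target: float = 0.1
    overdominance_allowed: bool = True
    literal_unit_residual: bool = False

    @property
    def sigma2_a_target(self) -> float:
        return self.h2 * self.sigma2_p

    @property
    def sigma2_e(self) -> float:
        if self.literal_unit_residual:
            return 1.0
        return self.sigma2_p - self.sigma2_a_target - self.sigma2_d_target

    def validate(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ConfigurationError(f"h2={self.h2} outside [0, 1]")
        if self.sigma2_p <= 0 or self.sigma2_d_target < 0:
            raise ConfigurationError("variances must be non-negative, sigma2_p positive")
        if self.sigma2_a_target + self.sigma2_d_target >= self.sigma2_p:
            raise ConfigurationError(
                "additive plus dominance variance must stay below sigma2_p")


@dataclass
class SelectionConfig:
    """Breeding-program sizes per breed per generation."""
    n_founders: int = 100
    n_expansion_generations: int = 100
    n_candidates: int = 1000
    n_males_selected: int = 100
    n_females_selected: int = 200
    n_purebred_offspring: int = 1000
    n_crossbred_offspring: int = 1000

    def validate(self) -> None:
        if self.n_founders <= 0 or self.n_candidates <= 0:
            raise ConfigurationError("founder and candidate counts must be positive")
        if self.n_candidates % 2:
            raise ConfigurationError("n_candidates must be even (half male, half female)")
        if self.n_males_selected > self.n_candidates // 2:
            raise ConfigurationError("cannot select more males than available")
        if self.n_females_selected > self.n_candidates // 2:
            raise ConfigurationError("cannot select more females than available")
        if self.n_purebred_offspring <= 0 or self.n_crossbred_offspring <= 0:
            raise ConfigurationError("offspring counts must be positive")


@dataclass
class ChainConfig:
    """Gibbs chain settings for the Bayesian ridge regression."""
    n_iter: int = 20000
    burn_in: int = 3000
    df: float = 5.0
    r2: float = 0.5      # assumed model R2, split equally over effect classes

    def validate(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ConfigurationError("chain length must exceed burn-in")
        if self.df <= 0 or not (0.0 < self.r2 < 1.0):
            raise ConfigurationError("df must be positive and r2 in (0, 1)")


@dataclass
class StudyConfig:
    """Full factorial study configuration."""
    model_id: int = 1
    training_mode: str = "purebred"          # or "crossbred"
    w_values: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_generations: int = 40
    n_replicates: int = 50
    master_seed: int = 1
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    trait: TraitConfig = field(default_factory=TraitConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)

    def __post_init__(self):
        if self.model_id == 2:
            pass  # caller sets trait targets; for_model() applies conventions
        if isinstance(self.w_values, list):
            self.w_values = tuple(self.w_values)

    def validate(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ConfigurationError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if self.training_mode not in ("purebred", "crossbred"):
            raise ConfigurationError(f"unknown training_mode {self.training_mode!r}")
        if any(not 0.0 <= w <= 1.0 for w in self.w_values):
            raise ConfigurationError("selection weights must lie in [0, 1]")
        if self.n_generations < 1 or self.n_replicates < 1:
            raise ConfigurationError("need at least one generation and one replicate")
        self.genome.validate()
        self.trait.validate()
        self.selection.validate()
        self.chain.validate()


def trait_config_for_model(model_id: int, **overrides) -> TraitConfig:
    """Trait settings for the three genetic models.

    Model 1: dominance variance 0.1, over-dominance allowed (~25% of QTL).
    Model 2: dominance variance 0.05 (~10% over-dominant).
    Model 3: dominance variance 0.1, over-dominance excluded.
    """
    if model_id == 1:
        cfg = TraitConfig(sigma2_d_target=0.1, overdominance_allowed=True)
    elif model_id == 2:
        cfg = TraitConfig(sigma2_d_target=0.05, overdominance_allowed=True)
    elif model_id == 3:
        cfg = TraitConfig(sigma2_d_target=0.1, overdominance_allowed=False)
    else:
        raise ConfigurationError(f"model_id must be 1, 2 or 3, got {model_id}")
    return dataclasses.replace(cfg, **overrides)


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    d["w_values"] = list(cfg.w_values)
    return d


def load_study_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        cfg = StudyConfig(
            model_id=raw.get("model_id", 1),
            training_mode=raw.get("training_mode", "purebred"),
            w_values=tuple(raw.get("w_values", (0.0, 0.25, 0.5, 0.75, 1.0))),
            n_generations=raw.get("n_generations", 40),
            n_replicates=raw.get("n_replicates", 50),
            master_seed=raw.get("master_seed", 1),
            genome=GenomeConfig(**raw.get("genome", {})),
            trait=TraitConfig(**raw.get("trait", {})),
            selection=SelectionConfig(**raw.get("selection", {})),
            chain=ChainConfig(**raw.get("chain", {})),
        )
    except TypeError as exc:
        raise ConfigurationError(f"unrecognized configuration key: {exc}") from exc
    cfg.validate()
    return cfg


def save_study_config(cfg: StudyConfig, path) -> None:
    cfg.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)
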
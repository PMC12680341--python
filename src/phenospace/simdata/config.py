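"""Configuration objects for the synthetic inbred-panel / F2-cross generator.

The generator emulates a common-garden study design for a selfing plant:
a structured panel of fully inbred wild accessions (several genetic groups),
hundreds of F2 families obtained by crossing random pairs of accessions and
selfing the F1, six polygenic traits whose among-group differentiation is
controlled by a selection regime, additive spatial block effects, missing
values in one trait, and optionally a few planted phenotypic outlier
accessions carrying a distinctive haplotype block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

REGIMES = ("divergent", "stabilizing", "neutral")


@dataclass
class TraitSpec:
    """Genetic architecture of one polygenic trait.

    Parameters
    ----------
    name:
        Trait label (column name in the phenotype table).
    n_causal:
        Number of causal SNPs; causal sets are disjoint across traits.
    effect_sd:
        Scale of additive effects, in trait units.  For ``divergent`` and
        ``neutral`` regimes it is the standard deviation of per-locus
        allele-substitution effects; for ``stabilizing`` it sets the
        latent (linkage-equilibrium) genetic standard deviation that
        recombination can release in the F2s.
    regime:
        ``divergent`` (group means pushed to `group_optima`),
        ``stabilizing`` (group means equal and standing variance hidden in
        complementary +/- allele configurations), or ``neutral`` (random
        effects).
    group_optima:
        Per-group target offsets of the mean genetic value, trait units.
        Used only by the divergent regime.
    h2:
        Narrow-sense heritability in (0, 1]; the residual variance is set
        from the realized genetic variance so that
        Vg / (Vg + Ve) = h2 exactly.
    baseline:
        Constant added to every phenotype so raw values stay positive
        (log / square-root transforms downstream require it).
    transform:
        Declared measurement-scale transform for downstream analyses:
        one of ``"log10"``, ``"sqrt"``, ``None``.
    """

    name: str
    n_causal: int
    effect_sd: float = 0.15
    regime: str = "neutral"
    group_optima: tuple[float, ...] | None = None
    h2: float = 0.8
    baseline: float = 20.0
    transform: str | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if self.regime == "divergent" and self.group_optima is None:
            raise ValueError(f"divergent trait {self.name!r} needs group_optima")


@dataclass
class OutlierSpec:
    """Planted phenotypic-outlier accessions.

    ``shift_sd`` is expressed in phenotypic standard deviations of the
    target trait among accessions; the haplotype block is a contiguous
    span of SNPs (in bp, on chromosome 1) overwritten with a divergent
    allele pattern shared by all planted outliers.
    """

    n_outliers: int
    trait: str
    shift_sd: float
    haplotype_block_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.n_outliers < 1:
            raise ValueError("n_outliers must be >= 1")


@dataclass
class SimConfig:
    """Full study-design configuration.

    Defaults mirror the emulated study scaled down roughly fourfold:
    180 accessions in 3 genetic groups, 640 F2 individuals from 160
    crosses, 6 traits over 5 chromosomes x 200 SNPs, 3 spatial blocks.
    """

    n_groups: int = 3
    n_accessions_per_group: int = 60
    n_crosses: int = 160
    n_f2_per_cross: int = 4
    n_chromosomes: int = 5
    snps_per_chromosome: int = 200
    chrom_length_bp: int = 1_000_000
    map_length_cM: float = 100.0
    fst_target: float = 0.2
    n_blocks: int = 3
    trait_specs: list[TraitSpec] = field(default_factory=list)
    # per-trait additive block effects, trait units; length n_blocks each
    block_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    missing_fraction: dict[str, float] = field(default_factory=dict)
    outlier_spec: OutlierSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_groups", self.n_groups),
            ("n_accessions_per_group", self.n_accessions_per_group),
            ("n_crosses", self.n_crosses),
            ("n_f2_per_cross", self.n_f2_per_cross),
            ("n_chromosomes", self.n_chromosomes),
            ("snps_per_chromosome", self.snps_per_chromosome),
            ("n_blocks", self.n_blocks),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError(f"fst_target must be in (0,1), got {self.fst_target}")
        for trait, frac in self.missing_fraction.items():
            if not (0.0 <= frac < 0.5):
                raise ValueError(f"missing_fraction[{trait}] must be in [0, 0.5)")
        n_snps = self.n_chromosomes * self.snps_per_chromosome
        if sum(t.n_causal for t in self.trait_specs) > n_snps:
            raise ValueError("causal sets (disjoint per trait) exceed total SNP count")
        for t in self.trait_specs:
            if t.regime == "divergent" and len(t.group_optima) != self.n_groups:
                raise ValueError(f"trait {t.name!r}: group_optima length != n_groups")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    @property
    def n_accessions(self) -> int:
        return self.n_groups * self.n_accessions_per_group

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        traits = [TraitSpec(**t) for t in raw.pop("trait_specs", [])]
        for t in traits:
            if t.group_optima is not None:
                t.group_optima = tuple(t.group_optima)
        outlier = raw.pop("outlier_spec", None)
        return cls(
            trait_specs=traits,
            outlier_spec=OutlierSpec(**outlier) if outlier else None,
            **raw,
        )


def default_trait_specs(n_groups: int = 3) -> list[TraitSpec]:
    """Six-trait architecture used as the default study condition.

    Two life-history traits under divergent selection (flowering time,
    biomass), three leaf-economics traits under stabilizing selection
    (SLA, LDMC, LNC) and one neutral trait (leaf area).  Optima are
    symmetric about zero and spaced linearly across groups.
    """

    def optima(spread: float) -> tuple[float, ...]:
        import numpy as np

        return tuple(float(v) for v in np.linspace(-spread, spread, n_groups))

    return [
        TraitSpec("flowering_time", 30, 0.15, "divergent", optima(0.6), 0.9,
                  transform="log10"),
        TraitSpec("biomass", 30, 0.15, "divergent", optima(0.45), 0.8,
                  transform="sqrt"),
        TraitSpec("leaf_area", 30, 0.15, "neutral", None, 0.7),
        TraitSpec("sla", 120, 1.0, "stabilizing", None, 0.8, transform="log10"),
        TraitSpec("ldmc", 120, 1.0, "stabilizing", None, 0.8),
        TraitSpec("lnc", 120, 1.0, "stabilizing", None, 0.8, transform="sqrt"),
    ]


def default_config(seed: int = 0, outliers: bool = False) -> SimConfig:
    """The desk-scale default study configuration."""
    specs = default_trait_specs()
    cfg = SimConfig(
        trait_specs=specs,
        block_effects={
            "flowering_time": (0.0, 0.6, -0.4),
            "biomass": (0.0, 0.3, -0.2),
            "leaf_area": (0.0, 0.2, 0.1),
            "sla": (0.0, -0.2, 0.3),
            "ldmc": (0.0, 0.1, -0.1),
            "lnc": (0.0, 0.2, -0.2),
        },
        missing_fraction={"lnc": 0.08},
        outlier_spec=OutlierSpec(5, "flowering_time", 6.0) if outliers else None,
        seed=seed,
    )
    return cfg
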
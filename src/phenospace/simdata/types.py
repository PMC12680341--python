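"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every phenotype table carries besides the trait columns.
PHENOTYPE_ID_COLS = ["individual_id", "generation", "genotype_id", "group", "block"]


@dataclass
class Genome:
    """Marker map: chromosome, physical (bp) and genetic (cM) positions.

    Positions are 1-based and strictly increasing within a chromosome;
    the genetic map is monotone non-decreasing with bp.
    """

    chromosome: np.ndarray  # int, per SNP
    position_bp: np.ndarray  # int, 1-based
    position_cM: np.ndarray  # float

    def __post_init__(self) -> None:
        for chrom in np.unique(self.chromosome):
            m = self.chromosome == chrom
            bp = self.position_bp[m]
            cm = self.position_cM[m]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on chrom {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions decreasing on chrom {chrom}")

    @property
    def n_snps(self) -> int:
        return self.chromosome.size

    def chrom_slice(self, chrom: int) -> np.ndarray:
        return np.flatnonzero(self.chromosome == chrom)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs, alternate-allele dosage in {0, 1, 2}.

    Missing calls are stored as NaN (dosage is float).  Fully inbred G0
    accessions carry only dosages 0 and 2; F2 individuals may be
    heterozygous.  ``group`` is defined for G0 rows only (NaN-like ""
    for F2s).
    """

    ids: np.ndarray  # str, per individual
    dosage: np.ndarray  # float (n, n_snps), values {0,1,2} or NaN
    generation: np.ndarray  # str, "G0" or "F2"
    group: np.ndarray  # str per individual ("" where undefined)
    genome: Genome

    def __post_init__(self) -> None:
        d = self.dosage
        if np.nanmin(d, initial=0) < 0:
            raise ValueError("negative dosage")
        g0 = self.generation == "G0"
        if g0.any():
            g0d = d[g0]
            obs = g0d[~np.isnan(g0d)]
            if np.any((obs != 0) & (obs != 2)):
                raise ValueError("G0 accessions must be fully homozygous (dosage 0 or 2)")

    @property
    def n_individuals(self) -> int:
        return self.ids.size

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_individuals(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {i: k for k, i in enumerate(self.ids)}
            idx = np.array([lookup[i] for i in mask_or_ids])
        return GenotypeMatrix(
            ids=self.ids[idx],
            dosage=self.dosage[idx],
            generation=self.generation[idx],
            group=self.group[idx],
            genome=self.genome,
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            ids=self.ids,
            dosage=self.dosage[:, keep],
            generation=self.generation,
            group=self.group,
            genome=Genome(
                chromosome=self.genome.chromosome[keep],
                position_bp=self.genome.position_bp[keep],
                position_cM=self.genome.position_cM[keep],
            ),
        )


@dataclass
class TraitArchitecture:
    """Per-trait causal loci and additive effects.

    A genotype's genetic value for a trait is
    ``sum_j a_j * (dosage_j - 1)`` over the trait's causal SNPs: parents
    (dosage 0/2) contribute -a_j / +a_j and heterozygotes contribute 0,
    so an F1 sits exactly at the parental midpoint (pure additivity).
    """

    causal_idx: dict[str, np.ndarray] = field(default_factory=dict)
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    def genetic_values(self, dosage: np.ndarray, trait: str) -> np.ndarray:
        idx = self.causal_idx[trait]
        a = self.effects[trait]
        return (dosage[:, idx] - 1.0) @ a


def new_phenotype_table(
    ids, generation, genotype_id, group, block, trait_values: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Assemble a phenotype table (one row per measured individual plant)."""
    df = pd.DataFrame(
        {
            "individual_id": ids,
            "generation": generation,
            "genotype_id": genotype_id,
            "group": group,
            "block": np.asarray(block, dtype=int),
        }
    )
    for name, vals in trait_values.items():
        df[name] = vals
    return df


def trait_columns(phenotypes: pd.DataFrame) -> list[str]:
    return [c for c in phenotypes.columns if c not in PHENOTYPE_ID_COLS]
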
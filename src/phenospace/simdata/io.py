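"""On-disk formats: VCF 4.2 for genotypes, TSV for phenotypes and groups.

Genotypes are stored as GT calls (0/0, 0/1, 1/1, ./.); the genetic map
position travels in an INFO field (``CM``) so a written dataset
round-trips losslessly through :func:`read_genotypes`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import Genome, GenotypeMatrix

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes(genotypes: GenotypeMatrix, path: str) -> None:
    """Write a VCF 4.2 with one record per SNP, sorted by (chrom, pos)."""
    g = genotypes.genome
    order = np.lexsort((g.position_bp, g.chromosome))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in np.unique(g.chromosome):
            length = int(g.position_bp[g.chromosome == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, genotypes.ids)) + "\n")
        for j in order:
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in genotypes.dosage[:, j]
            )
            fh.write(
                f"{g.chromosome[j]}\t{g.position_bp[j]}\tsnp{j:06d}\tA\tT\t.\t.\t"
                f"CM={g.position_cM[j]:.6f}\tGT\t{calls}\n"
            )


def read_genotypes(
    path: str, generation: np.ndarray | None = None, group: np.ndarray | None = None
) -> GenotypeMatrix:
    """Read dosages back from a VCF (missing calls -> NaN)."""
    vcf = VCF(path)
    ids = np.array(vcf.samples, dtype=object)
    chroms, bps, cms, rows = [], [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM))
        bps.append(var.POS)
        cm = var.INFO.get("CM")
        cms.append(float(cm) if cm is not None else float(var.POS))
        row = np.empty(ids.size)
        for i, gt in enumerate(var.genotypes):
            a = gt[:2]
            row[i] = np.nan if (a[0] < 0 or a[1] < 0) else float(a[0] + a[1])
        rows.append(row)
    vcf.close()
    dosage = np.array(rows).T if rows else np.empty((ids.size, 0))
    n = ids.size
    return GenotypeMatrix(
        ids=ids,
        dosage=dosage,
        generation=generation if generation is not None else np.array([""] * n, dtype=object),
        group=group if group is not None else np.array([""] * n, dtype=object),
        genome=Genome(
            chromosome=np.array(chroms, dtype=int),
            position_bp=np.array(bps, dtype=int),
            position_cM=np.array(cms),
        ),
    )


def write_phenotypes(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])


def write_groups(genotypes: GenotypeMatrix, path: str) -> None:
    pd.DataFrame(
        {
            "genotype_id": genotypes.ids,
            "generation": genotypes.generation,
            "group": genotypes.group,
        }
    ).to_csv(path, sep="\t", index=False)


def read_groups(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_dataset(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame, out_dir: str) -> dict:
    """Write genotypes.vcf, phenotypes.tsv and groups.tsv under `out_dir`."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "phenotypes": os.path.join(out_dir, "phenotypes.tsv"),
        "groups": os.path.join(out_dir, "groups.tsv"),
    }
    write_genotypes(genotypes, paths["vcf"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    write_groups(genotypes, paths["groups"])
    return paths


def read_dataset(out_dir: str) -> tuple[GenotypeMatrix, pd.DataFrame]:
    groups = read_groups(os.path.join(out_dir, "groups.tsv"))
    geno = read_genotypes(
        os.path.join(out_dir, "genotypes.vcf"),
        generation=groups["generation"].to_numpy(dtype=object),
        group=groups["group"].to_numpy(dtype=object),
    )
    phen = read_phenotypes(os.path.join(out_dir, "phenotypes.tsv"))
    return geno, phen
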
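"""Phenotype preprocessing: block correction, transforms, aggregation.

The order of operations is fixed and enforced by the pipeline:

1. estimate additive block effects on the replicated accession (G0) data
   with a two-way fixed-effects fit (genotype + block), reported as each
   block's least-square-mean deviation from block 1;
2. subtract those deviations from every observation in blocks >= 2, for
   both generations (F2s carry no replication, so their block effects can
   only be borrowed from the accessions);
3. apply the declared measurement-scale transforms (log10 / sqrt);
4. aggregate G0 replicates to per-accession means (missing replicates
   ignored); F2 individuals pass through unchanged;
5. optionally impute remaining missing cells by regularized iterative PCA
   and standardize columns to mean 0, SD 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simdata.types import trait_columns

TRANSFORMS = {
    "log10": np.log10,
    "sqrt": np.sqrt,
    None: lambda x: x,
}

#: default measurement-scale transforms for the six study traits
DEFAULT_TRANSFORMS: dict[str, str | None] = {
    "flowering_time": "log10",
    "sla": "log10",
    "lnc": "sqrt",
    "biomass": "sqrt",
    "leaf_area": None,
    "ldmc": None,
}


@dataclass
class BlockCorrection:
    """Per-trait least-square-mean deviation of each block from block 1."""

    blocks: list[int] = field(default_factory=list)  # sorted block labels
    deviations: dict[str, np.ndarray] = field(default_factory=dict)  # per trait, len(blocks); [0]=0


def estimate_block_effects(phenotypes: pd.DataFrame) -> BlockCorrection:
    """Least-square block effects from replicated G0 data.

    Fits, per trait, the additive fixed-effects model
    ``value ~ genotype + block`` on accession rows (unbalanced designs and
    missing cells are fine) and reports each block's least-square mean as
    a deviation from block 1.
    """
    g0 = phenotypes[phenotypes["generation"] == "G0"]
    blocks = sorted(g0["block"].unique())
    traits = trait_columns(phenotypes)
    corr = BlockCorrection(blocks=blocks)
    if len(blocks) == 1:
        for t in traits:
            corr.deviations[t] = np.zeros(1)
        return corr
    if g0["genotype_id"].nunique() < 2:
        raise ValueError("need >= 2 replicated genotypes to separate block from genotype")

    for t in traits:
        sub = g0[["genotype_id", "block", t]].dropna()
        present = set(sub["block"].unique())
        missing_blocks = [int(b) for b in blocks if b not in present]
        if missing_blocks:
            raise ValueError(f"trait {t!r}: no observations in block(s) {missing_blocks}")
        geno_d = pd.get_dummies(sub["genotype_id"], drop_first=True, dtype=float)
        block_d = pd.get_dummies(sub["block"].astype("category"), drop_first=True,
                                 prefix="block", dtype=float)
        X = sm.add_constant(pd.concat([geno_d, block_d], axis=1), has_constant="add")
        fit = sm.OLS(sub[t].to_numpy(), X.to_numpy()).fit()
        coefs = pd.Series(fit.params, index=X.columns)
        dev = np.zeros(len(blocks))
        for k, b in enumerate(blocks[1:], start=1):
            dev[k] = coefs[f"block_{b}"]
        corr.deviations[t] = dev
    return corr


def apply_block_correction(phenotypes: pd.DataFrame, correction: BlockCorrection) -> pd.DataFrame:
    """Subtract block deviations from blocks >= 2 for both generations."""
    out = phenotypes.copy()
    present = set(out["block"].unique())
    unknown = present - set(correction.blocks)
    if unknown:
        raise ValueError(f"correction does not cover block(s) {sorted(unknown)}")
    index = {b: k for k, b in enumerate(correction.blocks)}
    pos = out["block"].map(index).to_numpy()
    for t, dev in correction.deviations.items():
        if t in out.columns:
            out[t] = out[t].to_numpy() - dev[pos]
    return out


def transform_and_aggregate(
    phenotypes: pd.DataFrame, transforms: dict[str, str | None] | None = None
) -> pd.DataFrame:
    """Apply measurement-scale transforms, then average G0 replicates.

    Returns a trait matrix with one row per genotype (accession or F2
    individual), columns ``genotype_id``, ``generation``, ``group`` and
    the transformed traits.
    """
    if transforms is None:
        transforms = DEFAULT_TRANSFORMS
    traits = trait_columns(phenotypes)
    out = phenotypes.copy()
    for t in traits:
        kind = transforms.get(t)
        vals = out[t].to_numpy(dtype=float)
        if kind == "log10":
            bad = np.flatnonzero(vals <= 0)
            if bad.size:
                raise ValueError(f"trait {t!r}: non-positive values under log10 at rows {bad[:10].tolist()}")
        elif kind == "sqrt":
            bad = np.flatnonzero(vals < 0)
            if bad.size:
                raise ValueError(f"trait {t!r}: negative values under sqrt at rows {bad[:10].tolist()}")
        elif kind is not None and kind not in TRANSFORMS:
            raise ValueError(f"unknown transform {kind!r} for trait {t!r}")
        out[t] = TRANSFORMS[kind](vals) if kind else vals

    agg = (
        out.groupby(["genotype_id", "generation", "group"], dropna=False, sort=False)[traits]
        .mean()  # skipna by default: missing replicates ignored
        .reset_index()
    )
    return agg


def impute_missing_iterative_pca(
    matrix: pd.DataFrame, n_components: int = 2, max_iter: int = 200, tol: float = 1e-6
) -> pd.DataFrame:
    """Regularized iterative-PCA (EM) imputation of missing trait cells.

    Missing cells start at column means; the matrix is then alternately
    approximated by its rank-`n_components` truncated SVD and the missing
    cells replaced by the reconstruction, until the largest cell change
    drops below `tol` or `max_iter` sweeps.  Observed cells are never
    altered.
    """
    traits = trait_columns(matrix)
    X = matrix[traits].to_numpy(dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return matrix.copy()
    if np.any(miss.all(axis=0)):
        bad = [traits[j] for j in np.flatnonzero(miss.all(axis=0))]
        raise ValueError(f"column(s) entirely missing: {bad}")
    frac = miss.mean(axis=0)
    if np.any(frac >= 0.5):
        bad = [traits[j] for j in np.flatnonzero(frac >= 0.5)]
        raise ValueError(f"column(s) over 50% missing: {bad}")

    col_means = np.nanmean(X, axis=0)
    Xf = np.where(miss, col_means, X)
    for _ in range(max_iter):
        mu = Xf.mean(axis=0)
        Xc = Xf - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        low = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components] + mu
        new = np.where(miss, low, X)
        delta = np.max(np.abs(new - Xf))
        Xf = new
        if delta < tol:
            break
    out = matrix.copy()
    out[traits] = Xf
    return out


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale trait columns to mean 0, SD 1 (n-1 denominator)."""
    traits = trait_columns(matrix)
    out = matrix.copy()
    for t in traits:
        x = out[t].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"trait {t!r} is constant; cannot standardize")
        out[t] = (x - np.nanmean(x)) / sd
    return out


def preprocess_pipeline(
    phenotypes: pd.DataFrame,
    transforms: dict[str, str | None] | None = None,
    impute: bool = True,
    n_components: int = 2,
) -> pd.DataFrame:
    """Full preprocessing: correct -> transform -> aggregate -> impute -> standardize."""
    correction = estimate_block_effects(phenotypes)
    corrected = apply_block_correction(phenotypes, correction)
    matrix = transform_and_aggregate(corrected, transforms)
    if impute and matrix[trait_columns(matrix)].isna().any().any():
        matrix = impute_missing_iterative_pca(matrix, n_components=n_components)
    return standardize(matrix)
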
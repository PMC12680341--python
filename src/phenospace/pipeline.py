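"""End-to-end phenotypic-space analysis built from the module primitives.

`phenotypic_space` runs PCA with axis-significance testing on a combined
(G0 + F2) trait matrix, splits the significant-axis scores by generation
and estimates resampled hypervolumes per group; `trait_removal_sensitivity`
reruns the same analysis without one trait and reports the volume
reduction per group together with the new consensus outlier list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypervolume import PCASpace, ResampledVolumes, pca_with_significance, resampled_hypervolumes
from .outliers import ConsensusReport, consensus_pipeline
from .preprocess import standardize
from .simdata.types import trait_columns


@dataclass
class PhenotypicSpace:
    pca: PCASpace
    dim: int
    acc_ids: np.ndarray
    acc_scores: np.ndarray
    f2_scores: np.ndarray
    acc_volumes: ResampledVolumes
    f2_volumes: ResampledVolumes

    @property
    def volume_ratio(self) -> float:
        """Mean F2 hypervolume volume over mean accession volume."""
        return self.f2_volumes.mean / self.acc_volumes.mean


def phenotypic_space(
    matrix: pd.DataFrame,
    n_sub: int | None = None,
    reps: int = 10,
    dim: int | None = None,
    n_perm: int = 300,
    samples_per_point: int = 200,
    seed: int = 0,
) -> PhenotypicSpace:
    """PCA + per-generation resampled hypervolumes on a trait matrix.

    `matrix` holds one row per genotype with `generation` labels; it is
    standardized and decomposed into principal axes.  By default the
    hypervolumes use ``min(5, n_traits - 1)`` axes — when traits carry
    largely independent information the permutation test is conservative
    (every axis sits near its null eigenvalue even though all are
    biologically real), so the sequential test result is reported in the
    returned PCA space but does not silently shrink the analysis space;
    pass ``dim`` explicitly (e.g. ``dim=pca.n_significant``) to override.
    Both generations are subsampled to a common size `n_sub` (default:
    90% of the smaller group) before each hypervolume fit.
    """
    rng = np.random.default_rng(seed)
    std = standardize(matrix)
    pca = pca_with_significance(std, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)))
    n_traits = len(trait_columns(matrix))
    d = dim if dim is not None else min(5, n_traits - 1)
    d = min(max(2, d), n_traits)
    scores = pca.scores[:, :d]
    gen = matrix["generation"].to_numpy()
    acc_mask = gen == "G0"
    f2_mask = gen == "F2"
    acc_scores, f2_scores = scores[acc_mask], scores[f2_mask]
    if n_sub is None:
        n_sub = int(0.9 * min(acc_scores.shape[0], f2_scores.shape[0]))
    acc_vol = resampled_hypervolumes(
        acc_scores, n_sub=n_sub, reps=reps, samples_per_point=samples_per_point,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    f2_vol = resampled_hypervolumes(
        f2_scores, n_sub=n_sub, reps=reps, samples_per_point=samples_per_point,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return PhenotypicSpace(
        pca=pca, dim=d,
        acc_ids=matrix.loc[acc_mask, "genotype_id"].to_numpy(),
        acc_scores=acc_scores, f2_scores=f2_scores,
        acc_volumes=acc_vol, f2_volumes=f2_vol,
    )


@dataclass
class SensitivityResult:
    dropped_trait: str
    dim_full: int
    dim_reduced: int
    reduction_raw: dict[str, float]  # per group, (vol_full - vol_red)/vol_full
    reduction_per_dim: dict[str, float]  # same, after d-th-root renormalization
    outliers_full: ConsensusReport
    outliers_reduced: ConsensusReport


def trait_removal_sensitivity(
    matrix: pd.DataFrame,
    drop_trait: str,
    seed: int = 0,
    space_kwargs: dict | None = None,
    consensus_kwargs: dict | None = None,
) -> SensitivityResult:
    """Volume and outlier-list sensitivity to removing one trait.

    Reruns PCA and the per-group hypervolumes without `drop_trait` and
    reports, per group, the raw volume reduction
    ``(vol_full - vol_reduced) / vol_full`` — note the dimensionality of
    the reduced space may differ, so SD^d units change — together with a
    per-dimension (d-th-root extent) version that is comparable across
    dimensionalities, plus consensus outlier lists before and after.
    """
    traits = trait_columns(matrix)
    if drop_trait not in traits:
        raise ValueError(f"unknown trait {drop_trait!r}")
    if len(traits) - 1 < 3:
        raise ValueError("need at least 3 traits after removal")
    space_kwargs = dict(space_kwargs or {})
    consensus_kwargs = dict(consensus_kwargs or {})

    full = phenotypic_space(matrix, seed=seed, **space_kwargs)
    reduced = phenotypic_space(matrix.drop(columns=[drop_trait]), seed=seed, **space_kwargs)

    def reductions(f: PhenotypicSpace, r: PhenotypicSpace):
        raw, per_dim = {}, {}
        for grp, vf, vr in (
            ("G0", f.acc_volumes.mean, r.acc_volumes.mean),
            ("F2", f.f2_volumes.mean, r.f2_volumes.mean),
        ):
            raw[grp] = 1.0 - vr / vf
            per_dim[grp] = 1.0 - vr ** (1.0 / r.dim) / vf ** (1.0 / f.dim)
        return raw, per_dim

    raw, per_dim = reductions(full, reduced)
    cons_full = consensus_pipeline(
        full.acc_scores, full.acc_ids, full.f2_scores, seed=seed, **consensus_kwargs
    )
    cons_red = consensus_pipeline(
        reduced.acc_scores, reduced.acc_ids, reduced.f2_scores, seed=seed, **consensus_kwargs
    )
    return SensitivityResult(
        dropped_trait=drop_trait,
        dim_full=full.dim,
        dim_reduced=reduced.dim,
        reduction_raw=raw,
        reduction_per_dim=per_dim,
        outliers_full=cons_full,
        outliers_reduced=cons_red,
    )
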
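import warnings

import numpy as np
import pytest

import phenospace as ps

warnings.filterwarnings("ignore", category=UserWarning)


def fast_config(seed: int = 11, outliers: bool = False) -> ps.SimConfig:
    """Small study design for unit tests: 60 accessions, 120 F2s, 300 SNPs."""
    specs = [
        ps.TraitSpec("flowering_time", 15, 0.15, "divergent", (-0.6, 0.0, 0.6), 0.9,
                     transform="log10"),
        ps.TraitSpec("biomass", 15, 0.15, "divergent", (-0.45, 0.0, 0.45), 0.8,
                     transform="sqrt"),
        ps.TraitSpec("leaf_area", 15, 0.15, "neutral", None, 0.7),
        ps.TraitSpec("sla", 40, 1.0, "stabilizing", None, 0.8, transform="log10"),
        ps.TraitSpec("ldmc", 40, 1.0, "stabilizing", None, 0.8),
        ps.TraitSpec("lnc", 40, 1.0, "stabilizing", None, 0.8, transform="sqrt"),
    ]
    return ps.SimConfig(
        n_accessions_per_group=20,
        n_crosses=30,
        n_f2_per_cross=4,
        n_chromosomes=2,
        snps_per_chromosome=150,
        trait_specs=specs,
        block_effects={"flowering_time": (0.0, 0.6, -0.4), "biomass": (0.0, 0.3, -0.2)},
        missing_fraction={"lnc": 0.08},
        outlier_spec=ps.OutlierSpec(3, "flowering_time", 6.0) if outliers else None,
        seed=seed,
    )


@pytest.fixture(scope="session")
def fast_dataset():
    return ps.simulate_dataset(fast_config(seed=11))


@pytest.fixture(scope="session")
def fast_matrix(fast_dataset):
    corr = ps.estimate_block_effects(fast_dataset.phenotypes)
    corrected = ps.apply_block_correction(fast_dataset.phenotypes, corr)
    mat = ps.transform_and_aggregate(corrected)
    return ps.impute_missing_iterative_pca(mat)


@pytest.fixture(scope="session")
def outlier_dataset():
    """Desk-scale dataset with planted phenotypic outliers."""
    return ps.simulate_dataset(ps.default_config(seed=1, outliers=True))


@pytest.fixture(scope="session")
def outlier_scores(outlier_dataset):
    ds = outlier_dataset
    corr = ps.estimate_block_effects(ds.phenotypes)
    mat = ps.impute_missing_iterative_pca(
        ps.transform_and_aggregate(ps.apply_block_correction(ds.phenotypes, corr))
    )
    std = ps.standardize(mat)
    pca = ps.pca_with_significance(std, n_perm=100, seed=1)
    gen = mat["generation"].to_numpy()
    return {
        "acc_scores": pca.scores[gen == "G0"],
        "f2_scores": pca.scores[gen == "F2"],
        "acc_ids": mat.loc[gen == "G0", "genotype_id"].to_numpy(),
        "planted": set(outlier_dataset.outlier_ids),
        "matrix": mat,
    }


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
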
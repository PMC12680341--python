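"""QST-FST machinery, transgressive-segregation ratios and SMA regression.

QST is estimated as the among-group share of quantitative-trait variance,
V_among / (V_among + V_within) — the definition appropriate for a panel of
selfing inbred lines (no factor-2 outcrosser correction).  It is compared
with a *neutral FST*: per-SNP multi-population Weir-Cockerham theta, kept
where theta exceeds the 95th percentile of a label-permutation null, and
summarized by the median of the significant values.  The degree of
transgressive segregation of a trait is CV(F2) / CV(G0); regressing it on
QST/FST across traits with a standardized major axis line recovers the
prediction that traits under stabilizing selection (low QST) transgress
most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata.types import GenotypeMatrix


# ---------------------------------------------------------------------------
# QST
# ---------------------------------------------------------------------------

@dataclass
class QstEstimate:
    trait: str
    qst: float
    interval: tuple[float, float]
    v_among: float
    v_within: float


def _anova_components(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Method-of-moments variance components for unbalanced one-way design."""
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    means = sums / sizes
    n_tot = values.size
    grand = values.mean()
    ss_within = float(np.sum((values - means[codes]) ** 2))
    ss_among = float(np.sum(sizes * (means - grand) ** 2))
    ms_within = ss_within / (n_tot - n_groups)
    ms_among = ss_among / (n_groups - 1)
    n0 = (n_tot - np.sum(sizes**2) / n_tot) / (n_groups - 1)
    v_within = ms_within
    v_among = max(0.0, (ms_among - ms_within) / n0)
    return v_among, v_within, sizes


def estimate_qst(
    values: np.ndarray,
    groups: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
) -> QstEstimate | None:
    """QST = V_among / (V_among + V_within) with a parametric-bootstrap CI.

    Variance components come from a one-way random-effects decomposition
    (method of moments, unbalanced groups allowed).  The 95% interval is
    obtained by resimulating `n_boot` datasets from the fitted components
    under the same group design and re-estimating; it is widened if needed
    to contain the point estimate.  Groups of size 1 are dropped with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    small = sizes < 2
    if small.any():
        warnings.warn(
            f"dropping group(s) of size 1: {list(labels[small])}", stacklevel=2
        )
        keep = ~small[codes]
        values, groups = values[keep], groups[keep]
        labels, codes = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")

    v_among, v_within, sizes = _anova_components(values, codes, labels.size)
    total = v_among + v_within
    qst = float(np.clip(v_among / total, 0.0, 1.0)) if total > 0 else 0.0

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        gm = rng.normal(0.0, np.sqrt(v_among), size=labels.size)
        sim = gm[codes] + rng.normal(0.0, np.sqrt(v_within), size=values.size)
        va, vw, _ = _anova_components(sim, codes, labels.size)
        tot = va + vw
        boot[b] = np.clip(va / tot, 0.0, 1.0) if tot > 0 else 0.0
    lo, hi = np.quantile(boot, [0.025, 0.975])
    lo, hi = min(lo, qst), max(hi, qst)
    return QstEstimate(trait="", qst=qst, interval=(float(lo), float(hi)),
                       v_among=v_among, v_within=v_within)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_fst(genotypes: GenotypeMatrix | np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-SNP multi-population Weir-Cockerham (1984) theta.

    Computes the variance components a (among populations), b (among
    individuals within populations) and c (within individuals) from group
    sample sizes, allele frequencies and observed heterozygote
    frequencies; theta = a / (a + b + c).  Monomorphic SNPs (and SNPs with
    a + b + c = 0) return NaN.  Fully inbred panels are handled by the
    same diploid estimator: observed heterozygosity simply enters as ~0.
    """
    dosage = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    r = labels.size
    if r < 2:
        raise ValueError("need >= 2 groups")

    obs = ~np.isnan(dosage)
    onehot = np.zeros((r, dosage.shape[0]))
    onehot[codes, np.arange(dosage.shape[0])] = 1.0

    n_i = onehot @ obs  # (r, snps) individuals with calls
    alt = onehot @ np.where(obs, dosage, 0.0)  # alt allele counts * 1
    het = onehot @ np.where(obs, dosage == 1.0, 0.0)  # het individuals

    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt / (2.0 * n_i)
        h_i = het / n_i

        valid_pop = n_i > 0
        r_eff = valid_pop.sum(axis=0).astype(float)
        n_sum = n_i.sum(axis=0)
        nbar = n_sum / r_eff
        nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r_eff - 1.0)
        pbar = np.where(valid_pop, n_i * p_i, 0.0).sum(axis=0) / n_sum
        s2 = np.where(valid_pop, n_i * (p_i - pbar) ** 2, 0.0).sum(axis=0) / ((r_eff - 1.0) * nbar)
        hbar = np.where(valid_pop, n_i * h_i, 0.0).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r_eff - 1.0) / r_eff * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - (r_eff - 1.0) / r_eff * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    mono = (pbar <= 0.0) | (pbar >= 1.0)
    theta[mono] = np.nan
    if np.all(np.isnan(theta)):
        raise ValueError("all SNPs monomorphic; FST undefined")
    return theta


def fst_permutation_threshold(
    genotypes: GenotypeMatrix | np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    pct: float = 95.0,
    seed: int = 0,
) -> float:
    """Significance threshold for per-SNP theta from permuted group labels.

    The null distribution pools theta over all SNPs and all `n_perm`
    label permutations; the threshold is its `pct`-th percentile (linear
    interpolation).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    null = []
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = wc_fst(genotypes, perm)
        null.append(t[~np.isnan(t)])
    return float(np.percentile(np.concatenate(null), pct))


def neutral_fst(thetas: np.ndarray, threshold: float) -> float:
    """Median of per-SNP theta values strictly above the threshold."""
    thetas = np.asarray(thetas, dtype=float)
    sig = thetas[~np.isnan(thetas) & (thetas > threshold)]
    if sig.size == 0:
        raise ValueError(
            "no SNP exceeds the permutation threshold; "
            "more SNPs or stronger structure needed"
        )
    return float(np.median(sig))


@dataclass
class FstResult:
    theta: np.ndarray
    threshold: float
    significant: np.ndarray  # bool mask, theta > threshold
    neutral_fst: float


def fst_analysis(
    genotypes: GenotypeMatrix | np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    pct: float = 95.0,
    seed: int = 0,
) -> FstResult:
    """Observed theta, permutation threshold, significance mask, neutral median."""
    theta = wc_fst(genotypes, groups)
    thr = fst_permutation_threshold(genotypes, groups, n_perm=n_perm, pct=pct, seed=seed)
    mask = ~np.isnan(theta) & (theta > thr)
    return FstResult(theta=theta, threshold=thr, significant=mask,
                     neutral_fst=neutral_fst(theta, thr))


# ---------------------------------------------------------------------------
# transgressive segregation
# ---------------------------------------------------------------------------

@dataclass
class TransgressionStats:
    trait: str
    cv_f2: float
    cv_g0: float
    ratio: float


def transgression_ratio(
    f2_values: np.ndarray, g0_values: np.ndarray, trait: str = ""
) -> TransgressionStats:
    """CV(F2) / CV(G0) on a common (transformed) measurement scale.

    Both CVs use the n-1 denominator; a ratio above 1 means the
    recombinants spread wider, relative to their mean, than the wild
    panel — the signature of transgressive segregation.
    """
    f2 = np.asarray(f2_values, dtype=float)
    g0 = np.asarray(g0_values, dtype=float)
    f2, g0 = f2[~np.isnan(f2)], g0[~np.isnan(g0)]
    m_f2, m_g0 = f2.mean(), g0.mean()
    if m_f2 <= 0 or m_g0 <= 0:
        raise ValueError(f"trait {trait!r}: CV undefined for non-positive mean")
    cv_f2 = float(f2.std(ddof=1) / m_f2)
    cv_g0 = float(g0.std(ddof=1) / m_g0)
    return TransgressionStats(trait=trait, cv_f2=cv_f2, cv_g0=cv_g0,
                              ratio=cv_f2 / cv_g0 if cv_g0 > 0 else np.inf)


# ---------------------------------------------------------------------------
# standardized major axis regression
# ---------------------------------------------------------------------------

@dataclass
class SmaFit:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int


def sma_regression(x: np.ndarray, y: np.ndarray) -> SmaFit:
    """Standardized major axis line: slope = sign(r) * SD_y / SD_x.

    The SMA line minimizes the sum of products of horizontal and vertical
    deviations and is symmetric in x and y (swapping them inverts the
    slope).  The p-value is the two-sided correlation t-test with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SmaFit(slope=float(slope), intercept=intercept, r2=r**2, pvalue=p, n=n)


# ---------------------------------------------------------------------------
# per-trait orchestration
# ---------------------------------------------------------------------------

def qst_fst_analysis(
    trait_matrix: pd.DataFrame,
    genotypes: GenotypeMatrix,
    traits: list[str] | None = None,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Per-trait QST (G0 accession means, genetic-group labels) vs neutral FST.

    `trait_matrix` is a preprocessed per-genotype table with `generation`
    and `group` columns; genotypes supply the SNPs (G0 rows only are used
    for FST).  Returns a dict with per-trait QstEstimate, the FstResult,
    per-trait transgression ratios and the SMA fit of transgression ratio
    on QST / neutral-FST.
    """
    from .simdata.types import trait_columns

    if traits is None:
        traits = trait_columns(trait_matrix)
    g0_rows = trait_matrix["generation"] == "G0"
    f2_rows = trait_matrix["generation"] == "F2"

    g0_geno = genotypes.subset_individuals(genotypes.generation == "G0")
    fst = fst_analysis(g0_geno, g0_geno.group, n_perm=n_perm, seed=seed)

    qsts, trans = {}, {}
    for k, t in enumerate(traits):
        est = estimate_qst(
            trait_matrix.loc[g0_rows, t].to_numpy(),
            trait_matrix.loc[g0_rows, "group"].to_numpy(),
            n_boot=n_boot, seed=seed + 17 * (k + 1),
        )
        est.trait = t
        qsts[t] = est
        trans[t] = transgression_ratio(
            trait_matrix.loc[f2_rows, t].to_numpy(),
            trait_matrix.loc[g0_rows, t].to_numpy(),
            trait=t,
        )
    ratio_qf = np.array([qsts[t].qst / fst.neutral_fst for t in traits])
    ratio_tr = np.array([trans[t].ratio for t in traits])
    sma = sma_regression(ratio_qf, ratio_tr) if len(traits) >= 3 else None
    return {"qst": qsts, "fst": fst, "transgression": trans,
            "qst_fst_ratio": dict(zip(traits, ratio_qf)), "sma": sma}
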
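"""SNP filtering and windowed diversity statistics (pi, Tajima's D).

Statistics are computed from diploid dosages: each individual contributes
two allele copies per site, missing calls reduce the site-specific sample
size.  Windows tile each chromosome from position 1 in fixed,
non-overlapping, 1-based spans; trailing partial windows are retained and
flagged.  Per-site nucleotide diversity is the mean pairwise difference
among allele copies; the window value divides the sum by the window
length in bp (not by the number of variant sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .quantgen import SmaFit, sma_regression
from .simdata.types import GenotypeMatrix


@dataclass
class VariantFilterSpec:
    maf_min: float = 0.05
    max_missing: float = 0.05
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_failed_maf: int
    n_failed_missing: int


def filter_variants(
    genotypes: GenotypeMatrix, spec: VariantFilterSpec
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep SNPs with MAF >= maf_min and missing fraction <= max_missing.

    MAF and missingness are computed on the requested sample subset
    (default: all individuals); thresholds are inclusive.  The filter is
    idempotent.
    """
    geno = genotypes
    if spec.samples is not None:
        if len(spec.samples) == 0:
            raise ValueError("empty sample subset")
        geno = genotypes.subset_individuals(np.asarray(spec.samples, dtype=object))
    d = geno.dosage
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_obs > 0, maf, 0.0)
    miss = 1.0 - n_obs / d.shape[0]
    ok_maf = maf >= spec.maf_min
    ok_miss = miss <= spec.max_missing
    keep = ok_maf & ok_miss
    report = FilterReport(
        n_input=d.shape[1],
        n_kept=int(keep.sum()),
        n_failed_maf=int((~ok_maf).sum()),
        n_failed_missing=int((~ok_miss).sum()),
    )
    return genotypes.subset_snps(keep), report


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    chromosome: int
    start: int  # 1-based inclusive
    end: int  # inclusive
    n_snps: int
    pi: float  # per-bp
    tajima_d: float  # NaN when undefined
    partial: bool = False


def _site_components(dosage: np.ndarray):
    """Per-site allele-copy counts and pairwise-difference fractions."""
    obs = ~np.isnan(dosage)
    n_alleles = 2.0 * obs.sum(axis=0)
    alt = np.where(obs, dosage, 0.0).sum(axis=0)
    ref = n_alleles - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs = n_alleles * (n_alleles - 1.0) / 2.0
        pi_site = np.where(pairs > 0, alt * ref / pairs, 0.0)
    return n_alleles, alt, pi_site


def _window_edges(positions: np.ndarray, window_bp: int):
    last = int(positions.max())
    starts = np.arange(1, last + 1, window_bp)
    return starts


def windowed_pi(genotypes: GenotypeMatrix, window_bp: int = 10_000) -> list[WindowStat]:
    """Nucleotide diversity per bp in fixed windows.

    pi_site = (pairwise allele differences) / (pairs of allele copies)
    among non-missing calls; window pi = sum(pi_site) / window_bp.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    return _windowed(genotypes, window_bp, want_d=False)


def windowed_tajimas_d(genotypes: GenotypeMatrix, window_bp: int = 100) -> list[WindowStat]:
    """Tajima's D per fixed window.

    D = (khat - S/a1) / sqrt(e1*S + e2*S*(S-1)) with khat the mean
    pairwise difference count, S the number of segregating sites, and the
    standard constants computed for the window's allele-copy sample size
    (the median of per-site non-missing allele counts).  Windows with
    S = 0, or with fewer than 4 allele copies, are undefined (NaN).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    return _windowed(genotypes, window_bp, want_d=True)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for n allele copies."""
    if n < 2:
        raise ValueError("need >= 2 allele copies")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _windowed(genotypes: GenotypeMatrix, window_bp: int, want_d: bool) -> list[WindowStat]:
    g = genotypes.genome
    out: list[WindowStat] = []
    for chrom in np.unique(g.chromosome):
        idx = g.chrom_slice(chrom)
        pos = g.position_bp[idx]
        dosage = genotypes.dosage[:, idx]
        n_alleles, alt, pi_site = _site_components(dosage)
        seg = (alt > 0) & (alt < n_alleles)
        last = int(pos.max())
        for start in _window_edges(pos, window_bp):
            end = start + window_bp - 1
            partial = end > last
            in_w = (pos >= start) & (pos <= end)
            s = int(seg[in_w].sum())
            pi = float(pi_site[in_w].sum()) / window_bp
            d = np.nan
            if want_d and s > 0:
                n_med = int(np.median(n_alleles[in_w & seg]))
                if n_med < 4:
                    warnings.warn(
                        f"window {chrom}:{start}-{end}: fewer than 4 allele copies; D undefined",
                        stacklevel=2,
                    )
                else:
                    c = tajima_constants(n_med)
                    khat = float(pi_site[in_w].sum())
                    var = c["e1"] * s + c["e2"] * s * (s - 1.0)
                    d = (khat - s / c["a1"]) / np.sqrt(var) if var > 0 else np.nan
            out.append(WindowStat(int(chrom), int(start), int(end), s, pi, d, partial))
    return out


def pi_correlation(
    pi_a: list[WindowStat], pi_b: list[WindowStat]
) -> tuple[SmaFit, int]:
    """SMA fit of per-window pi between two sample subsets.

    Windows are matched on (chromosome, start); windows undefined (NaN)
    in either subset are dropped.  Returns the fit and the number of
    dropped windows.
    """
    index_b = {(w.chromosome, w.start): w for w in pi_b}
    xs, ys, dropped = [], [], 0
    for w in pi_a:
        other = index_b.get((w.chromosome, w.start))
        if other is None:
            dropped += 1
            continue
        if np.isnan(w.pi) or np.isnan(other.pi):
            dropped += 1
            continue
        xs.append(w.pi)
        ys.append(other.pi)
    if len(xs) < 3:
        raise ValueError("fewer than 3 shared windows")
    return sma_regression(np.array(xs), np.array(ys)), dropped


def windows_to_frame(windows: list[WindowStat]):
    """Tabulate window statistics (chrom, start, end, S, pi, tajima_d)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [w.chromosome for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "pi": [w.pi for w in windows],
            "tajima_d": [w.tajima_d for w in windows],
            "partial": [w.partial for w in windows],
        }
    )
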
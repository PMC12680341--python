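"""Forward simulation of a structured inbred panel and F2 crosses.

The generator works in five stages:

1. per-group allele frequencies under the Balding-Nichols model, which
   yields a panel whose multi-group Weir-Cockerham FST matches a target;
2. fully homozygous accession genotypes drawn from those frequencies
   (selfing species: every line is inbred, dosages 0 or 2);
3. additive polygenic trait architectures whose among-group behaviour
   encodes a selection regime (divergent, stabilizing, neutral);
4. F2 families: a deterministic F1 per cross, then meiosis with
   Poisson-distributed crossovers and no interference (Haldane model);
5. phenotypes = baseline + genetic value + block effect + Gaussian
   residual scaled to the requested heritability, with MCAR missingness
   and, optionally, planted outlier accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import OutlierSpec, SimConfig, TraitSpec
from .types import Genome, GenotypeMatrix, TraitArchitecture, new_phenotype_table


class ConfigurationError(ValueError):
    """A trait architecture cannot be realized with the given loci."""


# ---------------------------------------------------------------------------
# stage 1-2: structured frequencies and inbred genotypes
# ---------------------------------------------------------------------------

def simulate_structured_frequencies(
    n_snps: int, n_groups: int, fst_target: float, seed: int
) -> np.ndarray:
    """Per-group alternate-allele frequencies under the Balding-Nichols model.

    Ancestral frequencies are Uniform(0.05, 0.95); each group's frequency
    is Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p with
    F = `fst_target`, so realized multi-group FST matches the target up to
    sampling noise.

    Returns an (n_groups, n_snps) array.
    """
    if not np.isfinite(fst_target) or not (0.0 < fst_target < 1.0):
        raise ValueError(f"fst_target must be a finite fraction in (0,1), got {fst_target}")
    if n_snps < 1 or n_groups < 1:
        raise ValueError("n_snps and n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_snps)
    scale = (1.0 - fst_target) / fst_target
    freqs = rng.beta(p * scale, (1.0 - p) * scale, size=(n_groups, n_snps))
    return np.clip(freqs, 0.0, 1.0)


def make_genome(
    n_chromosomes: int,
    snps_per_chromosome: int,
    chrom_length_bp: int,
    map_length_cM: float,
    seed: int,
) -> Genome:
    """Evenly spread SNPs with a uniform genetic map (cM linear in bp)."""
    rng = np.random.default_rng(seed)
    chroms, bps, cms = [], [], []
    for c in range(1, n_chromosomes + 1):
        bp = np.sort(
            rng.choice(np.arange(1, chrom_length_bp + 1), size=snps_per_chromosome, replace=False)
        )
        chroms.append(np.full(snps_per_chromosome, c))
        bps.append(bp)
        cms.append(bp / chrom_length_bp * map_length_cM)
    return Genome(
        chromosome=np.concatenate(chroms),
        position_bp=np.concatenate(bps).astype(int),
        position_cM=np.concatenate(cms),
    )


def simulate_inbred_genotypes(
    freqs: np.ndarray, n_per_group: int, seed: int, genome: Genome | None = None
) -> GenotypeMatrix:
    """Fully homozygous accessions: dosage 2*Bernoulli(p_group) per SNP."""
    rng = np.random.default_rng(seed)
    n_groups, n_snps = freqs.shape
    if genome is None:
        genome = Genome(
            chromosome=np.ones(n_snps, dtype=int),
            position_bp=np.arange(1, n_snps + 1),
            position_cM=np.arange(n_snps, dtype=float),
        )
    dosage = np.empty((n_groups * n_per_group, n_snps))
    groups = np.empty(n_groups * n_per_group, dtype=object)
    for g in range(n_groups):
        sl = slice(g * n_per_group, (g + 1) * n_per_group)
        dosage[sl] = 2.0 * (rng.random((n_per_group, n_snps)) < freqs[g])
        groups[sl] = f"group{g + 1}"
    ids = np.array([f"acc{i:04d}" for i in range(dosage.shape[0])], dtype=object)
    return GenotypeMatrix(
        ids=ids,
        dosage=dosage,
        generation=np.array(["G0"] * dosage.shape[0], dtype=object),
        group=groups,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# stage 3: trait architectures
# ---------------------------------------------------------------------------

def assign_trait_architecture(
    genome: Genome,
    group_freqs: np.ndarray,
    trait_specs: list[TraitSpec],
    seed: int,
    genotypes: GenotypeMatrix | None = None,
) -> TraitArchitecture:
    """Draw disjoint causal SNP sets and additive effects per trait.

    *Divergent* traits get effects solved (minimum-norm least squares, plus
    a random null-space component of scale ``effect_sd``) so expected group
    mean genetic values equal ``group_optima``.  *Stabilizing* traits get
    effects orthogonal to the realized group-mean genotype differences and
    lying in the lowest-variance directions of the accession genotype
    matrix: group means coincide and standing variance is hidden in
    complementary +/- allele configurations, exactly the configuration that
    recombination in an F2 cross releases as transgressive segregation.
    *Neutral* traits get iid Gaussian effects.

    When `genotypes` (the G0 panel) is provided, stabilizing architectures
    are built against realized genotypes; otherwise they fall back to
    expected frequencies (weaker variance hiding).
    """
    rng = np.random.default_rng(seed)
    n_groups, n_snps = group_freqs.shape
    needed = sum(t.n_causal for t in trait_specs)
    if needed > n_snps:
        raise ConfigurationError(f"need {needed} causal SNPs, only {n_snps} available")

    available = np.arange(n_snps)
    rng.shuffle(available)
    available = list(available)
    arch = TraitArchitecture()

    freq_spread = group_freqs.max(axis=0) - group_freqs.min(axis=0)
    # realized panel frequencies guard against loci that happen to be
    # monomorphic in the sampled accessions (a drawn-frequency locus near
    # 0 or 1 often is), which would contribute no segregating variance
    if genotypes is not None:
        g0_mask = genotypes.generation == "G0"
        panel_freq = np.nanmean(genotypes.dosage[g0_mask], axis=0) / 2.0
    else:
        panel_freq = group_freqs.mean(axis=0)
    panel_maf = np.minimum(panel_freq, 1.0 - panel_freq)

    for spec in trait_specs:
        if spec.regime == "divergent":
            # prefer differentiated loci so the optima are reachable with
            # small per-locus effects
            pool = sorted(available, key=lambda j: -freq_spread[j])
            idx = np.array(sorted(pool[: spec.n_causal]))
        elif spec.regime == "stabilizing":
            # need loci that segregate in the panel but differ little
            # across groups; among qualified loci prefer low spread
            qualified = [j for j in available if panel_maf[j] >= 0.1]
            if len(qualified) < spec.n_causal:
                qualified = sorted(available, key=lambda j: -panel_maf[j])[: spec.n_causal]
            pool = sorted(qualified, key=lambda j: freq_spread[j])
            idx = np.array(sorted(pool[: spec.n_causal]))
        else:
            idx = np.array(sorted(available[: spec.n_causal]))
        if idx.size < spec.n_causal:
            raise ConfigurationError(f"trait {spec.name!r}: not enough loci available")
        for j in idx:
            available.remove(j)

        a = _draw_effects(spec, idx, group_freqs, genotypes, rng)
        arch.causal_idx[spec.name] = idx
        arch.effects[spec.name] = a
    return arch


def _draw_effects(spec, idx, group_freqs, genotypes, rng) -> np.ndarray:
    n_groups = group_freqs.shape[0]
    k = idx.size
    # expected per-group mean of (dosage - 1) at each causal locus
    D = 2.0 * group_freqs[:, idx] - 1.0  # (n_groups, k)

    if spec.regime == "divergent":
        optima = np.asarray(spec.group_optima, dtype=float)
        a0, *_ = np.linalg.lstsq(D, optima, rcond=None)
        resid = D @ a0 - optima
        if np.max(np.abs(resid)) > 0.05 * max(1.0, np.max(np.abs(optima))):
            raise ConfigurationError(
                f"trait {spec.name!r}: optima unreachable with selected loci "
                f"(max residual {np.max(np.abs(resid)):.3g}); "
                "increase n_causal or fst_target"
            )
        # random polygenic component in the null space of D keeps group
        # means on target while spreading effects over all loci
        z = rng.normal(0.0, spec.effect_sd, size=k)
        a = a0 + z - np.linalg.pinv(D) @ (D @ z)
        return a

    if spec.regime == "neutral":
        return rng.normal(0.0, spec.effect_sd, size=k)

    # stabilizing
    if genotypes is not None:
        g0 = genotypes.generation == "G0"
        X = genotypes.dosage[g0][:, idx] - 1.0
        labels = genotypes.group[g0]
        # centered realized group means: constraint rows forcing equal
        # group mean genetic values
        M = np.vstack([X[labels == g].mean(axis=0) for g in np.unique(labels)])
        M = M - M.mean(axis=0)
        Xc = X - X.mean(axis=0)
    else:
        M = D - D.mean(axis=0)
        Xc = D - D.mean(axis=0)
    # orthonormal basis of the constraint null space
    _, s_m, vt_m = np.linalg.svd(M, full_matrices=True)
    rank = int(np.sum(s_m > 1e-9 * max(1.0, s_m[0] if s_m.size else 0.0)))
    N = vt_m[rank:].T  # (k, k - rank)
    B = Xc @ N
    _, s_b, vt_b = np.linalg.svd(B, full_matrices=False)
    # combine the lowest-variance directions -> effects whose realized
    # accession-panel variance is tiny
    q = max(1, min(8, vt_b.shape[0]))
    w = rng.normal(size=q)
    w /= np.linalg.norm(w)
    a = N @ (vt_b[-q:].T @ w)
    # scale so the linkage-equilibrium (releasable) variance is effect_sd^2
    if genotypes is not None:
        p = np.nanmean(genotypes.dosage[genotypes.generation == "G0"][:, idx], axis=0) / 2.0
    else:
        p = group_freqs[:, idx].mean(axis=0)
    le_var = float(np.sum(4.0 * p * (1.0 - p) * a**2))
    if le_var <= 0:
        raise ConfigurationError(f"trait {spec.name!r}: degenerate stabilizing architecture")
    return a * (spec.effect_sd / np.sqrt(le_var))


# ---------------------------------------------------------------------------
# stage 4: meiosis and F2 crosses
# ---------------------------------------------------------------------------

def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, genome: Genome, rng) -> np.ndarray:
    """One recombinant gamete from a heterozygous F1 (Haldane model)."""
    out = np.empty_like(hap_a)
    for chrom in np.unique(genome.chromosome):
        m = genome.chromosome == chrom
        cm = genome.position_cM[m]
        span_morgan = (cm[-1] - cm[0]) / 100.0 if cm.size > 1 else 0.0
        n_xo = rng.poisson(span_morgan)
        xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
        start = rng.integers(2)
        phase = (start + np.searchsorted(xo, cm, side="right")) % 2
        out[m] = np.where(phase == 0, hap_a[m], hap_b[m])
    return out


def simulate_f2_cross(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    genome: Genome,
    n_offspring: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """F2 dosages from a cross of two fully homozygous parents.

    The F1 is deterministic (heterozygous wherever the parents differ);
    each F2 is the union of two independent F1 gametes.  Crossovers per
    chromosome are Poisson(map length in Morgans) at uniform cM positions,
    i.e. Haldane's map function with no interference.

    Returns an (n_offspring, n_snps) dosage array.
    """
    for p in (parent_a, parent_b):
        arr = np.asarray(p, dtype=float)
        if np.any(np.isnan(arr)) or np.any((arr != 0) & (arr != 2)):
            raise ValueError("parents must be fully homozygous with no missing calls")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap_a = np.asarray(parent_a, dtype=float) / 2.0
    hap_b = np.asarray(parent_b, dtype=float) / 2.0
    out = np.empty((n_offspring, hap_a.size))
    for i in range(n_offspring):
        out[i] = _gamete(hap_a, hap_b, genome, rng) + _gamete(hap_a, hap_b, genome, rng)
    return out


def simulate_f2_population(
    g0: GenotypeMatrix, n_crosses: int, n_f2_per_cross: int, seed: int
) -> GenotypeMatrix:
    """F2s from a balanced crossing design over the accession panel.

    Mirrors a designed diallel-like cross panel in which every accession
    serves as a parent: the first ``n_acc // 2`` crosses form a random
    perfect pairing of the whole panel, remaining crosses are random
    pairs (across groups).  With fewer crosses than ``n_acc // 2`` a
    random subset of the pairing is used and coverage is partial.
    """
    rng = np.random.default_rng(seed)
    n_acc = g0.n_individuals
    perm = rng.permutation(n_acc)
    pairing = [np.array([perm[2 * k], perm[2 * k + 1]]) for k in range(n_acc // 2)]
    if n_crosses <= len(pairing):
        pairs = pairing[:n_crosses]
    else:
        pairs = pairing + [
            rng.choice(n_acc, size=2, replace=False)
            for _ in range(n_crosses - len(pairing))
        ]
    dosages, ids = [], []
    for c, (ia, ib) in enumerate(pairs):
        d = simulate_f2_cross(g0.dosage[ia], g0.dosage[ib], g0.genome, n_f2_per_cross, rng)
        dosages.append(d)
        ids.extend(f"f2_{c:03d}_{k}" for k in range(n_f2_per_cross))
    dosage = np.vstack(dosages)
    n = dosage.shape[0]
    return GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        dosage=dosage,
        generation=np.array(["F2"] * n, dtype=object),
        group=np.array([""] * n, dtype=object),
        genome=g0.genome,
    )


def combine(g0: GenotypeMatrix, f2: GenotypeMatrix) -> GenotypeMatrix:
    return GenotypeMatrix(
        ids=np.concatenate([g0.ids, f2.ids]),
        dosage=np.vstack([g0.dosage, f2.dosage]),
        generation=np.concatenate([g0.generation, f2.generation]),
        group=np.concatenate([g0.group, f2.group]),
        genome=g0.genome,
    )


# ---------------------------------------------------------------------------
# stage 5: phenotypes
# ---------------------------------------------------------------------------

def synthesize_phenotypes(
    genotypes: GenotypeMatrix,
    architecture: TraitArchitecture,
    trait_specs: list[TraitSpec],
    n_blocks: int,
    block_effects: dict[str, tuple[float, ...]],
    missing_fraction: dict[str, float],
    seed: int,
    f2_blocks: np.ndarray | None = None,
):
    """Phenotypes under the common-garden design.

    G0 accessions are replicated once per spatial block (B rows each);
    F2 individuals are unreplicated and sit in a single block (uniform
    random if `f2_blocks` is not given).  Per trait:

        value = baseline + genetic + block_effect[block] + N(0, Ve)

    with Ve = Vg (1 - h2) / h2 where Vg is the *realized* genetic variance
    over unique genotypes, so var(genetic)/var(total | blocks removed)
    equals h2 exactly in expectation, and exactly when h2 = 1 (Ve = 0).
    Missingness is completely at random at the per-trait rate.
    """
    rng = np.random.default_rng(seed)
    g0_mask = genotypes.generation == "G0"
    f2_mask = ~g0_mask
    n_g0 = int(g0_mask.sum())
    n_f2 = int(f2_mask.sum())
    if f2_blocks is None:
        f2_blocks = rng.integers(1, n_blocks + 1, size=n_f2)

    rows_id, rows_gen, rows_geno, rows_group, rows_block = [], [], [], [], []
    for i in np.flatnonzero(g0_mask):
        for b in range(1, n_blocks + 1):
            rows_id.append(f"{genotypes.ids[i]}_b{b}")
            rows_gen.append("G0")
            rows_geno.append(genotypes.ids[i])
            rows_group.append(genotypes.group[i])
            rows_block.append(b)
    for k, i in enumerate(np.flatnonzero(f2_mask)):
        rows_id.append(str(genotypes.ids[i]))
        rows_gen.append("F2")
        rows_geno.append(genotypes.ids[i])
        rows_group.append("")
        rows_block.append(int(f2_blocks[k]))
    rows_block = np.asarray(rows_block)

    geno_order = np.concatenate([np.repeat(np.flatnonzero(g0_mask), n_blocks),
                                 np.flatnonzero(f2_mask)])

    values: dict[str, np.ndarray] = {}
    for spec in trait_specs:
        g_all = architecture.genetic_values(genotypes.dosage, spec.name)
        vg = float(np.var(g_all, ddof=1)) if g_all.size > 1 else 0.0
        ve = vg * (1.0 - spec.h2) / spec.h2
        be = np.asarray(block_effects.get(spec.name, np.zeros(n_blocks)), dtype=float)
        if be.size != n_blocks:
            raise ValueError(f"block_effects[{spec.name!r}] must have length {n_blocks}")
        vals = (
            spec.baseline
            + g_all[geno_order]
            + be[rows_block - 1]
            + (rng.normal(0.0, np.sqrt(ve), size=geno_order.size) if ve > 0 else 0.0)
        )
        frac = missing_fraction.get(spec.name, 0.0)
        if frac > 0:
            vals = vals.copy()
            vals[rng.random(vals.size) < frac] = np.nan
        values[spec.name] = vals

    return new_phenotype_table(
        np.array(rows_id, dtype=object),
        np.array(rows_gen, dtype=object),
        np.array(rows_geno, dtype=object),
        np.array(rows_group, dtype=object),
        rows_block,
        values,
    )


def plant_outlier_accessions(
    genotypes: GenotypeMatrix,
    phenotypes,
    outlier_spec: OutlierSpec,
    seed: int,
):
    """Plant extreme accessions: a phenotypic shift plus a marker haplotype.

    Randomly chosen G0 accessions have their target-trait values (all block
    replicates) shifted upward by ``shift_sd`` accession-level phenotypic
    standard deviations, and a contiguous haplotype block on chromosome 1
    overwritten with the minor allele at every SNP (a divergent pattern
    shared by all planted outliers).  Returns
    ``(genotypes, phenotypes, outlier_ids)``; a shift too small to exceed
    the F2 range raises a warning, not an error.
    """
    rng = np.random.default_rng(seed)
    g0_ids = genotypes.ids[genotypes.generation == "G0"]
    if outlier_spec.n_outliers >= g0_ids.size:
        raise ValueError("n_outliers must be smaller than the number of accessions")
    outlier_ids = list(rng.choice(g0_ids, size=outlier_spec.n_outliers, replace=False))

    trait = outlier_spec.trait
    phen = phenotypes.copy()
    g0_rows = phen["generation"] == "G0"
    acc_means = phen.loc[g0_rows].groupby("genotype_id")[trait].mean()
    sd = float(acc_means.std(ddof=1))
    shift = outlier_spec.shift_sd * sd
    target_rows = phen["genotype_id"].isin(outlier_ids)
    phen.loc[target_rows, trait] = phen.loc[target_rows, trait] + shift

    f2_vals = phen.loc[phen["generation"] == "F2", trait].dropna()
    if f2_vals.size and phen.loc[target_rows, trait].max() <= f2_vals.max():
        warnings.warn(
            f"planted shift ({outlier_spec.shift_sd} SD) does not exceed the F2 range "
            f"of trait {trait!r}", stacklevel=2,
        )

    geno = GenotypeMatrix(
        ids=genotypes.ids.copy(),
        dosage=genotypes.dosage.copy(),
        generation=genotypes.generation.copy(),
        group=genotypes.group.copy(),
        genome=genotypes.genome,
    )
    chrom1 = geno.genome.chrom_slice(1)
    bp = geno.genome.position_bp[chrom1]
    span = outlier_spec.haplotype_block_bp
    start_bp = int(rng.integers(bp[0], max(bp[0] + 1, bp[-1] - span)))
    block = chrom1[(bp >= start_bp) & (bp < start_bp + span)]
    if block.size:
        non_out = ~np.isin(geno.ids, outlier_ids) & (geno.generation == "G0")
        major = np.nanmean(geno.dosage[non_out][:, block], axis=0) > 1.0
        pattern = np.where(major, 0.0, 2.0)  # minor allele, homozygous
        out_rows = np.flatnonzero(np.isin(geno.ids, outlier_ids))
        geno.dosage[np.ix_(out_rows, block)] = pattern
    return geno, phen, outlier_ids


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genotypes: GenotypeMatrix  # G0 + F2 combined
    phenotypes: "object"  # pandas DataFrame (PhenotypeTable)
    architecture: TraitArchitecture
    group_freqs: np.ndarray
    outlier_ids: list[str]

    @property
    def g0(self) -> GenotypeMatrix:
        return self.genotypes.subset_individuals(self.genotypes.generation == "G0")

    @property
    def f2(self) -> GenotypeMatrix:
        return self.genotypes.subset_individuals(self.genotypes.generation == "F2")


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator under `config` (all randomness from its seed)."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=6)
    freqs = simulate_structured_frequencies(
        config.n_snps, config.n_groups, config.fst_target, int(seeds[0])
    )
    genome = make_genome(
        config.n_chromosomes, config.snps_per_chromosome,
        config.chrom_length_bp, config.map_length_cM, int(seeds[1]),
    )
    g0 = simulate_inbred_genotypes(freqs, config.n_accessions_per_group, int(seeds[2]), genome)
    arch = assign_trait_architecture(genome, freqs, config.trait_specs, int(seeds[3]), genotypes=g0)
    f2 = simulate_f2_population(g0, config.n_crosses, config.n_f2_per_cross, int(seeds[4]))
    everyone = combine(g0, f2)
    phen = synthesize_phenotypes(
        everyone, arch, config.trait_specs, config.n_blocks,
        config.block_effects, config.missing_fraction, int(seeds[5]),
    )
    outlier_ids: list[str] = []
    if config.outlier_spec is not None:
        everyone, phen, outlier_ids = plant_outlier_accessions(
            everyone, phen, config.outlier_spec, int(seeds[5]) ^ 0x5EED,
        )
    return SimulatedDataset(config, everyone, phen, arch, freqs, outlier_ids)
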
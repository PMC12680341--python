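"""Variant filtering and windowed diversity statistics, checked against
brute-force pairwise-difference computations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenospace as ps
from phenospace.popgen import tajima_constants
from phenospace.simdata.types import Genome, GenotypeMatrix


def make_geno(dosage, positions=None, chrom=None, generation=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = np.asarray(positions if positions is not None else np.arange(1, m + 1))
    chrom = np.asarray(chrom if chrom is not None else np.ones(m, dtype=int))
    return GenotypeMatrix(
        ids=np.array([f"i{k}" for k in range(n)], dtype=object),
        dosage=dosage,
        generation=np.array(generation if generation is not None else [""] * n, dtype=object),
        group=np.array([""] * n, dtype=object),
        genome=Genome(chromosome=chrom, position_bp=positions, position_cM=positions.astype(float)),
    )


def pi_brute(dosage, length):
    """Sum over all pairs of allele copies of per-site difference fractions."""
    # expand diploids to allele copies (homozygotes -> two equal copies;
    # heterozygote -> one of each); per-site, drop missing individuals
    total = 0.0
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        col = col[~np.isnan(col)]
        copies = []
        for d in col:
            copies += [1, 1] if d == 2 else ([0, 1] if d == 1 else [0, 0])
        copies = np.array(copies)
        n = copies.size
        if n < 2:
            continue
        diffs = sum(
            copies[a] != copies[b] for a in range(n) for b in range(a + 1, n)
        )
        total += diffs / (n * (n - 1) / 2)
    return total / length


class TestFilterVariants:
    def test_maf_threshold_inclusive(self):
        # panel frequencies 0, 0.03̄, 0.05, 0.2, 0.5 over 30 haploid-pairs
        rng = np.random.default_rng(1)
        n = 30
        freqs = [0.0, 1 / 30, 0.05, 0.2, 0.5]
        cols = []
        for f in freqs:
            alt = int(round(f * 2 * n))
            col = np.zeros(n)
            col[: alt // 2] = 2.0
            if alt % 2:
                col[alt // 2] = 1.0
            cols.append(col)
        geno = make_geno(np.column_stack(cols))
        kept, report = ps.filter_variants(geno, ps.VariantFilterSpec(maf_min=0.05, max_missing=0.0))
        assert kept.n_snps == 3  # 0.05 kept (boundary inclusive), 0.2, 0.5
        assert report.n_kept == 3

    def test_missingness_threshold(self):
        col = np.full(50, 2.0)
        col[:3] = np.nan  # 6% missing
        ok = np.tile([0.0, 2.0], 25)
        geno = make_geno(np.column_stack([col, ok]))
        kept, _ = ps.filter_variants(geno, ps.VariantFilterSpec(maf_min=0.0, max_missing=0.05))
        assert kept.n_snps == 1

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_filter_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(25, 40), p=[0.4, 0.1, 0.45, 0.05])
        geno = make_geno(dosage)
        spec = ps.VariantFilterSpec(maf_min=0.05, max_missing=0.1)
        once, _ = ps.filter_variants(geno, spec)
        twice, rep = ps.filter_variants(once, spec)
        assert twice.n_snps == once.n_snps
        assert rep.n_kept == once.n_snps

    def test_empty_subset_rejected(self):
        geno = make_geno(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="empty"):
            ps.filter_variants(geno, ps.VariantFilterSpec(samples=[]))


class TestWindowedPi:
    def test_two_homozygotes_three_sites(self):
        """Two inbred lines differing at 3 sites in one 10 kb window:
        each site contributes (2*2)/C(4,2)=2/3; pi = 2 / 10000."""
        dosage = np.array([[2.0, 2.0, 2.0], [0.0, 0.0, 0.0]])
        geno = make_geno(dosage, positions=np.array([100, 200, 300]))
        stats = ps.windowed_pi(geno, window_bp=10_000)
        assert len(stats) == 1
        assert stats[0].pi == pytest.approx(3 * (2 / 3) / 10_000)
        assert stats[0].pi == pytest.approx(2e-4)

    def test_monomorphic_window_zero(self):
        geno = make_geno(np.full((6, 4), 2.0))
        stats = ps.windowed_pi(geno, window_bp=100)
        assert stats[0].pi == 0.0

    def test_agreement_with_pairwise_brute_force(self):
        rng = np.random.default_rng(2)
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(10, 200), p=[0.4, 0.15, 0.4, 0.05])
        positions = np.sort(rng.choice(np.arange(1, 5000), 200, replace=False))
        geno = make_geno(dosage, positions=positions)
        stats = ps.windowed_pi(geno, window_bp=5000)
        ours = sum(w.pi * 5000 for w in stats)
        brute = pi_brute(dosage, 1.0)
        assert ours == pytest.approx(brute, abs=1e-12)

    def test_tiling_completeness(self):
        """Window sums equal the genome-wide per-site total exactly."""
        rng = np.random.default_rng(3)
        dosage = 2.0 * (rng.random((8, 300)) < 0.3)
        positions = np.sort(rng.choice(np.arange(1, 20_000), 300, replace=False))
        geno = make_geno(dosage, positions=positions)
        fine = ps.windowed_pi(geno, window_bp=100)
        coarse = ps.windowed_pi(geno, window_bp=20_000)
        assert sum(w.pi * 100 for w in fine) == pytest.approx(
            sum(w.pi * 20_000 for w in coarse), abs=1e-12
        )

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="window_bp"):
            ps.windowed_pi(make_geno(np.zeros((2, 2))), window_bp=0)


def tajima_constants_brute(n):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


class TestTajimasD:
    @pytest.mark.parametrize("n", [4, 10, 50])
    def test_constants_match_brute_force(self, n):
        ours = tajima_constants(n)
        ref = tajima_constants_brute(n)
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, abs=1e-12)

    def test_d_matches_hand_computation(self):
        """One window computed by hand: the numerator khat - S/a1 and the
        variance term follow the standard constants exactly (so D = 0
        precisely when khat equals the Watterson expectation S/a1)."""
        dosage = np.array([[2.0, 2.0], [0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        geno = make_geno(dosage, positions=np.array([10, 20]))
        stats = ps.windowed_tajimas_d(geno, window_bp=100)
        c = tajima_constants(8)
        khat = 2 * (4 * 4 / (8 * 7 / 2))  # two sites, 4 alt x 4 ref copies
        s = 2
        expected = (khat - s / c["a1"]) / np.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
        assert stats[0].tajima_d == pytest.approx(expected, abs=1e-12)

    def test_no_segregating_sites_undefined(self):
        geno = make_geno(np.full((5, 3), 2.0))
        stats = ps.windowed_tajimas_d(geno, window_bp=100)
        assert np.isnan(stats[0].tajima_d)

    def test_neutral_sfs_null_mean_near_zero(self):
        """Sites with counts drawn from the neutral frequency spectrum
        (P(c) proportional to 1/c) give E[khat] = S/a1, so mean D ~ 0."""
        rng = np.random.default_rng(4)
        n_ind, n_windows, s_per = 40, 1000, 5
        n_copies = 2 * n_ind
        c_support = np.arange(1, n_copies)
        c_probs = (1.0 / c_support) / np.sum(1.0 / c_support)
        cols = []
        for _ in range(n_windows * s_per):
            c = rng.choice(c_support, p=c_probs)
            copies = np.zeros(n_copies)
            copies[rng.choice(n_copies, size=c, replace=False)] = 1.0
            cols.append(copies[::2] + copies[1::2])  # fold copies into diploids
        dosage = np.column_stack(cols)
        positions = np.arange(n_windows * s_per) * 20 + 10  # 5 SNPs per 100 bp
        stats = ps.windowed_tajimas_d(make_geno(dosage, positions=positions), window_bp=100)
        ds = np.array([w.tajima_d for w in stats])
        assert abs(np.nanmean(ds)) < 0.3

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_allele_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.choice([0.0, 1.0, 2.0], size=(12, 30))
        geno_a = make_geno(dosage)
        geno_b = make_geno(2.0 - dosage)  # ref/alt flip at every SNP
        da = [w.tajima_d for w in ps.windowed_tajimas_d(geno_a, window_bp=10)]
        db = [w.tajima_d for w in ps.windowed_tajimas_d(geno_b, window_bp=10)]
        assert np.allclose(da, db, equal_nan=True)


class TestPiCorrelation:
    def test_identical_subsets_give_identity_line(self):
        rng = np.random.default_rng(5)
        dosage = 2.0 * (rng.random((20, 200)) < rng.uniform(0.1, 0.9, 200))
        geno = make_geno(dosage, positions=np.sort(rng.choice(np.arange(1, 9999), 200, replace=False)))
        stats = ps.windowed_pi(geno, window_bp=1000)
        fit, dropped = ps.pi_correlation(stats, stats)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert dropped == 0

    def test_split_panmictic_panel_slope_near_one(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 400)
        dosage = 2.0 * (rng.random((80, 400)) < p)
        positions = np.sort(rng.choice(np.arange(1, 40_000), 400, replace=False))
        a = make_geno(dosage[:40], positions=positions)
        b = make_geno(dosage[40:], positions=positions)
        fit, _ = ps.pi_correlation(
            ps.windowed_pi(a, window_bp=2000), ps.windowed_pi(b, window_bp=2000)
        )
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert fit.r2 > 0.5

    def test_too_few_windows_rejected(self):
        geno = make_geno(np.tile([0.0, 2.0], (6, 1)), positions=np.array([1, 2]))
        stats = ps.windowed_pi(geno, window_bp=10_000)
        with pytest.raises(ValueError, match="3 shared"):
            ps.pi_correlation(stats, stats)
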
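"""Consensus detection of phenotypically unique accessions.

The procedure mirrors the resampling logic of the phenotypic-space
analysis: build many hypervolumes per group on equal-size subsamples,
form (a seeded subset of) ordered pairs of one accession-side and one
F2-side hypervolume, and score every accession's observed point for
membership in the pair's accession-side *unique component* — occupied
by the accession subsample but not by the F2 one.  Accessions that
accumulate the bulk of these occurrences — the smallest set covering 95%
of all occurrences — form one run's outlier list; the final consensus
keeps accessions present in enough independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial import cKDTree

from .hypervolume import (
    DEFAULT_NU,
    DEFAULT_SAMPLES_PER_POINT,
    Hypervolume,
    resampled_hypervolumes,
)


@dataclass
class OccurrenceCounts:
    counts: dict[str, int]  # accession id -> occurrences in unique components
    total_comparisons: int

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())


@dataclass
class ConsensusReport:
    run_lists: list[list[str]]
    min_count: int
    consensus: list[str]
    run_counts: dict[str, int] = field(default_factory=dict)


def unique_occurrence_counts(
    acc_scores: np.ndarray,
    acc_ids: np.ndarray,
    f2_scores: np.ndarray,
    n_sub: int = 500,
    reps: int = 100,
    n_pairs: int | None = None,
    nu: float = DEFAULT_NU,
    gamma: float | None = None,
    samples_per_point: int = DEFAULT_SAMPLES_PER_POINT,
    seed: int = 0,
) -> OccurrenceCounts:
    """Occurrences of each accession inside accession-side unique components.

    Builds `reps` hypervolumes per group on subsamples of size `n_sub`;
    for each ordered (accession-hv, F2-hv) pair — all ``reps**2`` pairs,
    or a seeded random subset of `n_pairs` — every accession's observed
    point is scored for membership in the pair's accession-side unique
    component: within the accession subsample's occupied region but
    outside the F2 subsample's (occupancy by nearest-neighbour distance
    with a self-calibrated radius; see the inline notes).
    """
    if n_pairs is None and reps**2 > 10**6:
        raise ValueError(
            f"{reps}**2 pairs exceed 1e6; pass n_pairs to enumerate a seeded subset"
        )
    acc_scores = np.asarray(acc_scores, dtype=float)
    f2_scores = np.asarray(f2_scores, dtype=float)
    acc_ids = np.asarray(acc_ids)
    rng = np.random.default_rng(seed)

    acc_res = resampled_hypervolumes(
        acc_scores, n_sub=min(n_sub, acc_scores.shape[0]), reps=reps,
        nu=nu, gamma=gamma, samples_per_point=samples_per_point,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    f2_res = resampled_hypervolumes(
        f2_scores, n_sub=min(n_sub, f2_scores.shape[0]), reps=reps,
        nu=nu, gamma=gamma, samples_per_point=samples_per_point,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    if n_pairs is None:
        pairs = [(i, j) for i in range(reps) for j in range(reps)]
    else:
        pairs = [tuple(rng.integers(0, reps, size=2)) for _ in range(n_pairs)]

    # membership in a pair's accession-side unique component: inside the
    # accession hypervolume (boundary test) and NOT within the F2
    # hypervolume's occupied region.  F2 occupancy is judged by nearest-
    # neighbour distance to the fitted F2 subsample itself, with the
    # radius self-calibrated as the 95th percentile of that subsample's
    # own nearest-neighbour spacings: a query farther from every F2
    # point than F2 points typically are from each other occupies space
    # the F2s never reached.  (Proximity to the Monte-Carlo unique-
    # component subcloud is far noisier: the subcloud hugs the F2
    # boundary, so interior accessions sit within one characteristic
    # spacing of it, and its density varies with the sampling budget.)
    def occupied(hv: Hypervolume, queries: np.ndarray) -> np.ndarray:
        tree = cKDTree(hv.points)
        self_nn = tree.query(hv.points, k=2)[0][:, 1]
        tau = float(np.quantile(self_nn, 0.95))
        return tree.query(queries, k=1)[0] <= tau

    # the accession-side test must not delegate to the one-class boundary:
    # with nu > 0 the boundary treats the most extreme ~nu of the fit
    # points as outliers, i.e. it would drop exactly the accessions the
    # procedure is looking for
    in_acc = np.array([occupied(hv, acc_scores) for hv in acc_res.hypervolumes])
    out_f2 = np.array([~occupied(hv, acc_scores) for hv in f2_res.hypervolumes])

    counts = dict.fromkeys(acc_ids.tolist(), 0)
    for i, j in pairs:
        for a in acc_ids[in_acc[i] & out_f2[j]]:
            counts[a] += 1
    return OccurrenceCounts(counts=counts, total_comparisons=len(pairs))


def select_95pct_contributors(
    counts: OccurrenceCounts, coverage: float = 0.95
) -> list[str]:
    """The smallest set of accessions covering `coverage` of all occurrences.

    Accessions are ranked by occurrence count (descending, ties broken by
    id for determinism); the returned prefix is the shortest whose
    cumulative count reaches ``coverage * total``, extended inclusively
    over any accessions tied with the last one admitted.  Accessions with
    zero occurrences are never returned.
    """
    total = counts.total_occurrences
    if total == 0:
        return []
    ranked = sorted(
        ((a, c) for a, c in counts.counts.items() if c > 0),
        key=lambda ac: (-ac[1], ac[0]),
    )
    target = coverage * total
    out, cum = [], 0
    for k, (a, c) in enumerate(ranked):
        out.append(a)
        cum += c
        if cum >= target:
            last = c
            for a2, c2 in ranked[k + 1:]:
                if c2 == last:
                    out.append(a2)
                else:
                    break
            break
    return out


def consensus_outliers(run_lists: list[list[str]], min_count: int = 6) -> ConsensusReport:
    """Accessions present in at least `min_count` of the run lists."""
    if len(run_lists) < 1:
        raise ValueError("need at least one run list")
    if min_count > len(run_lists):
        raise ValueError(f"min_count={min_count} exceeds number of runs ({len(run_lists)})")
    run_counts: dict[str, int] = {}
    for lst in run_lists:
        for a in set(lst):
            run_counts[a] = run_counts.get(a, 0) + 1
    consensus = sorted(a for a, c in run_counts.items() if c >= min_count)
    return ConsensusReport(run_lists=run_lists, min_count=min_count,
                           consensus=consensus, run_counts=run_counts)


def consensus_pipeline(
    acc_scores: np.ndarray,
    acc_ids: np.ndarray,
    f2_scores: np.ndarray,
    runs: int = 10,
    min_count: int = 6,
    coverage: float = 0.95,
    seed: int = 0,
    **occurrence_kwargs,
) -> ConsensusReport:
    """Repeat the occurrence counting `runs` times (master-seed offsets)
    and keep accessions appearing in at least `min_count` run lists."""
    rng = np.random.default_rng(seed)
    run_lists = []
    for _ in range(runs):
        counts = unique_occurrence_counts(
            acc_scores, acc_ids, f2_scores,
            seed=int(rng.integers(0, 2**31 - 1)), **occurrence_kwargs,
        )
        run_lists.append(select_95pct_contributors(counts, coverage=coverage))
    return consensus_outliers(run_lists, min_count=min_count)


def percent_reduction(count_full: int, count_reduced: int) -> float:
    """Percentage drop from `count_full` to `count_reduced`, one decimal
    (half-up rounding): 100 * (full - reduced) / full."""
    if count_full <= 0:
        raise ValueError("count_full must be positive")
    if count_reduced < 0:
        raise ValueError("counts must be non-negative")
    pct = Decimal(100) * (Decimal(count_full) - Decimal(count_reduced)) / Decimal(count_full)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
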
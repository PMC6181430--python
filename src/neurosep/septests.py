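"""Tests of decoding separability and the competing operational tests.

The core statistic quantifies deviations from decoding separability (DDS)
in a 2x2 design.  For each level ``i`` of the target dimension, kernel
density estimates of the decoded values are formed at the two levels of the
irrelevant dimension and compared pointwise on a fixed evaluation grid:

    DDS = sum_i sum_k | p_i1(A_k) - p_i2(A_k) |

summed over both target levels and all 1,000 grid points.  Following the
original formulation the raw statistic sums density values without a
grid-spacing factor; :func:`l1_distance` provides the properly scaled L1
distance separately.  The raw DDS is positive even under separability
(KDE estimation error never vanishes at finite n), so it is standardized
against a permutation null: the irrelevant-dimension labels are shuffled
200 times separately within each target level -- exchangeable exactly when
decoding separability holds -- and the observed statistic is expressed as
its mid-rank percentile in that empirical distribution, reported both as
percentile - 50 (null around 0) and as a proportion (null around 0.5).

Also provided: classification-accuracy invariance/generalization verdicts
derived from closed-form decoding distributions, the weight-vector
orthogonality index, and the pattern-difference (interaction) permutation
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .decoding import DecodingDistribution

__all__ = [
    "EvaluationGrid",
    "DensityEstimate",
    "DDSResult",
    "AccuracyTable",
    "OrthogonalityResult",
    "PatternDifferenceResult",
    "build_grid",
    "estimate_density",
    "l1_distance",
    "dds_statistic",
    "standardize_dds",
    "accuracy_table",
    "accuracy_invariance_and_generalization",
    "orthogonality_index",
    "pattern_difference_test",
    "variance_explained",
]

GRID_POINTS = 1000
N_SHUFFLES = 200


@dataclass(frozen=True)
class EvaluationGrid:
    """Uniform grid spanning twice the data range, centered on the data."""

    points: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        if points.ndim != 1 or points.size < 2:
            raise ValueError("grid needs at least two points")
        object.__setattr__(self, "points", points)


@dataclass(frozen=True)
class DensityEstimate:
    grid: EvaluationGrid
    density: np.ndarray
    bandwidth: float
    n: int

    def __post_init__(self) -> None:
        density = np.asarray(self.density, dtype=float)
        if density.shape != self.grid.points.shape:
            raise ValueError("density and grid lengths differ")
        if np.any(density < 0):
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "density", density)


@dataclass(frozen=True)
class DDSResult:
    """Raw DDS with its permutation EDF and standardized indices."""

    raw: float
    edf: np.ndarray
    standardized_percentile: float  # percentile in the EDF minus 50, in [-50, 50]
    standardized_proportion: float  # percentile / 100, in [0, 1]
    standardized_z: float  # (raw - mean(EDF)) / sd(EDF); continuous, unbounded
    n_shuffles: int
    seed: int | None
    bandwidth: str = "pooled"

    def value(self, scale: str = "proportion") -> float:
        if scale in ("proportion",):
            return self.standardized_proportion
        if scale in ("percentile_minus_50", "percentile"):
            return self.standardized_percentile
        if scale in ("edf_z", "z"):
            return self.standardized_z
        raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class AccuracyTable:
    """P(correct label for target level i | condition (i, j)), shape (L_A, L_B)."""

    values: np.ndarray
    chance: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("accuracy table must be 2-D (target x irrelevant)")
        if np.any((values < 0) | (values > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class OrthogonalityResult:
    cosine: float
    angle_deg: float
    pearson_of_vectors: float


@dataclass(frozen=True)
class PatternDifferenceResult:
    interaction_vector: np.ndarray
    statistic: float
    permutation_p: float
    n_perm: int


# ---------------------------------------------------------------------------
# density machinery


def build_grid(
    samples: np.ndarray | Sequence[float], n_points: int = GRID_POINTS
) -> EvaluationGrid:
    """Evaluation grid for pooled decoded values.

    ``n_points`` evenly spaced points starting at the minimum data point
    minus half the data range and finishing at the maximum plus half the
    range (span = twice the data range).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least two values to build a grid")
    lo, hi = float(samples.min()), float(samples.max())
    data_range = hi - lo
    if data_range <= 0:
        raise ValueError("degenerate range: all values identical")
    points = np.linspace(lo - data_range / 2.0, hi + data_range / 2.0, n_points)
    return EvaluationGrid(points=points, spacing=float(points[1] - points[0]))


def _scott_bandwidth(samples: np.ndarray) -> float:
    sd = float(np.std(samples, ddof=1))
    if sd <= 0:
        raise ValueError("zero sample standard deviation: KDE bandwidth undefined")
    return sd * samples.size ** (-1.0 / 5.0)


def _kde_eval(samples: np.ndarray, points: np.ndarray, h: float) -> np.ndarray:
    # chunked over samples to keep the kernel matrix cache-friendly at large n
    out = np.zeros(points.size)
    for start in range(0, samples.size, 4096):
        chunk = samples[start : start + 4096]
        z = (points[None, :] - chunk[:, None]) / h
        out += np.exp(-0.5 * z * z).sum(axis=0)
    return out / (samples.size * h * np.sqrt(2.0 * np.pi))


def estimate_density(
    samples: np.ndarray | Sequence[float],
    grid: EvaluationGrid,
    bandwidth: float | None = None,
) -> DensityEstimate:
    """Gaussian KDE with Scott's-rule bandwidth (``h = sd * n^(-1/5)``).

    Equivalent to the usual automatic-bandwidth Gaussian KDE for univariate
    data (sample SD with one delta degree of freedom).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least two samples for a KDE")
    h = float(bandwidth) if bandwidth is not None else _scott_bandwidth(samples)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    density = _kde_eval(samples, grid.points, h)
    return DensityEstimate(grid=grid, density=density, bandwidth=h, n=samples.size)


def l1_distance(p: DensityEstimate, q: DensityEstimate) -> float:
    """Riemann-sum L1 distance between two densities on a shared grid."""
    if p.grid.points.shape != q.grid.points.shape or not np.array_equal(
        p.grid.points, q.grid.points
    ):
        raise ValueError("density estimates must share the same grid")
    return float(np.abs(p.density - q.density).sum() * p.grid.spacing)


# ---------------------------------------------------------------------------
# the DDS statistic


def _design_levels(
    samples: Mapping[tuple[int, int], np.ndarray],
) -> tuple[list[int], list[int]]:
    levels_a = sorted({i for i, _ in samples})
    levels_b = sorted({j for _, j in samples})
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("the DDS statistic is defined for a 2x2 design")
    for i in levels_a:
        for j in levels_b:
            if (i, j) not in samples or len(np.ravel(samples[(i, j)])) == 0:
                raise ValueError(f"missing or empty sample for condition {(i, j)}")
    return levels_a, levels_b


def _pooled(samples: Mapping[tuple[int, int], np.ndarray]) -> np.ndarray:
    return np.concatenate([np.ravel(np.asarray(v, float)) for v in samples.values()])


def dds_statistic(
    samples: Mapping[tuple[int, int], np.ndarray],
    grid: EvaluationGrid | None = None,
) -> float:
    """Raw DDS for a 2x2 design of decoded-value samples.

    The grid is built from all four conditions pooled (shared support);
    each condition's KDE uses its own Scott bandwidth.  The sum runs over
    both target levels and all grid points, with no spacing factor.
    """
    levels_a, levels_b = _design_levels(samples)
    if grid is None:
        grid = build_grid(_pooled(samples))
    total = 0.0
    for i in levels_a:
        p1 = estimate_density(samples[(i, levels_b[0])], grid).density
        p2 = estimate_density(samples[(i, levels_b[1])], grid).density
        total += float(np.abs(p1 - p2).sum())
    return total


def standardize_dds(
    samples: Mapping[tuple[int, int], np.ndarray],
    n_shuffles: int = N_SHUFFLES,
    seed: int | np.random.Generator | None = None,
    bandwidth: str = "pooled",
    include_observed_in_edf: bool = False,
    grid: EvaluationGrid | None = None,
) -> DDSResult:
    """Permutation-standardized DDS.

    The irrelevant-dimension labels are shuffled ``n_shuffles`` times,
    separately within each target level, and the DDS is recomputed each time
    to build the null EDF.  The grid is built once from the pooled data and
    reused across permutations.  The observed statistic's mid-rank percentile
    in the EDF gives the standardized indices (ties get half weight).

    ``bandwidth`` selects how KDE bandwidths are assigned:

    - ``"pooled"`` (default): one Scott bandwidth per target level, computed
      from that level's pooled sample with the per-condition sample size.
      Being permutation-invariant, it makes the shuffle null exactly
      exchangeable, and the observed statistic is computed with the same
      bandwidth for consistency.
    - ``"per-condition"``: each condition's (and each shuffled pseudo
      condition's) KDE gets its own Scott bandwidth, recomputed inside every
      permutation; this mirrors per-sample automatic bandwidth selection.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    if bandwidth not in ("pooled", "per-condition"):
        raise ValueError("bandwidth must be 'pooled' or 'per-condition'")
    levels_a, levels_b = _design_levels(samples)
    if grid is None:
        grid = build_grid(_pooled(samples))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    contributions = np.zeros(n_shuffles + 1)  # row 0 = observed arrangement
    for i in levels_a:
        x1 = np.ravel(np.asarray(samples[(i, levels_b[0])], float))
        x2 = np.ravel(np.asarray(samples[(i, levels_b[1])], float))
        if x1.size < 2 or x2.size < 2:
            raise ValueError("need >= 2 decoded values per condition")
        x = np.concatenate([x1, x2])
        n1 = x1.size
        base = np.zeros(x.size, dtype=bool)
        base[:n1] = True  # True marks membership in the first irrelevant level
        labels = np.empty((n_shuffles + 1, x.size), dtype=bool)
        labels[0] = base
        for s in range(1, n_shuffles + 1):
            labels[s] = rng.permutation(base)
        if bandwidth == "pooled":
            contributions += _level_dds_pooled(x, labels, n1, grid.points)
        else:
            contributions += _level_dds_per_condition(x, labels, grid.points)

    raw = float(contributions[0])
    edf = contributions[1:]
    reference = np.append(edf, raw) if include_observed_in_edf else edf
    percentile = (
        100.0
        * (np.count_nonzero(reference < raw) + 0.5 * np.count_nonzero(reference == raw))
        / reference.size
    )
    edf_sd = float(edf.std(ddof=1))
    z = (raw - float(edf.mean())) / edf_sd if edf_sd > 0 else 0.0
    return DDSResult(
        raw=raw,
        edf=edf,
        standardized_percentile=percentile - 50.0,
        standardized_proportion=percentile / 100.0,
        standardized_z=z,
        n_shuffles=n_shuffles,
        seed=seed if isinstance(seed, int) else None,
        bandwidth=bandwidth,
    )


def _level_dds_pooled(
    x: np.ndarray, labels: np.ndarray, n1: int, points: np.ndarray
) -> np.ndarray:
    """One target level's DDS contribution for every label arrangement.

    With a shared bandwidth the KDE is linear in sample membership, so every
    arrangement reduces to one row of a contrast-matrix product with a
    precomputed kernel matrix.
    """
    n2 = x.size - n1
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        raise ValueError("zero sample standard deviation: KDE bandwidth undefined")
    # Scott's rule with the per-condition sample size (balanced designs use
    # the average of the two condition sizes)
    h = sd * (0.5 * (n1 + n2)) ** (-1.0 / 5.0)
    z = (points[None, :] - x[:, None]) / h
    kernel = np.exp(-0.5 * z * z) / (h * np.sqrt(2.0 * np.pi))  # (n, grid)
    contrast = np.where(labels, 1.0 / n1, -1.0 / n2)  # (S+1, n)
    diff = contrast @ kernel
    return np.abs(diff).sum(axis=1)


def _level_dds_per_condition(
    x: np.ndarray, labels: np.ndarray, points: np.ndarray
) -> np.ndarray:
    out = np.empty(labels.shape[0])
    for s, lab in enumerate(labels):
        x1, x2 = x[lab], x[~lab]
        p1 = _kde_eval(x1, points, _scott_bandwidth(x1))
        p2 = _kde_eval(x2, points, _scott_bandwidth(x2))
        out[s] = np.abs(p1 - p2).sum()
    return out


# ---------------------------------------------------------------------------
# classification accuracy invariance / generalization


def _validate_partition(regions: Sequence[Sequence[tuple[float, float]]]) -> None:
    intervals = []
    for region in regions:
        for lo, hi in region:
            if not lo < hi:
                raise ValueError(f"empty or inverted interval ({lo}, {hi})")
            intervals.append((float(lo), float(hi)))
    intervals.sort()
    if intervals[0][0] != -np.inf or intervals[-1][1] != np.inf:
        raise ValueError("regions must cover the whole real line")
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        if hi1 < lo2:
            raise ValueError(f"gap between {hi1} and {lo2}: regions must cover R")
        if hi1 > lo2:
            raise ValueError(f"regions overlap between {lo2} and {hi1}")


def accuracy_table(
    decoding_dists: Mapping[tuple[int, int], DecodingDistribution],
    regions: Sequence[Sequence[tuple[float, float]]],
) -> AccuracyTable:
    """Correct-classification probabilities from closed-form decoding distributions.

    ``regions[i-1]`` is the list of half-open intervals of the real line
    that the classifier labels as target level ``i``; together the regions
    must partition the line.  Entry ``(i, j)`` is the Gaussian probability
    mass of condition ``(i, j)``'s decoding distribution inside region i.
    """
    _validate_partition(regions)
    levels_a = sorted({i for i, _ in decoding_dists})
    levels_b = sorted({j for _, j in decoding_dists})
    if len(regions) != len(levels_a):
        raise ValueError("need one region per target level")
    values = np.empty((len(levels_a), len(levels_b)))
    for a_idx, i in enumerate(levels_a):
        for b_idx, j in enumerate(levels_b):
            dist = decoding_dists[(i, j)]
            mass = 0.0
            for lo, hi in regions[a_idx]:
                if dist.variance > 0:
                    mass += norm.cdf(hi, dist.mean, dist.sd) - norm.cdf(
                        lo, dist.mean, dist.sd
                    )
                else:
                    mass += float(lo <= dist.mean < hi)
            values[a_idx, b_idx] = min(max(mass, 0.0), 1.0)
    return AccuracyTable(values=values, chance=1.0 / len(levels_a))


def accuracy_invariance_and_generalization(
    table: AccuracyTable, tol: float = 1e-9
) -> dict[str, bool]:
    """Verdicts for the two classification-accuracy properties.

    *Invariance*: for every target level, accuracy is identical (within
    ``tol``) across irrelevant-dimension levels.  *Generalization*: whenever
    accuracy exceeds chance at the first irrelevant level, it exceeds chance
    at every level.  Invariance implies generalization; the converse fails.
    """
    values = table.values
    invariance = bool(np.all(values.max(axis=1) - values.min(axis=1) <= tol))
    generalization = True
    for row in values:
        if row[0] > table.chance and not np.all(row > table.chance):
            generalization = False
            break
    return {"invariance": invariance, "generalization": generalization}


# ---------------------------------------------------------------------------
# orthogonality and pattern-difference tests


def orthogonality_index(w_a: np.ndarray, w_b: np.ndarray) -> OrthogonalityResult:
    """Angle-based orthogonality of two summary vectors.

    Reports the cosine of the angle, the angle in degrees, and the Pearson
    correlation of the two vectors (equal to the cosine only after mean
    centering).
    """
    w_a = np.ravel(np.asarray(w_a, dtype=float))
    w_b = np.ravel(np.asarray(w_b, dtype=float))
    if w_a.shape != w_b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(w_a), np.linalg.norm(w_b)
    if na == 0 or nb == 0:
        raise ValueError("orthogonality undefined for a zero vector")
    cosine = float(np.clip(w_a @ w_b / (na * nb), -1.0, 1.0))
    ca, cb = w_a - w_a.mean(), w_b - w_b.mean()
    denom = np.linalg.norm(ca) * np.linalg.norm(cb)
    pearson = float(np.clip(ca @ cb / denom, -1.0, 1.0)) if denom > 0 else np.nan
    return OrthogonalityResult(
        cosine=cosine,
        angle_deg=float(np.degrees(np.arccos(cosine))),
        pearson_of_vectors=pearson,
    )


def pattern_difference_test(
    patterns: Mapping[tuple[int, int], np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PatternDifferenceResult:
    """Permutation test of pattern-difference invariance (the A x B interaction).

    The interaction vector is the difference of mean-pattern differences,
    ``[a(A1B1) - a(A2B1)] - [a(A1B2) - a(A2B2)]``; its Euclidean norm is the
    statistic.  The null shuffles the irrelevant-dimension labels within each
    target level.
    """
    levels_a, levels_b = _design_levels(patterns)
    mats = {
        cond: np.atleast_2d(np.asarray(patterns[cond], dtype=float))
        for cond in patterns
    }
    widths = {m.shape[1] for m in mats.values()}
    if len(widths) != 1:
        raise ValueError("all conditions must have the same number of measures")

    def interaction(groups: Mapping[tuple[int, int], np.ndarray]) -> np.ndarray:
        means = {cond: groups[cond].mean(axis=0) for cond in groups}
        return (means[(levels_a[0], levels_b[0])] - means[(levels_a[1], levels_b[0])]) - (
            means[(levels_a[0], levels_b[1])] - means[(levels_a[1], levels_b[1])]
        )

    observed_vec = interaction(mats)
    observed = float(np.linalg.norm(observed_vec))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    count = 0
    for _ in range(n_perm):
        shuffled: dict[tuple[int, int], np.ndarray] = {}
        for i in levels_a:
            pool = np.vstack([mats[(i, levels_b[0])], mats[(i, levels_b[1])]])
            order = rng.permutation(pool.shape[0])
            n1 = mats[(i, levels_b[0])].shape[0]
            shuffled[(i, levels_b[0])] = pool[order[:n1]]
            shuffled[(i, levels_b[1])] = pool[order[n1:]]
        if np.linalg.norm(interaction(shuffled)) >= observed:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return PatternDifferenceResult(
        interaction_vector=observed_vec, statistic=observed, permutation_p=p, n_perm=n_perm
    )


def variance_explained(r: float) -> float:
    """Percentage of variance explained by a correlation of ``r`` (100 r^2)."""
    return 100.0 * float(r) ** 2
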
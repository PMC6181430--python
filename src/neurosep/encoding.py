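"""Multichannel encoding models for two-dimensional stimulus designs.

A stimulus varies along two discrete dimensions, A (the *target* dimension,
levels ``i = 1..L_A``) and B (the *irrelevant* dimension, levels
``j = 1..L_B``).  A bank of ``N`` tuned channels encodes the stimulus: on
each trial the channel response vector ``r`` is drawn from a multivariate
Gaussian with mean ``f(A_i B_j)`` (the tuning functions evaluated at the
stimulus) and covariance ``Sigma(A_i B_j)`` (channel noise).

*Encoding separability* of A from B holds when the whole response
distribution for each level of A is invariant across levels of B, which for
the Gaussian model decomposes into tuning separability
(``f(A_i B_j) = f(A_i)``) and noise invariance
(``Sigma(A_i B_j) = Sigma(A_i)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusGrid",
    "TuningMatrix",
    "EncodingModel",
    "TuningViolation",
    "SeparabilityReport",
    "make_gaussian_tuning_bank",
    "build_encoding_model",
    "apply_violation",
    "sample_responses",
    "check_encoding_separability",
    "model_to_json",
    "model_from_json",
]

#: absolute tolerance for analytic separability checks (models are exact
#: objects, not estimates)
SEPARABILITY_TOL = 1e-10


@dataclass(frozen=True)
class StimulusGrid:
    """A factorial L_A x L_B stimulus design.

    Conditions are addressed with 1-based pairs ``(i, j)``.  The flat
    condition ordering used for matrix columns is row-major over ``(i, j)``:
    ``(1,1), (1,2), ..., (1,L_B), (2,1), ...``.
    """

    levels_a: int
    levels_b: int
    labels_a: tuple[str, ...] | None = None
    labels_b: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.levels_a < 2 or self.levels_b < 2:
            raise ValueError("both dimensions need at least 2 levels")
        for labels, n, dim in (
            (self.labels_a, self.levels_a, "A"),
            (self.labels_b, self.levels_b, "B"),
        ):
            if labels is not None and len(labels) != n:
                raise ValueError(f"labels for dimension {dim} must have length {n}")

    @property
    def n_conditions(self) -> int:
        return self.levels_a * self.levels_b

    def conditions(self) -> list[tuple[int, int]]:
        """All conditions in the declared (row-major) column order."""
        return [
            (i, j)
            for i in range(1, self.levels_a + 1)
            for j in range(1, self.levels_b + 1)
        ]

    def column(self, condition: tuple[int, int]) -> int:
        """Flat 0-based column index of condition ``(i, j)``."""
        i, j = condition
        if not (1 <= i <= self.levels_a and 1 <= j <= self.levels_b):
            raise ValueError(
                f"condition {condition!r} outside {self.levels_a}x{self.levels_b} grid"
            )
        return (i - 1) * self.levels_b + (j - 1)


@dataclass(frozen=True)
class TuningMatrix:
    """Mean channel responses, one column per condition (row-major order)."""

    values: np.ndarray  # (N, L_A * L_B)
    grid: StimulusGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != self.grid.n_conditions:
            raise ValueError(
                f"tuning matrix must be N x {self.grid.n_conditions}, got {values.shape}"
            )
        if values.shape[0] == 0:
            raise ValueError("need at least one channel")
        if not np.all(np.isfinite(values)):
            raise ValueError("tuning matrix has non-finite entries")
        object.__setattr__(self, "values", values)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def mean_response(self, condition: tuple[int, int]) -> np.ndarray:
        return self.values[:, self.grid.column(condition)]


@dataclass(frozen=True)
class EncodingModel:
    """Gaussian multichannel encoding model: r | (i,j) ~ N(f(ij), Sigma(ij))."""

    grid: StimulusGrid
    tuning: TuningMatrix
    noise_cov: np.ndarray  # (n_conditions, N, N)

    def __post_init__(self) -> None:
        cov = np.asarray(self.noise_cov, dtype=float)
        n = self.tuning.n_channels
        expected = (self.grid.n_conditions, n, n)
        if cov.shape != expected:
            raise ValueError(f"noise_cov must have shape {expected}, got {cov.shape}")
        for k, sigma in enumerate(cov):
            _check_psd(sigma, f"condition {self.grid.conditions()[k]}")
        object.__setattr__(self, "noise_cov", cov)

    @property
    def n_channels(self) -> int:
        return self.tuning.n_channels

    def mean(self, condition: tuple[int, int]) -> np.ndarray:
        return self.tuning.mean_response(condition)

    def cov(self, condition: tuple[int, int]) -> np.ndarray:
        return self.noise_cov[self.grid.column(condition)]


@dataclass(frozen=True)
class TuningViolation:
    """A localized breach of encoding separability.

    ``kind="tuning"`` adds the deviation vector ``delta`` to the mean
    response of one condition; ``kind="noise"`` multiplies that condition's
    channel-noise covariance by ``noise_scale``.
    """

    delta: np.ndarray
    target_condition: tuple[int, int]
    kind: str = "tuning"
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if not np.all(np.isfinite(delta)):
            raise ValueError("delta must be finite")
        if self.kind not in ("tuning", "noise"):
            raise ValueError(f"unknown violation kind {self.kind!r}")
        if self.kind == "noise" and self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        object.__setattr__(self, "delta", delta)


@dataclass(frozen=True)
class SeparabilityReport:
    tuning_separable: bool
    noise_separable: bool
    max_tuning_gap: float
    max_cov_gap: float
    target_dim: str

    @property
    def separable(self) -> bool:
        return self.tuning_separable and self.noise_separable


def _check_psd(sigma: np.ndarray, what: str) -> None:
    if not np.allclose(sigma, sigma.T, atol=1e-12):
        raise ValueError(f"covariance for {what} is not symmetric")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min(initial=0.0) < -1e-10 * max(1.0, abs(eigvals).max(initial=1.0)):
        raise ValueError(f"covariance for {what} is not positive semidefinite")


def make_gaussian_tuning_bank(
    grid: StimulusGrid,
    centers: Sequence[float],
    widths: Sequence[float] | float,
    gains: Sequence[float] | float,
    dim_values: Sequence[float],
    dim: str = "A",
) -> TuningMatrix:
    """Bank of Gaussian (bell-shaped) tuning curves over one stimulus dimension.

    Channel ``c`` responds to condition ``(i, j)`` with
    ``gain_c * exp(-(v - center_c)^2 / (2 width_c^2))`` where ``v`` is the
    real-valued stimulus coordinate of the level on dimension ``dim``
    (``dim_values[i-1]`` for ``dim="A"``).  Because the response depends only
    on that coordinate, the bank is tuning-separable from the other dimension
    by construction.  Sigmoidal or otherwise shaped banks can be supplied
    directly as a :class:`TuningMatrix`.
    """
    centers = np.asarray(centers, dtype=float)
    n = centers.size
    if n == 0:
        raise ValueError("need at least one channel")
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (n,)).copy()
    gains = np.broadcast_to(np.asarray(gains, dtype=float), (n,)).copy()
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    if np.any(gains <= 0):
        raise ValueError("gains must be positive")
    if dim not in ("A", "B"):
        raise ValueError("dim must be 'A' or 'B'")
    n_levels = grid.levels_a if dim == "A" else grid.levels_b
    dim_values = np.asarray(dim_values, dtype=float)
    if dim_values.shape != (n_levels,):
        raise ValueError(
            f"dim_values must map the {n_levels} levels of {dim} to stimulus values"
        )
    values = np.empty((n, grid.n_conditions))
    for k, (i, j) in enumerate(grid.conditions()):
        v = dim_values[i - 1] if dim == "A" else dim_values[j - 1]
        values[:, k] = gains * np.exp(-((v - centers) ** 2) / (2.0 * widths**2))
    return TuningMatrix(values=values, grid=grid)


def build_encoding_model(
    grid: StimulusGrid,
    tuning: TuningMatrix,
    noise_cov: np.ndarray | Mapping[tuple[int, int], np.ndarray] | float,
) -> EncodingModel:
    """Assemble an encoding model from a tuning bank and channel noise.

    ``noise_cov`` may be a scalar variance (expands to ``sigma^2 * I`` for
    every condition, i.e. independent homogeneous channel noise), a single
    N x N covariance shared by all conditions, a mapping from condition to
    covariance, or a full ``(n_conditions, N, N)`` stack.
    """
    n = tuning.n_channels
    n_cond = grid.n_conditions
    if np.isscalar(noise_cov):
        var = float(noise_cov)  # type: ignore[arg-type]
        if var < 0:
            raise ValueError("scalar noise variance must be non-negative")
        cov = np.broadcast_to(var * np.eye(n), (n_cond, n, n)).copy()
    elif isinstance(noise_cov, Mapping):
        cov = np.empty((n_cond, n, n))
        for k, cond in enumerate(grid.conditions()):
            if cond not in noise_cov:
                raise ValueError(f"missing covariance for condition {cond}")
            cov[k] = np.asarray(noise_cov[cond], dtype=float)
    else:
        arr = np.asarray(noise_cov, dtype=float)
        if arr.shape == (n, n):
            cov = np.broadcast_to(arr, (n_cond, n, n)).copy()
        elif arr.shape == (n_cond, n, n):
            cov = arr.copy()
        else:
            raise ValueError(
                f"noise_cov shape {arr.shape} incompatible with N={n}, "
                f"{n_cond} conditions"
            )
    return EncodingModel(grid=grid, tuning=tuning, noise_cov=cov)


def apply_violation(model: EncodingModel, violation: TuningViolation) -> EncodingModel:
    """Return a copy of ``model`` with the violation applied to its target condition."""
    col = model.grid.column(violation.target_condition)
    if violation.kind == "tuning":
        if violation.delta.shape != (model.n_channels,):
            raise ValueError(
                f"delta must have length {model.n_channels}, got {violation.delta.shape}"
            )
        values = model.tuning.values.copy()
        values[:, col] = values[:, col] + violation.delta
        tuning = TuningMatrix(values=values, grid=model.grid)
        return replace(model, tuning=tuning)
    cov = model.noise_cov.copy()
    cov[col] = cov[col] * violation.noise_scale
    return replace(model, noise_cov=cov)


def sample_responses(
    model: EncodingModel,
    condition: tuple[int, int],
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. channel-response vectors for one condition.

    Returns an ``(n, N)`` array.  The same seed (and parameters) always
    yields a bit-identical sample.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean = model.mean(condition)
    cov = model.cov(condition)
    return rng.multivariate_normal(mean, cov, size=n, method="svd")


def check_encoding_separability(
    model: EncodingModel,
    target_dim: str = "A",
    tol: float = SEPARABILITY_TOL,
) -> SeparabilityReport:
    """Analytic check of encoding separability of the target dimension.

    Tuning separability requires every mean-response vector for a given
    target level to be identical across irrelevant-dimension levels; noise
    separability requires the same of the covariances.  The reported gaps
    are max-norm discrepancies over all level pairs.
    """
    if target_dim not in ("A", "B"):
        raise ValueError("target_dim must be 'A' or 'B'")
    grid = model.grid
    if target_dim == "A":
        groups = [
            [(i, j) for j in range(1, grid.levels_b + 1)]
            for i in range(1, grid.levels_a + 1)
        ]
    else:
        groups = [
            [(i, j) for i in range(1, grid.levels_a + 1)]
            for j in range(1, grid.levels_b + 1)
        ]
    max_tuning_gap = 0.0
    max_cov_gap = 0.0
    for conds in groups:
        f_ref = model.mean(conds[0])
        cov_ref = model.cov(conds[0])
        for cond in conds[1:]:
            max_tuning_gap = max(
                max_tuning_gap, float(np.abs(model.mean(cond) - f_ref).max())
            )
            max_cov_gap = max(
                max_cov_gap, float(np.abs(model.cov(cond) - cov_ref).max())
            )
    return SeparabilityReport(
        tuning_separable=max_tuning_gap <= tol,
        noise_separable=max_cov_gap <= tol,
        max_tuning_gap=max_tuning_gap,
        max_cov_gap=max_cov_gap,
        target_dim=target_dim,
    )


def model_to_json(model: EncodingModel) -> str:
    """Serialize an encoding model to a JSON document."""
    payload = {
        "grid": {
            "levels_a": model.grid.levels_a,
            "levels_b": model.grid.levels_b,
            "labels_a": list(model.grid.labels_a) if model.grid.labels_a else None,
            "labels_b": list(model.grid.labels_b) if model.grid.labels_b else None,
        },
        "tuning": model.tuning.values.tolist(),
        "noise_cov": model.noise_cov.tolist(),
    }
    return json.dumps(payload)


def model_from_json(document: str) -> EncodingModel:
    payload = json.loads(document)
    g = payload["grid"]
    grid = StimulusGrid(
        levels_a=g["levels_a"],
        levels_b=g["levels_b"],
        labels_a=tuple(g["labels_a"]) if g.get("labels_a") else None,
        labels_b=tuple(g["labels_b"]) if g.get("labels_b") else None,
    )
    tuning = TuningMatrix(values=np.asarray(payload["tuning"], dtype=float), grid=grid)
    return EncodingModel(
        grid=grid, tuning=tuning, noise_cov=np.asarray(payload["noise_cov"], dtype=float)
    )
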
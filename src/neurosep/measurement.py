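"""Measurement models: from channel responses to indirect activity measures.

Neuroimaging never observes channel responses ``r`` directly; it observes
``M`` activity measures (voxels, electrodes) ``a = B r + e`` with a linear
mixing matrix ``B`` and additive zero-mean Gaussian measurement error
``e ~ N(0, Sigma_e)``.  Decoding linearly from ``a`` yields a decoded value
whose distribution is the channel-level decoding distribution convolved with
the Gaussian error kernel ``N(0, b' Sigma_e b)``.  The same convolution
applies to the *difference* between two decoding distributions, so a
difference function observed through noisy measurements is the clean
difference smoothed by that kernel -- nonzero structure survives (attenuated)
and a zero difference stays zero, which is what makes decoding-separability
tests valid on indirect data.

The measurement error is assumed stimulus-independent.  A nonlinear
measurement map can be supplied as a user hook, but the convolution
guarantee only covers the linear case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from .decoding import LinearDecoder

__all__ = [
    "MeasurementModel",
    "DifferenceFunction",
    "measure",
    "predicted_noisy_difference",
    "measurement_to_json",
    "measurement_from_json",
    "write_patterns_csv",
    "read_patterns_csv",
]


@dataclass(frozen=True)
class MeasurementModel:
    """Linear measurement map ``a = B r + e`` with ``e ~ N(0, Sigma_e)``."""

    mixing: np.ndarray  # (M, N)
    error_cov: np.ndarray  # (M, M)
    nonlinearity: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        mixing = np.asarray(self.mixing, dtype=float)
        if mixing.ndim != 2:
            raise ValueError("mixing must be an M x N matrix")
        if not np.all(np.isfinite(mixing)):
            raise ValueError("mixing matrix has non-finite entries")
        m = mixing.shape[0]
        cov = np.asarray(self.error_cov, dtype=float)
        if np.isscalar(self.error_cov) or cov.ndim == 0:
            cov = float(cov) * np.eye(m)
        if cov.shape != (m, m):
            raise ValueError(f"error_cov must be {m} x {m}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("error covariance is not symmetric")
        if np.linalg.eigvalsh(cov).min(initial=0.0) < -1e-10:
            raise ValueError("error covariance is not positive semidefinite")
        object.__setattr__(self, "mixing", mixing)
        object.__setattr__(self, "error_cov", cov)

    @property
    def n_measures(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[1]


@dataclass(frozen=True)
class DifferenceFunction:
    """A difference between two densities evaluated on a uniform grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.shape != values.shape or grid.ndim != 1:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(values)):
            raise ValueError("difference function has non-finite values")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def spacing(self) -> float:
        diffs = np.diff(self.grid)
        if diffs.size == 0:
            raise ValueError("grid needs at least two points")
        if not np.allclose(diffs, diffs[0], rtol=1e-8, atol=1e-12 * abs(diffs[0])):
            raise ValueError("grid spacing is not uniform")
        return float(diffs[0])


def measure(
    mm: MeasurementModel,
    responses: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Map ``(n, N)`` channel responses to ``(n, M)`` noisy activity patterns."""
    responses = np.asarray(responses, dtype=float)
    single = responses.ndim == 1
    if single:
        responses = responses[None, :]
    if responses.shape[1] != mm.n_channels:
        raise ValueError(
            f"responses have {responses.shape[1]} channels, model expects {mm.n_channels}"
        )
    if mm.nonlinearity is not None:
        clean = np.apply_along_axis(mm.nonlinearity, 1, responses)
    else:
        clean = responses @ mm.mixing.T
    if np.any(mm.error_cov):
        rng = (
            np.random.default_rng(seed)
            if not isinstance(seed, np.random.Generator)
            else seed
        )
        noise = rng.multivariate_normal(
            np.zeros(mm.n_measures), mm.error_cov, size=clean.shape[0], method="svd"
        )
        clean = clean + noise
    return clean[0] if single else clean


def predicted_noisy_difference(
    clean: DifferenceFunction,
    decoder: LinearDecoder,
    mm: MeasurementModel,
) -> DifferenceFunction:
    """Difference function expected after measurement error.

    Convolves the clean channel-level difference with the Gaussian error
    kernel of variance ``b' Sigma_e b``, on the same grid.  Direct discrete
    convolution with zero padding, kernel truncated at +/- 6 SD.
    """
    if decoder.trained_on != "measurements":
        raise ValueError("the error kernel is defined for a measurement-space decoder")
    if decoder.n_features != mm.n_measures:
        raise ValueError("decoder/measurement dimension mismatch")
    spacing = clean.spacing  # validates uniformity
    var = float(decoder.weights @ mm.error_cov @ decoder.weights)
    if var <= 0:
        return DifferenceFunction(grid=clean.grid.copy(), values=clean.values.copy())
    sd = np.sqrt(var)
    half = int(np.ceil(6.0 * sd / spacing))
    offsets = np.arange(-half, half + 1) * spacing
    kernel = norm.pdf(offsets, scale=sd) * spacing
    # full convolution, then the centered slice (robust when the kernel is
    # longer than the grid)
    full = np.convolve(clean.values, kernel, mode="full")
    out = full[half : half + clean.values.size]
    return DifferenceFunction(grid=clean.grid.copy(), values=out)


def write_patterns_csv(patterns, path) -> None:
    """Write per-condition activity patterns as a flat trial table.

    Columns: trial, level_A, level_B, voxel_1..voxel_M.
    """
    import pandas as pd

    rows = []
    for (i, j), mat in sorted(patterns.items()):
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        for t, row in enumerate(mat, start=1):
            record = {"trial": t, "level_A": i, "level_B": j}
            record.update({f"voxel_{m + 1}": v for m, v in enumerate(row)})
            rows.append(record)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_patterns_csv(path):
    """Read a flat trial table back into a condition -> (n, M) mapping."""
    import pandas as pd

    frame = pd.read_csv(path)
    voxel_cols = [c for c in frame.columns if c.startswith("voxel_")]
    if not voxel_cols:
        raise ValueError("pattern CSV needs voxel_1..voxel_M columns")
    out = {}
    for (i, j), group in frame.groupby(["level_A", "level_B"]):
        out[(int(i), int(j))] = group[voxel_cols].to_numpy(dtype=float)
    return out


def measurement_to_json(mm: MeasurementModel) -> str:
    if mm.nonlinearity is not None:
        raise ValueError("cannot serialize a model with a nonlinearity hook")
    return json.dumps(
        {"mixing": mm.mixing.tolist(), "error_cov": mm.error_cov.tolist()}
    )


def measurement_from_json(document: str) -> MeasurementModel:
    payload = json.loads(document)
    return MeasurementModel(
        mixing=np.asarray(payload["mixing"], dtype=float),
        error_cov=np.asarray(payload["error_cov"], dtype=float),
    )
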
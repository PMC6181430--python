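"""Synthetic worlds for every named separability regime.

Each world bundles a 2x2 encoding model, a linear decoder and a measurement
model, tagged by regime:

- ``separable``: Gaussian tuning bank depending only on the target
  dimension, homogeneous channel noise -- encoding (hence decoding)
  separability holds.
- ``hidden_violation``: a tuning deviation ``delta`` on condition (1,1)
  breaks encoding separability, but the decoder is built orthogonal to
  ``delta`` so the closed-form decoding distributions stay identical across
  the irrelevant dimension.
- ``exposed_violation``: the same deviation paired with a unit decoder
  aligned with it, so the decoding means at target level 1 differ by exactly
  ``effect_size`` (in units of the decoding SD when ``noise_sd = 1``).
- ``noise_violation``: channel-noise covariance of condition (1,1) scaled
  by ``1 + effect_size``.
- ``orthogonal_weights`` / ``oblique_weights``: additive signal directions
  for the two dimensions at 90 or 45 degrees, for weight-orthogonality
  fixtures.

Defaults mirror the study design the tests emulate: a 2x2 factorial (two
levels per dimension), four Gaussian channels, unit channel noise.  All
randomness flows from the explicit seed; identical (regime, parameters,
seed) yield bit-identical worlds and datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoding import LinearDecoder, construct_counterexample_decoder, decode
from .encoding import (
    EncodingModel,
    StimulusGrid,
    TuningMatrix,
    TuningViolation,
    apply_violation,
    build_encoding_model,
    make_gaussian_tuning_bank,
    sample_responses,
)
from .measurement import MeasurementModel, measure
from .searchlight import VolumeDataset, sphere_offsets

__all__ = ["World", "TrialData", "REGIMES", "make_world", "generate_trials",
           "generate_volume_dataset", "replicate_study"]

REGIMES = (
    "separable",
    "hidden_violation",
    "exposed_violation",
    "noise_violation",
    "orthogonal_weights",
    "oblique_weights",
)


@dataclass(frozen=True)
class World:
    encoding: EncodingModel
    decoder: LinearDecoder
    measurement: MeasurementModel
    grid: StimulusGrid
    regime: str
    seed: int | None
    meta: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class TrialData:
    """Per-condition samples at every representational stage."""

    responses: dict  # condition -> (n, N) channel responses
    patterns: dict  # condition -> (n, M) measured activity
    decoded: dict  # condition -> (n,) decoded values


def _baseline_bank(grid: StimulusGrid, n_channels: int) -> TuningMatrix:
    # channels tile the span of the two target-level coordinates (1 and 2)
    centers = np.linspace(0.5, 2.5, n_channels)
    return make_gaussian_tuning_bank(
        grid,
        centers=centers,
        widths=1.0,
        gains=1.0,
        dim_values=np.arange(1, grid.levels_a + 1, dtype=float),
        dim="A",
    )


def _discriminant_decoder(model: EncodingModel) -> LinearDecoder:
    """Unit-norm decoder along the mean-response difference between A levels."""
    f1 = model.mean((1, 1))
    f2 = model.mean((2, 1))
    b = f2 - f1
    norm = np.linalg.norm(b)
    if norm == 0:
        raise ValueError("target levels have identical mean responses")
    b = b / norm
    beta = -float(b @ (f1 + f2)) / 2.0
    return LinearDecoder(beta=beta, weights=b, trained_on="channels",
                         meta={"construction": "discriminant"})


def make_world(
    regime: str,
    n_channels: int = 4,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
    levels: tuple[int, int] = (2, 2),
    measurement_error_sd: float = 0.0,
    oblique_angle_deg: float = 45.0,
) -> World:
    """Build a synthetic world for one regime (see module docstring)."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    grid = StimulusGrid(levels_a=levels[0], levels_b=levels[1])
    rng = np.random.default_rng(seed)
    meta: dict = {}

    if regime in ("orthogonal_weights", "oblique_weights"):
        angle = 90.0 if regime == "orthogonal_weights" else oblique_angle_deg
        model, decoder, meta = _weights_world(
            grid, n_channels, effect_size, noise_sd, rng, angle
        )
    else:
        bank = _baseline_bank(grid, n_channels)
        model = build_encoding_model(grid, bank, noise_sd**2)
        if regime == "separable":
            decoder = _discriminant_decoder(model)
        elif regime == "noise_violation":
            violation = TuningViolation(
                delta=np.zeros(n_channels),
                target_condition=(1, 1),
                kind="noise",
                noise_scale=1.0 + effect_size,
            )
            model = apply_violation(model, violation)
            decoder = _discriminant_decoder(model)
            meta["noise_scale"] = 1.0 + effect_size
        else:  # tuning violation regimes
            direction = rng.standard_normal(n_channels)
            direction /= np.linalg.norm(direction)
            delta = effect_size * direction
            model = apply_violation(
                model,
                TuningViolation(delta=delta, target_condition=(1, 1), kind="tuning"),
            )
            meta["delta"] = delta
            if regime == "hidden_violation":
                raw = construct_counterexample_decoder(delta, 0.0, rng)
                b = raw.weights / np.linalg.norm(raw.weights)
            else:  # exposed_violation: unit decoder with b' delta = effect_size
                raw = construct_counterexample_decoder(
                    delta, effect_size, rng, null_scale=0.0
                )
                b = raw.weights  # = delta / ||delta||, already unit norm
            beta = -float(b @ model.tuning.values.mean(axis=1))
            decoder = LinearDecoder(beta=beta, weights=b, trained_on="channels",
                                    meta=raw.meta)

    n = model.n_channels
    if measurement_error_sd > 0:
        mm = MeasurementModel(mixing=np.eye(n), error_cov=measurement_error_sd**2 * np.eye(n))
    else:
        mm = MeasurementModel(mixing=np.eye(n), error_cov=np.zeros((n, n)))
    return World(
        encoding=model,
        decoder=decoder,
        measurement=mm,
        grid=grid,
        regime=regime,
        seed=seed,
        meta=meta,
    )


def _weights_world(
    grid: StimulusGrid,
    n_channels: int,
    effect_size: float,
    noise_sd: float,
    rng: np.random.Generator,
    angle_deg: float,
) -> tuple[EncodingModel, LinearDecoder, dict]:
    if n_channels < 2:
        raise ValueError("weight-angle regimes need at least 2 channels")
    u_a = rng.standard_normal(n_channels)
    u_a /= np.linalg.norm(u_a)
    z = rng.standard_normal(n_channels)
    v = z - (z @ u_a) * u_a
    v /= np.linalg.norm(v)
    theta = np.radians(angle_deg)
    u_b = np.cos(theta) * u_a + np.sin(theta) * v
    half = effect_size / 2.0
    values = np.empty((n_channels, grid.n_conditions))
    for k, (i, j) in enumerate(grid.conditions()):
        s_a = -half if i == 1 else half
        s_b = -half if j == 1 else half
        values[:, k] = 1.0 + s_a * u_a + s_b * u_b
    tuning = TuningMatrix(values=values, grid=grid)
    model = build_encoding_model(grid, tuning, noise_sd**2)
    decoder = _discriminant_decoder(model)
    return model, decoder, {"u_a": u_a, "u_b": u_b, "angle_deg": angle_deg}


def generate_trials(
    world: World, n_per_condition: int, seed: int | None = None
) -> TrialData:
    """Sample trials through the whole chain: responses -> patterns -> decoded."""
    if n_per_condition < 2:
        raise ValueError("need at least 2 trials per condition")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * world.grid.n_conditions)
    responses: dict = {}
    patterns: dict = {}
    decoded: dict = {}
    for k, cond in enumerate(world.grid.conditions()):
        r_rng = np.random.default_rng(children[2 * k])
        m_rng = np.random.default_rng(children[2 * k + 1])
        r = sample_responses(world.encoding, cond, n_per_condition, r_rng)
        responses[cond] = r
        patterns[cond] = measure(world.measurement, r, m_rng)
        decoded[cond] = decode(world.decoder, r)
    return TrialData(responses=responses, patterns=patterns, decoded=decoded)


def replicate_study(
    regime: str,
    n_per_condition: int,
    n_replicates: int,
    seed: int | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    n_channels: int = 4,
    n_shuffles: int = 200,
    bandwidth: str = "pooled",
) -> np.ndarray:
    """Proportion-scale standardized DDS over seeded world replicates.

    Each replicate builds a fresh world, draws ``n_per_condition`` trials per
    condition, decodes, and runs the permutation-standardized DDS test;
    returns the array of standardized proportions (null value 0.5).  The
    backbone of type-I-error and power studies.
    """
    from .septests import standardize_dds

    proportions = np.empty(n_replicates)
    for k, child in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rng = np.random.default_rng(child)
        world_seed = int(rng.integers(2**31 - 1))
        world = make_world(
            regime,
            n_channels=n_channels,
            effect_size=effect_size,
            noise_sd=noise_sd,
            seed=world_seed,
        )
        trials = generate_trials(world, n_per_condition, seed=world_seed + 1)
        result = standardize_dds(
            trials.decoded,
            n_shuffles=n_shuffles,
            seed=world_seed + 2,
            bandwidth=bandwidth,
        )
        proportions[k] = result.standardized_proportion
    return proportions


def generate_volume_dataset(
    world: World,
    shape: tuple[int, int, int] = (20, 20, 20),
    signal_center: tuple[int, int, int] | None = None,
    signal_radius: float = 4,
    n_per_condition: int = 40,
    snr: float = 1.0,
    seed: int | None = None,
) -> tuple[VolumeDataset, np.ndarray]:
    """Volumetric fixture with the world's signal planted in a sphere.

    Voxels inside the signal sphere carry measured patterns mixed from the
    world's channel responses by a seeded random mixing matrix, scaled so
    its Frobenius norm is ``snr * error_sd * sqrt(n_signal_voxels)``
    (``snr = 0`` gives pure noise); all voxels carry i.i.d. unit-variance
    Gaussian measurement noise.  Returns the dataset and a boolean mask of
    the signal voxels.
    """
    shape = tuple(int(s) for s in shape)
    if signal_center is None:
        signal_center = tuple(s // 2 for s in shape)
    offsets = sphere_offsets(signal_radius)
    coords = offsets + np.asarray(signal_center)
    if np.any(coords < 0) or np.any(coords >= np.asarray(shape)):
        raise ValueError("signal sphere extends outside the volume")
    children = np.random.SeedSequence(seed).spawn(3)
    mix_rng = np.random.default_rng(children[0])
    noise_rng = np.random.default_rng(children[1])
    trial_ss = children[2]
    m = coords.shape[0]
    n = world.encoding.n_channels
    error_sd = 1.0
    mixing = mix_rng.standard_normal((m, n))
    fro = np.linalg.norm(mixing)
    if fro > 0:
        mixing *= snr * error_sd * np.sqrt(m) / fro

    conditions = world.grid.conditions()
    n_trials = n_per_condition * len(conditions)
    data = noise_rng.normal(0.0, error_sd, size=shape + (n_trials,))
    rows = []
    x, y, z = coords.T
    trial_rngs = [np.random.default_rng(c) for c in trial_ss.spawn(len(conditions))]
    t = 0
    for cond, c_rng in zip(conditions, trial_rngs):
        r = sample_responses(world.encoding, cond, n_per_condition, c_rng)
        signal = r @ mixing.T  # (n_per_condition, m)
        for row in signal:
            data[x, y, z, t] += row
            rows.append({"trial": t + 1, "level_A": cond[0], "level_B": cond[1]})
            t += 1
    table = pd.DataFrame(rows)
    signal_mask = np.zeros(shape, dtype=bool)
    signal_mask[x, y, z] = True
    ds = VolumeDataset(
        data=data, mask=np.ones(shape, dtype=bool), trial_table=table
    )
    return ds, signal_mask
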
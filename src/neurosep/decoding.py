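"""Linear decoding of channel or voxel activity.

A linear decoder maps an activity vector to a scalar estimate of the
stimulus value on the target dimension, ``A_hat = beta + b' x``.  With a
Gaussian encoding model the decoded value is itself Gaussian with mean
``beta + b' f(ij)`` and variance ``b' Sigma(ij) b``, which gives the
closed-form decoding distributions used throughout.

*Decoding separability* holds when the decoding distribution for each
target level is invariant across irrelevant-dimension levels.  Encoding
separability implies decoding separability for any fixed decoder, but the
converse fails: for any tuning deviation ``delta != 0`` there are decoders
with ``b' delta = 0`` that hide the violation, and decoders with
``b' delta = d != 0`` that expose it as a mean shift of exactly ``d``.
:func:`construct_counterexample_decoder` builds either kind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .encoding import EncodingModel

__all__ = [
    "LinearDecoder",
    "DecodingDistribution",
    "decode",
    "closed_form_decoding_distribution",
    "fit_linear_classifier",
    "construct_counterexample_decoder",
    "decoder_to_json",
    "decoder_from_json",
    "write_decoded_csv",
    "read_decoded_csv",
]


@dataclass(frozen=True)
class LinearDecoder:
    """Affine map from activity to a scalar decoded value."""

    beta: float
    weights: np.ndarray
    trained_on: str = "channels"  # or "measurements"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if not np.all(np.isfinite(w)):
            raise ValueError("decoder weights must be finite")
        if self.trained_on not in ("channels", "measurements"):
            raise ValueError("trained_on must be 'channels' or 'measurements'")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "beta", float(self.beta))

    @property
    def n_features(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class DecodingDistribution:
    """Gaussian law of the decoded value for one condition."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def decode(decoder: LinearDecoder, activity: np.ndarray) -> np.ndarray:
    """Apply the decoder to an ``(n, K)`` activity matrix (or a single vector)."""
    activity = np.asarray(activity, dtype=float)
    single = activity.ndim == 1
    if single:
        activity = activity[None, :]
    if activity.shape[1] != decoder.n_features:
        raise ValueError(
            f"activity has {activity.shape[1]} features, decoder expects "
            f"{decoder.n_features}"
        )
    out = decoder.beta + activity @ decoder.weights
    return out[0] if single else out


def closed_form_decoding_distribution(
    model: EncodingModel,
    decoder: LinearDecoder,
    condition: tuple[int, int] | None = None,
) -> DecodingDistribution | dict[tuple[int, int], DecodingDistribution]:
    """Exact Gaussian decoding distribution(s) implied by model and decoder.

    With ``condition=None`` returns the full condition -> distribution map.
    """
    if decoder.trained_on != "channels":
        raise ValueError("closed form requires a decoder over channel responses")
    if decoder.n_features != model.n_channels:
        raise ValueError("decoder/model dimension mismatch")

    def one(cond: tuple[int, int]) -> DecodingDistribution:
        mean = decoder.beta + decoder.weights @ model.mean(cond)
        var = decoder.weights @ model.cov(cond) @ decoder.weights
        return DecodingDistribution(mean=float(mean), variance=float(max(var, 0.0)))

    if condition is not None:
        return one(condition)
    return {cond: one(cond) for cond in model.grid.conditions()}


def fit_linear_classifier(
    activity: np.ndarray,
    labels: np.ndarray,
    regularization: float = 1.0,
    trained_on: str = "channels",
) -> LinearDecoder:
    """Fit a soft-margin linear SVM and return it as a signed-distance decoder.

    The returned weights are the hyperplane normal scaled to unit norm and
    ``beta`` is the matching offset, so decoded values are signed Euclidean
    distances to the decision boundary (positive toward the class with the
    larger label).  The fit is deterministic given the data and settings.
    ``regularization`` is the SVM cost parameter C; the default 1.0 fits
    linearly separable training sets exactly.
    """
    activity = np.asarray(activity, dtype=float)
    labels = np.asarray(labels)
    if activity.ndim != 2:
        raise ValueError("activity must be an (n, K) matrix")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    if activity.shape[0] < 4:
        raise ValueError("need at least 4 training samples")
    svm = SVC(kernel="linear", C=regularization, shrinking=False, tol=1e-6)
    svm.fit(activity, labels)
    w = svm.coef_.ravel()
    norm = float(np.linalg.norm(w))
    if norm == 0:
        raise ValueError("degenerate SVM solution (zero normal vector)")
    decision = (activity @ w + svm.intercept_[0]) > 0
    accuracy = float(np.mean(np.where(decision, classes[1], classes[0]) == labels))
    decoder = LinearDecoder(
        beta=float(svm.intercept_[0]) / norm,
        weights=w / norm,
        trained_on=trained_on,
        meta={
            "classifier": "linear-svm",
            "C": regularization,
            "classes": classes.tolist(),
            "training_accuracy": accuracy,
        },
    )
    return decoder


def construct_counterexample_decoder(
    delta: np.ndarray,
    d: float,
    seed: int | np.random.Generator | None = None,
    null_scale: float = 1.0,
) -> LinearDecoder:
    """Build a non-zero weight vector with a prescribed response to a tuning deviation.

    Solves ``b' delta = d`` as the minimum-norm particular solution plus a
    seeded random component from the null space of ``delta`` (scaled by
    ``null_scale``).  ``d = 0`` yields a decoder blind to the violation
    (decoding separability holds despite the encoding failure); ``d != 0``
    yields one that exposes it as a mean shift of exactly ``d``.
    """
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    nrm2 = float(delta @ delta)
    if nrm2 == 0:
        raise ValueError("delta must be non-zero")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    particular = (d / nrm2) * delta
    b = particular.copy()
    if null_scale != 0.0 and delta.size > 1:
        z = rng.standard_normal(delta.size)
        z_null = z - (z @ delta / nrm2) * delta
        b = particular + null_scale * z_null
    # retry if the null component happened to cancel everything (d = 0 case)
    attempts = 0
    while np.linalg.norm(b) < 1e-12:
        if null_scale == 0.0 or delta.size == 1:
            raise ValueError("cannot build a non-zero decoder with d=0 in one dimension")
        z = rng.standard_normal(delta.size)
        b = particular + null_scale * (z - (z @ delta / nrm2) * delta)
        attempts += 1
        if attempts > 100:  # pragma: no cover
            raise RuntimeError("failed to draw a non-degenerate null component")
    assert abs(b @ delta - d) <= 1e-10 * max(1.0, abs(d), float(np.abs(b).max()))
    return LinearDecoder(beta=0.0, weights=b, trained_on="channels",
                         meta={"construction": "counterexample", "d": d})


def decoder_to_json(decoder: LinearDecoder) -> str:
    return json.dumps(
        {
            "beta": decoder.beta,
            "weights": decoder.weights.tolist(),
            "trained_on": decoder.trained_on,
            "meta": decoder.meta,
        }
    )


def decoder_from_json(document: str) -> LinearDecoder:
    payload = json.loads(document)
    return LinearDecoder(
        beta=payload["beta"],
        weights=np.asarray(payload["weights"], dtype=float),
        trained_on=payload.get("trained_on", "channels"),
        meta=payload.get("meta", {}),
    )


def write_decoded_csv(
    samples: Mapping[tuple[int, int], np.ndarray], path: str | Path
) -> None:
    """Write per-condition decoded values as (trial, level_A, level_B, decoded_value)."""
    rows = []
    for (i, j), values in sorted(samples.items()):
        for t, v in enumerate(np.asarray(values, dtype=float), start=1):
            rows.append({"trial": t, "level_A": i, "level_B": j, "decoded_value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decoded_csv(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    frame = pd.read_csv(path)
    required = {"level_A", "level_B", "decoded_value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"decoded-value CSV missing columns {sorted(missing)}")
    out: dict[tuple[int, int], np.ndarray] = {}
    for (i, j), group in frame.groupby(["level_A", "level_B"]):
        out[(int(i), int(j))] = group["decoded_value"].to_numpy(dtype=float)
    return out
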
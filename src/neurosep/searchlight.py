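"""Searchlight drivers and group-level permutation inference.

The decoding-separability test and the weight-orthogonality index are run
inside a moving spherical neighborhood (radius in voxels, Euclidean, center
included) over a 4-D volume of single-trial activity patterns.  Per center,
in-mask voxels inside the sphere are the features: a linear SVM decodes the
target dimension pooling all trials, decoded values are the signed distances
to the hyperplane, and the permutation-standardized DDS (or the correlation
between the two dimensions' classifier weights) becomes the map value at
that center.  Centers with fewer than two usable voxels or degenerate
condition data are left missing (NaN).

Group inference over per-subject maps uses a voxelwise one-sample
sign-flip permutation test with family-wise control through the
max-statistic distribution (the nonparametric logic of cluster-based
randomization tools, without cluster-mass correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .decoding import decode, fit_linear_classifier
from .septests import standardize_dds

__all__ = [
    "VolumeDataset",
    "SearchlightMap",
    "GroupTestResult",
    "sphere_offsets",
    "searchlight_dds",
    "searchlight_orthogonality",
    "differential_contrast",
    "group_sign_flip_test",
    "cluster_forming_threshold",
    "save_map_nifti",
    "load_volume_dataset",
]

DEFAULT_RADIUS = 3


@dataclass
class VolumeDataset:
    """4-D trial-wise activity volume with a mask and a trial table.

    ``data`` is (X, Y, Z, trials); ``mask`` is a binary 3-D array of the
    same spatial shape; ``trial_table`` has one row per trial with integer
    ``level_A`` and ``level_B`` columns (optional ``trial`` / ``run``).
    ``affine`` is carried through to NIfTI output untouched.
    """

    data: np.ndarray
    mask: np.ndarray
    trial_table: pd.DataFrame
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (X, Y, Z, trials)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask and data spatial shapes differ")
        for col in ("level_A", "level_B"):
            if col not in self.trial_table.columns:
                raise ValueError(f"trial table missing column {col!r}")
        if len(self.trial_table) != self.data.shape[3]:
            raise ValueError("trial count does not match table rows")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_trials(self) -> int:
        return self.data.shape[3]

    def standardized(self) -> "VolumeDataset":
        """Z-score every in-mask voxel's values across trials (by column)."""
        data = self.data.copy()
        vox = data[self.mask]  # (n_voxels, trials)
        mu = vox.mean(axis=1, keepdims=True)
        sd = vox.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        data[self.mask] = (vox - mu) / sd
        return VolumeDataset(
            data=data,
            mask=self.mask,
            trial_table=self.trial_table,
            affine=self.affine,
        )


@dataclass
class SearchlightMap:
    """Per-center map values on the voxel lattice (NaN outside mask/missing).

    ``aux`` may carry companion arrays on the same lattice; DDS maps store
    the continuous EDF z-score there (the percentile index saturates at
    +/-50 once the observed statistic clears the whole EDF, so peak
    localization needs an unbounded companion).
    """

    values: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)
    affine: np.ndarray | None = None
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.affine is None:
            self.affine = np.eye(4)

    def peak(self) -> tuple[int, int, int]:
        """Coordinate of the maximum map value.

        Ties (e.g. saturated percentile indices) are broken by the
        ``edf_z`` companion array when present.
        """
        values = self.values
        finite = np.isfinite(values)
        if not finite.any():
            raise ValueError("map has no finite values")
        best = np.nanmax(values)
        at_best = finite & (values == best)
        if at_best.sum() > 1 and "edf_z" in self.aux:
            z = np.where(at_best, self.aux["edf_z"], -np.inf)
            return tuple(np.unravel_index(np.nanargmax(z), values.shape))
        return tuple(np.unravel_index(np.nanargmax(values), values.shape))


@dataclass
class GroupTestResult:
    t_map: np.ndarray
    p_map: np.ndarray  # voxelwise, uncorrected
    p_fwe_map: np.ndarray  # max-statistic family-wise corrected
    mask: np.ndarray
    n_perm: int
    exhaustive: bool
    alternative: str


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer 3-D offsets with Euclidean norm <= radius (center included)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    axis = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def _sphere_features(
    ds: VolumeDataset, center: tuple[int, int, int], offsets: np.ndarray
) -> np.ndarray | None:
    """Trial x voxel matrix for in-mask, in-bounds voxels around a center."""
    coords = offsets + np.asarray(center)
    shape = np.asarray(ds.mask.shape)
    inside = np.all((coords >= 0) & (coords < shape), axis=1)
    coords = coords[inside]
    x, y, z = coords.T
    in_mask = ds.mask[x, y, z]
    coords = coords[in_mask]
    if coords.shape[0] < 2:
        return None
    x, y, z = coords.T
    return ds.data[x, y, z, :].T  # (trials, voxels)


def _iter_centers(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(mask)


def searchlight_dds(
    ds: VolumeDataset,
    target_dim: str = "A",
    radius: float = DEFAULT_RADIUS,
    n_shuffles: int = 200,
    seed: int | None = None,
    scale: str = "percentile_minus_50",
    bandwidth: str = "pooled",
    regularization: float = 1.0,
    standardize: bool = True,
) -> SearchlightMap:
    """Standardized-DDS searchlight map for the target dimension.

    Per center: columns (voxels) are z-scored over all trials (done once,
    volume-wide), the linear classifier for the target dimension is trained
    pooling all data, trials are projected onto the hyperplane normal, and
    the projected values enter the DDS permutation test.  Center-specific
    shuffle seeds are spawned deterministically from ``seed`` in scan order.
    """
    if target_dim not in ("A", "B"):
        raise ValueError("target_dim must be 'A' or 'B'")
    if scale not in ("percentile_minus_50", "proportion", "edf_z"):
        raise ValueError("scale must be 'percentile_minus_50', 'proportion' or 'edf_z'")
    work = ds.standardized() if standardize else ds
    offsets = sphere_offsets(radius)
    target = work.trial_table[f"level_{target_dim}"].to_numpy()
    irrelevant = work.trial_table[
        "level_B" if target_dim == "A" else "level_A"
    ].to_numpy()
    centers = _iter_centers(work.mask)
    children = np.random.SeedSequence(seed).spawn(len(centers))
    values = np.full(work.mask.shape, np.nan)
    z_values = np.full(work.mask.shape, np.nan)
    for center, child in zip(centers, children):
        features = _sphere_features(work, tuple(center), offsets)
        if features is None:
            continue
        value, z = _dds_at_center(
            features,
            target,
            irrelevant,
            n_shuffles,
            np.random.default_rng(child),
            bandwidth,
            regularization,
            scale,
        )
        values[tuple(center)] = value
        z_values[tuple(center)] = z
    return SearchlightMap(
        values=values,
        mask=work.mask,
        metadata={
            "analysis": "dds",
            "target_dim": target_dim,
            "radius": radius,
            "n_shuffles": n_shuffles,
            "seed": seed,
            "scale": scale,
            "bandwidth": bandwidth,
        },
        affine=work.affine,
        aux={"edf_z": z_values},
    )


def _dds_at_center(
    features: np.ndarray,
    target: np.ndarray,
    irrelevant: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
    bandwidth: str,
    regularization: float,
    scale: str,
) -> tuple[float, float]:
    try:
        decoder = fit_linear_classifier(features, target, regularization=regularization)
        decoded = decode(decoder, features)
        samples = {}
        for i in np.unique(target):
            for j in np.unique(irrelevant):
                sel = (target == i) & (irrelevant == j)
                samples[(int(i), int(j))] = decoded[sel]
        result = standardize_dds(
            samples, n_shuffles=n_shuffles, seed=rng, bandwidth=bandwidth
        )
    except ValueError:
        return np.nan, np.nan
    value = result.value(scale if scale != "percentile_minus_50" else "percentile")
    return value, result.standardized_z


def searchlight_orthogonality(
    ds: VolumeDataset,
    radius: float = DEFAULT_RADIUS,
    seed: int | None = None,
    regularization: float = 1.0,
    standardize: bool = True,
) -> SearchlightMap:
    """Correlation between the A- and B-classifier weight vectors per center."""
    work = ds.standardized() if standardize else ds
    offsets = sphere_offsets(radius)
    labels_a = work.trial_table["level_A"].to_numpy()
    labels_b = work.trial_table["level_B"].to_numpy()
    values = np.full(work.mask.shape, np.nan)
    for center in _iter_centers(work.mask):
        features = _sphere_features(work, tuple(center), offsets)
        if features is None:
            continue
        try:
            dec_a = fit_linear_classifier(features, labels_a, regularization=regularization)
            dec_b = fit_linear_classifier(features, labels_b, regularization=regularization)
        except ValueError:
            continue
        wa, wb = dec_a.weights, dec_b.weights
        ca, cb = wa - wa.mean(), wb - wb.mean()
        denom = np.linalg.norm(ca) * np.linalg.norm(cb)
        if denom == 0:
            continue
        values[tuple(center)] = float(ca @ cb / denom)
    return SearchlightMap(
        values=values,
        mask=work.mask,
        metadata={"analysis": "orthogonality", "radius": radius, "seed": seed},
        affine=work.affine,
    )


def differential_contrast(map_a: SearchlightMap, map_b: SearchlightMap) -> SearchlightMap:
    """Voxelwise difference of two standardized maps (one serving as control).

    Exploratory: differencing two maps lets one analysis absorb a shared
    conservative bias of the standardization, at the cost of a less direct
    interpretation.
    """
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps must share a lattice")
    return SearchlightMap(
        values=map_a.values - map_b.values,
        mask=map_a.mask & map_b.mask,
        metadata={"analysis": "differential", "minuend": map_a.metadata,
                  "subtrahend": map_b.metadata},
        affine=map_a.affine,
    )


def _sign_flip_matrix(
    n_subjects: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    if 2**n_subjects <= n_perm:
        bits = np.arange(2**n_subjects)
        flips = ((bits[:, None] >> np.arange(n_subjects)) & 1) * 2 - 1
        return flips.astype(float), True
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    return flips, False


def group_sign_flip_test(
    maps: list[SearchlightMap] | list[np.ndarray],
    n_perm: int = 5000,
    alternative: str = "greater",
    seed: int | None = None,
) -> GroupTestResult:
    """One-sample sign-flip permutation test across subject maps.

    The voxelwise statistic is the one-sample t on the subject values; the
    null is built by flipping the sign of whole subject maps.  When
    ``2^S <= n_perm`` all sign patterns are enumerated exhaustively (the
    identity pattern makes the smallest attainable p equal to ``2^-S``);
    otherwise ``n_perm`` random patterns are drawn and the observed pattern
    is added to the reference set.  Family-wise corrected p-values come from
    the distribution of the maximum statistic over in-mask voxels.
    """
    if len(maps) < 2:
        raise ValueError("need at least two subjects")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    arrays, masks, affines = [], [], []
    for m in maps:
        if isinstance(m, SearchlightMap):
            arrays.append(m.values)
            masks.append(m.mask)
            affines.append(m.affine)
        else:
            arrays.append(np.asarray(m, dtype=float))
            masks.append(np.isfinite(arrays[-1]))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("subject maps are not aligned on a common lattice")
    stack = np.stack(arrays)  # (S, X, Y, Z)
    valid = np.logical_and.reduce(masks) & np.all(np.isfinite(stack), axis=0)
    data = stack[:, valid]  # (S, V)
    n_subjects = data.shape[0]
    rng = np.random.default_rng(seed)
    flips, exhaustive = _sign_flip_matrix(n_subjects, n_perm, rng)

    def t_stat(signed: np.ndarray) -> np.ndarray:
        mean = signed.mean(axis=0)
        sd = signed.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n_subjects))
            t = np.where(sd == 0, np.sign(mean) * np.inf, t)
            return np.where((sd == 0) & (mean == 0), 0.0, t)

    def orient(t: np.ndarray) -> np.ndarray:
        if alternative == "greater":
            return t
        if alternative == "less":
            return -t
        return np.abs(t)

    observed = orient(t_stat(data))
    count = np.zeros(observed.shape)
    count_max = np.zeros(observed.shape)
    for flip in flips:
        perm = orient(t_stat(flip[:, None] * data))
        count += perm >= observed
        count_max += perm.max(initial=-np.inf) >= observed
    if exhaustive:
        denom = flips.shape[0]
        p = count / denom
        p_fwe = count_max / denom
    else:
        # observed pattern added to the reference set
        p = (count + 1.0) / (flips.shape[0] + 1.0)
        p_fwe = (count_max + 1.0) / (flips.shape[0] + 1.0)

    shape = arrays[0].shape
    t_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    p_fwe_map = np.full(shape, np.nan)
    t_map[valid] = t_stat(data)
    p_map[valid] = p
    p_fwe_map[valid] = p_fwe
    return GroupTestResult(
        t_map=t_map,
        p_map=p_map,
        p_fwe_map=p_fwe_map,
        mask=valid,
        n_perm=flips.shape[0],
        exhaustive=exhaustive,
        alternative=alternative,
    )


def cluster_forming_threshold(p: float, df: int) -> float:
    """Student-t critical value used as a cluster-forming height threshold."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(t_dist.ppf(1.0 - p, df))


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O


def save_map_nifti(slmap: SearchlightMap, path: str | Path, sidecar: bool = True) -> None:
    """Write a map as NIfTI-1 plus a JSON settings sidecar."""
    import nibabel as nib

    img = nib.Nifti1Image(slmap.values.astype(np.float64), slmap.affine)
    nib.save(img, str(path))
    if sidecar:
        meta = {k: v for k, v in slmap.metadata.items()}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def load_map_nifti(path: str | Path) -> SearchlightMap:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    meta_path = Path(str(path) + ".json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SearchlightMap(
        values=values,
        mask=np.isfinite(values),
        metadata=metadata,
        affine=np.asarray(img.affine),
    )


def save_volume_dataset(
    ds: VolumeDataset, data_path: str | Path, mask_path: str | Path, table_path: str | Path
) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(ds.data.astype(np.float64), ds.affine), str(data_path))
    nib.save(
        nib.Nifti1Image(ds.mask.astype(np.uint8), ds.affine), str(mask_path)
    )
    ds.trial_table.to_csv(table_path, index=False)


def load_volume_dataset(
    data_path: str | Path, mask_path: str | Path, table_path: str | Path
) -> VolumeDataset:
    import nibabel as nib

    data_img = nib.load(str(data_path))
    mask_img = nib.load(str(mask_path))
    table = pd.read_csv(table_path)
    return VolumeDataset(
        data=np.asarray(data_img.get_fdata(), dtype=float),
        mask=np.asarray(mask_img.get_fdata()) > 0,
        trial_table=table,
        affine=np.asarray(data_img.affine),
    )
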
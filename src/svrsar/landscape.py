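"""Activity landscapes: MDS embedding, potency surface, smoothing metrics.

An activity landscape combines a 2D projection of all pairwise Tanimoto
similarities of a compound set (metric multidimensional scaling of the
dissimilarities 1 − Tc) with a potency surface interpolated over the
projection. Peaks of the surface are highly potent compounds; activity
cliffs appear as rugged regions where peaks rise next to valleys.

The surface uses inverse-distance-weighted (Shepard) interpolation with
power 2 over all compounds: parameter-free, exact at compound locations,
and bounded by the observed potency range. Because observed and predicted
landscapes share the embedding (conserved topology), they can be compared
cell by cell; :func:`compare_surfaces` quantifies the flattening of
predicted landscapes (lost peak height, compressed range, vanished peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter
from sklearn.manifold import smacof as _smacof

from .errors import ConvergenceError, ValidationError

#: Local maxima count as peaks only above mean(observed surface) + this offset.
PEAK_THRESHOLD_OFFSET = 1.0
#: A predicted peak within this Chebyshev cell radius matches an observed one.
PEAK_MATCH_RADIUS = 2


@dataclass
class Embedding:
    """2D MDS coordinates (record order) with the final stress value."""

    coords: np.ndarray  # (n, 2)
    stress: float


@dataclass
class SurfaceGrid:
    """Regular r×r potency surface over the embedding's bounding box.

    ``values[i, j]`` is the interpolated potency at (xs[i], ys[j]).
    """

    values: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    potency_range: tuple[float, float]


@dataclass
class SmoothingReport:
    """Observed-vs-predicted landscape flattening metrics.

    peak_height_loss
        max(observed surface) − max(predicted surface), in pKi.
    surface_range_ratio
        (max − min) of the predicted surface over that of the observed one.
    disc_delta
        observed disc_raw − predicted disc_raw.
    n_lost_peaks
        observed local maxima above the peak threshold with no predicted
        local maximum within the match radius.
    """

    peak_height_loss: float
    surface_range_ratio: float
    disc_delta: float
    n_lost_peaks: int


def embed_mds(sim_matrix: np.ndarray, seed: int) -> Embedding:
    """Metric stress-majorization MDS of the dissimilarities 1 − Tc."""
    sim_matrix = np.asarray(sim_matrix, dtype=float)
    n = sim_matrix.shape[0]
    if n < 1:
        raise ValidationError("embed_mds needs >= 1 compound")
    if n == 1:
        return Embedding(coords=np.zeros((1, 2)), stress=0.0)
    D = 1.0 - sim_matrix
    coords, stress = _smacof(
        D,
        metric=True,
        n_components=2,
        n_init=4,
        max_iter=2000,
        eps=1e-12,
        random_state=int(seed) % (2**32),
        normalized_stress=False,
    )
    stress = float(stress)
    if not np.all(np.isfinite(coords)) or not np.isfinite(stress):
        raise ConvergenceError(f"MDS failed to converge (stress={stress})")
    return Embedding(coords=coords, stress=stress)


def interpolate_surface(
    embedding: Embedding, potencies: np.ndarray, resolution: int = 100
) -> SurfaceGrid:
    """Shepard/IDW (power 2) potency surface over the embedding bounding box.

    A grid node coinciding with a compound location takes that compound's
    potency (mean over exactly coincident compounds); all other values are
    convex combinations, hence bounded by [min, max] of the input potencies.
    """
    if resolution < 2:
        raise ValidationError("resolution must be >= 2")
    p = np.asarray(potencies, dtype=float)
    coords = embedding.coords
    if coords.shape[0] != p.size:
        raise ValidationError("embedding and potency vector must align")
    xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), resolution)
    ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = (
        (nodes[:, 0:1] - coords[None, :, 0]) ** 2
        + (nodes[:, 1:2] - coords[None, :, 1]) ** 2
    )
    exact = d2 < 1e-24
    with np.errstate(divide="ignore"):
        w = 1.0 / d2
    vals = np.empty(nodes.shape[0])
    hit = exact.any(axis=1)
    if hit.any():
        cnt = exact[hit].sum(axis=1)
        vals[hit] = (exact[hit] @ p) / cnt
    rest = ~hit
    vals[rest] = (w[rest] @ p) / w[rest].sum(axis=1)
    return SurfaceGrid(
        values=vals.reshape(resolution, resolution),
        xs=xs,
        ys=ys,
        potency_range=(float(p.min()), float(p.max())),
    )


def _peak_mask(values: np.ndarray, threshold: float) -> np.ndarray:
    # 8-neighborhood local maxima strictly above the potency threshold
    local_max = values >= maximum_filter(values, size=3, mode="nearest")
    return local_max & (values > threshold)


def compare_surfaces(
    observed: SurfaceGrid,
    predicted: SurfaceGrid,
    observed_disc: float,
    predicted_disc: float,
    peak_threshold: float | None = None,
    match_radius: int = PEAK_MATCH_RADIUS,
) -> SmoothingReport:
    """Quantify the smoothing of a predicted landscape vs the observed one.

    Both grids must share shape and axes (same embedding). Identical inputs
    yield the identity report (loss 0, ratio 1, delta 0, no lost peaks).
    """
    if observed.values.shape != predicted.values.shape or not (
        np.array_equal(observed.xs, predicted.xs)
        and np.array_equal(observed.ys, predicted.ys)
    ):
        raise ValidationError("compare_surfaces requires identical grids")
    if peak_threshold is None:
        peak_threshold = float(observed.values.mean()) + PEAK_THRESHOLD_OFFSET

    obs_range = float(observed.values.max() - observed.values.min())
    pred_range = float(predicted.values.max() - predicted.values.min())
    if obs_range < 1e-12:
        ratio = 1.0 if pred_range < 1e-12 else float("inf")
    else:
        ratio = pred_range / obs_range

    obs_peaks = np.argwhere(_peak_mask(observed.values, peak_threshold))
    pred_peaks = np.argwhere(_peak_mask(predicted.values, peak_threshold))
    lost = 0
    for op in obs_peaks:
        if pred_peaks.size == 0 or not (
            np.max(np.abs(pred_peaks - op), axis=1).min() <= match_radius
        ):
            lost += 1
    return SmoothingReport(
        peak_height_loss=float(observed.values.max() - predicted.values.max()),
        surface_range_ratio=ratio,
        disc_delta=float(observed_disc - predicted_disc),
        n_lost_peaks=lost,
    )


def write_surface_tsv(grid: SurfaceGrid, path) -> None:
    """Row-major surface dump with a bounding-box header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"#bbox={grid.xs[0]!r},{grid.xs[-1]!r},{grid.ys[0]!r},{grid.ys[-1]!r}"
            f"\t#potency_range={grid.potency_range[0]!r},{grid.potency_range[1]!r}\n"
        )
        for row in grid.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
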
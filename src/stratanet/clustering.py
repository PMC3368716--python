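"""Per-layer, per-time-point distance-geometry placement and change detection.

At one time point each entity on a layer carries a single scalar, so the
natural inter-entity distance is ``|v_i - v_j|``.  Coordinates are
reconstructed from the distance matrix by classical multidimensional scaling
truncated to three dimensions: double-center ``-1/2 J D^2 J``, keep the
three largest nonnegative eigenpairs, scale eigenvectors by the square roots
of their eigenvalues.  A 1-D metric embeds exactly, so the recovered
pairwise distances reproduce ``|v_i - v_j|``; the placement is purely for
visual grouping of similar trajectories and feeds the snapshot renderer.

The change detector flags entities with the largest absolute value jump
between two consecutive time points — sudden peaks or declines that are
often more informative than the values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import LayeredNetwork, ValidationError

__all__ = [
    "Embedding",
    "ChangeReport",
    "distance_geometry_embed",
    "cluster_layer_at_time",
    "top_changers",
]


@dataclass
class Embedding:
    """3-D coordinates for one layer at one time point."""

    layer: str
    time_point: str
    coordinates: dict[str, np.ndarray]
    #: entities on the layer skipped because their value at t is missing
    excluded: list[str] = field(default_factory=list)


@dataclass
class ChangeReport:
    """Per-entity absolute change between two consecutive time points.

    ``top`` holds the k largest movers sorted by descending delta; ties at
    the k-th delta are all included, so the list may exceed k.
    """

    layer: str
    from_time: str
    to_time: str
    deltas: dict[str, float]
    top: list[str]


def distance_geometry_embed(D: np.ndarray) -> np.ndarray:
    """Coordinates (n x 3) realizing distance matrix `D` as well as rank 3 allows.

    Classical MDS (Torgerson scaling): ``B = -1/2 J D^2 J`` with the centering
    matrix ``J = I - 11'/n``; the top three nonnegative eigenpairs of B give
    the configuration.  Negative eigenvalues (a non-Euclidean D) are truncated
    to zero, yielding the best rank-3 Euclidean approximation.  For a D that
    is exactly realizable in <= 3 dimensions the output's pairwise distances
    reproduce D up to a rigid transform.

    Determinism: eigenpairs sorted by descending eigenvalue; each axis's sign
    is fixed so its largest-magnitude coordinate is positive.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    n = D.shape[0]
    if not np.allclose(D, D.T, rtol=0, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValidationError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValidationError("distance matrix diagonal must be zero")
    if n == 1:
        return np.zeros((1, 3))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2  # symmetrize against rounding
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][: min(3, n)]
    w_top = np.clip(w[order], 0.0, None)
    V_top = V[:, order]
    coords = V_top * np.sqrt(w_top)
    # sign convention: largest-magnitude entry of each axis positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                coords[:, j] = -col
    if coords.shape[1] < 3:
        coords = np.hstack(
            [coords, np.zeros((n, 3 - coords.shape[1]))]
        )
    return coords


def cluster_layer_at_time(
    net: LayeredNetwork, layer: str, t: str
) -> Embedding:
    """Embed a layer's entities by their scalar values at time point `t`.

    The distance between two entities is the absolute difference of their
    values at t; entities with a missing value at t are excluded and listed
    in ``Embedding.excluded``.
    """
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    ti = net.time_index(t)
    present: list[str] = []
    excluded: list[str] = []
    vals: list[float] = []
    for entity in net.entities_on_layer(layer):
        v = net.values[(layer, entity)][ti]
        if np.isnan(v):
            excluded.append(entity)
        else:
            present.append(entity)
            vals.append(float(v))
    if len(present) < 2:
        raise ValidationError(
            f"layer {layer!r} has {len(present)} usable entities at {t!r}; "
            "need at least 2"
        )
    v = np.array(vals)
    D = np.abs(v[:, None] - v[None, :])
    coords = distance_geometry_embed(D)
    return Embedding(
        layer=layer,
        time_point=t,
        coordinates={e: coords[i] for i, e in enumerate(present)},
        excluded=excluded,
    )


def top_changers(
    net: LayeredNetwork, layer: str, from_t: str, k: int = 1
) -> ChangeReport:
    """Entities with the largest |value change| to the next time point.

    Deltas are computed for every entity with non-missing values at both
    ``from_t`` and the immediately following time point.  The top list keeps
    the k largest; ties at the cutoff are all retained.
    """
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    if k < 1:
        raise ValidationError("k must be a positive integer")
    i = net.time_index(from_t)
    if i + 1 >= net.n_time_points:
        raise ValidationError(
            f"{from_t!r} is the last time point; no following point to compare"
        )
    to_t = net.time_points[i + 1]
    deltas: dict[str, float] = {}
    for entity in net.entities_on_layer(layer):
        vec = net.values[(layer, entity)]
        if not (np.isnan(vec[i]) or np.isnan(vec[i + 1])):
            deltas[entity] = float(abs(vec[i + 1] - vec[i]))
    ranked = sorted(deltas, key=lambda e: (-deltas[e], e))
    top: list[str] = []
    for e in ranked:
        if len(top) < k or deltas[e] == deltas[top[-1]]:
            top.append(e)
        else:
            break
    return ChangeReport(
        layer=layer, from_time=from_t, to_time=to_t, deltas=deltas, top=top
    )
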
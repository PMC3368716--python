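"""Static per-time-point figure rendering: small multiples, one panel per layer.

The 2-D small-multiples projection stands in for a stacked-3D scene; the
contract is the *draw manifest* the renderer returns — per-layer node
positions, colors and sizes plus the edge lists actually drawn — which is a
pure, reproducible function of (network, time point, options).  Node colors
come from the per-layer value colormap; correlation edges are drawn yellow
(positive) or red (negative); tracked entities are enlarged; top changers
are connected across layer panels with a marker line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import cluster_layer_at_time, top_changers
from .colormap import ColorScale, YELLOW_BLUE, rgb_to_hex, value_to_color
from .correlation import CorrelationRecord
from .model_io import LayeredNetwork, ValidationError, layer_stats

__all__ = ["SnapshotOptions", "render_snapshot", "render_sweep"]

_NODE_SIZE = 40.0
_TRACKED_SIZE = 120.0


@dataclass
class SnapshotOptions:
    """Rendering switches for one snapshot."""

    embed: bool = False  # distance-geometry positions instead of a grid
    correlations: list[CorrelationRecord] = field(default_factory=list)
    tracked: set[str] = field(default_factory=set)
    top_changes: bool = False  # connect top changers across layer panels
    scale: ColorScale = YELLOW_BLUE


def _grid_positions(entities: list[str]) -> dict[str, tuple[float, float]]:
    n = len(entities)
    cols = max(1, int(np.ceil(np.sqrt(n))))
    return {
        e: (float(i % cols), float(-(i // cols)))
        for i, e in enumerate(entities)
    }


def _embed_positions(
    net: LayeredNetwork, layer: str, t: str
) -> dict[str, tuple[float, float]]:
    emb = cluster_layer_at_time(net, layer, t)
    pos = {e: (float(c[0]), float(c[1])) for e, c in emb.coordinates.items()}
    grid = _grid_positions(emb.excluded)
    # park value-less entities on a side strip so every node is drawn
    if emb.excluded:
        xs = [p[0] for p in pos.values()] or [0.0]
        off = max(xs) + 1.0
        for e in emb.excluded:
            gx, gy = grid[e]
            pos[e] = (off + gx * 0.2, gy * 0.2)
    return pos


def build_manifest(
    net: LayeredNetwork, t: str, options: SnapshotOptions
) -> dict:
    """Deterministic draw manifest for one time point (no rendering)."""
    ti = net.time_index(t)
    manifest: dict = {"time_point": t, "layers": {}, "cross_layer": []}
    changers_by_layer: dict[str, list[str]] = {}
    if options.top_changes:
        # highlight the change arriving at t (first point: the change leaving it)
        from_t = net.time_points[ti - 1] if ti > 0 else t
        if net.n_time_points >= 2:
            for layer in net.layers:
                changers_by_layer[layer] = top_changers(
                    net, layer, from_t, k=1
                ).top
    for layer in net.layers:
        entities = net.entities_on_layer(layer)
        if not entities:
            manifest["layers"][layer] = {"nodes": {}, "edges": []}
            continue
        stats = layer_stats(net, layer)
        if options.embed and len(entities) >= 2:
            try:
                pos = _embed_positions(net, layer, t)
            except ValidationError:  # < 2 usable values at t
                pos = _grid_positions(entities)
        else:
            pos = _grid_positions(entities)
        nodes = {}
        for e in entities:
            v = float(net.values[(layer, e)][ti])
            nodes[e] = {
                "pos": [round(pos[e][0], 9), round(pos[e][1], 9)],
                "color": rgb_to_hex(
                    value_to_color(v, stats, options.scale)
                ),
                "size": _TRACKED_SIZE if e in options.tracked else _NODE_SIZE,
            }
        edges = [
            {"a": a, "b": b, "kind": "interaction", "color": "#999999"}
            for lay, a, b in sorted(net.intra_edges)
            if lay == layer
        ]
        for rec in options.correlations:
            if rec.layer == layer:
                edges.append(
                    {
                        "a": rec.entity_a,
                        "b": rec.entity_b,
                        "kind": "correlation",
                        "color": "#ffd700"
                        if rec.sign == "positive"
                        else "#ff0000",
                    }
                )
        manifest["layers"][layer] = {"nodes": nodes, "edges": edges}
    # top changers joined across panels, the cross-layer highlight
    seen = []
    for layer, tops in changers_by_layer.items():
        for e in tops:
            if e not in seen:
                seen.append(e)
    manifest["cross_layer"] = [
        {"entity": e, "layers": [l for l in changers_by_layer if e in changers_by_layer[l]]}
        for e in seen
    ]
    return manifest


def render_snapshot(
    net: LayeredNetwork,
    t: str,
    options: SnapshotOptions | None = None,
    path=None,
) -> dict:
    """Render one time point to `path` (PNG/SVG by suffix); returns the
    draw manifest.  With ``path=None`` only the manifest is produced."""
    if t not in net.time_points:
        raise ValidationError(f"unknown time point {t!r}")
    options = options or SnapshotOptions()
    manifest = build_manifest(net, t, options)
    if path is None:
        return manifest

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_layers = len(net.layers)
    fig, axes = plt.subplots(
        1, n_layers, figsize=(3.2 * max(n_layers, 1), 3.4), squeeze=False
    )
    for ax, layer in zip(axes[0], net.layers):
        panel = manifest["layers"][layer]
        for edge in panel["edges"]:
            pa = panel["nodes"][edge["a"]]["pos"]
            pb = panel["nodes"][edge["b"]]["pos"]
            lw = 0.5 if edge["kind"] == "interaction" else 1.4
            ax.plot(
                [pa[0], pb[0]], [pa[1], pb[1]],
                color=edge["color"], linewidth=lw, zorder=1,
            )
        if panel["nodes"]:
            xs = [nd["pos"][0] for nd in panel["nodes"].values()]
            ys = [nd["pos"][1] for nd in panel["nodes"].values()]
            cs = [nd["color"] for nd in panel["nodes"].values()]
            ss = [nd["size"] for nd in panel["nodes"].values()]
            ax.scatter(xs, ys, c=cs, s=ss, edgecolors="black",
                       linewidths=0.4, zorder=2)
        for item in manifest["cross_layer"]:
            if layer in item["layers"] and item["entity"] in panel["nodes"]:
                px, py = panel["nodes"][item["entity"]]["pos"]
                ax.scatter([px], [py], marker="D", s=160, facecolors="none",
                           edgecolors="#00aa00", linewidths=1.6, zorder=3)
        ax.set_title(layer, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle(f"t = {t}", fontsize=10)
    fig.tight_layout()
    fig.savefig(str(path), dpi=110)
    plt.close(fig)
    return manifest


def render_sweep(
    net: LayeredNetwork,
    options: SnapshotOptions | None = None,
    out_dir=".",
    prefix: str = "snapshot",
    ext: str = "png",
) -> list[dict]:
    """One numbered image per time point; returns the manifests in order."""
    import os

    manifests = []
    for i, t in enumerate(net.time_points):
        path = os.path.join(str(out_dir), f"{prefix}_{i:04d}.{ext}")
        manifests.append(render_snapshot(net, t, options, path))
    return manifests
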
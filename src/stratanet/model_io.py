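"""Layered time-course network data model and I/O.

A :class:`LayeredNetwork` holds one network replicated across several
*layers* (categories of biological measurement: an epigenetic mark, mRNA
abundance, a morphological phenotype, ...).  Every entity (gene, protein,
knockdown target) carries, per layer it appears on, a vector of values over
a shared ordered grid of time points.  Missing values are stored as NaN and
written out as the token ``NA``.

Two equivalent on-disk dialects are supported:

TSV — three sections::

    #LAYERS
    <layer name>                     (one per line, in order)
    #VALUES\t<t1>\t<t2>\t...\t<tN>   (header row carries the time labels)
    <layer>\t<entity>\t<v1>\t...\t<vN>
    #EDGES
    <layerA>\t<entityA>\t<layerB>\t<entityB>

    An edge row is intra-layer when layerA == layerB.

JSON — an object with keys ``layers``, ``time_points``, ``values``
(layer → entity → list, ``null`` for missing), ``intra_edges`` and
``inter_edges``.

Export targets: Pajek ``.net`` and a plain two-column interaction list
(Medusa-style).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "LayeredNetwork",
    "LayerStats",
    "read_layered_network",
    "write_layered_network",
    "layer_stats",
    "export_pajek",
    "export_edgelist",
]


class FormatError(ValueError):
    """The file does not parse under the declared dialect."""


class ValidationError(ValueError):
    """The parsed content violates a network invariant."""


def _canon_intra(layer: str, a: str, b: str) -> tuple[str, str, str]:
    lo, hi = sorted((a, b))
    return (layer, lo, hi)


def _canon_inter(
    end_a: tuple[str, str], end_b: tuple[str, str]
) -> tuple[tuple[str, str], tuple[str, str]]:
    lo, hi = sorted((end_a, end_b))
    return (lo, hi)


@dataclass
class LayeredNetwork:
    """A multi-layer network with per-(layer, entity) time-series values.

    Parameters
    ----------
    layers
        Ordered layer names, unique.
    entities
        Ordered entity identifiers; an entity may appear on any subset of
        layers (it appears on a layer iff ``(layer, entity)`` has a value
        vector).
    time_points
        Ordered labels of the shared time grid (length N).
    values
        Map ``(layer, entity) -> float array of length N``; NaN = missing.
    intra_edges
        Unordered within-layer pairs, stored canonically as
        ``(layer, min(a, b), max(a, b))``.
    inter_edges
        Between-layer links, stored canonically as a sorted pair of
        ``(layer, entity)`` endpoints.
    """

    layers: list[str]
    entities: list[str]
    time_points: list[str]
    values: dict[tuple[str, str], np.ndarray]
    intra_edges: set[tuple[str, str, str]] = field(default_factory=set)
    inter_edges: set[tuple[tuple[str, str], tuple[str, str]]] = field(
        default_factory=set
    )

    def __post_init__(self) -> None:
        self.values = {
            k: np.asarray(v, dtype=float) for k, v in self.values.items()
        }
        self.intra_edges = {_canon_intra(*e) for e in self.intra_edges}
        self.inter_edges = {_canon_inter(*e) for e in self.inter_edges}

    # -- structure queries -------------------------------------------------

    @property
    def n_time_points(self) -> int:
        return len(self.time_points)

    def entities_on_layer(self, layer: str) -> list[str]:
        """Entities with a value vector on `layer`, in declaration order."""
        return [e for e in self.entities if (layer, e) in self.values]

    def time_index(self, t: str) -> int:
        try:
            return self.time_points.index(t)
        except ValueError:
            raise ValidationError(f"unknown time point {t!r}") from None

    def value(self, layer: str, entity: str, t: str) -> float:
        return float(self.values[(layer, entity)][self.time_index(t)])

    # -- validation --------------------------------------------------------

    def validate(self) -> "LayeredNetwork":
        """Check all invariants; return self or raise ValidationError."""
        if len(set(self.layers)) != len(self.layers):
            raise ValidationError("duplicate layer names")
        if len(set(self.entities)) != len(self.entities):
            raise ValidationError("duplicate entity identifiers")
        n = len(self.time_points)
        known_entities = set(self.entities)
        for (layer, entity), vec in self.values.items():
            if layer not in self.layers:
                raise ValidationError(
                    f"value row references undeclared layer {layer!r}"
                )
            if entity not in known_entities:
                raise ValidationError(
                    f"value row references undeclared entity {entity!r}"
                )
            if vec.shape != (n,):
                raise ValidationError(
                    f"value vector for entity {entity!r} on layer {layer!r} "
                    f"has length {vec.size}, expected {n}"
                )
        for layer, a, b in self.intra_edges:
            if a == b:
                raise ValidationError(f"self-edge on {a!r} (layer {layer!r})")
            for e in (a, b):
                if (layer, e) not in self.values:
                    raise ValidationError(
                        f"edge endpoint {e!r} not present on layer {layer!r}"
                    )
        for end_a, end_b in self.inter_edges:
            if end_a == end_b:
                raise ValidationError(f"self-edge on {end_a!r}")
            for layer, e in (end_a, end_b):
                if (layer, e) not in self.values:
                    raise ValidationError(
                        f"edge endpoint {e!r} not present on layer {layer!r}"
                    )
        return self

    # -- equality (NaN-aware on values) ------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayeredNetwork):
            return NotImplemented
        if (
            self.layers != other.layers
            or self.entities != other.entities
            or self.time_points != other.time_points
            or self.intra_edges != other.intra_edges
            or self.inter_edges != other.inter_edges
            or set(self.values) != set(other.values)
        ):
            return False
        return all(
            np.array_equal(self.values[k], other.values[k], equal_nan=True)
            for k in self.values
        )


@dataclass(frozen=True)
class LayerStats:
    """Extremes of a layer's non-missing values over the whole time course."""

    layer: str
    min_value: float
    max_value: float


def layer_stats(net: LayeredNetwork, layer: str) -> LayerStats:
    """Min/max over all entities and time points of one layer, ignoring NaN.

    The per-layer range anchors that layer's color scale; ranges are never
    pooled across layers because different layers may measure incomparable
    quantities.
    """
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    vecs = [v for (lay, _), v in net.values.items() if lay == layer]
    pool = np.concatenate(vecs) if vecs else np.array([])
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValidationError(f"layer {layer!r} has no non-missing values")
    return LayerStats(layer, float(pool.min()), float(pool.max()))


# -- TSV dialect -----------------------------------------------------------

_NA = "NA"


def _fmt(x: float) -> str:
    x = float(x)
    return _NA if math.isnan(x) else repr(x)


def _parse_value(tok: str, lineno: int) -> float:
    if tok == _NA:
        return math.nan
    try:
        return float(tok)
    except ValueError:
        raise FormatError(f"line {lineno}: bad numeric value {tok!r}") from None


def _read_tsv(text: str) -> LayeredNetwork:
    layers: list[str] = []
    entities: list[str] = []
    time_points: list[str] | None = None
    values: dict[tuple[str, str], np.ndarray] = {}
    intra: set = set()
    inter: set = set()
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.split("\t")
            tag = fields[0]
            if tag == "#LAYERS":
                section = "layers"
            elif tag == "#VALUES":
                section = "values"
                time_points = fields[1:]
                if not time_points:
                    raise FormatError(
                        f"line {lineno}: #VALUES header carries no time labels"
                    )
            elif tag == "#EDGES":
                section = "edges"
            else:
                raise FormatError(f"line {lineno}: unknown section {tag!r}")
            continue
        if section == "layers":
            layers.append(line.strip())
        elif section == "values":
            fields = line.split("\t")
            if len(fields) != 2 + len(time_points):  # type: ignore[arg-type]
                raise FormatError(
                    f"line {lineno}: expected layer, entity and "
                    f"{len(time_points)} values, got {len(fields)} fields"  # type: ignore[arg-type]
                )
            layer, entity = fields[0], fields[1]
            vec = np.array([_parse_value(t, lineno) for t in fields[2:]])
            if entity not in entities:
                entities.append(entity)
            if (layer, entity) in values:
                raise FormatError(
                    f"line {lineno}: duplicate value row for "
                    f"{entity!r} on {layer!r}"
                )
            values[(layer, entity)] = vec
        elif section == "edges":
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"line {lineno}: edge rows need 4 fields, got {len(fields)}"
                )
            la, ea, lb, eb = fields
            if la == lb:
                intra.add((la, ea, eb))
            else:
                inter.add(((la, ea), (lb, eb)))
        else:
            raise FormatError(f"line {lineno}: content before any section header")
    if time_points is None:
        raise FormatError("missing #VALUES section")
    if not layers:
        raise FormatError("missing #LAYERS section")
    net = LayeredNetwork(layers, entities, time_points, values, intra, inter)
    return net.validate()


def _write_tsv(net: LayeredNetwork) -> str:
    out: list[str] = ["#LAYERS"]
    out.extend(net.layers)
    out.append("#VALUES\t" + "\t".join(net.time_points))
    # entity-major so that first-appearance order reconstructs net.entities
    for entity in net.entities:
        for layer in net.layers:
            if (layer, entity) in net.values:
                vec = net.values[(layer, entity)]
                out.append(
                    "\t".join([layer, entity] + [_fmt(x) for x in vec])
                )
    out.append("#EDGES")
    for layer, a, b in sorted(net.intra_edges):
        out.append("\t".join([layer, a, layer, b]))
    for (la, ea), (lb, eb) in sorted(net.inter_edges):
        out.append("\t".join([la, ea, lb, eb]))
    return "\n".join(out) + "\n"


# -- JSON dialect ----------------------------------------------------------


def _read_json(text: str) -> LayeredNetwork:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from None
    try:
        layers = list(doc["layers"])
        time_points = list(doc["time_points"])
        raw_values = doc["values"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"missing required key: {exc}") from None
    values: dict[tuple[str, str], np.ndarray] = {}
    entities: list[str] = list(doc.get("entities", []))
    for layer in layers:
        for entity, vec in raw_values.get(layer, {}).items():
            if entity not in entities:
                entities.append(entity)
            values[(layer, entity)] = np.array(
                [math.nan if v is None else float(v) for v in vec]
            )
    intra = {tuple(e) for e in doc.get("intra_edges", [])}
    inter = {
        (tuple(ea), tuple(eb)) for ea, eb in doc.get("inter_edges", [])
    }
    net = LayeredNetwork(layers, entities, time_points, values, intra, inter)
    return net.validate()


def _write_json(net: LayeredNetwork) -> str:
    raw_values: dict[str, dict[str, list]] = {}
    for layer in net.layers:
        raw_values[layer] = {
            entity: [
                None if math.isnan(x) else x
                for x in net.values[(layer, entity)]
            ]
            for entity in net.entities_on_layer(layer)
        }
    doc = {
        "layers": net.layers,
        "entities": net.entities,
        "time_points": net.time_points,
        "values": raw_values,
        "intra_edges": [list(e) for e in sorted(net.intra_edges)],
        "inter_edges": [
            [list(ea), list(eb)] for ea, eb in sorted(net.inter_edges)
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


# -- public I/O ------------------------------------------------------------


def read_layered_network(path, format: str | None = None) -> LayeredNetwork:
    """Read a layered network from `path` in the TSV or JSON dialect.

    ``format`` is ``"tsv"`` or ``"json"``; when None it is inferred from the
    file suffix (``.json`` → JSON, anything else → TSV).  Missing values are
    preserved as NaN, never coerced to zero.
    """
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "tsv"
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return parse_layered_network(text, format)


def parse_layered_network(text: str, format: str = "tsv") -> LayeredNetwork:
    if format == "tsv":
        return _read_tsv(text)
    if format == "json":
        return _read_json(text)
    raise ValueError(f"unknown format {format!r}")


def write_layered_network(
    net: LayeredNetwork, path, format: str | None = None
) -> None:
    """Write `net` to `path`; inverse of :func:`read_layered_network`."""
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "tsv"
    text = dump_layered_network(net, format)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def dump_layered_network(net: LayeredNetwork, format: str = "tsv") -> str:
    net.validate()
    if format == "tsv":
        return _write_tsv(net)
    if format == "json":
        return _write_json(net)
    raise ValueError(f"unknown format {format!r}")


# -- graph export ----------------------------------------------------------


def export_pajek(net: LayeredNetwork, layer: str, path) -> None:
    """Write one layer's intra-layer graph as a Pajek ``.net`` file.

    Vertices are numbered 1-based in entity declaration order; the edge
    section lists one ``i j`` pair per intra-layer edge.
    """
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    nodes = net.entities_on_layer(layer)
    index = {e: i + 1 for i, e in enumerate(nodes)}
    lines = [f"*Vertices {len(nodes)}"]
    lines += [f'{i + 1} "{e}"' for i, e in enumerate(nodes)]
    lines.append("*Edges")
    for lay, a, b in sorted(net.intra_edges):
        if lay == layer:
            lines.append(f"{index[a]} {index[b]}")
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def export_edgelist(net: LayeredNetwork, layer: str, path) -> None:
    """Write one layer's edges as a plain two-column interaction list."""
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    lines = [
        f"{a} {b}" for lay, a, b in sorted(net.intra_edges) if lay == layer
    ]
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
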
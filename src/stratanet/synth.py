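"""Seeded synthetic layered time-course networks with planted structure.

The generator emulates the two study shapes this toolkit targets:

* ``esc_core`` — a core embryonic-stem-cell gene network replicated on four
  measurement layers (histone acetylation, Pol II binding, mRNA, protein)
  over three time points (days 1, 3, 5), with positively/negatively
  correlated gene pairs recurring on two or more layers and a large step
  change for one gene.
* ``mitotic_screen`` — knockdown phenotype profiling: seven morphological
  phenotype layers over 90 time points spanning 45 hours, non-negative
  penetrance trajectories, a sparse "rare phenotype" layer, and a
  late-onset latent signal (a gene whose effect appears only near the end
  of the course).

Planted truths (correlated pairs, step changes, latent onsets) are part of
the spec, so they are identical across seeds; only the noise differs.  A
manifest of the planted structure is returned next to the network so tests
and downstream tooling can verify recovery.

Noise model: i.i.d. Gaussian on top of piecewise-linear planted
trajectories; penetrance-style layers are clipped at zero.  Correlated
pairs share a latent ramp plus independent noise, and the noise weight is
halved until the realized sample correlation reaches the pair's target, so
a planted pair always clears the significance threshold it was planted for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model_io import LayeredNetwork

__all__ = [
    "PlantedPair",
    "PlantedStep",
    "PlantedLatent",
    "SynthSpec",
    "generate",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class PlantedPair:
    """Two entities sharing a latent trajectory on the given layers.

    sign +1 plants a positive correlation, -1 a negative one; the realized
    sample |r| on every listed layer is tuned to be >= target_r.
    """

    entity_a: str
    entity_b: str
    layers: tuple[str, ...]
    sign: int = 1
    target_r: float = 0.999


@dataclass(frozen=True)
class PlantedStep:
    """An abrupt value jump of `magnitude` between time_index-1 and time_index."""

    entity: str
    layer: str
    time_index: int
    magnitude: float


@dataclass(frozen=True)
class PlantedLatent:
    """A late-onset signal: flat near zero until onset_index, then a ramp up."""

    entity: str
    layer: str
    onset_index: int


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic network draw."""

    layer_names: tuple[str, ...]
    n_entities: int
    time_labels: tuple[str, ...]
    noise_sd: float = 0.05
    amplitude: float = 10.0
    baseline_range: tuple[float, float] = (1.0, 9.0)
    edge_prob: float = 0.08
    clip_at_zero: bool = False
    rare_layers: tuple[str, ...] = ()
    rare_layer_sparsity: float = 0.0
    planted_correlated_pairs: tuple[PlantedPair, ...] = ()
    planted_step_changes: tuple[PlantedStep, ...] = ()
    planted_latent_signals: tuple[PlantedLatent, ...] = ()
    entity_prefix: str = "gene"
    entity_width: int = 0  # 0 = derive from n_entities
    seed: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def n_time_points(self) -> int:
        return len(self.time_labels)

    def entity_names(self) -> list[str]:
        width = self.entity_width or max(2, len(str(self.n_entities)))
        return [
            f"{self.entity_prefix}_{i + 1:0{width}d}"
            for i in range(self.n_entities)
        ]

    def validate(self) -> "SynthSpec":
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(set(self.layer_names)) != self.n_layers:
            raise ValueError("layer names must be unique")
        names = set(self.entity_names())
        n = self.n_time_points
        for p in self.planted_correlated_pairs:
            if p.entity_a not in names or p.entity_b not in names:
                raise ValueError(f"planted pair references unknown entity: {p}")
            if p.entity_a == p.entity_b:
                raise ValueError("planted pair must use two distinct entities")
            for lay in p.layers:
                if lay not in self.layer_names:
                    raise ValueError(f"planted pair references unknown layer {lay!r}")
            if not 0 < abs(p.target_r) <= 1 or p.sign not in (-1, 1):
                raise ValueError(f"bad planted pair parameters: {p}")
        for s in self.planted_step_changes:
            if s.entity not in names or s.layer not in self.layer_names:
                raise ValueError(f"planted step references unknown entity/layer: {s}")
            if not 1 <= s.time_index < n:
                raise ValueError(
                    f"step time index {s.time_index} outside 1..{n - 1}"
                )
        for latent in self.planted_latent_signals:
            if latent.entity not in names or latent.layer not in self.layer_names:
                raise ValueError(
                    f"planted latent references unknown entity/layer: {latent}"
                )
            if not 0 < latent.onset_index < n - 1:
                raise ValueError(
                    f"latent onset {latent.onset_index} outside 1..{n - 2}"
                )
        for lay in self.rare_layers:
            if lay not in self.layer_names:
                raise ValueError(f"unknown rare layer {lay!r}")
        if not 0 <= self.rare_layer_sparsity <= 1:
            raise ValueError("rare_layer_sparsity must be in [0, 1]")
        return self


def _sample_r(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def _clip(vec: np.ndarray, spec: SynthSpec) -> np.ndarray:
    return np.clip(vec, 0.0, None) if spec.clip_at_zero else vec


def _tuned_pair(
    latent: np.ndarray,
    eps_a: np.ndarray,
    eps_b: np.ndarray,
    sign: int,
    target_r: float,
    spec: SynthSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrink the noise weight until the realized |r| reaches target_r."""
    base_b = spec.amplitude - latent if sign < 0 else latent
    w = spec.noise_sd
    for _ in range(64):
        a = _clip(latent + w * eps_a, spec)
        b = _clip(base_b + w * eps_b, spec)
        r = _sample_r(a, b)
        if sign * r >= target_r:
            return a, b
        w /= 2
    return _clip(latent, spec), _clip(base_b, spec)


def generate(spec: SynthSpec) -> tuple[LayeredNetwork, dict]:
    """Draw one network from `spec`; returns (network, manifest).

    The manifest records every planted truth plus the realized per-layer
    correlations of planted pairs, JSON-serializable.  Identical specs
    (same seed) give identical networks; plants are seed-independent.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    entities = spec.entity_names()
    n = spec.n_time_points
    lo, hi = spec.baseline_range

    values: dict[tuple[str, str], np.ndarray] = {}
    for layer in spec.layer_names:
        for entity in entities:
            base = rng.uniform(lo, hi)
            vec = base + rng.normal(0.0, spec.noise_sd, size=n)
            values[(layer, entity)] = _clip(vec, spec)

    manifest: dict = {
        "seed": spec.seed,
        "planted_pairs": [],
        "planted_steps": [],
        "planted_latents": [],
        "rare_zero_entities": {},
    }

    # correlated pairs share a monotone latent ramp plus tuned noise
    latent = np.linspace(0.0, spec.amplitude, n)
    for pair in spec.planted_correlated_pairs:
        realized = {}
        for layer in pair.layers:
            a, b = _tuned_pair(
                latent,
                rng.normal(0.0, 1.0, size=n),
                rng.normal(0.0, 1.0, size=n),
                pair.sign,
                pair.target_r,
                spec,
            )
            values[(layer, pair.entity_a)] = a
            values[(layer, pair.entity_b)] = b
            realized[layer] = _sample_r(a, b)
        manifest["planted_pairs"].append(
            {**asdict(pair), "layers": list(pair.layers), "realized_r": realized}
        )

    for step in spec.planted_step_changes:
        base = (lo + hi) / 2
        vec = base + rng.normal(0.0, spec.noise_sd, size=n)
        vec[step.time_index :] += step.magnitude
        values[(step.layer, step.entity)] = _clip(vec, spec)
        manifest["planted_steps"].append(asdict(step))

    for sig in spec.planted_latent_signals:
        vec = rng.normal(0.0, spec.noise_sd, size=n)
        ramp_len = n - sig.onset_index
        vec[sig.onset_index :] += np.linspace(0.0, spec.amplitude, ramp_len)
        values[(sig.layer, sig.entity)] = np.clip(vec, 0.0, None)
        manifest["planted_latents"].append(asdict(sig))

    # sparse "rare phenotype" layers: a fraction of entities shows nothing
    planted_entities = {
        (lay, e)
        for p in spec.planted_correlated_pairs
        for lay in p.layers
        for e in (p.entity_a, p.entity_b)
    }
    planted_entities |= {(s.layer, s.entity) for s in spec.planted_step_changes}
    planted_entities |= {(s.layer, s.entity) for s in spec.planted_latent_signals}
    for layer in spec.rare_layers:
        eligible = [
            e for e in entities if (layer, e) not in planted_entities
        ]
        n_zero = int(round(spec.rare_layer_sparsity * len(eligible)))
        zeroed = sorted(
            rng.choice(eligible, size=n_zero, replace=False).tolist()
        )
        for e in zeroed:
            values[(layer, e)] = np.zeros(n)
        manifest["rare_zero_entities"][layer] = zeroed

    # one random interaction topology, replicated on every layer
    intra: set[tuple[str, str, str]] = set()
    m = len(entities)
    mask = np.triu(rng.random((m, m)) < spec.edge_prob, k=1)
    for i, j in np.argwhere(mask):
        for layer in spec.layer_names:
            intra.add((layer, entities[i], entities[j]))

    net = LayeredNetwork(
        layers=list(spec.layer_names),
        entities=entities,
        time_points=list(spec.time_labels),
        values=values,
        intra_edges=intra,
    ).validate()
    return net, manifest


# -- study-shaped presets --------------------------------------------------


def _esc_core(n_entities: int | None, n_time_points: int | None, seed: int) -> SynthSpec:
    if n_time_points not in (None, 3):
        raise ValueError("the esc_core shape has exactly 3 time points")
    return SynthSpec(
        layer_names=(
            "histone_acetylation",
            "pol2_binding",
            "mrna",
            "protein",
        ),
        n_entities=n_entities or 30,
        time_labels=("day1", "day3", "day5"),
        noise_sd=0.05,
        amplitude=10.0,
        baseline_range=(1.0, 9.0),
        planted_correlated_pairs=(
            PlantedPair(
                "gene_02", "gene_05", ("histone_acetylation", "mrna"), 1, 0.999
            ),
            PlantedPair(
                "gene_03", "gene_07", ("pol2_binding", "protein"), -1, 0.999
            ),
        ),
        planted_step_changes=(
            PlantedStep("gene_11", "histone_acetylation", 1, 8.0),
        ),
        entity_width=2,
        seed=seed,
    )


def _mitotic_screen(
    n_entities: int | None, n_time_points: int | None, seed: int
) -> SynthSpec:
    n_t = n_time_points or 90
    if n_t < 10:
        raise ValueError("the mitotic screen shape needs >= 10 time points")
    # 90 half-hour frames span 45 hours; fewer points keep the same window
    labels = tuple(f"h{(i + 1) * 45.0 / n_t:05.2f}" for i in range(n_t))
    m = n_entities or 1067
    return SynthSpec(
        layer_names=(
            "mitotic_delay",
            "binuclear",
            "polylobed",
            "grape",
            "large",
            "dynamic",
            "apoptosis",
        ),
        n_entities=m,
        time_labels=labels,
        noise_sd=0.02,
        amplitude=1.0,
        baseline_range=(0.02, 0.25),
        edge_prob=0.002,
        clip_at_zero=True,
        rare_layers=("grape",),
        rare_layer_sparsity=0.7,
        planted_correlated_pairs=(
            PlantedPair(
                "gene_0002",
                "gene_0005",
                ("polylobed", "binuclear", "apoptosis"),
                1,
                0.6,
            ),
        ),
        planted_step_changes=(
            PlantedStep("gene_0011", "dynamic", n_t // 2, 0.6),
        ),
        planted_latent_signals=(
            PlantedLatent("gene_0001", "grape", (2 * n_t) // 3),
        ),
        entity_width=4,
        seed=seed,
    )


PRESETS = {"esc_core": _esc_core, "mitotic_screen": _mitotic_screen}


def preset(
    name: str,
    n_entities: int | None = None,
    n_time_points: int | None = None,
    seed: int = 0,
) -> SynthSpec:
    """Spec matching one of the two study shapes.

    ``esc_core``: 4 layers x 3 time points (default 30 genes).
    ``mitotic_screen``: 7 phenotype layers x 90 time points over 45 h
    (default 1067 genes; ``n_time_points=50`` gives the one-cell-cycle
    window).
    """
    try:
        builder = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return builder(n_entities, n_time_points, seed).validate()


def manifest_to_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=1, sort_keys=True) + "\n"
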
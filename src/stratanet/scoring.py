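"""Similarity scoring of per-entity time-series vectors.

Two schemes summarize a whole trajectory into one number per entity:

(a) *average* — the arithmetic mean of the non-missing values; high when
    the signal is persistently strong.
(b) *wilson* — the lower bound of the Wilson score confidence interval for
    a Bernoulli proportion.  Each time point is converted to a binary
    "rating": positive iff its value strictly exceeds a configurable
    threshold (default 0, matching penetrance-style data where any nonzero
    score means the phenotype is present).  With p-hat the positive
    fraction, n the number of ratings and z the (1 - alpha/2) Gaussian
    quantile, the score is

        (p-hat + z^2/(2n) - z * sqrt(p-hat(1-p-hat)/n + z^2/(4n^2)))
        -----------------------------------------------------------
                          1 + z^2/n

    which balances the observed positive fraction against small-sample
    uncertainty: a short all-positive series scores well below 1.

Raw scores are binned onto a 0..10 scale against the *layer's own* score
range (never pooled across layers) and colored white → red, so entities
with similar overall behavior are colored identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .colormap import RGB, score_to_color
from .model_io import LayeredNetwork, ValidationError

__all__ = [
    "WilsonParams",
    "SimilarityScore",
    "average_score",
    "wilson_lower_bound",
    "score_layer",
    "track_entity",
    "plot_track",
]


@dataclass(frozen=True)
class WilsonParams:
    """Knobs of the Wilson lower-bound scheme.

    alpha sets the Gaussian quantile z_{alpha/2} (default 0.05 → z ≈ 1.96);
    positive_threshold is the value a time point must strictly exceed to
    count as a positive rating.
    """

    alpha: float = 0.05
    positive_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")

    @property
    def z(self) -> float:
        return float(sps.norm.ppf(1 - self.alpha / 2))


@dataclass(frozen=True)
class SimilarityScore:
    entity: str
    layer: str
    scheme: str  # average | wilson
    raw_score: float
    bin: int  # 0..10
    color: RGB


def _nonmissing(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v[~np.isnan(v)]


def average_score(v) -> float:
    """Arithmetic mean of the non-missing values of one trajectory."""
    vals = _nonmissing(v)
    if vals.size == 0:
        raise ValueError("cannot average an all-missing vector")
    return float(vals.mean())


def wilson_lower_bound(v, params: WilsonParams = WilsonParams()) -> float:
    """Wilson score interval lower bound for the trajectory's positive fraction."""
    vals = _nonmissing(v)
    n = vals.size
    if n == 0:
        raise ValueError("need at least one non-missing rating")
    phat = float(np.sum(vals > params.positive_threshold)) / n
    if phat == 0.0:
        return 0.0
    z = params.z
    z2 = z * z
    lower = (
        phat + z2 / (2 * n) - z * math.sqrt(phat * (1 - phat) / n + z2 / (4 * n * n))
    ) / (1 + z2 / n)
    return float(lower)


def _bin_score(raw: float, lo: float, hi: float) -> int:
    """floor(10 * normalized) clamped to 0..10; degenerate range → bin 0."""
    if hi == lo:
        return 0
    b = math.floor(10 * (raw - lo) / (hi - lo))
    return max(0, min(10, b))


def score_layer(
    net: LayeredNetwork,
    layer: str,
    scheme: str = "average",
    params: WilsonParams = WilsonParams(),
) -> list[SimilarityScore]:
    """One similarity score per entity on `layer`, binned against that
    layer's raw-score range and colored white → red.

    Intensity is scored independently per layer: bins on different layers
    are not comparable.
    """
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    if scheme not in ("average", "wilson"):
        raise ValueError(f"unknown scheme {scheme!r}")
    entities = net.entities_on_layer(layer)
    raw: dict[str, float] = {}
    for entity in entities:
        vec = net.values[(layer, entity)]
        if scheme == "average":
            raw[entity] = average_score(vec)
        else:
            raw[entity] = wilson_lower_bound(vec, params)
    if not raw:
        return []
    lo, hi = min(raw.values()), max(raw.values())
    out = []
    for entity in entities:
        b = _bin_score(raw[entity], lo, hi)
        out.append(
            SimilarityScore(
                entity=entity,
                layer=layer,
                scheme=scheme,
                raw_score=raw[entity],
                bin=b,
                color=score_to_color(b),
            )
        )
    return out


def track_entity(net: LayeredNetwork, entity: str) -> pd.DataFrame:
    """Trajectory table for one entity: rows = layers it appears on,
    columns = time points, missing preserved as NaN.

    Feeds the per-entity line chart (one line per layer) used to follow a
    single knockdown/gene through the time course.
    """
    if entity not in net.entities:
        raise ValidationError(f"unknown entity {entity!r}")
    rows = {
        layer: net.values[(layer, entity)]
        for layer in net.layers
        if (layer, entity) in net.values
    }
    if not rows:
        raise ValidationError(f"entity {entity!r} appears on no layer")
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=net.time_points
    )


def plot_track(table: pd.DataFrame, entity: str, path) -> None:
    """Render the trajectory table as a line chart, one line per layer."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(table.shape[1])
    for layer, row in table.iterrows():
        ax.plot(x, row.to_numpy(), marker="o", markersize=3, label=layer)
    ax.set_xticks(x)
    ax.set_xticklabels(table.columns, rotation=90, fontsize=6)
    ax.set_xlabel("time point")
    ax.set_ylabel("value")
    ax.set_title(entity)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
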
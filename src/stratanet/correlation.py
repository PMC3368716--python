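"""Pairwise time-series correlation with small-sample significance rules.

Two routes to significance, both two-sided with df = n - 2:

* Pearson — a pair is significant at level alpha iff |r| reaches the
  product-moment (PMCC) critical value, obtained by exact inversion of the
  Student-t quantile, r_crit = t_crit / sqrt(t_crit^2 + df).  With only
  three time points (df = 1) this demands |r| > 0.997 at alpha = 0.05.
* Spearman — rank correlation assessed through the approximate t statistic
  t = r * sqrt(n - 2) / sqrt(1 - r^2), t ~ Student(df = n - 2) under the
  null.

A pair of entities is a *recurrent* correlation when it tests significant
on at least two layers; per-layer signs are retained because mixed-sign
recurrence (positive on one measurement level, negative on another) is a
biologically meaningful pattern.

Caveat: consecutive time points are not independent samples, so these tests
are a first rough screen for co-varying trajectories, not calibrated
inference; optional Benjamini-Hochberg control over each layer's pair
family is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "ALLOWED_ALPHAS",
    "ConstantVectorError",
    "CorrelationRecord",
    "RecurrentCorrelation",
    "pearson_r",
    "spearman_r",
    "pearson_critical_r",
    "spearman_significance",
    "significant_correlations",
    "recurrent_correlations",
]

logger = logging.getLogger(__name__)

#: significance levels offered for correlation display
ALLOWED_ALPHAS = (0.10, 0.05, 0.02, 0.01)


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant series (zero variance)."""


@dataclass(frozen=True)
class CorrelationRecord:
    """One significant entity-pair correlation on one layer."""

    layer: str
    entity_a: str
    entity_b: str
    method: str  # pearson | spearman
    r: float
    n: int  # paired non-missing time points used
    alpha: float
    significant: bool
    sign: str  # positive | negative


@dataclass(frozen=True)
class RecurrentCorrelation:
    """An entity pair significantly correlated on >= 2 layers."""

    entity_a: str
    entity_b: str
    layers: tuple[str, ...]
    signs: tuple[str, ...]  # per-layer, aligned with `layers`
    consistent_sign: bool


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_r(x, y) -> float:
    """Product-moment correlation over pairwise-complete observations."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError(
            f"need >= 3 paired non-missing time points, have {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError(
            "correlation undefined for a constant series"
        )
    return float(sps.pearsonr(x, y).statistic)


def spearman_r(x, y) -> float:
    """Rank correlation (average ranks for ties), pairwise-complete."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError(
            f"need >= 3 paired non-missing time points, have {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError(
            "correlation undefined for a constant series"
        )
    return float(sps.spearmanr(x, y).statistic)


def pearson_critical_r(n: int, alpha: float) -> float:
    """Minimal |r| two-sided significant at `alpha` for an n-point series.

    Exact inversion of the PMCC critical-value table: with df = n - 2 and
    t_crit the two-sided Student-t critical value,
    ``r_crit = t_crit / sqrt(t_crit^2 + df)``.  Strictly decreasing in n,
    increasing as alpha shrinks; at n = 3, alpha = 0.05 it equals 0.997 to
    three decimals.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 time points, got {n}")
    _check_alpha(alpha)
    df = n - 2
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def spearman_significance(r: float, n: int) -> tuple[float, float]:
    """(t statistic, two-sided p) for a Spearman correlation of n points.

    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)``, approximately Student-t with
    n - 2 degrees of freedom under the null; |r| = 1 maps to p = 0 by
    convention.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 time points, got {n}")
    if abs(r) > 1:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    df = n - 2
    if abs(r) == 1:
        return (np.inf if r > 0 else -np.inf, 0.0)
    t = r * np.sqrt(df) / np.sqrt(1 - r**2)
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def _check_alpha(alpha: float, free: bool = False) -> None:
    if free:
        if not 0 < alpha < 1:
            raise ValueError(f"alpha {alpha} outside (0, 1)")
        return
    if not any(np.isclose(alpha, a) for a in ALLOWED_ALPHAS):
        raise ValueError(
            f"alpha {alpha} not in the offered set {ALLOWED_ALPHAS}"
        )


def _sign(r: float) -> str:
    return "positive" if r >= 0 else "negative"


def significant_correlations(
    net,
    layer: str,
    method: str = "pearson",
    alpha: float = 0.05,
    sign_filter: str = "all",
    alpha_free: bool = False,
    bh: bool = False,
) -> list[CorrelationRecord]:
    """All significant entity-pair correlations on one layer.

    Every unordered pair of entities sharing >= 3 non-missing time points is
    tested.  Pearson pairs are kept when |r| >= the critical value for their
    n; Spearman pairs when the Eq.-t p-value is <= alpha.  Constant-vector
    pairs are skipped (and counted in the log).  ``sign_filter`` in
    {"all", "positive", "negative"} is applied last.  ``bh=True`` replaces
    the per-pair threshold rule with Benjamini-Hochberg control at `alpha`
    over the layer's pair family.
    """
    if layer not in net.layers:
        raise ValueError(f"unknown layer {layer!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if sign_filter not in ("all", "positive", "negative"):
        raise ValueError(f"unknown sign filter {sign_filter!r}")
    _check_alpha(alpha, free=alpha_free)
    entities = net.entities_on_layer(layer)
    skipped_constant = 0
    skipped_short = 0
    tested: list[tuple[str, str, float, int, float]] = []  # a, b, r, n, p
    M = (
        np.array([net.values[(layer, e)] for e in entities])
        if entities
        else np.empty((0, net.n_time_points))
    )
    if entities and not np.isnan(M).any() and M.shape[1] >= 3:
        # complete data: one matrix correlation per layer
        usable = [i for i in range(len(entities)) if np.ptp(M[i]) > 0]
        n_const = len(entities) - len(usable)
        skipped_constant = n_const * (len(entities) - 1) - n_const * (n_const - 1) // 2
        if len(usable) >= 2:
            sub = M[usable]
            if method == "pearson":
                R = np.corrcoef(sub)
            else:
                R = sps.spearmanr(sub.T).statistic
                R = np.atleast_2d(R)
                if R.shape == (1, 1):  # two series collapse to a scalar
                    r01 = float(R[0, 0])
                    R = np.array([[1.0, r01], [r01, 1.0]])
            n_t = M.shape[1]
            for ii, jj in combinations(range(len(usable)), 2):
                a, b = entities[usable[ii]], entities[usable[jj]]
                r = float(np.clip(R[ii, jj], -1.0, 1.0))
                _, p = spearman_significance(r, n_t)
                tested.append((a, b, r, n_t, p))
    else:
        for a, b in combinations(entities, 2):
            x, y = _paired(net.values[(layer, a)], net.values[(layer, b)])
            if x.size < 3:
                skipped_short += 1
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped_constant += 1
                continue
            if method == "pearson":
                r = float(sps.pearsonr(x, y).statistic)
            else:
                r = float(sps.spearmanr(x, y).statistic)
            _, p = spearman_significance(r, x.size)
            tested.append((a, b, r, x.size, p))
    if skipped_constant or skipped_short:
        logger.info(
            "layer %s: skipped %d constant-vector and %d short pairs",
            layer,
            skipped_constant,
            skipped_short,
        )
    if bh:
        keep = _bh_keep([p for *_, p in tested], alpha)
    else:
        keep = []
        for a, b, r, n, p in tested:
            if method == "pearson":
                keep.append(abs(r) >= pearson_critical_r(n, alpha)
                            if not alpha_free
                            else abs(r) >= _critical_free(n, alpha))
            else:
                keep.append(p <= alpha)
    records = [
        CorrelationRecord(
            layer=layer,
            entity_a=a,
            entity_b=b,
            method=method,
            r=r,
            n=n,
            alpha=alpha,
            significant=True,
            sign=_sign(r),
        )
        for (a, b, r, n, p), k in zip(tested, keep)
        if k
    ]
    if sign_filter != "all":
        records = [rec for rec in records if rec.sign == sign_filter]
    return records


def _critical_free(n: int, alpha: float) -> float:
    df = n - 2
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def _bh_keep(pvalues: list[float], alpha: float) -> list[bool]:
    """Benjamini-Hochberg step-up over one family of p-values."""
    m = len(pvalues)
    if m == 0:
        return []
    order = np.argsort(pvalues)
    cutoff = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= alpha * rank / m:
            cutoff = rank
    keep = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= cutoff:
            keep[idx] = True
    return keep


def recurrent_correlations(
    net,
    method: str = "pearson",
    alpha: float = 0.05,
    min_layers: int = 2,
    sign_filter: str = "all",
    alpha_free: bool = False,
) -> list[RecurrentCorrelation]:
    """Entity pairs significantly correlated on at least `min_layers` layers.

    Per-layer signs are retained and may disagree across layers;
    ``sign_filter="positive"`` (or negative) keeps only pairs whose every
    counted layer record has that sign.
    """
    if min_layers < 2:
        raise ValueError("min_layers must be >= 2")
    by_pair: dict[tuple[str, str], list[CorrelationRecord]] = {}
    for layer in net.layers:
        for rec in significant_correlations(
            net, layer, method=method, alpha=alpha, alpha_free=alpha_free
        ):
            key = tuple(sorted((rec.entity_a, rec.entity_b)))
            by_pair.setdefault(key, []).append(rec)
    out: list[RecurrentCorrelation] = []
    for (a, b), recs in sorted(by_pair.items()):
        if len(recs) < min_layers:
            continue
        signs = tuple(rec.sign for rec in recs)
        if sign_filter != "all" and any(s != sign_filter for s in signs):
            continue
        out.append(
            RecurrentCorrelation(
                entity_a=a,
                entity_b=b,
                layers=tuple(rec.layer for rec in recs),
                signs=signs,
                consistent_sign=len(set(signs)) == 1,
            )
        )
    return out
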
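"""Similarity of stiffness distributions and ensemble summaries.

The similarity statistic is the coefficient of determination evaluated
between two equal-length value vectors (here: aligned stiffness histograms),

    R^2 = 1 - sum((y_obs - y_calc)^2) / sum((y_obs - ybar)^2),

with ybar the mean of the *observed* vector.  Note the statistic is not
symmetric in its arguments: by convention the measurement under evaluation
goes in the "observed" slot and the comparator (a second group, a reference
method, a simulation) in the "calculated" slot.  R^2 = 1 iff the vectors are
identical and can be negative for poor matches.

Histograms intended for pairwise comparison must share one binning rule;
:func:`histogram_ensemble` computes Freedman–Diaconis edges on the pooled
data of everything being compared and stamps a fingerprint on each
histogram so mismatched binnings are rejected instead of silently compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stiffness import StiffnessMap

__all__ = [
    "ComparisonResult",
    "StiffnessHistogram",
    "r_squared",
    "freedman_diaconis_edges",
    "stiffness_histogram",
    "histogram_ensemble",
    "pairwise_r2",
    "ensemble_summary",
]


@dataclass
class ComparisonResult:
    r_squared: float
    n: int
    observed_mean: float


@dataclass
class StiffnessHistogram:
    """Histogram of per-pixel stiffness values under a shared binning rule."""

    edges: np.ndarray
    frequencies: np.ndarray
    normalized: bool
    source_id: str = ""
    rule: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if self.edges.size != self.frequencies.size + 1:
            raise ValueError("edges/frequencies size mismatch")
        if self.normalized and self.frequencies.sum() > 0:
            s = self.frequencies.sum()
            if not np.isclose(s, 1.0):
                raise ValueError("normalized histogram must sum to 1")


def r_squared(observed: np.ndarray, calculated: np.ndarray) -> ComparisonResult:
    """Coefficient of determination of ``calculated`` against ``observed``."""
    y = np.asarray(observed, dtype=float).ravel()
    yc = np.asarray(calculated, dtype=float).ravel()
    if y.size != yc.size:
        raise ValueError("observed and calculated must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    ybar = y.mean()
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0:
        raise ValueError("observed vector is constant: zero total variance")
    ss_res = float(np.sum((y - yc) ** 2))
    return ComparisonResult(r_squared=1.0 - ss_res / ss_tot, n=y.size, observed_mean=float(ybar))


def freedman_diaconis_edges(values: np.ndarray, min_bins: int = 4) -> np.ndarray:
    """Freedman–Diaconis bin edges; falls back to sqrt(n) bins for flat IQR."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 2:
        raise ValueError("need at least 2 values to bin")
    lo, hi = float(v[0]), float(v[-1])
    if hi == lo:
        hi = lo + max(abs(lo), 1.0) * 1e-6
        return np.linspace(lo - (hi - lo), hi, min_bins + 1)
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    width = 2.0 * iqr / v.size ** (1.0 / 3.0)
    if width <= 0:
        n_bins = max(int(np.sqrt(v.size)), min_bins)
    else:
        n_bins = max(int(np.ceil((hi - lo) / width)), min_bins)
    return np.linspace(lo, hi, n_bins + 1)


def _values_of(obj) -> np.ndarray:
    if isinstance(obj, StiffnessMap):
        vals = obj.masked_values()
    else:
        vals = np.asarray(obj, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty mask: no values to histogram")
    return vals


def _fingerprint(edges: np.ndarray, normalized: bool) -> str:
    return (
        f"fd|n={edges.size - 1}|lo={edges[0]:.9g}|hi={edges[-1]:.9g}"
        f"|norm={normalized}"
    )


def stiffness_histogram(
    source,
    edges: np.ndarray | None = None,
    normalize: bool = True,
    source_id: str = "",
) -> StiffnessHistogram:
    """Histogram of a stiffness map (masked pixels) or a value vector.

    If ``edges`` is omitted a Freedman–Diaconis rule on this object's own
    values is used; for cross-object comparison compute shared edges first
    (see :func:`histogram_ensemble`).
    """
    vals = _values_of(source)
    if edges is None:
        edges = freedman_diaconis_edges(vals)
    counts, _ = np.histogram(vals, bins=edges)
    freq = counts.astype(float)
    if normalize:
        total = freq.sum()
        if total > 0:
            freq /= total
    return StiffnessHistogram(
        edges=np.asarray(edges, float),
        frequencies=freq,
        normalized=normalize,
        source_id=source_id,
        rule=_fingerprint(np.asarray(edges, float), normalize),
    )


def histogram_ensemble(
    *groups: Sequence,
    normalize: bool = True,
) -> list[list[StiffnessHistogram]]:
    """Histogram several groups of maps under one shared binning rule.

    Edges are Freedman–Diaconis on the pooled values of all groups, so any
    two resulting histograms are comparable bin by bin.
    """
    pooled = np.concatenate([_values_of(m) for g in groups for m in g])
    edges = freedman_diaconis_edges(pooled)
    out = []
    for gi, g in enumerate(groups):
        out.append(
            [
                stiffness_histogram(m, edges=edges, normalize=normalize,
                                    source_id=f"g{gi}_{mi}")
                for mi, m in enumerate(g)
            ]
        )
    return out


def pairwise_r2(
    set_a: Sequence[StiffnessHistogram],
    set_b: Sequence[StiffnessHistogram],
) -> tuple[np.ndarray, float, float]:
    """|set_a| x |set_b| matrix of R² values plus its mean and SD.

    Entry [i, j] treats histogram a_i as observed and b_j as calculated.
    All histograms must share one binning rule.
    """
    if not set_a or not set_b:
        raise ValueError("both histogram sets must be non-empty")
    rule = set_a[0].rule
    for h in list(set_a) + list(set_b):
        if h.rule != rule:
            raise ValueError(
                f"binning mismatch: {h.rule!r} vs {rule!r}; histogram the maps "
                "with shared edges (histogram_ensemble) before comparison"
            )
    mat = np.empty((len(set_a), len(set_b)))
    for i, ha in enumerate(set_a):
        for j, hb in enumerate(set_b):
            mat[i, j] = r_squared(ha.frequencies, hb.frequencies).r_squared
    return mat, float(mat.mean()), float(mat.std(ddof=1)) if mat.size > 1 else 0.0


def ensemble_summary(records: Iterable[Mapping] | pd.DataFrame) -> pd.DataFrame:
    """Per-group mean ± SD of per-object mean stiffness and thickness.

    ``records`` holds one row per object with at least ``group`` and
    ``stiffness`` columns (``thickness`` optional).  Single-object groups
    report SD = 0.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("empty group: nothing to summarize")
    if "group" not in df or "stiffness" not in df:
        raise ValueError("records need 'group' and 'stiffness' fields")
    cols = ["stiffness"] + (["thickness"] if "thickness" in df else [])
    agg = df.groupby("group")[cols].agg(["count", "mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    agg = agg.rename(columns={"stiffness_count": "n"})
    if "thickness_count" in agg:
        agg = agg.drop(columns=["thickness_count"])
    std_cols = [c for c in agg.columns if c.endswith("_std")]
    agg[std_cols] = agg[std_cols].fillna(0.0)
    return agg.reset_index()
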
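"""Nonparametric comparisons of accessibility surfaces.

Kruskal-Wallis across the (service, group) surfaces, Dunn's post-hoc
pairwise tests with Bonferroni adjustment, and Mann-Whitney U for the
drive-versus-transit contrast per surface. Hexagon cells are the
observations; cells with zero accessibility are real low-access
observations and are included. All p-values are two-sided. Cells are
spatially autocorrelated, so these tests overstate effective sample size —
a caveat of the design, documented rather than corrected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .model import AccessibilitySurface

BONFERRONI = "bonferroni"


@dataclass
class GroupComparisonResult:
    """One hypothesis test: statistic, p, optional adjusted p, group sizes."""

    test: str
    statistic: float
    p: float
    groups: list[str]
    ns: list[int]
    p_adjusted: Optional[float] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise DataError(f"p-value {self.p} outside [0, 1]")
        if self.p_adjusted is not None:
            assert self.p_adjusted >= self.p - 1e-12 and self.p_adjusted <= 1.0

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "p": self.p,
             "groups": self.groups, "ns": self.ns}
        if self.p_adjusted is not None:
            d["p_adjusted"] = self.p_adjusted
        if self.direction is not None:
            d["direction"] = self.direction
        return d


def _check_samples(samples: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    if len(samples) < min_groups:
        raise DataError(f"need at least {min_groups} groups, got {len(samples)}")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise DataError(f"group {i} has no observations")
    return arrays


def kruskal_wallis(samples: Sequence[Sequence[float]],
                   labels: Optional[Sequence[str]] = None) -> GroupComparisonResult:
    """Kruskal-Wallis rank test with tie correction; p from chi-square with
    k-1 degrees of freedom. Fully tied data (all values identical) has no
    rank variation and yields H = 0, p = 1."""
    arrays = _check_samples(samples)
    labels = list(labels) if labels else [f"group{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return GroupComparisonResult(test="kruskal_wallis", statistic=float(h),
                                 p=float(p), groups=labels,
                                 ns=[int(a.size) for a in arrays])


def _rank_stats(arrays: list[np.ndarray]):
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start:start + a.size].mean()))
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    return mean_ranks, n_total, tie_term


def dunn_posthoc(samples: Sequence[Sequence[float]],
                 adjust: str = BONFERRONI,
                 labels: Optional[Sequence[str]] = None
                 ) -> list[GroupComparisonResult]:
    """Dunn's pairwise z-tests on mean ranks after a Kruskal-Wallis test.

    z_ab = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b))
    with T the tie term sum(t^3 - t). Bonferroni multiplies each raw p by
    the number of pairs, capped at 1.
    """
    if adjust != BONFERRONI:
        raise DataError(f"unknown adjustment {adjust!r}")
    arrays = _check_samples(samples)
    labels = list(labels) if labels else [f"group{i}" for i in range(len(arrays))]
    mean_ranks, n_total, tie_term = _rank_stats(arrays)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    k = len(arrays)
    m = k * (k - 1) // 2
    results = []
    for a, b in itertools.combinations(range(k), 2):
        se2 = var_base * (1.0 / arrays[a].size + 1.0 / arrays[b].size)
        if se2 <= 0.0:  # fully tied data: no evidence of any difference
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(se2)
            p = 2.0 * sps.norm.sf(abs(z))
        results.append(GroupComparisonResult(
            test="dunn", statistic=float(z), p=float(p),
            p_adjusted=min(1.0, float(p) * m),
            groups=[labels[a], labels[b]],
            ns=[int(arrays[a].size), int(arrays[b].size)],
            direction=(labels[a] if z > 0 else labels[b] if z < 0 else "tie"),
        ))
    return results


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 labels: tuple[str, str] = ("a", "b")) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small samples (both n <= 8); otherwise the
    tie-corrected normal approximation with continuity correction. The
    reported direction is the sample with the larger rank mass (which
    stochastically dominates).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("Mann-Whitney requires two non-empty samples")
    small = x.size <= 8 and y.size <= 8
    method = "exact" if small else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    mid = x.size * y.size / 2.0
    direction = labels[0] if u1 > mid else labels[1] if u1 < mid else "tie"
    return GroupComparisonResult(test="mann_whitney", statistic=u1,
                                 p=float(min(res.pvalue, 1.0)),
                                 groups=list(labels),
                                 ns=[int(x.size), int(y.size)],
                                 direction=direction)


def _surface_values(surf: AccessibilitySurface) -> np.ndarray:
    if surf.A_normalized is None:
        raise DataError("surface has no normalized values; run normalize() first")
    return surf.A_normalized


def _label(key) -> str:
    service, group, mode = key
    return f"{service.value}:{group.value}:{mode}"


def compare_surfaces(surfaces: dict) -> dict:
    """Full comparison report over a dict of surfaces keyed by
    (Service, Group, mode).

    Per mode: one Kruskal-Wallis across the (service, group) surfaces plus
    Dunn's pairwise tests. Per (service, group) present in both modes: one
    Mann-Whitney drive-vs-transit test (surfaces must share the same grid).
    Returns a JSON-ready report with one record per test and per-surface
    summaries (cell-wise mean with a normal-approximation 95% CI).
    """
    report: dict = {"kruskal_wallis": [], "dunn": [], "mann_whitney": [],
                    "summaries": []}
    modes = sorted({k[2] for k in surfaces})
    for mode in modes:
        keys = sorted((k for k in surfaces if k[2] == mode),
                      key=lambda k: (k[0].value, k[1].value))
        if len(keys) >= 2:
            samples = [_surface_values(surfaces[k]) for k in keys]
            labels = [_label(k) for k in keys]
            kw = kruskal_wallis(samples, labels)
            kw_d = kw.to_dict()
            kw_d["mode"] = mode
            report["kruskal_wallis"].append(kw_d)
            for r in dunn_posthoc(samples, labels=labels):
                d = r.to_dict()
                d["mode"] = mode
                report["dunn"].append(d)
    pairs = sorted({(k[0], k[1]) for k in surfaces},
                   key=lambda p: (p[0].value, p[1].value))
    for service, group in pairs:
        kd, kt = (service, group, "drive"), (service, group, "transit")
        if kd in surfaces and kt in surfaces:
            sd, st = surfaces[kd], surfaces[kt]
            if sd.cell_ids != st.cell_ids:
                raise DataError(
                    f"{service.value}/{group.value}: drive and transit surfaces "
                    "are on different grids; mode comparison needs a shared grid")
            mw = mann_whitney(_surface_values(sd), _surface_values(st),
                              labels=(_label(kd), _label(kt)))
            report["mann_whitney"].append(mw.to_dict())
    for k in sorted(surfaces, key=_label):
        v = _surface_values(surfaces[k])
        mean = float(v.mean())
        half = 1.959963984540054 * float(v.std(ddof=1)) / math.sqrt(v.size) if v.size > 1 else 0.0
        report["summaries"].append({
            "surface": _label(k), "n_cells": int(v.size),
            "mean_normalized": mean,
            "ci95": [mean - half, mean + half],
        })
    return report
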
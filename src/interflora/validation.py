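"""Score validation: boundary-pair distributions and module linkage.

Two checks that a high interaction score means what it should:

1. *Boundary pairs.*  Producer--transporter (metabolic--non-metabolic) pairs
   sit at the interface between species; if the score captures interspecific
   interaction, their scores should be stochastically greater than ordinary
   metabolic--metabolic pairs (one-sided two-sample Kolmogorov--Smirnov).

2. *Module linkage.*  Pathway modules are self-contained units of one
   species' metabolism, so intermediate (non-edge) compounds should stay
   within a species while terminal (edge) compounds can link modules across
   species.  Binning pairs by score and comparing the scores of
   edge-compound vs non-edge-compound pairs (one-sided Mann--Whitney, edge
   greater) tests whether high-scoring pairs preferentially connect module
   termini.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pathway_graph import (
    AdjacentPair,
    ModuleDefinition,
    PAIR_CLASS_BOUNDARY,
    PAIR_CLASS_METABOLIC,
    module_edge_lookup,
)
from .scoring import ScoredPair


@dataclass
class DistributionComparison:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    sidedness: str
    group_a: str = ""
    group_b: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "n1": self.n_a,
            "n2": self.n_b,
            "sidedness": self.sidedness,
        }


@dataclass
class WindowedLinkage:
    """Per-score-window counts of module edge- vs non-edge-compound pairs."""

    windows: list[tuple[float, float]]
    edge_counts: list[int]
    non_edge_counts: list[int]
    edge_scores: list[float] = field(default_factory=list)
    non_edge_scores: list[float] = field(default_factory=list)

    @property
    def edge_fraction(self) -> list[float]:
        out = []
        for e, n in zip(self.edge_counts, self.non_edge_counts):
            tot = e + n
            out.append(e / tot if tot else float("nan"))
        return out


def compare_boundary_scores(
    scored: Sequence[ScoredPair], exact: bool = False
) -> DistributionComparison:
    """One-sided KS test: are boundary-pair scores stochastically greater?

    Compares the defined scores of metabolic--non-metabolic pairs against
    metabolic--metabolic pairs.  ``alternative="less"`` on the boundary group
    as first sample asks whether its CDF lies below the metabolic one, i.e.
    whether boundary scores are stochastically greater.
    """
    bnd = [p.score for p in scored if p.defined and p.pair_class == PAIR_CLASS_BOUNDARY]
    met = [p.score for p in scored if p.defined and p.pair_class == PAIR_CLASS_METABOLIC]
    if not bnd:
        raise ValueError(f"no defined pairs in class {PAIR_CLASS_BOUNDARY!r}")
    if not met:
        raise ValueError(f"no defined pairs in class {PAIR_CLASS_METABOLIC!r}")
    method = "exact" if exact else "auto"
    res = stats.ks_2samp(bnd, met, alternative="less", method=method)
    return DistributionComparison(
        test_name="ks_2samp",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(bnd),
        n_b=len(met),
        sidedness="one-sided (boundary greater)",
        group_a=PAIR_CLASS_BOUNDARY,
        group_b=PAIR_CLASS_METABOLIC,
    )


def module_linkage_by_window(
    scored: Sequence[ScoredPair],
    modules: Sequence[ModuleDefinition],
    window_width: float = 0.1,
    score_range: tuple[float, float] = (-1.0, 1.0),
) -> WindowedLinkage:
    """Bin defined pairs by score; count module edge vs non-edge pairs.

    Windows are half-open [lo, hi) of the given width over ``score_range``;
    the last window is closed.  Pairs whose compounds touch no module
    (lookup ``absent``) are excluded.
    """
    if window_width <= 0:
        raise ValueError("window_width must be > 0")
    lo, hi = score_range
    n_win = max(1, int(round((hi - lo) / window_width)))
    windows = [(lo + i * window_width, lo + (i + 1) * window_width) for i in range(n_win)]
    edge_counts = [0] * n_win
    non_edge_counts = [0] * n_win
    edge_scores: list[float] = []
    non_edge_scores: list[float] = []
    for p in scored:
        if not p.defined:
            continue
        kind = module_edge_lookup(
            AdjacentPair(p.ko_a, p.ko_b, compounds=p.compounds, pair_class=p.pair_class), modules
        )
        if kind == "absent":
            continue
        i = int((p.score - lo) / window_width)
        i = min(max(i, 0), n_win - 1)
        if kind == "edge":
            edge_counts[i] += 1
            edge_scores.append(p.score)
        else:
            non_edge_counts[i] += 1
            non_edge_scores.append(p.score)
    return WindowedLinkage(windows, edge_counts, non_edge_counts, edge_scores, non_edge_scores)


def edge_vs_nonedge_test(
    linkage: WindowedLinkage,
    tau: Optional[float] = None,
    alternative: str = "greater",
    by_window_fraction: bool = False,
) -> DistributionComparison:
    """Mann--Whitney rank-sum test of edge- vs non-edge-compound pair scores.

    Default: compare the raw score distributions of the two compound classes,
    one-sided with edge greater.  With ``tau`` given, both classes are
    restricted to scores >= tau.  ``by_window_fraction=True`` instead
    compares the per-window edge fractions of windows below vs at/above tau
    (requires tau).
    """
    if by_window_fraction:
        if tau is None:
            raise ValueError("by_window_fraction requires tau")
        lo_frac = [f for (l, _), f in zip(linkage.windows, linkage.edge_fraction) if l < tau and not np.isnan(f)]
        hi_frac = [f for (l, _), f in zip(linkage.windows, linkage.edge_fraction) if l >= tau and not np.isnan(f)]
        a, b = hi_frac, lo_frac
        label_a, label_b = "windows >= tau", "windows < tau"
    else:
        a = list(linkage.edge_scores)
        b = list(linkage.non_edge_scores)
        if tau is not None:
            a = [s for s in a if s >= tau]
            b = [s for s in b if s >= tau]
        label_a, label_b = "edge", "non_edge"
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"Mann-Whitney needs >= 2 per class; got {label_a}={len(a)}, {label_b}={len(b)}"
        )
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return DistributionComparison(
        test_name="mannwhitneyu",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        sidedness=f"one-sided ({label_a} {alternative})" if alternative != "two-sided" else "two-sided",
        group_a=label_a,
        group_b=label_b,
    )


def write_linkage_tsv(linkage: WindowedLinkage, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["score_lo", "score_hi", "edge_count", "non_edge_count", "edge_fraction"])
        for (lo, hi), e, n, f in zip(
            linkage.windows, linkage.edge_counts, linkage.non_edge_counts, linkage.edge_fraction
        ):
            w.writerow([lo, hi, e, n, f])
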
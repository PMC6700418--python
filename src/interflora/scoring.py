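"""The interspecific interaction score.

For a pathway-adjacent KO pair the score is

    S = D * R

where D is the dissimilarity of the two phylogenetic profiles (default
``(1 - r_phylo) / 2`` with r_phylo the Pearson/phi correlation of the binary
genus-presence vectors, so D is 1 for perfectly complementary distributions
and 0 for identical ones) and R is the correlation of the two co-occurrence
profiles across samples.  High S flags a candidate interaction boundary:
the two functions live in different genera yet rise and fall together across
individuals.  Pairs with S >= 0.6 are treated as highly likely to interact
interspecifically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pathway_graph import AdjacentPair, PAIR_CLASS_UNCLASSIFIED
from .profiles import ProfileSet

logger = logging.getLogger(__name__)

DISSIMILARITY_MODES = ("half_one_minus_r", "one_minus_r", "neg_r")

#: Default interaction-score threshold.
DEFAULT_TAU = 0.6


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector is constant.

    Clipped into [-1, 1] so that numerically exact inputs (identical or
    sign-flipped vectors) give exactly +/-1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.ndim != 1 or xa.size < 2:
        raise ValueError("vectors must be 1-D with length >= 2")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        return math.nan
    r = float(dx @ dy) / math.sqrt(ssx * ssy)
    return min(1.0, max(-1.0, r))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return math.nan
    rho = stats.spearmanr(xa, ya).statistic
    return float(min(1.0, max(-1.0, rho)))


def phylo_dissimilarity(
    pa: Sequence[int], pb: Sequence[int], mode: str = "half_one_minus_r"
) -> float:
    """Dissimilarity of two binary phylogenetic profiles.

    With r the phi (Pearson-on-binary) correlation:
    ``half_one_minus_r``: D = (1 - r)/2, in [0, 1] (default);
    ``one_minus_r``: D = 1 - r; ``neg_r``: D = -r.
    NaN (undefined r, constant profile) propagates.
    """
    if mode not in DISSIMILARITY_MODES:
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    pa = np.asarray(pa)
    pb = np.asarray(pb)
    for v in (pa, pb):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("phylogenetic profiles must be binary (0/1)")
    r = pearson(pa.astype(float), pb.astype(float))
    if math.isnan(r):
        return math.nan
    if mode == "half_one_minus_r":
        return (1.0 - r) / 2.0
    if mode == "one_minus_r":
        return 1.0 - r
    return -r


@dataclass(frozen=True, eq=False)
class ScoredPair:
    """One adjacent KO pair with its interaction score components."""

    ko_a: str
    ko_b: str
    dissimilarity: float  # D
    correlation: float  # R (co-occurrence)
    score: float  # S = D * R
    compounds: frozenset[str] = frozenset()
    pair_class: str = PAIR_CLASS_UNCLASSIFIED
    defined: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return (self.ko_a, self.ko_b)

    def __eq__(self, other: object) -> bool:
        # NaN components (undefined pairs) compare equal so that round-trips
        # through the TSV format preserve equality
        if not isinstance(other, ScoredPair):
            return NotImplemented

        def same(a: float, b: float) -> bool:
            return a == b or (math.isnan(a) and math.isnan(b))

        return (
            self.key == other.key
            and same(self.dissimilarity, other.dissimilarity)
            and same(self.correlation, other.correlation)
            and same(self.score, other.score)
            and self.compounds == other.compounds
            and self.pair_class == other.pair_class
            and self.defined == other.defined
        )

    def __hash__(self) -> int:
        return hash((self.key, self.pair_class, self.defined))


def score_pairs(
    pairs: Sequence[AdjacentPair],
    profiles: ProfileSet,
    mode: str = "half_one_minus_r",
    cooccurrence: str = "pearson",
    sample_indices: Optional[Sequence[int]] = None,
) -> list[ScoredPair]:
    """Score candidate pairs; pairs with a KO absent from the profiles are
    skipped (count logged).  A pair is ``defined=False`` when either
    correlation is undefined (constant profile) — such pairs carry NaN
    components and are excluded from thresholded selections.

    ``sample_indices`` restricts the co-occurrence correlation to a sample
    subset (e.g. one cohort).
    """
    if cooccurrence not in ("pearson", "spearman"):
        raise ValueError(f"unknown co-occurrence estimator {cooccurrence!r}")
    corr = pearson if cooccurrence == "pearson" else spearman
    idx = None if sample_indices is None else np.asarray(sample_indices)
    out: list[ScoredPair] = []
    skipped = 0
    for pair in pairs:
        if pair.ko_a not in profiles or pair.ko_b not in profiles:
            skipped += 1
            continue
        pa = profiles.presence(pair.ko_a)
        pb = profiles.presence(pair.ko_b)
        xa = profiles.abundance(pair.ko_a)
        xb = profiles.abundance(pair.ko_b)
        if idx is not None:
            xa = xa[idx]
            xb = xb[idx]
        d = phylo_dissimilarity(pa, pb, mode=mode)
        r = corr(xa, xb)
        defined = not (math.isnan(d) or math.isnan(r))
        s = d * r if defined else math.nan
        out.append(
            ScoredPair(
                pair.ko_a,
                pair.ko_b,
                dissimilarity=d,
                correlation=r,
                score=s,
                compounds=pair.compounds,
                pair_class=pair.pair_class,
                defined=defined,
            )
        )
    if skipped:
        logger.info("score_pairs: skipped %d pairs with KOs absent from profiles", skipped)
    return out


def select_interacting(
    scored: Sequence[ScoredPair], tau: float = DEFAULT_TAU, inclusive: bool = True
) -> list[ScoredPair]:
    """Defined pairs at or above the score threshold, best first.

    Sorted by descending score, ties broken by the (ko_a, ko_b) key.
    """
    if inclusive:
        keep = [p for p in scored if p.defined and p.score >= tau]
    else:
        keep = [p for p in scored if p.defined and p.score > tau]
    return sorted(keep, key=lambda p: (-p.score, p.ko_a, p.ko_b))


def write_scores_tsv(scored: Sequence[ScoredPair], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["ko_a", "ko_b", "dissimilarity", "correlation", "score", "compounds", "pair_class", "defined"])
        for p in scored:
            w.writerow(
                [p.ko_a, p.ko_b, repr(p.dissimilarity), repr(p.correlation), repr(p.score),
                 ";".join(sorted(p.compounds)), p.pair_class, int(p.defined)]
            )


def read_scores_tsv(path: str | Path) -> list[ScoredPair]:
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ScoredPair(
                    row["ko_a"],
                    row["ko_b"],
                    dissimilarity=float(row["dissimilarity"]),
                    correlation=float(row["correlation"]),
                    score=float(row["score"]),
                    compounds=frozenset(c for c in row["compounds"].split(";") if c),
                    pair_class=row["pair_class"],
                    defined=bool(int(row["defined"])),
                )
            )
    return out
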
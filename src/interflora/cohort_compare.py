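"""Healthy-vs-disease cohort comparison of interaction scores.

Scores are computed per cohort on the same candidate-pair universe; the
pairs defined in both cohorts form a shared table with per-pair score
difference delta = score_healthy - score_disease.  Cohort-specific pairs are
those whose delta lies more than ``k_sd`` standard deviations from the mean
delta *and* whose score in the favoured cohort exceeds the interaction
threshold tau.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import DEFAULT_TAU, ScoredPair


@dataclass
class CohortScoreTable:
    """Shared-pair score table; rows indexed by the canonical pair key."""

    table: pd.DataFrame  # columns: score_healthy, score_disease, delta
    healthy_samples: list[str] = field(default_factory=list)
    disease_samples: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pair_keys(self) -> list[tuple[str, str]]:
        return list(self.table.index)


def shared_pairs(
    scored_healthy: Sequence[ScoredPair],
    scored_disease: Sequence[ScoredPair],
    healthy_samples: Optional[Sequence[str]] = None,
    disease_samples: Optional[Sequence[str]] = None,
) -> CohortScoreTable:
    """Join the two cohorts' defined pairs on the pair key."""
    h = {p.key: p.score for p in scored_healthy if p.defined}
    d = {p.key: p.score for p in scored_disease if p.defined}
    keys = sorted(set(h) & set(d))
    if not keys:
        raise ValueError("no KO pair defined in both cohorts")
    df = pd.DataFrame(
        {
            "score_healthy": [h[k] for k in keys],
            "score_disease": [d[k] for k in keys],
        },
        index=pd.MultiIndex.from_tuples(keys, names=["ko_a", "ko_b"]),
    )
    df["delta"] = df["score_healthy"] - df["score_disease"]
    return CohortScoreTable(
        table=df,
        healthy_samples=list(healthy_samples or []),
        disease_samples=list(disease_samples or []),
    )


def specific_pairs(
    table: CohortScoreTable,
    tau: float = DEFAULT_TAU,
    k_sd: float = 2.0,
    require_other_below: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract cohort-specific pairs by the k-standard-deviation rule.

    With mu, sigma the mean and sample (n-1) standard deviation of delta
    over all shared pairs: healthy-specific pairs satisfy
    delta > mu + k_sd*sigma and score_healthy > tau; disease-specific pairs
    satisfy delta < mu - k_sd*sigma and score_disease > tau.
    ``require_other_below`` additionally demands the unfavoured cohort's
    score be <= tau.
    """
    df = table.table
    if len(df) < 3:
        raise ValueError("need >= 3 shared pairs to estimate the delta spread")
    mu = float(df["delta"].mean())
    sigma = float(df["delta"].std(ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate cohorts: zero variance of score differences")
    healthy_mask = (df["delta"] > mu + k_sd * sigma) & (df["score_healthy"] > tau)
    disease_mask = (df["delta"] < mu - k_sd * sigma) & (df["score_disease"] > tau)
    if require_other_below:
        healthy_mask &= df["score_disease"] <= tau
        disease_mask &= df["score_healthy"] <= tau
    return df[healthy_mask].copy(), df[disease_mask].copy()


def write_cohort_tsv(
    table: CohortScoreTable,
    path: str | Path,
    healthy_specific: Optional[pd.DataFrame] = None,
    disease_specific: Optional[pd.DataFrame] = None,
    compounds: Optional[dict[tuple[str, str], frozenset[str]]] = None,
) -> None:
    """Write the shared-pair table (pair, compounds, scores, delta, class)."""
    h_keys = set(healthy_specific.index) if healthy_specific is not None else set()
    d_keys = set(disease_specific.index) if disease_specific is not None else set()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["ko_a", "ko_b", "compounds", "score_h", "score_d", "delta", "class"])
        for key, row in table.table.iterrows():
            cls = "healthy_specific" if key in h_keys else (
                "disease_specific" if key in d_keys else "shared"
            )
            cpds = ";".join(sorted(compounds.get(key, ()))) if compounds else ""
            w.writerow(
                [key[0], key[1], cpds, repr(row["score_healthy"]), repr(row["score_disease"]),
                 repr(row["delta"]), cls]
            )
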
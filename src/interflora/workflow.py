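"""End-to-end convenience runs over a synthetic or on-disk dataset.

Thin glue over the analysis modules: parse KGML, build the merged network,
enumerate and classify candidate pairs, build profiles and score.  Used by
the examples, the CLI and the acceptance script; each step is equally
callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pathway_graph as pg
from . import profiles as pr
from . import scoring
from .synthdata import SyntheticDataset


@dataclass
class ScoredDataset:
    graph: pg.PathwayGraph
    pairs: list[pg.AdjacentPair]
    profile_set: pr.ProfileSet
    scored: list[scoring.ScoredPair]

    def by_key(self) -> dict[tuple[str, str], scoring.ScoredPair]:
        return {p.key: p for p in self.scored}


def score_dataset(
    dataset: SyntheticDataset,
    mode: str = "half_one_minus_r",
    require_compounds: bool = True,
    sample_indices: Optional[Sequence[int]] = None,
    presence_epsilon: float = 0.0,
) -> ScoredDataset:
    """Run the full candidate-pair scoring pipeline on a synthetic dataset."""
    docs = [pg.parse_kgml(text) for text in dataset.pathway.kgml.values()]
    graph = pg.build_graph(docs)
    pairs = pg.enumerate_pairs(graph, require_compounds=require_compounds)
    pairs = pg.classify_boundary(pairs, graph)
    profile_set = pr.build_profiles(
        dataset.community.ko_by_genus,
        dataset.community.ko_by_sample,
        presence_epsilon=presence_epsilon,
    )
    scored = scoring.score_pairs(
        pairs, profile_set, mode=mode, sample_indices=sample_indices
    )
    return ScoredDataset(graph=graph, pairs=pairs, profile_set=profile_set, scored=scored)


def planted_and_background_scores(
    scored: Sequence[scoring.ScoredPair], truth_keys: set[tuple[str, str]]
) -> tuple[list[float], list[float]]:
    """Split defined scores into planted-pair and background-pair lists."""
    planted, background = [], []
    for p in scored:
        if not p.defined:
            continue
        (planted if p.key in truth_keys else background).append(p.score)
    return planted, background
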
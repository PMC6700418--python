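"""Random-metagenome null models.

To ask whether a real community is *structured* to support interspecific
interactions, its per-donor interaction content is compared against two
nulls drawn from a genome catalog restricted to the community's genera:

* a **random genome set** — genomes combined at random, accepted only when
  the union of their KO repertoires falls inside the observed per-donor
  unique-KO envelope [ko_min, ko_max];
* a **random gene set** — KOs sampled at random from an accepted genome
  set's union, with size drawn from the same envelope.

For each group the number of interacting KO pairs fully contained in the KO
universe is counted and normalised by the number of unique KOs.  A
structured community should beat the genome null, which should beat the
gene null.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoredPair


class RejectionError(RuntimeError):
    """Rejection sampling exhausted without an accepted draw."""


@dataclass(frozen=True)
class Genome:
    genome_id: str
    genus: str
    kos: frozenset[str]

    def __post_init__(self) -> None:
        if not self.kos:
            raise ValueError(f"genome {self.genome_id} has an empty KO set")
        if not self.genus:
            raise ValueError(f"genome {self.genome_id} has an empty genus")


@dataclass
class GenomeCatalog:
    genomes: list[Genome]

    def restrict(self, genus_whitelist: Optional[Iterable[str]]) -> "GenomeCatalog":
        if genus_whitelist is None:
            return self
        allowed = set(genus_whitelist)
        return GenomeCatalog([g for g in self.genomes if g.genus in allowed])

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class SimulationConfig:
    ko_min: int
    ko_max: int
    n_draws: int = 1000
    genus_whitelist: Optional[frozenset[str]] = None
    seed: Optional[int] = None
    max_rejections: int = 10_000

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.ko_min > self.ko_max:
            raise ValueError("ko_min must be <= ko_max")


@dataclass
class NullDraw:
    kind: str  # "genome_set" | "gene_set"
    unique_kos: frozenset[str]
    n_genomes: Optional[int] = None
    n_interacting_pairs: Optional[int] = None
    normalized_count: Optional[float] = None


def draw_genome_set(
    catalog: GenomeCatalog, cfg: SimulationConfig, rng: np.random.Generator
) -> NullDraw:
    """Rejection-sample one random genome set.

    The genome count is uniform on [1, |catalog|]; genomes are drawn without
    replacement (a genus may still contribute several genomes).  A draw is
    accepted iff its union KO count lies in [ko_min, ko_max].
    """
    cat = catalog.restrict(cfg.genus_whitelist)
    n = len(cat)
    if n == 0:
        raise ValueError("empty genome catalog after genus restriction")
    for _ in range(cfg.max_rejections):
        m = int(rng.integers(1, n + 1))
        idx = rng.choice(n, size=m, replace=False)
        union: set[str] = set()
        for i in idx:
            union |= cat.genomes[int(i)].kos
        if cfg.ko_min <= len(union) <= cfg.ko_max:
            return NullDraw(kind="genome_set", unique_kos=frozenset(union), n_genomes=m)
    raise RejectionError(
        f"no genome set with {cfg.ko_min}-{cfg.ko_max} unique KOs found in "
        f"{cfg.max_rejections} attempts; consider widening the KO envelope"
    )


def draw_gene_set(
    genome_draw: NullDraw, cfg: SimulationConfig, rng: np.random.Generator
) -> NullDraw:
    """Sample a random gene (KO) set from an accepted genome set's union.

    The size k is uniform on [ko_min, min(ko_max, |union|)]; KOs are drawn
    without replacement.
    """
    universe = sorted(genome_draw.unique_kos)
    n = len(universe)
    if n < cfg.ko_min:
        raise ValueError(f"genome set has {n} KOs, below ko_min={cfg.ko_min}")
    hi = min(cfg.ko_max, n)
    k = int(rng.integers(cfg.ko_min, hi + 1))
    idx = rng.choice(n, size=k, replace=False)
    return NullDraw(kind="gene_set", unique_kos=frozenset(universe[int(i)] for i in idx))


def count_interactions(
    ko_universe: frozenset[str] | set[str], interacting_pairs: Sequence[ScoredPair]
) -> tuple[int, float]:
    """Count interacting pairs fully inside a KO universe; normalise by size."""
    if not ko_universe:
        raise ValueError("empty KO universe")
    count = sum(1 for p in interacting_pairs if p.ko_a in ko_universe and p.ko_b in ko_universe)
    return count, count / len(ko_universe)


def donor_ko_universes(
    ko_by_sample: pd.DataFrame, epsilon: float = 0.0
) -> dict[str, frozenset[str]]:
    """Per-donor detected-KO sets (abundance > epsilon)."""
    out = {}
    arr = ko_by_sample.to_numpy()
    kos = np.asarray(ko_by_sample.index)
    for j, donor in enumerate(ko_by_sample.columns):
        out[str(donor)] = frozenset(kos[arr[:, j] > epsilon])
    return out


def donor_envelope(universes: Mapping[str, frozenset[str]]) -> tuple[int, int]:
    """Observed per-donor unique-KO envelope (min, max), used as the
    acceptance bounds for null draws."""
    sizes = [len(v) for v in universes.values()]
    return min(sizes), max(sizes)


def run_null_experiment(
    catalog: GenomeCatalog,
    cfg: SimulationConfig,
    interacting_pairs: Sequence[ScoredPair],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[NullDraw], list[NullDraw]]:
    """Draw ``cfg.n_draws`` genome sets and matched gene sets, with
    interaction counts filled in."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome_draws: list[NullDraw] = []
    gene_draws: list[NullDraw] = []
    for _ in range(cfg.n_draws):
        gset = draw_genome_set(catalog, cfg, rng)
        gset.n_interacting_pairs, gset.normalized_count = count_interactions(
            gset.unique_kos, interacting_pairs
        )
        genome_draws.append(gset)
        kset = draw_gene_set(gset, cfg, rng)
        kset.n_interacting_pairs, kset.normalized_count = count_interactions(
            kset.unique_kos, interacting_pairs
        )
        gene_draws.append(kset)
    return genome_draws, gene_draws


def structured_normalized_counts(
    universes: Mapping[str, frozenset[str]], interacting_pairs: Sequence[ScoredPair]
) -> list[float]:
    return [count_interactions(u, interacting_pairs)[1] for u in universes.values()]


@dataclass
class ThreeGroupReport:
    anova_f: float
    anova_p: float
    mw_real_vs_genome: "tuple[float, float]"
    mw_real_vs_gene: "tuple[float, float]"
    mw_genome_vs_gene: "tuple[float, float]"
    mean_real: float
    mean_genome: float
    mean_gene: float
    n_real: int
    n_genome: int
    n_gene: int

    def as_dict(self) -> dict:
        return {
            "anova": {"F": self.anova_f, "p": self.anova_p},
            "mannwhitney_one_sided": {
                "real_gt_genome": {"U": self.mw_real_vs_genome[0], "p": self.mw_real_vs_genome[1]},
                "real_gt_gene": {"U": self.mw_real_vs_gene[0], "p": self.mw_real_vs_gene[1]},
                "genome_gt_gene": {"U": self.mw_genome_vs_gene[0], "p": self.mw_genome_vs_gene[1]},
            },
            "means": {"real": self.mean_real, "genome": self.mean_genome, "gene": self.mean_gene},
            "n": {"real": self.n_real, "genome": self.n_genome, "gene": self.n_gene},
        }


def compare_three_groups(
    real: Sequence[float], genome_null: Sequence[float], gene_null: Sequence[float]
) -> ThreeGroupReport:
    """One-way ANOVA across the three normalised-count samples plus one-sided
    Mann--Whitney tests (real > genome null, real > gene null,
    genome null > gene null)."""
    for name, g in (("real", real), ("genome_null", genome_null), ("gene_null", gene_null)):
        if len(g) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations, got {len(g)}")
    f, p = stats.f_oneway(real, genome_null, gene_null)

    def mw(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
        res = stats.mannwhitneyu(a, b, alternative="greater")
        return float(res.statistic), float(res.pvalue)

    return ThreeGroupReport(
        anova_f=float(f),
        anova_p=float(p),
        mw_real_vs_genome=mw(real, genome_null),
        mw_real_vs_gene=mw(real, gene_null),
        mw_genome_vs_gene=mw(genome_null, gene_null),
        mean_real=float(np.mean(real)),
        mean_genome=float(np.mean(genome_null)),
        mean_gene=float(np.mean(gene_null)),
        n_real=len(real),
        n_genome=len(genome_null),
        n_gene=len(gene_null),
    )


# ---------------------------------------------------------------------------
# I/O

def read_catalog_tsv(path: str | Path) -> GenomeCatalog:
    """Read a long-format catalog TSV (genome_id, genus, ko_id)."""
    kos: dict[str, set[str]] = {}
    genus: dict[str, str] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gid = row["genome_id"]
            if gid not in kos:
                kos[gid] = set()
                genus[gid] = row["genus"]
                order.append(gid)
            kos[gid].add(row["ko_id"])
    return GenomeCatalog([Genome(g, genus[g], frozenset(kos[g])) for g in order])


def write_catalog_tsv(catalog: GenomeCatalog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["genome_id", "genus", "ko_id"])
        for g in catalog.genomes:
            for ko in sorted(g.kos):
                w.writerow([g.genome_id, g.genus, ko])


def write_draws_tsv(draws: Sequence[NullDraw], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["kind", "n_kos", "count", "normalized"])
        for d in draws:
            w.writerow([d.kind, len(d.unique_kos), d.n_interacting_pairs, d.normalized_count])
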
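"""Synthetic microbiome communities with planted interspecific interactions.

Everything the pipeline consumes — KGML pathway maps, module definitions,
KO x genus and KO x sample abundance tables, per-donor tables and a genome
catalog — is generated here from one :class:`CommunitySpec`, with a known
truth list of planted interacting pairs.

The generator emulates the statistical structure the interaction score
assumes: a planted pair's two KOs are distributed over *complementary*
genus blocks (anti-correlated phylogenetic profiles, strength
``complementarity_strength``) while their abundances across samples share a
latent per-sample factor (positive co-occurrence, strength
``cooccurrence_strength``) with multiplicative lognormal noise.  Background
KOs get independent presence and abundance.  Donors are drawn from a few
planted community types (genus subsets) so donor clustering has recoverable
block structure, and per-donor sequencing-depth heterogeneity gives the
per-donor unique-KO counts a non-trivial envelope for the null simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_compare import CohortScoreTable
from .pathway_graph import ModuleDefinition, write_modules_tsv
from .simulation import Genome, GenomeCatalog, write_catalog_tsv


@dataclass(frozen=True)
class PlantedPair:
    ko_a: str
    ko_b: str
    kind: str  # "metabolic" | "boundary"

    @property
    def key(self) -> tuple[str, str]:
        return (self.ko_a, self.ko_b)


@dataclass
class CommunitySpec:
    """Conditions of one synthetic community study.

    Counts and the noise level follow the small-community reference setting;
    coupling strengths interpolate linearly between independence (0) and
    perfect complementarity / co-occurrence (1).
    """

    n_genera: int = 20
    n_kos: int = 300
    n_samples: int = 60
    n_planted_pairs: int = 10
    n_boundary_pairs: int = 3
    background_pair_density: float = 0.02
    noise_sd: float = 0.3
    complementarity_strength: float = 0.9
    cooccurrence_strength: float = 0.9
    # detection / depth model
    detection_prob: float = 0.6
    depth_range: tuple[float, float] = (0.75, 1.25)
    planted_detection_prob: float = 0.9
    # genus content / genome catalog
    genus_ko_density: float = 0.25
    genome_carry_prob: float = 0.7
    genomes_per_genus: tuple[int, int] = (1, 3)
    # donor community structure
    n_community_types: int = 3
    type_genus_prob: float = 0.6
    donor_genus_flip: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("n_genera", "n_kos", "n_samples", "n_planted_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_kos < 4:
            raise ValueError("n_kos must be >= 4")
        for name in ("complementarity_strength", "cooccurrence_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_chain = self.n_kos - self.n_boundary_pairs
        if n_chain < 10 * (self.n_planted_pairs - 1) + 2 + self.n_boundary_pairs:
            raise ValueError("n_kos too small for the requested planted/boundary pairs")


PRESETS: dict[str, CommunitySpec] = {
    "small": CommunitySpec(),
    "medium": CommunitySpec(
        n_genera=40, n_kos=1000, n_samples=150, n_planted_pairs=25, n_boundary_pairs=8
    ),
}


def preset(name: str, seed: Optional[int] = None) -> CommunitySpec:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


# ---------------------------------------------------------------------------
# Pathway generation


@dataclass
class SyntheticPathway:
    kgml: dict[str, str]  # file name -> KGML XML text
    modules: list[ModuleDefinition]
    truth: list[PlantedPair]
    metabolic_kos: list[str]
    transporter_kos: list[str]


def _ko(i: int) -> str:
    return f"K{i:05d}"


def _cpd(i: int) -> str:
    return f"C{i:05d}"


def _kgml_doc(
    map_id: str,
    ortholog_entries: Sequence[tuple[str, Sequence[str]]],
    compound_entries: Sequence[tuple[str, str]],
    map_entries: Sequence[tuple[str, str]],
    relations: Sequence[tuple[str, str, str, Optional[str]]],
) -> str:
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="path:ko{map_id}" org="ko" number="{map_id}" title="synthetic map {map_id}">',
    ]
    for eid, kos in ortholog_entries:
        name = " ".join(f"ko:{k}" for k in kos)
        lines.append(f'  <entry id="{eid}" name="{name}" type="ortholog"/>')
    for eid, cid in compound_entries:
        lines.append(f'  <entry id="{eid}" name="cpd:{cid}" type="compound"/>')
    for eid, target in map_entries:
        lines.append(f'  <entry id="{eid}" name="path:ko{target}" type="map"/>')
    for e1, e2, rtype, cpd_entry in relations:
        lines.append(f'  <relation entry1="{e1}" entry2="{e2}" type="{rtype}">')
        if cpd_entry is not None:
            lines.append(f'    <subtype name="compound" value="{cpd_entry}"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def generate_pathway(
    spec: CommunitySpec, rng: Optional[np.random.Generator] = None
) -> SyntheticPathway:
    """Emit a connected synthetic KO network as valid KGML documents.

    Metabolic KOs form a chain split over two metabolic maps (00010, 00020)
    joined by reciprocal maplink relations through a shared compound; every
    ECrel edge carries a compound entry.  Planted metabolic pairs occupy
    disjoint chain edges.  Each boundary pair links a metabolic producer to
    a transporter KO on the non-metabolic map 02010 through a dedicated
    compound (again via maplink).  Chain compounds are grouped into module
    definitions whose termini are edge compounds and whose interior
    compounds are internal.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_b = spec.n_boundary_pairs
    n_chain = spec.n_kos - n_b
    chain = [_ko(i + 1) for i in range(n_chain)]
    transporters = [_ko(n_chain + j + 1) for j in range(n_b)]

    planted_idx = [(10 * i, 10 * i + 1) for i in range(spec.n_planted_pairs)]
    planted_members = {i for ab in planted_idx for i in ab}

    split = n_chain // 2
    if (split - 1, split) in planted_idx:
        split += 1

    next_cpd = 1
    chain_compounds: list[str] = []
    for _ in range(n_chain - 1):
        chain_compounds.append(_cpd(next_cpd))
        next_cpd += 1
    boundary_compounds = []
    for _ in range(n_b):
        boundary_compounds.append(_cpd(next_cpd))
        next_cpd += 1

    # producers: chain KOs not in planted metabolic pairs, evenly spaced
    candidates = [i for i in range(n_chain) if i not in planted_members]
    if n_b > 0:
        step = max(1, len(candidates) // max(n_b, 1))
        producer_idx = [candidates[(i * step + 3) % len(candidates)] for i in range(n_b)]
        # ensure distinct
        seen: set[int] = set()
        fixed = []
        pool = iter(c for c in candidates if c not in producer_idx)
        for p in producer_idx:
            if p in seen:
                p = next(pool)
            seen.add(p)
            fixed.append(p)
        producer_idx = fixed
    else:
        producer_idx = []

    truth = [
        PlantedPair(*sorted((chain[a], chain[b])), kind="metabolic") for a, b in planted_idx
    ]
    for j, p in enumerate(producer_idx):
        truth.append(PlantedPair(*sorted((chain[p], transporters[j])), kind="boundary"))

    # extra background edges inside each map half
    n_extra = int(spec.background_pair_density * n_chain)
    extra_edges: list[tuple[int, int, str]] = []
    chain_set = {tuple(sorted(e)) for e in zip(range(n_chain - 1), range(1, n_chain))}
    attempts = 0
    while len(extra_edges) < n_extra and attempts < 50 * max(n_extra, 1):
        attempts += 1
        half = rng.integers(0, 2)
        lo, hi = (0, split) if half == 0 else (split, n_chain)
        if hi - lo < 3:
            continue
        i, j = sorted(rng.choice(np.arange(lo, hi), size=2, replace=False).tolist())
        if (i, j) in chain_set or i == j:
            continue
        chain_set.add((i, j))
        extra_edges.append((i, j, _cpd(next_cpd)))
        next_cpd += 1

    def build_map(map_id: str, lo: int, hi: int, other_map: str, link_out: bool) -> str:
        kos = chain[lo:hi]
        eid = {}
        orthologs = []
        for t, ko in enumerate(kos):
            eid[ko] = str(t + 1)
            orthologs.append((eid[ko], [ko]))
        next_eid = len(kos) + 1
        compounds = []
        relations = []

        def add_compound(cid: str) -> str:
            nonlocal next_eid
            e = str(next_eid)
            next_eid += 1
            compounds.append((e, cid))
            return e

        map_ents = []

        def add_map_entry(target: str) -> str:
            nonlocal next_eid
            e = str(next_eid)
            next_eid += 1
            map_ents.append((e, target))
            return e

        # intra-map chain edges
        for i in range(lo, hi - 1):
            ce = add_compound(chain_compounds[i])
            relations.append((eid[chain[i]], eid[chain[i + 1]], "ECrel", ce))
        # extra background edges inside this half
        for i, j, cid in extra_edges:
            if lo <= i < hi and lo <= j < hi:
                ce = add_compound(cid)
                relations.append((eid[chain[i]], eid[chain[j]], "ECrel", ce))
        # chain-splitting maplink towards the other metabolic map
        link_cpd = chain_compounds[split - 1]
        if link_out and hi == split:  # first half links via its last KO
            ce = add_compound(link_cpd)
            me = add_map_entry(other_map)
            relations.append((eid[chain[split - 1]], me, "maplink", ce))
        if not link_out and lo == split:  # second half links via its first KO
            ce = add_compound(link_cpd)
            me = add_map_entry(other_map)
            relations.append((eid[chain[split]], me, "maplink", ce))
        # boundary maplinks from producers on this map towards 02010
        for j, p in enumerate(producer_idx):
            if lo <= p < hi:
                ce = add_compound(boundary_compounds[j])
                me = add_map_entry("02010")
                relations.append((eid[chain[p]], me, "maplink", ce))
        return _kgml_doc(map_id, orthologs, compounds, map_ents, relations)

    kgml = {
        "ko00010.xml": build_map("00010", 0, split, "00020", link_out=True),
        "ko00020.xml": build_map("00020", split, n_chain, "00010", link_out=False),
    }

    # non-metabolic transporter map
    orthologs = [(str(j + 1), [t]) for j, t in enumerate(transporters)]
    next_eid = len(transporters) + 1
    compounds = []
    map_ents = []
    relations = []
    for j, p in enumerate(producer_idx):
        ce = str(next_eid)
        next_eid += 1
        compounds.append((ce, boundary_compounds[j]))
        target = "00010" if p < split else "00020"
        me = str(next_eid)
        next_eid += 1
        map_ents.append((me, target))
        relations.append((str(j + 1), me, "maplink", ce))
    kgml["ko02010.xml"] = _kgml_doc("02010", orthologs, compounds, map_ents, relations)

    # modules over consecutive chain compounds; block length 5 puts planted
    # chain edges (every 10th compound) at module termini, so planted
    # interspecific handoffs occur at module boundaries by construction
    modules = []
    block = 5
    for m, start in enumerate(range(0, len(chain_compounds) - 1, block)):
        cpds = chain_compounds[start : start + block]
        if len(cpds) < 3:
            continue
        modules.append(
            ModuleDefinition(
                module_id=f"M{m + 1:05d}",
                edge_compounds=frozenset({cpds[0], cpds[-1]}),
                internal_compounds=frozenset(cpds[1:-1]),
            )
        )

    return SyntheticPathway(
        kgml=kgml,
        modules=modules,
        truth=truth,
        metabolic_kos=chain,
        transporter_kos=transporters,
    )


# ---------------------------------------------------------------------------
# Community generation


@dataclass
class SyntheticCommunity:
    ko_by_genus: pd.DataFrame
    ko_by_sample: pd.DataFrame
    donor_tables: dict[str, pd.DataFrame]
    donor_types: dict[str, int]
    catalog: GenomeCatalog
    truth: list[PlantedPair]


@dataclass
class SyntheticDataset:
    spec: CommunitySpec
    pathway: SyntheticPathway
    community: SyntheticCommunity

    @property
    def truth(self) -> list[PlantedPair]:
        return self.pathway.truth


def generate_community(
    spec: CommunitySpec,
    pathway: SyntheticPathway,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticCommunity:
    """Generate abundance tables, donor tables and a genome catalog with the
    pathway's planted pairs coupled at the spec's strengths.

    Planted pairs: genus presence on complementary balanced blocks with
    per-genus flip probability ``(1 - complementarity)/2``; shared
    per-sample detection (probability ``planted_detection_prob``) and a
    shared lognormal latent factor mixed at weight ``cooccurrence_strength``
    with independent factors, times ``exp(noise_sd * eps)`` noise.  In the
    noiseless, fully coupled limit the pair's presence vectors are exact
    complements and its abundance vectors are identical.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    kos = pathway.metabolic_kos + pathway.transporter_kos
    n_kos = len(kos)
    genera = [f"g{i + 1:03d}" for i in range(spec.n_genera)]
    samples = [f"d{i + 1:03d}" for i in range(spec.n_samples)]
    ko_index = {k: i for i, k in enumerate(kos)}
    planted = pathway.truth
    planted_members = {k for p in planted for k in p.key}

    # --- genus presence -----------------------------------------------------
    presence = (rng.random((n_kos, spec.n_genera)) < spec.genus_ko_density).astype(np.int8)
    flip_p = (1.0 - spec.complementarity_strength) / 2.0
    half = spec.n_genera // 2
    for pair in planted:
        perm = rng.permutation(spec.n_genera)
        z = np.zeros(spec.n_genera, dtype=np.int8)
        z[perm[:half]] = 1
        flips_a = (rng.random(spec.n_genera) < flip_p).astype(np.int8)
        flips_b = (rng.random(spec.n_genera) < flip_p).astype(np.int8)
        presence[ko_index[pair.ko_a]] = z ^ flips_a
        presence[ko_index[pair.ko_b]] = (1 - z) ^ flips_b

    genus_scale = np.exp(rng.normal(0.0, 0.5, size=(n_kos, spec.n_genera)))
    ko_by_genus = pd.DataFrame(presence * genus_scale, index=kos, columns=genera)
    ko_by_genus.index.name = "ko"

    # --- sample abundance ---------------------------------------------------
    abundance = np.zeros((n_kos, spec.n_samples))
    depth = spec.detection_prob * rng.uniform(*spec.depth_range, size=spec.n_samples)
    depth = np.clip(depth, 0.01, 0.99)
    w = spec.cooccurrence_strength
    for pair in planted:
        z_d = (rng.random(spec.n_samples) < spec.planted_detection_prob).astype(float)
        logf = rng.normal(0.0, 1.0, spec.n_samples)
        for ko in pair.key:
            u = rng.normal(0.0, 1.0, spec.n_samples)
            eps = rng.normal(0.0, 1.0, spec.n_samples)
            la = w * logf + (1.0 - w) * u + spec.noise_sd * eps
            abundance[ko_index[ko]] = z_d * np.exp(la)
    for ko in kos:
        if ko in planted_members:
            continue
        det = (rng.random(spec.n_samples) < depth).astype(float)
        abundance[ko_index[ko]] = det * np.exp(rng.normal(0.0, 1.0, spec.n_samples))
    ko_by_sample = pd.DataFrame(abundance, index=kos, columns=samples)
    ko_by_sample.index.name = "ko"

    # --- donor community types and per-donor tables -------------------------
    type_masks = (rng.random((spec.n_community_types, spec.n_genera)) < spec.type_genus_prob)
    for t in range(spec.n_community_types):
        if not type_masks[t].any():
            type_masks[t, int(rng.integers(spec.n_genera))] = True
    donor_types = {d: i % spec.n_community_types for i, d in enumerate(samples)}
    donor_tables = {}
    for d in samples:
        mask = type_masks[donor_types[d]].copy()
        flips = rng.random(spec.n_genera) < spec.donor_genus_flip
        mask = mask ^ flips
        donor_tables[d] = ko_by_genus * mask[np.newaxis, :]

    # --- genome catalog ------------------------------------------------------
    genomes = []
    lo, hi = spec.genomes_per_genus
    for gi, genus in enumerate(genera):
        genus_kos = [kos[i] for i in range(n_kos) if presence[i, gi]]
        if not genus_kos:
            continue
        for t in range(int(rng.integers(lo, hi + 1))):
            carry = rng.random(len(genus_kos)) < spec.genome_carry_prob
            gset = frozenset(k for k, c in zip(genus_kos, carry) if c)
            if not gset:
                gset = frozenset({genus_kos[int(rng.integers(len(genus_kos)))]})
            genomes.append(Genome(f"{genus}.{t + 1}", genus, gset))
    catalog = GenomeCatalog(genomes)

    return SyntheticCommunity(
        ko_by_genus=ko_by_genus,
        ko_by_sample=ko_by_sample,
        donor_tables=donor_tables,
        donor_types=donor_types,
        catalog=catalog,
        truth=list(planted),
    )


def generate_dataset(
    spec: CommunitySpec, rng: Optional[np.random.Generator] = None
) -> SyntheticDataset:
    """Generate a full synthetic study: pathway + community from one RNG."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pathway = generate_pathway(spec, rng)
    community = generate_community(spec, pathway, rng)
    return SyntheticDataset(spec=spec, pathway=pathway, community=community)


# ---------------------------------------------------------------------------
# Cohort-table generator (for the two-standard-deviation rule)


def generate_cohort_pairs(
    n_pairs: int = 1000,
    n_planted: int = 10,
    rng: Optional[np.random.Generator] = None,
    base_sigma: float = 0.05,
) -> tuple[CohortScoreTable, set[tuple[str, str]]]:
    """Synthetic shared-pair cohort table with planted healthy-specific pairs.

    Background score differences are drawn from a clipped normal
    (|delta| <= 1.5 * base_sigma) so they stay inside the 2-sigma band;
    planted pairs get delta = 4 * base_sigma (>= 3 sigma of the full set)
    and a favoured healthy score above the interaction threshold.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_planted >= n_pairs:
        raise ValueError("n_planted must be < n_pairs")
    keys = [(_ko(2 * i + 1), _ko(2 * i + 2)) for i in range(n_pairs)]
    planted_pos = rng.choice(n_pairs, size=n_planted, replace=False)
    planted_keys = {keys[int(i)] for i in planted_pos}
    score_h = rng.uniform(0.05, 0.55, n_pairs)
    delta = np.clip(rng.normal(0.0, base_sigma, n_pairs), -1.5 * base_sigma, 1.5 * base_sigma)
    score_h[planted_pos] = rng.uniform(0.7, 0.95, n_planted)
    delta[planted_pos] = 4.0 * base_sigma
    score_d = score_h - delta
    df = pd.DataFrame(
        {"score_healthy": score_h, "score_disease": score_d},
        index=pd.MultiIndex.from_tuples(keys, names=["ko_a", "ko_b"]),
    )
    df["delta"] = df["score_healthy"] - df["score_disease"]
    return CohortScoreTable(table=df), planted_keys


# ---------------------------------------------------------------------------
# Writing a dataset to disk in the formats the pipeline reads


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    (out / "kgml").mkdir(parents=True, exist_ok=True)
    for name, text in dataset.pathway.kgml.items():
        (out / "kgml" / name).write_text(text)
    write_modules_tsv(dataset.pathway.modules, out / "modules.tsv")
    dataset.community.ko_by_genus.to_csv(out / "ko_by_genus.tsv", sep="\t")
    dataset.community.ko_by_sample.to_csv(out / "ko_by_sample.tsv", sep="\t")
    donors = out / "donors"
    donors.mkdir(exist_ok=True)
    for d, table in dataset.community.donor_tables.items():
        table.to_csv(donors / f"{d}.tsv", sep="\t")
    write_catalog_tsv(dataset.community.catalog, out / "catalog.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("ko_a\tko_b\tkind\n")
        for p in dataset.truth:
            fh.write(f"{p.ko_a}\t{p.ko_b}\t{p.kind}\n")
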
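"""Gene-family construction by single-linkage clustering of homology hits.

A gene family is operationally a connected component of the graph whose
nodes are sequences and whose edges are homology hits surviving the
E-value / identity / match-length filters.  Families are then screened by
a species-composition rule chosen so that a family can, in principle,
inform the polyploidy-timing hypotheses: at least one *Chamaecrista*, two
*Glycine*, one *Medicago* and one *Vitis* member, and no more than 100
sequences in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import DEFAULT_SPECIES_MAP, HomologyHit, SpeciesMap

log = logging.getLogger("wgdtiming")


@dataclass(frozen=True)
class ClusterThresholds:
    """Hit-retention thresholds (all boundaries inclusive for retention)."""

    max_evalue: float = 1e-10
    min_pct_identity: float = 50.0
    min_match_nt: int = 180  # 60 aa

    def __post_init__(self):
        if self.max_evalue <= 0 or self.min_pct_identity <= 0 or self.min_match_nt <= 0:
            raise ValueError("cluster thresholds must be strictly positive")


@dataclass(frozen=True)
class CompositionFilter:
    """Per-species minimum counts and a total-size cap for retained families."""

    min_per_species: Mapping[str, int] = field(
        default_factory=lambda: {"C": 1, "G": 2, "M": 1, "V": 1}
    )
    max_total: int = 100

    def __post_init__(self):
        if any(v < 0 for v in self.min_per_species.values()):
            raise ValueError("per-species minima must be >= 0")
        if self.max_total < sum(self.min_per_species.values()):
            raise ValueError("max_total smaller than the sum of per-species minima")

    def accepts(self, species_counts: Mapping[str, int]) -> bool:
        total = sum(species_counts.values())
        return total <= self.max_total and all(
            species_counts.get(sp, 0) >= lo for sp, lo in self.min_per_species.items()
        )


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    member_ids: frozenset[str]
    species_counts: Mapping[str, int]


def dedupe_hits(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Reduce multiple HSP rows to the single best hit per ordered pair.

    Best = lowest E-value, ties broken by higher identity, then longer
    match, so the reduction is deterministic regardless of row order.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (h.evalue, -h.pct_identity, -h.match_length_nt) < (
            prev.evalue, -prev.pct_identity, -prev.match_length_nt
        ):
            best[key] = h
    return list(best.values())


def filter_hits(
    hits: Iterable[HomologyHit], thresholds: ClusterThresholds | None = None
) -> list[HomologyHit]:
    """Retain hits with evalue <= max, identity >= min and length >= min."""
    th = thresholds or ClusterThresholds()
    hits = list(hits)
    kept = [
        h
        for h in hits
        if h.evalue <= th.max_evalue
        and h.pct_identity >= th.min_pct_identity
        and h.match_length_nt >= th.min_match_nt
    ]
    log.info("filter_hits: %d -> %d hits", len(hits), len(kept))
    return kept


def single_linkage(
    hits: Iterable[HomologyHit],
    universe: Iterable[str],
    species_map: SpeciesMap | None = None,
) -> list[GeneFamily]:
    """Connected components of the (undirected) hit graph over ``universe``.

    Sequences never appearing in a hit become singleton families.  Family
    ids are ``fam`` + the zero-padded rank of the family's lexicographically
    smallest member, so output is reproducible.
    """
    smap = species_map or DEFAULT_SPECIES_MAP
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for h in hits:
        if h.query_id in graph and h.subject_id in graph:
            graph.add_edge(h.query_id, h.subject_id)
    components = sorted(nx.connected_components(graph), key=min)
    width = max(4, len(str(len(components))))
    families = []
    for rank, members in enumerate(components, start=1):
        counts: dict[str, int] = {}
        for m in members:
            counts[smap.species(m)] = counts.get(smap.species(m), 0) + 1
        families.append(
            GeneFamily(f"fam{rank:0{width}d}", frozenset(members), counts)
        )
    log.info(
        "single_linkage: %d sequences -> %d families", graph.number_of_nodes(), len(families)
    )
    return families


def composition_filter(
    families: Iterable[GeneFamily], comp: CompositionFilter | None = None
) -> list[GeneFamily]:
    comp = comp or CompositionFilter()
    families = list(families)
    kept = [f for f in families if comp.accepts(f.species_counts)]
    log.info("composition_filter: %d -> %d families", len(families), len(kept))
    return kept


def write_families(
    families: Iterable[GeneFamily], path, species_map: SpeciesMap | None = None
) -> None:
    """Write one row per family member: family_id, member_id, species."""
    smap = species_map or DEFAULT_SPECIES_MAP
    with open(path, "w") as fh:
        fh.write("family_id\tmember_id\tspecies\n")
        for fam in sorted(families, key=lambda f: f.family_id):
            for member in sorted(fam.member_ids):
                fh.write(f"{fam.family_id}\t{member}\t{smap.try_species(member) or '?'}\n")
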
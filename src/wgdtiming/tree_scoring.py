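"""Scoring gene-tree topologies against four polyploidy-timing hypotheses.

The question is when the early legume whole-genome duplication (WGD)
happened relative to the split between *Chamaecrista* (mimosoid clade)
and the papilionoids (*Glycine*, *Medicago*), and whether *Chamaecrista*
had its own independent WGD.  Each combination is a hypothesis with an
expected loss-free gene-tree shape, written as a species-coded pattern:

* H1a — WGD after the split, no Cf WGD: ``((((G,G),M),((G,G),M)),C)``
* H1b — WGD after the split, plus Cf WGD: the C leaf becomes ``(C,C)``
* H2a — WGD before the split: ``((((G,G),M),C),(((G,G),M),C))``
* H2b — WGD before the split, plus Cf WGD: each C becomes ``(C,C)``

All four contain the ``(G,G)`` cherries of the much more recent *Glycine*
duplication.  Real gene trees rarely show the full pattern because of
gene loss and non-recovery, so each hypothesis is expanded into the set
of *deletion variants* — the canonical topologies obtained by removing a
bounded number of leaves.  An observed clade matches a hypothesis when
its canonical string equals one of that hypothesis's variants; matching
is at minimal loss count, and ties across hypotheses are reported as
ambiguous rather than resolved.

Canonicalization replaces leaf names by species letters and sorts the
children of every node deterministically, so any rotation of the same
topology yields the same string (``(M,(G,G))`` and ``((G,G),M)`` count as
one pattern).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

from .io import DEFAULT_SPECIES_MAP, GeneTree, SpeciesMap

log = logging.getLogger("wgdtiming")

LEGUME_SPECIES = frozenset({"C", "G", "M"})

Pattern = tuple | str  # nested tuples of species letters; a leaf is a letter


@dataclass(frozen=True)
class HypothesisModel:
    """One timing hypothesis with its loss-free expected topology."""

    name: str
    pattern: tuple
    wgd_before_cf_split: bool
    cf_wgd: bool

    @property
    def canonical_pattern(self) -> str:
        return pattern_string(self.pattern)

    @property
    def n_leaves(self) -> int:
        return len(pattern_leaves(self.pattern))


_GGM = (("G", "G"), "M")

MODELS: Mapping[str, HypothesisModel] = {
    "H1a": HypothesisModel("H1a", ((_GGM, _GGM), "C"), False, False),
    "H1b": HypothesisModel("H1b", ((_GGM, _GGM), ("C", "C")), False, True),
    "H2a": HypothesisModel("H2a", ((_GGM, "C"), (_GGM, "C")), True, False),
    "H2b": HypothesisModel("H2b", ((_GGM, ("C", "C")), (_GGM, ("C", "C"))), True, True),
}
MODEL_ORDER = ("H1a", "H1b", "H2a", "H2b")


# ---------------------------------------------------------------------------
# canonical form


def _sort_key(s: str) -> tuple:
    # clades sort before leaves, then shorter before longer, then lexicographic
    return (0 if s.startswith("(") else 1, len(s), s)


def pattern_string(pattern: Pattern) -> str:
    """Canonical parenthesized string for a nested species pattern."""
    if isinstance(pattern, str):
        return pattern
    parts = sorted((pattern_string(c) for c in pattern), key=_sort_key)
    return "(" + ",".join(parts) + ")"


def pattern_leaves(pattern: Pattern) -> list[str]:
    if isinstance(pattern, str):
        return [pattern]
    return [leaf for child in pattern for leaf in pattern_leaves(child)]


def node_pattern(node: dendropy.Node, species_map: SpeciesMap | None = None) -> Pattern:
    """Species-coded nested pattern of a (sub)tree node."""
    smap = species_map or DEFAULT_SPECIES_MAP
    if node.is_leaf():
        return smap.species(node.taxon.label)
    return tuple(node_pattern(c, smap) for c in node.child_nodes())


def canonicalize(obj, species_map: SpeciesMap | None = None) -> str:
    """Canonical topology string of a tree, clade node or nested pattern.

    Equal topologies (up to child rotation and leaf naming within a
    species) map to equal strings; the function is idempotent on its own
    output's parsed pattern.
    """
    if isinstance(obj, dendropy.Tree):
        return pattern_string(node_pattern(obj.seed_node, species_map))
    if isinstance(obj, dendropy.Node):
        return pattern_string(node_pattern(obj, species_map))
    return pattern_string(obj)


# ---------------------------------------------------------------------------
# deletion variants


def published_loss_budget(model: HypothesisModel) -> dict[str, int]:
    """Published per-species loss maxima: <=2 G and <=1 M for every model,
    plus <=1 C when the early WGD precedes the *Chamaecrista* split."""
    return {"G": 2, "M": 1, "C": 1 if model.wgd_before_cf_split else 0, "V": 0}


def generic_loss_budget(max_losses: int) -> dict[str, int]:
    """Any-species budget: up to ``max_losses`` leaves of any one species."""
    return {sp: max_losses for sp in ("C", "G", "M", "V")}


def _without_leaves(pattern: Pattern, drop: frozenset[int]) -> Pattern | None:
    counter = itertools.count()

    def rec(p: Pattern) -> Pattern | None:
        if isinstance(p, str):
            return None if next(counter) in drop else p
        kids = [k for k in (rec(c) for c in p) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # suppress the degree-2 node left by the deletion
            return kids[0]
        return tuple(kids)

    return rec(pattern)


@dataclass(frozen=True)
class PatternVariantSet:
    """Canonical deletion variants of one hypothesis, keyed by loss count."""

    model: HypothesisModel
    variants: Mapping[int, frozenset[str]]
    budget: Mapping[str, int]

    def max_losses(self) -> int:
        return max(self.variants)


def enumerate_variants(
    model: HypothesisModel,
    max_losses: int = 3,
    budget: Mapping[str, int] | None = None,
) -> PatternVariantSet:
    """All canonical topologies reachable by deleting up to ``max_losses``
    leaves from the hypothesis pattern.

    Deletions respect the per-species ``budget`` (the published budget by
    default) and a variant must retain at least one C leaf — a clade with
    no *Chamaecrista* sequence cannot speak to the timing question.
    Degree-2 nodes left by a deletion are suppressed and variants are
    deduplicated by canonical string.
    """
    if max_losses < 0:
        raise ValueError("max_losses must be >= 0")
    if budget is None:
        budget = published_loss_budget(model)
    leaves = pattern_leaves(model.pattern)
    total_c = leaves.count("C")
    variants: dict[int, frozenset[str]] = {}
    for j in range(max_losses + 1):
        strings: set[str] = set()
        for combo in itertools.combinations(range(len(leaves)), j):
            dropped = Counter(leaves[i] for i in combo)
            if any(dropped[sp] > budget.get(sp, 0) for sp in dropped):
                continue
            if total_c - dropped["C"] == 0:
                continue
            reduced = _without_leaves(model.pattern, frozenset(combo))
            if reduced is None:
                continue
            strings.add(pattern_string(reduced))
        variants[j] = frozenset(strings)
    return PatternVariantSet(model, variants, dict(budget))


def build_variant_sets(
    models: Iterable[str] = MODEL_ORDER,
    max_losses: int = 3,
    budget: str = "published",
) -> dict[str, PatternVariantSet]:
    """Variant sets for several models under the 'published' or 'generic' budget."""
    out = {}
    for name in models:
        model = MODELS[name]
        b = published_loss_budget(model) if budget == "published" else generic_loss_budget(max_losses)
        out[name] = enumerate_variants(model, max_losses, b)
    return out


# ---------------------------------------------------------------------------
# tree handling


def root_on_vitis(
    tree: GeneTree, species_map: SpeciesMap | None = None
) -> GeneTree | None:
    """Root a gene tree on its lexicographically smallest *Vitis* leaf.

    Returns a stripped copy (no branch lengths, no support labels) rooted
    so that the chosen V leaf is the outgroup, or ``None`` when the tree
    has no V leaf (the family is then unscorable, not an error).  The
    smallest-label choice makes the published "arbitrarily chosen"
    outgroup deterministic; alternate rootings are not retried.
    """
    smap = species_map or DEFAULT_SPECIES_MAP
    t = tree.clone(depth=1)
    v_leaves = [
        lf for lf in t.leaf_node_iter() if smap.try_species(lf.taxon.label) == "V"
    ]
    if not v_leaves:
        return None
    outgroup = min(v_leaves, key=lambda lf: lf.taxon.label)
    t.is_rooted = True
    if outgroup.edge.length is None:
        # reroot_at_edge needs a length to split; topology-only trees get 1.0
        for nd in t.preorder_node_iter():
            if nd.edge.length is None:
                nd.edge.length = 1.0
    t.reroot_at_edge(outgroup.edge, update_bipartitions=False)
    t.suppress_unifurcations()
    for nd in t.preorder_node_iter():
        nd.edge.length = None
        if not nd.is_leaf():
            nd.label = None
    return t


def extract_legume_clades(
    tree: GeneTree, species_map: SpeciesMap | None = None
) -> list[dendropy.Node]:
    """Maximal clades containing only legume (C/G/M) leaves.

    A node qualifies when its leaf set has no V and its parent's does (or
    it is the root); these are the units scored against the hypothesis
    patterns — a tree with several V-separated legume clades contributes
    several scorable clades.
    """
    smap = species_map or DEFAULT_SPECIES_MAP
    spset: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            spset[nd] = frozenset({smap.species(nd.taxon.label)})
        else:
            s: set[str] = set()
            for c in nd.child_nodes():
                s |= spset[c]
            spset[nd] = frozenset(s)
    clades = []
    for nd in tree.preorder_node_iter():
        if not spset[nd] or not spset[nd] <= LEGUME_SPECIES:
            continue
        parent = nd.parent_node
        if parent is None or not spset[parent] <= LEGUME_SPECIES:
            clades.append(nd)
    return clades


# ---------------------------------------------------------------------------
# matching and counting


@dataclass(frozen=True)
class ScoreRecord:
    """The outcome of matching one legume clade against the variant sets."""

    family_id: str
    clade_index: int
    matched_model: str  # H1a/H1b/H2a/H2b, "none", or "ambiguous"
    loss_count: int | None
    observed_pattern: str
    tied_models: tuple[str, ...] = ()


def match_clade(
    clade,
    variant_sets: Mapping[str, PatternVariantSet],
    species_map: SpeciesMap | None = None,
    family_id: str = "",
    clade_index: int = 0,
) -> ScoreRecord:
    """Match a clade (node, pattern or canonical string) at minimal loss.

    The unique model matching at the smallest loss count wins; a tie
    between models at that count is "ambiguous" (excluded from model
    counts but reported); no match within the enumerated loss range is
    "none".  Clades with extra duplications beyond the four models can
    never match, since no variant contains them.
    """
    observed = clade if isinstance(clade, str) else canonicalize(clade, species_map)
    all_losses = sorted({j for vs in variant_sets.values() for j in vs.variants})
    for j in all_losses:
        matched = [
            name
            for name, vs in variant_sets.items()
            if observed in vs.variants.get(j, frozenset())
        ]
        if len(matched) == 1:
            return ScoreRecord(family_id, clade_index, matched[0], j, observed)
        if len(matched) > 1:
            return ScoreRecord(
                family_id, clade_index, "ambiguous", j, observed, tuple(matched)
            )
    return ScoreRecord(family_id, clade_index, "none", None, observed)


def count_singles_and_pairs(
    trees: Iterable[GeneTree], species_map: SpeciesMap | None = None
) -> tuple[Counter, Counter]:
    """Per-species leaf tallies and same-species cherry counts over trees.

    A cherry is an internal node with exactly two leaf children; only
    cherries whose two leaves share a species are counted (they are the
    terminal-duplication signal of recent WGD).
    """
    smap = species_map or DEFAULT_SPECIES_MAP
    singles: Counter = Counter()
    pairs: Counter = Counter()
    for tree in trees:
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                singles[smap.species(nd.taxon.label)] += 1
                continue
            kids = nd.child_nodes()
            if len(kids) == 2 and all(k.is_leaf() for k in kids):
                sp = {smap.species(k.taxon.label) for k in kids}
                if len(sp) == 1:
                    pairs[next(iter(sp))] += 1
    return singles, pairs


@dataclass
class CladeCountSummary:
    """Per-model x per-loss clade counts plus the headline tallies."""

    model_loss_counts: dict[str, list[int]]
    single_counts: Counter
    pair_counts: Counter
    max_losses: int
    n_trees: int = 0
    n_unscorable_trees: int = 0
    n_clades: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0

    def sum_losses(self, model: str, lo: int = 0, hi: int | None = None) -> int:
        hi = self.max_losses if hi is None else hi
        return sum(self.model_loss_counts[model][lo : hi + 1])

    def ratio_1ab_2ab(self, lo: int = 0, hi: int | None = None) -> float | None:
        """(H1a+H1b)/(H2a+H2b) over a loss-count range; None when undefined."""
        h1 = self.sum_losses("H1a", lo, hi) + self.sum_losses("H1b", lo, hi)
        h2 = self.sum_losses("H2a", lo, hi) + self.sum_losses("H2b", lo, hi)
        return None if h2 == 0 else h1 / h2

    def per_loss_ratio(self, j: int) -> float | None:
        return self.ratio_1ab_2ab(j, j)

    def counts_table(self) -> dict[str, list[int]]:
        return {m: list(self.model_loss_counts[m]) for m in MODEL_ORDER}

    def n_scorable_clades(self) -> int:
        return sum(sum(v) for v in self.model_loss_counts.values())


def score_dataset(
    trees: Sequence[GeneTree],
    max_losses: int = 3,
    budget: str = "published",
    species_map: SpeciesMap | None = None,
    models: Iterable[str] = MODEL_ORDER,
    per_tree: bool = False,
    family_ids: Sequence[str] | None = None,
) -> tuple[CladeCountSummary, list[ScoreRecord]]:
    """Root, canonicalize and match every scorable clade of every tree.

    ``per_tree=True`` scores only trees with exactly one maximal legume
    clade (one count per tree); the default scores every maximal legume
    clade of every tree.  Trees without a V leaf are counted as
    unscorable.  Single-sequence and cherry tallies are computed over all
    input trees, scorable or not.
    """
    smap = species_map or DEFAULT_SPECIES_MAP
    variant_sets = build_variant_sets(models, max_losses, budget)
    counts = {m: [0] * (max_losses + 1) for m in models}
    records: list[ScoreRecord] = []
    n_unscorable = 0
    n_clades = 0
    n_ambiguous = 0
    n_unmatched = 0
    ids = family_ids or [f"tree{i + 1:04d}" for i in range(len(trees))]
    for fam_id, tree in zip(ids, trees):
        rooted = root_on_vitis(tree, smap)
        if rooted is None:
            n_unscorable += 1
            continue
        clades = extract_legume_clades(rooted, smap)
        if per_tree and len(clades) != 1:
            n_unscorable += 1
            continue
        for k, clade in enumerate(clades):
            n_clades += 1
            rec = match_clade(clade, variant_sets, smap, fam_id, k)
            records.append(rec)
            if rec.matched_model == "ambiguous":
                n_ambiguous += 1
            elif rec.matched_model == "none":
                n_unmatched += 1
            else:
                counts[rec.matched_model][rec.loss_count] += 1
    singles, pairs = count_singles_and_pairs(trees, smap)
    summary = CladeCountSummary(
        model_loss_counts=counts,
        single_counts=singles,
        pair_counts=pairs,
        max_losses=max_losses,
        n_trees=len(trees),
        n_unscorable_trees=n_unscorable,
        n_clades=n_clades,
        n_ambiguous=n_ambiguous,
        n_unmatched=n_unmatched,
    )
    return summary, records


def write_scores(records: Sequence[ScoreRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tclade_index\tmatched_model\tloss_count\tobserved_pattern\ttied_models\n")
        for r in records:
            loss = "" if r.loss_count is None else str(r.loss_count)
            fh.write(
                f"{r.family_id}\t{r.clade_index}\t{r.matched_model}\t{loss}\t"
                f"{r.observed_pattern}\t{','.join(r.tied_models)}\n"
            )
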
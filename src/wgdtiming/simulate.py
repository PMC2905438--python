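"""Synthetic gene families with known polyploidy-timing ground truth.

The generator builds, for each family, the gene tree implied by the
species tree ((C,(G,M)),V) under one of the four timing hypotheses, with
duplications inserted at configured times: the early legume WGD (before
or after the C/(G,M) split, per hypothesis), the recent *Glycine* WGD,
and — for the "b" variants — an independent *Chamaecrista* WGD.  Gene
loss then prunes duplicate copies at random, and a purely synonymous
substitution process evolves codon sequences along the surviving tree,
so every pipeline stage (clustering, QC, scoring, Ks) can be checked
against known truth.

Times are in arbitrary units whose relative order is what matters; the
defaults echo fossil-calibrated divergence dates (C/papilionoid split 58,
G/M split 45, *Glycine* WGD 10) and place the early WGD at 56 (H1) or 62
(H2).  Branch lengths are elapsed time scaled by a per-lineage rate
multiplier — *Medicago* branches run faster, reproducing its documented
faster silent-site accumulation.

Sequence evolution draws root codons from the 4-fold-degenerate codon
boxes (GGN, GCN, ACN, CCN, GTN, TCN) and evolves only third positions
under an exact Jukes–Cantor process at ``syn_rate`` substitutions per
synonymous site per time unit; amino acids never change and stops never
arise.  Every codon therefore carries exactly one synonymous site, the
realized synonymous divergence of a pair is (rate x path length) in
expectation, and the NG86 + Jukes–Cantor estimator is unbiased for it —
which is what makes the estimator testable against truth.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .alignment_qc import CodonAlignment
from .io import HomologyHit, SequenceRecord, write_fasta, write_hit_table, write_newick
from .tree_scoring import MODELS, HypothesisModel

log = logging.getLogger("wgdtiming")

#: sequence-id prefixes per species (chosen to satisfy the default prefix rule)
LEAF_PREFIX = {"C": "Cf", "G": "Glyma", "M": "Mt", "V": "Vitis"}

#: 4-fold degenerate codon boxes used for root sequences
FOURFOLD_PREFIXES = ("GG", "GC", "AC", "CC", "GT", "TC")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    hypothesis: str = "H1a"
    n_families: int = 200
    n_codons: int = 200
    t_vitis_split: float = 115.0
    t_cf_split: float = 58.0
    t_gm_mt_split: float = 45.0
    t_early_wgd: float | None = None  # resolved per hypothesis when None
    t_gm_wgd: float = 10.0
    t_cf_wgd: float = 30.0
    syn_rate: float = 0.005  # synonymous substitutions / site / time unit
    mt_rate_multiplier: float = 1.2
    loss_prob: float = 0.1
    loss_mode: str = "duplicates"  # or "uniform"
    seed: int = 0

    @property
    def model(self) -> HypothesisModel:
        return MODELS[self.hypothesis]

    @property
    def early_wgd_time(self) -> float:
        if self.t_early_wgd is not None:
            return self.t_early_wgd
        if self.model.wgd_before_cf_split:
            return (self.t_cf_split + self.t_vitis_split) / 2.0  # early: before C split
        return 56.0

    def validate(self) -> None:
        if self.hypothesis not in MODELS:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if not self.t_vitis_split > self.t_cf_split > self.t_gm_mt_split > self.t_gm_wgd > 0:
            raise ValueError("speciation/WGD times out of order")
        early = self.early_wgd_time
        if self.model.wgd_before_cf_split:
            if not (self.t_cf_split < early < self.t_vitis_split):
                raise ValueError("H2 requires t_cf_split < t_early_wgd < t_vitis_split")
        else:
            if not (self.t_gm_mt_split < early < self.t_cf_split):
                raise ValueError("H1 requires t_gm_mt_split < t_early_wgd < t_cf_split")
        if self.model.cf_wgd and not (0 < self.t_cf_wgd < self.t_cf_split):
            raise ValueError("b-variants require 0 < t_cf_wgd < t_cf_split")
        if not (0 <= self.loss_prob < 1):
            raise ValueError("loss_prob must be in [0, 1)")
        if self.loss_mode not in ("duplicates", "uniform"):
            raise ValueError("loss_mode must be 'duplicates' or 'uniform'")
        if self.syn_rate <= 0 or self.mt_rate_multiplier < 1:
            raise ValueError("syn_rate must be positive and mt_rate_multiplier >= 1")


@dataclass
class SimulatedFamily:
    """One simulated gene family with its ground truth."""

    family_id: str
    true_hypothesis: str
    true_tree: dendropy.Tree  # post-loss, branch lengths in (rate-scaled) time
    full_leaf_count: int
    deleted_leaf_count: int
    loss_decisions: int
    losses_applied: int
    flagged: bool  # a required species was completely lost
    alignment: CodonAlignment | None = None


def _new_leaf(taxa, counters: Counter, species: str, family_tag: str) -> dendropy.Node:
    counters[species] += 1
    label = f"{LEAF_PREFIX[species]}_{family_tag}_{counters[species]}"
    nd = dendropy.Node()
    nd.taxon = taxa.new_taxon(label)
    return nd


def build_locus_tree(
    cfg: SimulationConfig, family_tag: str = "fam0001"
) -> dendropy.Tree:
    """The loss-free gene tree implied by the hypothesis and the times.

    Branch lengths are elapsed time scaled by the per-lineage rate
    multiplier (the *Medicago* terminal branch runs
    ``mt_rate_multiplier`` times faster).  The second child of every
    duplication node is marked as the deletable duplicate copy
    (``is_duplicate_copy``); gene loss samples those marks.
    """
    cfg.validate()
    taxa = dendropy.TaxonNamespace()
    counters: Counter = Counter()

    def leaf(species: str) -> dendropy.Node:
        return _new_leaf(taxa, counters, species, family_tag)

    def with_length(node: dendropy.Node, elapsed: float, rate: float = 1.0) -> dendropy.Node:
        node.edge.length = elapsed * rate
        return node

    def duplication(make_copy) -> dendropy.Node:
        nd = dendropy.Node()
        original = make_copy()
        duplicate = make_copy()
        duplicate.is_duplicate_copy = True
        nd.add_child(original)
        nd.add_child(duplicate)
        return nd

    def g_subtree() -> dendropy.Node:
        """G lineage from the G/M split; includes the recent Glycine WGD."""
        if cfg.t_gm_mt_split > cfg.t_gm_wgd:
            nd = duplication(lambda: with_length(leaf("G"), cfg.t_gm_wgd))
            return with_length(nd, cfg.t_gm_mt_split - cfg.t_gm_wgd)
        return with_length(leaf("G"), cfg.t_gm_mt_split)

    def m_subtree() -> dendropy.Node:
        return with_length(leaf("M"), cfg.t_gm_mt_split, cfg.mt_rate_multiplier)

    def c_subtree(t_from: float) -> dendropy.Node:
        if cfg.model.cf_wgd and t_from > cfg.t_cf_wgd:
            nd = duplication(lambda: with_length(leaf("C"), cfg.t_cf_wgd))
            return with_length(nd, t_from - cfg.t_cf_wgd)
        return with_length(leaf("C"), t_from)

    def gm_subtree(t_from: float, early_wgd: bool) -> dendropy.Node:
        """G/M ancestor lineage from ``t_from`` down to the present."""
        if early_wgd and t_from > cfg.early_wgd_time > cfg.t_gm_mt_split:
            nd = duplication(lambda: gm_subtree(cfg.early_wgd_time, False))
            return with_length(nd, t_from - cfg.early_wgd_time)
        split = dendropy.Node()
        split.add_child(g_subtree())
        split.add_child(m_subtree())
        split.edge.length = t_from - cfg.t_gm_mt_split
        return split

    def legume_subtree(t_from: float) -> dendropy.Node:
        if cfg.model.wgd_before_cf_split and t_from > cfg.early_wgd_time:
            nd = duplication(lambda: legume_copy(cfg.early_wgd_time))
            return with_length(nd, t_from - cfg.early_wgd_time)
        return legume_copy(t_from)

    def legume_copy(t_from: float) -> dendropy.Node:
        split = dendropy.Node()
        split.add_child(c_subtree(cfg.t_cf_split))
        split.add_child(gm_subtree(cfg.t_cf_split, not cfg.model.wgd_before_cf_split))
        split.edge.length = t_from - cfg.t_cf_split
        return split

    root = dendropy.Node()
    root.add_child(with_length(leaf("V"), cfg.t_vitis_split))
    root.add_child(legume_subtree(cfg.t_vitis_split))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


@dataclass
class LossOutcome:
    tree: dendropy.Tree
    deleted_leaf_count: int
    decisions: int
    deletions: int


def apply_losses(
    tree: dendropy.Tree,
    loss_prob: float,
    rng: np.random.Generator,
    mode: str = "duplicates",
) -> LossOutcome:
    """Prune gene copies at random, modelling loss and non-recovery.

    In the default ``duplicates`` mode each duplication's deletable copy
    (the subtree marked at construction) is lost independently with
    probability ``loss_prob``; at loss_prob=1 the tree collapses back to
    the single-copy species tree.  ``uniform`` mode instead deletes every
    non-root branch independently, which can remove required species
    entirely (such families are emitted but flagged downstream).
    Degree-2 nodes left by pruning are suppressed.  The input tree is
    modified in place.
    """
    n_leaves_before = len(tree.leaf_nodes())
    decisions = 0
    deletions = 0
    # preorder so that pruning an ancestor skips its nested duplications
    doomed: list[dendropy.Node] = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        deletable = (
            getattr(nd, "is_duplicate_copy", False)
            if mode == "duplicates"
            else True
        )
        if not deletable:
            continue
        if any(anc in doomed for anc in nd.ancestor_iter()):
            continue
        decisions += 1
        if rng.random() < loss_prob:
            doomed.append(nd)
            deletions += 1
    for nd in doomed:
        parent = nd.parent_node
        if parent is not None:
            parent.remove_child(nd)
    tree.suppress_unifurcations()
    # a pruned root child can leave a unary seed node
    while len(tree.seed_node.child_nodes()) == 1:
        only = tree.seed_node.child_nodes()[0]
        tree.seed_node.remove_child(only)
        tree.seed_node = only
        only.parent_node = None
    deleted = n_leaves_before - len(tree.leaf_nodes())
    return LossOutcome(tree, deleted, decisions, deletions)


_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def evolve_codons(
    tree: dendropy.Tree,
    n_codons: int,
    syn_rate: float,
    rng: np.random.Generator,
    family_id: str = "fam0001",
    species_of=None,
) -> CodonAlignment:
    """Evolve a stop-free codon alignment along a rate-scaled tree.

    Only third positions of 4-fold boxes change, under an exact
    Jukes–Cantor process with ``syn_rate`` expected substitutions per
    synonymous site per unit branch length; the output alignment is
    gap-free, in frame, and free of internal stops by construction.
    """
    if n_codons < 50:
        warnings.warn(
            f"n_codons={n_codons} < 50: per-family Ks estimates will be noisy",
            stacklevel=2,
        )
    from .io import DEFAULT_SPECIES_MAP

    smap = species_of or DEFAULT_SPECIES_MAP
    prefixes = [FOURFOLD_PREFIXES[i] for i in rng.integers(0, len(FOURFOLD_PREFIXES), n_codons)]
    root_third = rng.integers(0, 4, n_codons)
    states: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_third}
    rows: list[SequenceRecord] = []
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            pass
        else:
            parent_state = states[nd.parent_node]
            d = syn_rate * (nd.edge.length or 0.0)
            if d <= 0:
                state = parent_state.copy()
            else:
                p_same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
                u = rng.random(n_codons)
                jumps = rng.integers(0, 3, n_codons)  # which of the 3 other bases
                state = parent_state.copy()
                changed = u > p_same
                state[changed] = (state[changed] + 1 + jumps[changed]) % 4
            states[nd] = state
        if nd.is_leaf():
            third = states[nd]
            seq = "".join(
                prefixes[i] + "ACGT"[third[i]] for i in range(n_codons)
            )
            label = nd.taxon.label
            rows.append(SequenceRecord(label, smap.species(label), seq))
    return CodonAlignment(family_id, rows)


def simulate_pair(
    n_codons: int, divergence: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Two sequences separated by a true synonymous divergence.

    Equivalent to evolving a two-leaf tree whose path length times
    ``syn_rate`` equals ``divergence``; handy for estimator checks.
    """
    prefixes = [
        FOURFOLD_PREFIXES[i]
        for i in rng.integers(0, len(FOURFOLD_PREFIXES), n_codons)
    ]
    third_a = rng.integers(0, 4, n_codons)
    p_same = 0.25 + 0.75 * np.exp(-4.0 * divergence / 3.0)
    u = rng.random(n_codons)
    jumps = rng.integers(0, 3, n_codons)
    third_b = third_a.copy()
    changed = u > p_same
    third_b[changed] = (third_b[changed] + 1 + jumps[changed]) % 4
    seq_a = "".join(prefixes[i] + "ACGT"[third_a[i]] for i in range(n_codons))
    seq_b = "".join(prefixes[i] + "ACGT"[third_b[i]] for i in range(n_codons))
    return seq_a, seq_b


def simulate_families(cfg: SimulationConfig) -> list[SimulatedFamily]:
    """Generate ``cfg.n_families`` families, deterministic under the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    families = []
    width = max(4, len(str(cfg.n_families)))
    for k in range(1, cfg.n_families + 1):
        tag = f"fam{k:0{width}d}"
        tree = build_locus_tree(cfg, tag)
        full = len(tree.leaf_nodes())
        outcome = apply_losses(tree, cfg.loss_prob, rng, cfg.loss_mode)
        counts = Counter()
        for lf in tree.leaf_node_iter():
            for sp, prefix in LEAF_PREFIX.items():
                if lf.taxon.label.startswith(prefix):
                    counts[sp] += 1
        flagged = any(counts[sp] == 0 for sp in "CGMV")
        alignment = (
            evolve_codons(tree, cfg.n_codons, cfg.syn_rate, rng, family_id=tag)
            if counts
            else None
        )
        families.append(
            SimulatedFamily(
                family_id=tag,
                true_hypothesis=cfg.hypothesis,
                true_tree=tree,
                full_leaf_count=full,
                deleted_leaf_count=outcome.deleted_leaf_count,
                loss_decisions=outcome.decisions,
                losses_applied=outcome.deletions,
                flagged=flagged,
                alignment=alignment,
            )
        )
    return families


def _alignment_identity(seq_a: str, seq_b: str) -> float:
    same = sum(a == b for a, b in zip(seq_a, seq_b))
    return 100.0 * same / len(seq_a)


def family_hits(family: SimulatedFamily) -> list[HomologyHit]:
    """Synthetic all-vs-all hits for one family's alignment.

    Identity is measured from the alignment, the match length is the full
    alignment, and the E-value sits far below the clustering threshold, so
    single-linkage clustering reconstructs the true family.
    """
    aln = family.alignment
    if aln is None:
        return []
    hits = []
    rows = aln.rows
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            hits.append(
                HomologyHit(
                    rows[i].id,
                    rows[j].id,
                    1e-180,
                    round(_alignment_identity(rows[i].residues, rows[j].residues), 2),
                    len(rows[i].residues),
                )
            )
    return hits


def emit_dataset(
    cfg: SimulationConfig, out_dir: str | Path, force: bool = False
) -> list[SimulatedFamily]:
    """Write a complete simulated dataset to ``out_dir``.

    Layout: ``alignments/<fam>.fasta``, ``trees/<fam>.nwk``, ``hits.tsv``
    and ``truth.tsv``.  Output is byte-identical under the same config and
    seed.  Refuses a non-empty output directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    families = simulate_families(cfg)
    all_hits: list[HomologyHit] = []
    with open(out / "truth.tsv", "w") as truth:
        truth.write(
            "family_id\thypothesis\tn_leaves\tdeleted_leaves\tflagged\n"
        )
        for fam in families:
            if fam.alignment is not None:
                write_fasta(fam.alignment.rows, out / "alignments" / f"{fam.family_id}.fasta")
            write_newick([fam.true_tree], out / "trees" / f"{fam.family_id}.nwk")
            all_hits.extend(family_hits(fam))
            truth.write(
                f"{fam.family_id}\t{fam.true_hypothesis}\t"
                f"{fam.full_leaf_count - fam.deleted_leaf_count}\t"
                f"{fam.deleted_leaf_count}\t{int(fam.flagged)}\n"
            )
    write_hit_table(all_hits, out / "hits.tsv")
    log.info(
        "emit_dataset: %d %s families -> %s", cfg.n_families, cfg.hypothesis, out
    )
    return families
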
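"""Summary statistics over a directory of trimmed alignments and trees.

These are the dataset-level numbers the analysis reports for its final
alignment/tree set: tree and sequence totals, mean trimmed alignment
length, per-species single and cherry (terminal duplicate pair) counts,
within-species Ks pair counts, and the number of clades scorable by the
automated pattern matcher.  The functions work on any dataset in the
standard layout — simulated ones, or a published alignment/tree bundle a
user has unpacked locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from . import ks as ks_mod
from . import tree_scoring
from .alignment_qc import CodonAlignment, stop_free_fraction
from .io import DEFAULT_SPECIES_MAP, SpeciesMap, read_fasta, read_newick


@dataclass(frozen=True)
class DatasetSummary:
    n_trees: int
    n_sequences: int
    mean_alignment_length_nt: float
    single_counts: dict
    pair_counts: dict
    within_species_ks_pairs: dict  # category label -> pair count, e.g. {"GmGm": ...}
    scorable_clades: int  # automated matches within the loss budget
    n_clades: int


def _load_alignments(
    alignment_dir: Path, smap: SpeciesMap
) -> dict[str, CodonAlignment]:
    alignments = {}
    paths = sorted(
        p
        for pattern in ("*.fasta", "*.fa", "*.fna", "*.aln")
        for p in alignment_dir.glob(pattern)
    )
    if not paths:
        raise FileNotFoundError(f"no alignment FASTA files under {alignment_dir}")
    for p in paths:
        alignments[p.stem] = CodonAlignment(p.stem, read_fasta(p, smap))
    return alignments


def summarize_dataset(
    alignment_dir: str | Path,
    tree_dir: str | Path,
    species_map: SpeciesMap | None = None,
    max_losses: int = 3,
    compute_ks: bool = True,
) -> DatasetSummary:
    """Compute the headline statistics of an alignment/tree dataset."""
    smap = species_map or DEFAULT_SPECIES_MAP
    alignments = _load_alignments(Path(alignment_dir), smap)
    trees = []
    tree_paths = sorted(
        p
        for pattern in ("*.nwk", "*.tree", "*.newick", "*.tre")
        for p in Path(tree_dir).glob(pattern)
    )
    if not tree_paths:
        raise FileNotFoundError(f"no Newick tree files under {tree_dir}")
    family_ids = []
    for p in tree_paths:
        for t in read_newick(p):
            trees.append(t)
            family_ids.append(p.stem)

    n_sequences = sum(len(a.rows) for a in alignments.values())
    mean_len = (
        sum(a.length_nt for a in alignments.values()) / len(alignments)
        if alignments
        else math.nan
    )
    summary, _records = tree_scoring.score_dataset(
        trees, max_losses=max_losses, species_map=smap, family_ids=family_ids
    )

    within = {}
    if compute_ks:
        for aln in alignments.values():
            for rec in ks_mod.family_ks(aln):
                if rec.category in ("CfCf", "GmGm", "MtMt", "VvVv"):
                    within[rec.category] = within.get(rec.category, 0) + 1

    return DatasetSummary(
        n_trees=len(trees),
        n_sequences=n_sequences,
        mean_alignment_length_nt=mean_len,
        single_counts=dict(summary.single_counts),
        pair_counts=dict(summary.pair_counts),
        within_species_ks_pairs=within,
        scorable_clades=summary.n_scorable_clades(),
        n_clades=summary.n_clades,
    )


def contig_stop_free_fraction(
    fasta_path: str | Path, species_map: SpeciesMap | None = None
) -> float:
    """Fraction of contigs with no internal frame-0 stop codon."""
    records = read_fasta(fasta_path, species_map or DEFAULT_SPECIES_MAP)
    return stop_free_fraction(r.residues for r in records)
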
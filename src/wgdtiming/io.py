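"""Readers and writers for the pipeline's external formats.

Everything the pipeline exchanges with disk goes through this module:
FASTA sequence sets (Biopython), Newick gene trees (DendroPy), tabular
homology-hit files, and the Table-style count summaries.  It also owns
the species-coding rule — the mapping from sequence-id prefixes to the
one-letter species codes C (*Chamaecrista fasciculata*), G (*Glycine
max*), M (*Medicago truncatula*) and V (*Vitis vinifera*) — which every
downstream stage shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("wgdtiming")

#: the four species codes used throughout
SPECIES_CODES = ("C", "G", "M", "V")

#: two-letter display labels, used e.g. in Ks category names (CfGm, MtVv, ...)
SPECIES_LABELS = {"C": "Cf", "G": "Gm", "M": "Mt", "V": "Vv"}

#: default id-prefix -> species-code rule, mirroring the gene-id styles of
#: the source annotations (Glyma1.01, Mt2.0 mRNAs / BAC-based AC ids,
#: Genoscope Vitis ids) and the Chamaecrista contig names.
DEFAULT_SPECIES_PREFIXES: Mapping[str, str] = {
    "Glyma": "G",
    "Mt": "M",
    "Medtr": "M",
    "AC": "M",
    "Vitis": "V",
    "GSVIV": "V",
    "Cf": "C",
    "contig": "C",
}

#: characters allowed in nucleotide strings ('-' only in alignment context)
ALPHABET = frozenset("ACGTN-")


class SpeciesMap:
    """Total mapping from sequence ids to species codes via id prefixes.

    Longest matching prefix wins, so e.g. ``Medtr...`` is matched before a
    hypothetical two-letter ``Me`` prefix.
    """

    def __init__(self, prefixes: Mapping[str, str] | None = None):
        self.prefixes = dict(prefixes or DEFAULT_SPECIES_PREFIXES)
        for code in self.prefixes.values():
            if code not in SPECIES_CODES:
                raise ValueError(f"unknown species code {code!r}")
        self._ordered = sorted(self.prefixes, key=len, reverse=True)

    def try_species(self, seq_id: str) -> str | None:
        for prefix in self._ordered:
            if seq_id.startswith(prefix):
                return self.prefixes[prefix]
        return None

    def species(self, seq_id: str) -> str:
        code = self.try_species(seq_id)
        if code is None:
            raise KeyError(f"no species prefix matches sequence id {seq_id!r}")
        return code


DEFAULT_SPECIES_MAP = SpeciesMap()


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with its species assignment."""

    id: str
    species: str
    residues: str


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise similarity record from an all-vs-all homology search.

    ``match_length_nt`` is in nucleotides; tables whose search reported
    amino-acid lengths must be converted (aa x 3) upstream.
    """

    query_id: str
    subject_id: str
    evalue: float
    pct_identity: float
    match_length_nt: int


# A gene tree is a DendroPy tree whose leaf labels are sequence ids.
GeneTree = dendropy.Tree


def read_fasta(path: str | Path, species_map: SpeciesMap | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Ids are preserved verbatim; species are assigned by the prefix rule.
    Duplicate ids and ids with no matching species prefix are hard errors
    (the latter listing every offender).
    """
    smap = species_map or DEFAULT_SPECIES_MAP
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    unmappable: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        residues = str(entry.seq).upper()
        bad = set(residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {entry.id!r} in {path} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        code = smap.try_species(entry.id)
        if code is None:
            unmappable.append(entry.id)
            continue
        records.append(SequenceRecord(entry.id, code, residues))
    if unmappable:
        raise ValueError(
            f"{len(unmappable)} sequence id(s) in {path} match no species "
            f"prefix: {', '.join(sorted(unmappable)[:10])}"
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_newick(path: str | Path) -> list[GeneTree]:
    """Read one or more semicolon-terminated Newick trees.

    Multifurcations are preserved; numeric internal-node labels are kept as
    bootstrap support on ``node.label``.  Underscores in labels are literal
    (no quoting games).
    """
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports the line number in its message
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc
    return list(trees)


def write_newick(trees: Iterable[GeneTree], path: str | Path) -> None:
    tl = dendropy.TreeList()
    for t in trees:
        tl.append(t, taxon_import_strategy="add")
    tl.write(
        path=str(path),
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a tab-separated homology hit table.

    Expected columns: query, subject, E-value, percent identity, match
    length (nt); extra columns are ignored and ``#`` lines are comments.
    Self-hits (query == subject) are dropped; symmetric duplicates are
    retained because clustering treats hits as undirected edges.
    """
    try:
        frame = pd.read_csv(
            str(path), sep="\t", comment="#", header=None, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] < 5:
        raise ValueError(f"hit table {path} has {frame.shape[1]} columns; need >= 5")
    hits: list[HomologyHit] = []
    n_self = 0
    for idx, row in enumerate(frame.itertuples(index=False)):
        query, subject = str(row[0]), str(row[1])
        try:
            evalue = float(row[2])
            identity = float(row[3])
            length = int(float(row[4]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed numeric field at row {idx} of {path}") from exc
        if evalue < 0 or not (0.0 <= identity <= 100.0) or length <= 0:
            raise ValueError(f"out-of-range value at row {idx} of {path}")
        if query == subject:
            n_self += 1
            continue
        hits.append(HomologyHit(query, subject, evalue, identity, length))
    if n_self:
        log.info("read_hit_table: dropped %d self-hit(s)", n_self)
    log.info("read_hit_table: %d hits from %s", len(hits), path)
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#query\tsubject\tevalue\tpct_identity\tmatch_length_nt\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.evalue:.3g}\t"
                f"{h.pct_identity:.2f}\t{h.match_length_nt}\n"
            )


MODEL_ROW_ORDER = ("H1a", "H1b", "H2a", "H2b")


def write_counts(
    counts: Mapping[str, Sequence[int]],
    path: str | Path,
    max_losses: int = 3,
    ratio_row: bool = True,
) -> None:
    """Write a per-model x per-loss-count table as TSV.

    Rows are the four hypothesis models in fixed order (labelled without the
    leading "H", as in the published table layout), columns are ascending
    loss counts plus the 0-1 and 0-``max_losses`` sums, and an optional
    final row gives the (H1a+H1b)/(H2a+H2b) ratio per column ("NA" where the
    denominator is zero).  Output is deterministic: rewriting the same table
    yields a byte-identical file.
    """
    loss_cols = list(range(max_losses + 1))
    header = ["model", *[str(j) for j in loss_cols], "sum_0_1", f"sum_0_{max_losses}"]
    if not counts:
        Path(path).write_text("\t".join(header) + "\n")
        return
    normalized: dict[str, list[int]] = {}
    for model in MODEL_ROW_ORDER:
        row = counts.get(model, counts.get(model.lstrip("H"), []))
        vals = [int(row[j]) if j < len(row) else 0 for j in loss_cols]
        normalized[model] = vals
    lines = ["\t".join(header)]
    for model in MODEL_ROW_ORDER:
        vals = normalized[model]
        sums = [sum(vals[:2]), sum(vals)]
        lines.append("\t".join([model.lstrip("H"), *map(str, vals + sums)]))
    if ratio_row:
        cells = ["1ab/2ab"]
        columns = [[normalized[m][j] for m in MODEL_ROW_ORDER] for j in loss_cols]
        columns.append([sum(normalized[m][:2]) for m in MODEL_ROW_ORDER])
        columns.append([sum(normalized[m]) for m in MODEL_ROW_ORDER])
        for col in columns:
            h1 = col[0] + col[1]
            h2 = col[2] + col[3]
            cells.append("NA" if h2 == 0 else f"{h1 / h2:.1f}")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
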
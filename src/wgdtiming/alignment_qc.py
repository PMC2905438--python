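"""Codon-alignment trimming and reading-frame quality control.

Alignments enter the pipeline as in-frame codon alignments (gapped FASTA
whose length is a multiple of three).  Two screens decide whether a family
proceeds to tree scoring:

* trimming to the *Chamaecrista* core — only codon columns present in at
  least half of the C rows are kept, so the scored region is the part of
  the gene actually covered by the transcriptome assembly; and
* frame QC — the trimmed alignment must be essentially stop-free in frame
  (pooled internal-stop rate strictly below 0.1%) and at least 60 codons
  long.

Trimming operates on whole codon columns, never single nucleotide
columns, so the downstream synonymous-site arithmetic always sees intact
codons.  A codon with at most one gap character counts as "present"
(majority rule over its three positions); stop codons are TAA/TAG/TGA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import SequenceRecord

log = logging.getLogger("wgdtiming")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class QcThresholds:
    cf_core_fraction: float = 0.5
    max_internal_stop_fraction: float = 0.001
    min_length_aa: int = 60

    def __post_init__(self):
        if not (0 < self.cf_core_fraction <= 1):
            raise ValueError("cf_core_fraction must be in (0, 1]")
        if not (0 < self.max_internal_stop_fraction <= 1):
            raise ValueError("max_internal_stop_fraction must be in (0, 1]")
        if self.min_length_aa <= 0:
            raise ValueError("min_length_aa must be positive")


@dataclass
class CodonAlignment:
    """An in-frame codon alignment with species-tagged rows."""

    family_id: str
    rows: list[SequenceRecord]

    def __post_init__(self):
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment {self.family_id}: rows have unequal lengths")

    @property
    def length_nt(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.species] = counts.get(r.species, 0) + 1
        return counts

    def codon(self, row: int, col: int) -> str:
        return self.rows[row].residues[3 * col : 3 * col + 3]


def _codon_present(codon: str) -> bool:
    """Majority rule: a codon counts as non-gap if >= 2 of 3 positions are."""
    return sum(c != "-" for c in codon) >= 2


def trim_to_cf_core(
    alignment: CodonAlignment, cf_core_fraction: float = 0.5
) -> CodonAlignment:
    """Keep the codon columns covered by at least ``cf_core_fraction`` of C rows.

    The boundary is inclusive (a column present in exactly half of the C
    rows is kept).  Row order is preserved; no row is dropped.  With no C
    rows the operation is undefined and raises.
    """
    if alignment.length_nt % 3:
        raise ValueError(
            f"alignment {alignment.family_id}: length {alignment.length_nt} nt "
            "is not a whole number of codons"
        )
    c_rows = [i for i, r in enumerate(alignment.rows) if r.species == "C"]
    if not c_rows:
        raise ValueError(f"alignment {alignment.family_id}: no Chamaecrista sequences")
    keep = []
    for col in range(alignment.n_codons):
        present = sum(_codon_present(alignment.codon(i, col)) for i in c_rows)
        if present / len(c_rows) >= cf_core_fraction:
            keep.append(col)
    rows = [
        SequenceRecord(
            r.id,
            r.species,
            "".join(r.residues[3 * col : 3 * col + 3] for col in keep),
        )
        for r in alignment.rows
    ]
    return CodonAlignment(alignment.family_id, rows)


@dataclass(frozen=True)
class QcReport:
    family_id: str
    passed: bool
    length_nt: int
    internal_stop_fraction: float
    n_internal_stops: int
    n_nongap_codons: int
    reasons: tuple[str, ...] = ()


def _row_codons(residues: str) -> list[str]:
    return [residues[i : i + 3] for i in range(0, len(residues) - len(residues) % 3, 3)]


def frame_qc(
    alignment: CodonAlignment, thresholds: QcThresholds | None = None
) -> QcReport:
    """Pass/fail screen on pooled internal-stop rate and trimmed length.

    The stop rate pools all rows: internal stop codons (each row's final
    gap-free codon excluded, since a genuine terminator may survive
    trimming) over all gap-free codons.  Pass requires rate strictly below
    ``max_internal_stop_fraction`` and length >= 3 x ``min_length_aa`` nt.
    The result does not depend on row order.
    """
    th = thresholds or QcThresholds()
    n_stops = 0
    n_codons = 0
    for row in alignment.rows:
        gap_free = [c for c in _row_codons(row.residues) if "-" not in c]
        n_codons += len(gap_free)
        n_stops += sum(1 for c in gap_free[:-1] if c in STOP_CODONS)
    frac = n_stops / n_codons if n_codons else 0.0
    reasons = []
    if not frac < th.max_internal_stop_fraction:
        reasons.append(
            f"internal stop fraction {frac:.4%} not below "
            f"{th.max_internal_stop_fraction:.2%}"
        )
    if alignment.length_nt < 3 * th.min_length_aa:
        reasons.append(
            f"length {alignment.length_nt} nt below {3 * th.min_length_aa} nt"
        )
    return QcReport(
        family_id=alignment.family_id,
        passed=not reasons,
        length_nt=alignment.length_nt,
        internal_stop_fraction=frac,
        n_internal_stops=n_stops,
        n_nongap_codons=n_codons,
        reasons=tuple(reasons),
    )


def stop_free_fraction(sequences: Iterable[str]) -> float:
    """Fraction of unaligned sequences with no internal frame-0 stop codon.

    Reading starts at the first base; the final complete codon is excluded
    (it may legitimately be a terminator), as is any trailing partial
    codon.  Returns NaN for an empty input.
    """
    n = 0
    clean = 0
    for seq in sequences:
        n += 1
        codons = _row_codons(seq.upper())
        if not any(c in STOP_CODONS for c in codons[:-1]):
            clean += 1
    return clean / n if n else float("nan")


def write_qc_report(reports: Sequence[QcReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tlength_nt\tstop_fraction\tpass\treasons\n")
        for r in sorted(reports, key=lambda r: r.family_id):
            fh.write(
                f"{r.family_id}\t{r.length_nt}\t{r.internal_stop_fraction:.6f}\t"
                f"{int(r.passed)}\t{'; '.join(r.reasons)}\n"
            )
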
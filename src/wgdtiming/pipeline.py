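"""End-to-end driver: hits -> families -> QC'd alignments -> scores -> Ks.

Ties the stage modules together over an on-disk dataset laid out as
``emit_dataset`` writes it (per-family alignment FASTA and Newick tree,
plus a hit table), applying the filter cascade and logging the surviving
counts at every stage the way the original analysis reported its own
cascade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment_qc, clustering, ks, tree_scoring
from .alignment_qc import CodonAlignment
from .config import PipelineConfig
from .io import read_fasta, read_hit_table, read_newick, write_counts

log = logging.getLogger("wgdtiming")


@dataclass
class PipelineResult:
    cascade: dict[str, int]
    families: list[clustering.GeneFamily]
    qc_reports: list[alignment_qc.QcReport]
    summary: tree_scoring.CladeCountSummary | None
    score_records: list[tree_scoring.ScoreRecord]
    ks_records: list[ks.KsRecord]
    histograms: list[ks.KsHistogram] = field(default_factory=list)


def run_pipeline(
    dataset_dir: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run cluster -> alignment QC -> tree scoring -> Ks over a dataset.

    ``dataset_dir`` must contain ``alignments/*.fasta``, ``trees/*.nwk``
    and ``hits.tsv``.  When ``out_dir`` is given, the families table, QC
    report, per-clade scores, counts table, Ks records and histograms are
    written there as TSV.
    """
    cfg = config or PipelineConfig()
    smap = cfg.species_map()
    data = Path(dataset_dir)

    alignments: dict[str, CodonAlignment] = {}
    for fasta in sorted((data / "alignments").glob("*.fasta")):
        fam_id = fasta.stem
        alignments[fam_id] = CodonAlignment(fam_id, read_fasta(fasta, smap))
    universe = [r.id for aln in alignments.values() for r in aln.rows]

    hits = read_hit_table(data / "hits.tsv")
    hits = clustering.dedupe_hits(hits)
    kept_hits = clustering.filter_hits(hits, cfg.cluster)
    families = clustering.single_linkage(kept_hits, universe, smap)
    retained = clustering.composition_filter(families, cfg.composition)
    retained_sets = {f.member_ids for f in retained}

    cascade = {
        "clusters_initial": len(families),
        "clusters_composition": len(retained),
    }

    # QC each input family whose member set survived the composition filter
    trimmed: dict[str, CodonAlignment] = {}
    qc_reports = []
    for fam_id, aln in alignments.items():
        if frozenset(r.id for r in aln.rows) not in retained_sets:
            continue
        cut = alignment_qc.trim_to_cf_core(aln, cfg.qc.cf_core_fraction)
        if cut.length_nt == 0:
            continue
        report = alignment_qc.frame_qc(cut, cfg.qc)
        qc_reports.append(report)
        if report.passed:
            trimmed[fam_id] = cut
    cascade["alignments_trimmed"] = len(qc_reports)
    cascade["alignments_final"] = len(trimmed)
    log.info(
        "filter cascade: %s",
        " -> ".join(f"{k}={v}" for k, v in cascade.items()),
    )

    trees = []
    family_ids = []
    for fam_id in sorted(trimmed):
        tree_path = data / "trees" / f"{fam_id}.nwk"
        if tree_path.exists():
            for tree in read_newick(tree_path):
                trees.append(tree)
                family_ids.append(fam_id)
    summary, score_records = tree_scoring.score_dataset(
        trees,
        max_losses=cfg.scoring.max_losses,
        budget=cfg.scoring.budget,
        species_map=smap,
        per_tree=cfg.scoring.per_tree,
        family_ids=family_ids,
    )

    ks_records = []
    for fam_id in sorted(trimmed):
        ks_records.extend(ks.family_ks(trimmed[fam_id]))
    histograms = ks.build_histograms(ks_records, cfg.ks.bin_width, cfg.ks.cap)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        clustering.write_families(retained, out / "families.tsv", smap)
        alignment_qc.write_qc_report(qc_reports, out / "qc_report.tsv")
        tree_scoring.write_scores(score_records, out / "scores.tsv")
        write_counts(summary.counts_table(), out / "counts.tsv", cfg.scoring.max_losses)
        ks.write_ks_table(ks_records, out / "ks.tsv")
        ks.write_histograms(histograms, out / "histograms.tsv")
        with open(out / "cascade.tsv", "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in cascade.items():
                fh.write(f"{stage}\t{count}\n")

    return PipelineResult(
        cascade=cascade,
        families=retained,
        qc_reports=qc_reports,
        summary=summary,
        score_records=score_records,
        ks_records=ks_records,
        histograms=histograms,
    )
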
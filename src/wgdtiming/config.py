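"""Declarative configuration for the whole pipeline.

A single YAML file can override any threshold used by any stage, e.g.::

    species_prefixes: {Glyma: G, Mt: M, Vitis: V, Cf: C}
    cluster: {max_evalue: 1.0e-10, min_pct_identity: 50, min_match_nt: 180}
    composition: {min_per_species: {C: 1, G: 2, M: 1, V: 1}, max_total: 100}
    qc: {cf_core_fraction: 0.5, max_internal_stop_fraction: 0.001, min_length_aa: 60}
    scoring: {max_losses: 3, budget: published, per_tree: false}
    ks: {bin_width: 0.1, cap: 3.0}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alignment_qc import QcThresholds
from .clustering import ClusterThresholds, CompositionFilter
from .io import DEFAULT_SPECIES_PREFIXES, SpeciesMap


@dataclass
class ScoringOptions:
    max_losses: int = 3
    budget: str = "published"  # or "generic"
    per_tree: bool = False


@dataclass
class KsOptions:
    bin_width: float = 0.1
    cap: float = 3.0


@dataclass
class PipelineConfig:
    species_prefixes: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_PREFIXES))
    cluster: ClusterThresholds = field(default_factory=ClusterThresholds)
    composition: CompositionFilter = field(default_factory=CompositionFilter)
    qc: QcThresholds = field(default_factory=QcThresholds)
    scoring: ScoringOptions = field(default_factory=ScoringOptions)
    ks: KsOptions = field(default_factory=KsOptions)

    def species_map(self) -> SpeciesMap:
        return SpeciesMap(self.species_prefixes)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing keys keep their defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    if "species_prefixes" in raw:
        cfg.species_prefixes = dict(raw["species_prefixes"])
    if "cluster" in raw:
        cfg.cluster = ClusterThresholds(**raw["cluster"])
    if "composition" in raw:
        comp = raw["composition"]
        cfg.composition = CompositionFilter(
            min_per_species=comp.get("min_per_species", {"C": 1, "G": 2, "M": 1, "V": 1}),
            max_total=comp.get("max_total", 100),
        )
    if "qc" in raw:
        cfg.qc = QcThresholds(**raw["qc"])
    if "scoring" in raw:
        cfg.scoring = ScoringOptions(**raw["scoring"])
    if "ks" in raw:
        cfg.ks = KsOptions(**raw["ks"])
    return cfg
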
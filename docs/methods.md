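# Methods

## The question and the design

A whole-genome duplication (WGD) leaves two signatures in a set of gene
families: gene-tree topologies in which every lineage descending from the
duplicated genome carries paralog pairs, and a genome-wide burst of gene
pairs at a common synonymous divergence (Ks).  This package implements
both readouts for a four-species comparison — *Chamaecrista fasciculata*
(C, mimosoid clade), *Glycine max* (G) and *Medicago truncatula* (M)
(papilionoids), with *Vitis vinifera* (V) as the rosid outgroup — to ask
whether the early legume WGD known from *Glycine* and *Medicago* predates
the C/(G,M) split.

Four timing hypotheses are encoded as expected loss-free gene-tree
patterns over the species tree ((C,(G,M)),V):

| model | early WGD before C/(G,M) split? | independent C WGD? | canonical pattern |
|-------|--------------------------------|--------------------|-------------------|
| H1a   | no                             | no                 | `((((G,G),M),((G,G),M)),C)` |
| H1b   | no                             | yes                | `((C,C),(((G,G),M),((G,G),M)))` |
| H2a   | yes                            | no                 | `((((G,G),M),C),(((G,G),M),C))` |
| H2b   | yes                            | yes                | `(((C,C),((G,G),M)),((C,C),((G,G),M)))` |

All four include the `(G,G)` cherries of the much younger *Glycine* WGD.

## Gene families

Families are single-linkage clusters: connected components of the graph
whose edges are homology hits with E-value <= 1e-10, identity >= 50% and
match length >= 180 nt (60 aa); all boundaries are inclusive for
retention.  Hits are undirected — an edge exists if either direction
passes — and multiple HSP rows for an ordered pair are reduced to the
best one (lowest E-value, ties by identity then length) before
filtering.  Retained families must contain >= 1 C, >= 2 G, >= 1 M and
>= 1 V sequence and no more than 100 members in total: fewer G copies
could never show the duplicate pattern, and very large families churn
through birth and death too fast to be informative.  Connected components
are computed with networkx; an independent BFS implementation serves as
the oracle in the test suite.

## Alignment QC

Codon alignments are trimmed to the columns covered by at least half of
the family's C rows (boundary inclusive), in whole codons so the frame
survives; a codon with at most one gap position counts as covered
(majority rule over its three positions).  A trimmed alignment passes
when the pooled internal-stop rate — stop codons over all rows' gap-free
codons, excluding each row's final codon — is strictly below 0.1%, and
the trimmed length is at least 60 codons.  The stop rate is pooled per
alignment rather than per sequence; a per-sequence variant would be a
small change but the pooled rate matches "can this alignment be read
consistently in frame" most directly.

## Tree scoring

Trees are rooted on the lexicographically smallest V-leaf label — a
deterministic stand-in for an arbitrary outgroup choice — then stripped
of branch lengths and support.  Support values are parsed and carried in
the score records but never gate a match.  The scored units are the
maximal clades containing only C/G/M leaves; a tree with several
V-separated legume clades contributes several.

Canonicalization maps a clade to a species-coded string with children
sorted at every node (internal nodes before leaves, then by string
length, then lexicographically), so any rotation of a topology compares
equal.  Each hypothesis is expanded into deletion variants: every
canonical topology reachable by removing up to `max_losses` leaves
(default 3), subject to a per-species budget — at most 2 G and 1 M for
every model, plus at most 1 C for the H2 models, mirroring the original
enumeration; a `generic` budget (any species, up to the loss cap) is
available.  Variants that lose every C leaf are always excluded: without
a *Chamaecrista* sequence a clade cannot place the WGD relative to the
C split.  A clade matches the unique model whose variant set contains its
canonical string at the smallest loss count; ties across models at that
count are reported as `ambiguous` and excluded from the per-model counts
(conservative and auditable), and clades matching nothing — including any
clade with duplications beyond the modelled ones — are `none`.
Multifurcations are scored as-is and simply fail to match the binary
patterns.  Counts are reported per model and loss count with 0–1 and 0–3
sums and the (H1a+H1b)/(H2a+H2b) ratio per column.

The enumerator is verified against a brute-force oracle (delete every
leaf subset up to size 3, canonicalize, dedupe) for all four models and
both budgets.

## Ks

Synonymous distances use Nei–Gojobori (1986) counting with a
Jukes–Cantor correction, the combination implemented by the classic SNAP
tool.  Site counts exclude mutations through stop codons from both
numerator and denominator; multi-position codon differences average the
synonymous/nonsynonymous split over all substitution orders, skipping
orders that pass through a stop; when every order is blocked, each
differing position is scored in isolation, preferring whichever endpoint
context avoids a stop.  Codons with gaps or ambiguity in either sequence
are dropped pairwise.  ps = Sd/S is corrected as
Ks = -(3/4)·ln(1 - (4/3)·ps); ps >= 0.75 is saturated — the record is
kept and flagged but excluded from histograms, whose finite axis could
not hold it anyway.  Histograms are per unordered species-pair category
(CfCf … VvVv), half-open left-inclusive bins of width 0.1 up to a cap of
3.0 with an overflow bin, as proportions of the category's usable pairs.

## The simulator

Each family's gene tree is built from the species tree with duplications
inserted at configured times; defaults (arbitrary units, only relative
order matters): Vitis split 115, C/papilionoid split 58, G/M split 45,
*Glycine* WGD 10, early WGD 56 for H1 models and midway between the C and
V splits (86.5) for H2 models, C WGD 30 for b-variants.  The G/M split
default follows the younger of the two published fossil calibrations
(≈45 My rather than 54 My): with the faster *Medicago* clock below, the
older value would push simulated GmMt divergences past CfGm, inverting
the ordering the species phylogeny demands.  Branch lengths are elapsed
time, with *Medicago* terminal branches scaled by `mt_rate_multiplier`
(default 1.2) to emulate that lineage's faster silent-site accumulation.
With `syn_rate = 0.005` substitutions per synonymous site per unit time,
the implied Ks peaks land near the observed ones: GmGm recent ≈ 0.1,
GmGm old ≈ 0.56, GmMt ≈ 0.5–0.6, CfGm ≈ 0.58, CfMt ≈ 0.63, legume–Vitis
≈ 1.15–1.24.

Gene loss: each duplication designates one child as the surviving
original and the other as a deletable duplicate lineage, lost
independently with probability `loss_prob` (default 0.1); nested
duplications under a lost copy are never sampled.  This keeps the
limiting cases meaningful (loss 1 collapses to the single-copy species
tree; required species can never vanish) while exercising the
loss-variant matcher.  A `uniform` mode deletes any non-root branch and
can produce flagged families missing a species.

Sequence evolution is purely synonymous: root codons are drawn from the
4-fold-degenerate boxes (GGN, GCN, ACN, CCN, GTN, TCN) and only third
positions evolve, under an exact Jukes–Cantor process at `syn_rate`.
Every codon then carries exactly one synonymous site, amino acids and
reading frame never change, and the NG86+JC estimator is unbiased for
rate × path length — the property the estimator-consistency tests rely
on.  With arbitrary root codons, 2-fold-degenerate sites would evolve as
two-state chains that the Jukes–Cantor formula mis-corrects (≈ +0.13
bias at Ks 0.5), so the estimator could not be tested cleanly against
truth.  Default family size is 200 codons (600 nt), the same order as
real trimmed alignments (~550 nt).

What the simulator deliberately leaves out: indels and alignment error,
nonsynonymous change and selection, codon-usage bias, gene conversion,
incomplete lineage sorting, and phylogenetic reconstruction error (the
emitted trees are the true trees).  Passing round-trip tests therefore
show that the scoring and Ks machinery is correct, not that the
upstream steps of a real study (assembly, alignment, ML tree inference)
are error-free.

## Numerical and degenerate-input conventions

- Hit-table boundaries inclusive; stop-rate threshold strictly `<`.
- Trees without a V leaf are recorded unscorable, never raised.
- Rooting tie-break: smallest V-leaf label; topology-only trees are
  given unit branch lengths just to split the rooting edge, then
  stripped.
- `ps >= 0.75` → NaN Ks plus a `saturated` flag; zero comparable codons
  → `comparable=False` record.
- Histogram bins left-inclusive; overflow pooled at the cap.
- Family ids are `fam` + zero-padded rank of the family's smallest
  member id, so all outputs are byte-reproducible under a fixed seed.

## Problem sizes

The shipped checks use 200 simulated families per hypothesis for
recovery and estimator statistics, 120 per hypothesis in the analysis
scripts, 60–200 codons per family, and 1,000 synthetic ORFs for the
stop-screen check — sizes at which every reported proportion has small
enough sampling error for the assertions made about it.
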
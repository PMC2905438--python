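"""Pairwise synonymous-site distances and Ks histograms.

For every within-family pair of aligned coding sequences we count
synonymous (S) and nonsynonymous (N) sites and differences (Sd, Nd) with
the Nei–Gojobori (1986) method, then correct the observed proportion of
synonymous differences ps = Sd/S for multiple hits with the Jukes–Cantor
formula, Ks = -(3/4)·ln(1 - (4/3)·ps).  Ks is the field's standard proxy
for the age of a duplication or speciation event: a genome-wide burst of
gene pairs at a common Ks is the signature of a whole-genome duplication.

Counting conventions (standard genetic code throughout):

* the synonymous-site content of a codon position is the fraction of its
  single-step changes that are synonymous, with changes that would create
  a stop codon excluded from both numerator and denominator;
* S and N are averaged over the two sequences of a pair;
* codons differing at d positions average Sd/Nd over all d! single-step
  substitution pathways, excluding pathways passing through a stop codon
  (if every pathway is blocked, each differing position is scored in
  isolation);
* codons containing a gap or an ambiguous base in either sequence, or a
  stop codon, are skipped pairwise;
* ps >= 0.75 saturates the correction; such pairs keep their record but
  carry an undefined Ks and are excluded from histograms.

Histograms bin Ks per unordered species-pair category (CfCf, CfGm, ...,
VvVv) in half-open, left-inclusive bins of width 0.1, with values at or
beyond the cap pooled into an overflow bin, and report proportions of
each category's total.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from .alignment_qc import CodonAlignment
from .io import SPECIES_LABELS

log = logging.getLogger("wgdtiming")

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_AA.update({c: "*" for c in STOP_CODONS})

BASES = "ACGT"

#: ps at or above this value cannot be Jukes-Cantor corrected
SATURATION_PS = 0.75


def _comparable(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in BASES for b in codon)
        and codon not in STOP_CODONS
    )


def ng86_sites(codon: str) -> float:
    """Synonymous-site count of one codon (0 to 3).

    Each position contributes (synonymous single-step changes) /
    (single-step changes not creating a stop); e.g. a 4-fold degenerate
    third position contributes 1.0, TTT contributes 1/3 (only TTT->TTC is
    synonymous) and ATG contributes 0.
    """
    if not _comparable(codon):
        raise ValueError(f"codon {codon!r} is gapped, ambiguous or a stop")
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if _AA[alt] == _AA[codon]:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over stop-free pathways."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    total_s = total_n = 0.0
    n_valid = 0
    for order in itertools.permutations(diff):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _AA[nxt] == _AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            n_valid += 1
            total_s += sd
            total_n += nd
    if n_valid:
        return (total_s / n_valid, total_n / n_valid)
    # every pathway runs through a stop: score each position in isolation,
    # preferring whichever endpoint context avoids a stop codon
    sd = nd = 0.0
    for pos in diff:
        in_a = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
        in_b = codon_b[:pos] + codon_a[pos] + codon_b[pos + 1 :]
        if in_a not in STOP_CODONS:
            synonymous = _AA[in_a] == _AA[codon_a]
        elif in_b not in STOP_CODONS:
            synonymous = _AA[in_b] == _AA[codon_b]
        else:
            synonymous = False
        if synonymous:
            sd += 1
        else:
            nd += 1
    return (sd, nd)


@dataclass(frozen=True)
class CodonPairStats:
    """NG86 site and difference counts for one aligned sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    codons_compared: int


@dataclass(frozen=True)
class PairwiseNG86:
    stats: CodonPairStats
    ps: float  # Sd/S; NaN when no comparable codons
    pn: float  # Nd/N


def ng86_pairwise(seq_a: str, seq_b: str) -> PairwiseNG86:
    """NG86 proportions for two equal-length in-frame aligned sequences.

    Symmetric in its arguments; S + N equals 3 x codons_compared.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("aligned length is not a whole number of codons")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    s_a = s_b = sd = nd = 0.0
    m = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_comparable(ca) and _comparable(cb)):
            continue
        m += 1
        s_a += ng86_sites(ca)
        s_b += ng86_sites(cb)
        d_s, d_n = _pathway_diffs(ca, cb) if ca != cb else (0.0, 0.0)
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = 3.0 * m - S
    stats = CodonPairStats(S=S, N=N, Sd=sd, Nd=nd, codons_compared=m)
    ps = sd / S if S > 0 else float("nan")
    pn = nd / N if N > 0 else float("nan")
    return PairwiseNG86(stats, ps, pn)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction, d = -(3/4)·ln(1 - (4/3)·p).

    Returns NaN for p >= 0.75 (saturated); raises for p outside [0, 1].
    """
    if math.isnan(p):
        return float("nan")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if p >= SATURATION_PS:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pair_category(species_a: str, species_b: str) -> str:
    """Unordered species-pair label, e.g. ('G', 'C') -> 'CfGm'."""
    return "".join(sorted((SPECIES_LABELS[species_a], SPECIES_LABELS[species_b])))


@dataclass(frozen=True)
class KsRecord:
    """One gene-pair synonymous-distance measurement."""

    family_id: str
    id_a: str
    id_b: str
    category: str
    ps: float
    pn: float
    ks: float  # NaN when saturated or incomparable
    ka: float
    codons_compared: int
    saturated: bool
    comparable: bool


def family_ks(alignment: CodonAlignment) -> list[KsRecord]:
    """Ks/Ka records for every unordered sequence pair in a family."""
    records = []
    rows = alignment.rows
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            res = ng86_pairwise(a.residues, b.residues)
            comparable = res.stats.codons_compared > 0 and res.stats.S > 0
            saturated = comparable and res.ps >= SATURATION_PS
            records.append(
                KsRecord(
                    family_id=alignment.family_id,
                    id_a=a.id,
                    id_b=b.id,
                    category=pair_category(a.species, b.species),
                    ps=res.ps,
                    pn=res.pn,
                    ks=jukes_cantor(res.ps) if comparable else float("nan"),
                    ka=jukes_cantor(res.pn) if comparable else float("nan"),
                    codons_compared=res.stats.codons_compared,
                    saturated=saturated,
                    comparable=comparable,
                )
            )
    return records


@dataclass(frozen=True)
class KsHistogram:
    """Proportions of a category's gene pairs per Ks bin.

    ``proportions[i]`` covers the half-open bin [i*w, (i+1)*w); the final
    element is the overflow bin [cap, inf).  Proportions sum to 1 over the
    category's usable (unsaturated) pairs.
    """

    category: str
    bin_width: float
    cap: float
    proportions: tuple[float, ...]
    n_pairs: int

    def bins(self) -> list[tuple[float, float, float]]:
        out = []
        for i, p in enumerate(self.proportions[:-1]):
            out.append((i * self.bin_width, (i + 1) * self.bin_width, p))
        out.append((self.cap, math.inf, self.proportions[-1]))
        return out

    def modal_bin(self) -> tuple[float, float]:
        i = max(range(len(self.proportions)), key=lambda k: self.proportions[k])
        lo, hi, _ = self.bins()[i]
        return (lo, hi)


def build_histograms(
    records: Iterable[KsRecord], bin_width: float = 0.1, cap: float = 3.0
) -> list[KsHistogram]:
    """Per-category Ks histograms as proportions; empty categories omitted.

    Saturated and incomparable pairs are excluded (and logged); bins are
    left-inclusive.
    """
    n_bins = int(round(cap / bin_width))
    by_cat: dict[str, list[float]] = {}
    n_excluded = 0
    for r in records:
        if not r.comparable or r.saturated or math.isnan(r.ks):
            n_excluded += 1
            continue
        by_cat.setdefault(r.category, []).append(r.ks)
    if n_excluded:
        log.info("build_histograms: excluded %d saturated/incomparable pair(s)", n_excluded)
    hists = []
    for cat in sorted(by_cat):
        values = by_cat[cat]
        counts = [0] * (n_bins + 1)
        for v in values:
            idx = n_bins if v >= cap else int(v / bin_width)
            counts[idx] += 1
        total = len(values)
        hists.append(
            KsHistogram(
                category=cat,
                bin_width=bin_width,
                cap=cap,
                proportions=tuple(c / total for c in counts),
                n_pairs=total,
            )
        )
    return hists


def write_ks_table(records: Sequence[KsRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family_id\tid_a\tid_b\tcategory\tps\tpn\tks\tka\t"
            "codons_compared\tsaturated\tcomparable\n"
        )
        for r in records:
            fh.write(
                f"{r.family_id}\t{r.id_a}\t{r.id_b}\t{r.category}\t"
                f"{r.ps:.6f}\t{r.pn:.6f}\t{r.ks:.6f}\t{r.ka:.6f}\t"
                f"{r.codons_compared}\t{int(r.saturated)}\t{int(r.comparable)}\n"
            )


def write_histograms(hists: Sequence[KsHistogram], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tbin_lo\tbin_hi\tproportion\tn_pairs\n")
        for h in hists:
            for lo, hi, p in h.bins():
                hi_txt = "inf" if math.isinf(hi) else f"{hi:.1f}"
                fh.write(f"{h.category}\t{lo:.1f}\t{hi_txt}\t{p:.6f}\t{h.n_pairs}\n")
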
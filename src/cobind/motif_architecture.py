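"""Consensus-motif scanning and motif-architecture statistics.

This module answers three questions about a set of bound regions: how many
copies of a consensus motif each region carries, how consecutive copies are
spaced, and whether hits concentrate at region centers.  Scanning is exact
IUPAC-consensus matching on both strands; a palindromic consensus (one that
equals its own reverse complement, like the G-box CACGTG) is reported once,
on the forward strand, so it is never double counted.

Built-in specs cover the two motifs of interest: the G-box (CACGTG), bound by
bHLH factors such as PIF4, and the DOF-binding motif, available both as the
strict core AAAAG and as the broader consensus [T/A]AAAG (IUPAC WAAAG).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneModel, Peak

__all__ = [
    "IUPAC",
    "MotifSpec",
    "MotifHit",
    "SpacingDistribution",
    "CentralEnrichmentResult",
    "GBOX",
    "DOF_STRICT",
    "DOF_BROAD",
    "reverse_complement",
    "scan_motif",
    "scan_regions",
    "promoter_sequence",
    "motif_counts_per_peak",
    "spacing_distances",
    "background_spacing",
    "central_enrichment",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC-consensus string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are enumerated
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
        for c in consensus
    )
    return re.compile(f"(?={body})")


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC consensus motif."""

    name: str
    consensus: str

    def __post_init__(self):
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = [c for c in self.consensus if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in {self.consensus!r}")

    @property
    def palindromic(self) -> bool:
        """True when the consensus equals its IUPAC reverse complement."""
        return self.consensus == reverse_complement(self.consensus)

    def __len__(self) -> int:
        return len(self.consensus)


GBOX = MotifSpec("gbox", "CACGTG")
DOF_STRICT = MotifSpec("dof", "AAAAG")
DOF_BROAD = MotifSpec("dof_broad", "WAAAG")


@dataclass(frozen=True)
class MotifHit:
    """One consensus match inside one region, at its forward-strand offset."""

    motif_name: str
    region_id: str
    offset: int
    strand: str


def scan_motif(
    sequence: str,
    spec: MotifSpec,
    region_id: str = "",
    count_policy: str = "all",
) -> list[MotifHit]:
    """Scan one region for exact IUPAC-consensus matches on both strands.

    Minus-strand matches are reported at their forward-strand start offset.
    Palindromic motifs are scanned on the forward strand only.  ``N`` in the
    sequence never matches.  ``count_policy="all"`` reports every match;
    ``"nonoverlapping"`` keeps a greedy left-to-right subset per strand.
    """
    if count_policy not in ("all", "nonoverlapping"):
        raise ValueError(f"unknown count_policy {count_policy!r}")
    seq = sequence.upper()
    hits: list[MotifHit] = []
    strands = [("+", spec.consensus)]
    if not spec.palindromic:
        strands.append(("-", reverse_complement(spec.consensus)))
    m = len(spec)
    for strand, consensus in strands:
        offsets = [mt.start() for mt in _iupac_regex(consensus).finditer(seq)]
        if count_policy == "nonoverlapping":
            kept, last_end = [], -1
            for off in offsets:
                if off >= last_end:
                    kept.append(off)
                    last_end = off + m
            offsets = kept
        hits.extend(MotifHit(spec.name, region_id, off, strand) for off in offsets)
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(
    sequences: Mapping[str, str],
    specs: Iterable[MotifSpec],
    count_policy: str = "all",
) -> list[MotifHit]:
    """Scan many regions for many motifs; convenience wrapper over scan_motif."""
    hits: list[MotifHit] = []
    for spec in specs:
        for region_id, seq in sequences.items():
            hits.extend(scan_motif(seq, spec, region_id, count_policy))
    return hits


def motif_counts_per_peak(
    hits: Iterable[MotifHit], peaks: Sequence[Peak]
) -> dict[str, dict[int, int]]:
    """Per-motif frequency table: motif count k -> number of peaks with k hits.

    Peaks with zero hits are included at k=0, so each motif's table sums to
    the number of peaks.
    """
    peak_ids = {p.id for p in peaks}
    per_region: dict[str, Counter] = defaultdict(Counter)
    motifs = set()
    for h in hits:
        if h.region_id not in peak_ids:
            raise ValueError(f"hit references unknown peak {h.region_id!r}")
        motifs.add(h.motif_name)
        per_region[h.motif_name][h.region_id] += 1
    tables: dict[str, dict[int, int]] = {}
    for motif in motifs:
        counts = Counter(per_region[motif].get(p.id, 0) for p in peaks)
        tables[motif] = dict(sorted(counts.items()))
    return tables


@dataclass
class SpacingDistribution:
    """Start-to-start distances between consecutive same-motif hits.

    Distances are pooled across regions (regions with fewer than two hits
    contribute nothing) and summarized by a fixed-width histogram whose
    maximal bin's center is the mode estimate.
    """

    distances: list[int]
    bin_width: int = 5
    bin_edges: np.ndarray = field(default=None, repr=False)
    histogram: np.ndarray = field(default=None, repr=False)
    mode_estimate: float | None = None

    def __post_init__(self):
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if self.distances:
            top = (max(self.distances) // self.bin_width + 1) * self.bin_width
            self.bin_edges = np.arange(0, top + self.bin_width, self.bin_width)
            self.histogram, _ = np.histogram(self.distances, bins=self.bin_edges)
            i = int(np.argmax(self.histogram))
            self.mode_estimate = float(
                (self.bin_edges[i] + self.bin_edges[i + 1]) / 2
            )
        else:
            self.bin_edges = np.array([])
            self.histogram = np.array([], dtype=int)
            self.mode_estimate = None


def spacing_distances(hits: Iterable[MotifHit], bin_width: int = 5) -> SpacingDistribution:
    """Pooled consecutive-hit spacings of one motif across regions.

    Within each region hits are sorted by offset (strand ignored) and the
    successive start-to-start differences are collected.
    """
    by_region: dict[str, list[int]] = defaultdict(list)
    for h in hits:
        by_region[h.region_id].append(h.offset)
    distances: list[int] = []
    for offsets in by_region.values():
        offsets = sorted(set(offsets))
        distances.extend(b - a for a, b in zip(offsets, offsets[1:]))
    return SpacingDistribution(distances=distances, bin_width=bin_width)


def promoter_sequence(
    gene: GeneModel, genome: Mapping[str, str], window: int = 1000
) -> str:
    """The ``window`` bp 5' of the TSS in gene orientation (clipped at
    chromosome bounds), returned in gene orientation."""
    chrom_seq = genome[gene.interval.chrom]
    if gene.interval.strand == "+":
        lo = max(0, gene.tss - window)
        return chrom_seq[lo : gene.tss]
    hi = min(len(chrom_seq), gene.tss + 1 + window)
    return reverse_complement(chrom_seq[gene.tss + 1 : hi])


def background_spacing(
    genes: Sequence[GeneModel],
    target_gene_ids: set[str],
    genome: Mapping[str, str],
    spec: MotifSpec,
    promoter_window: int = 1000,
    bin_width: int = 5,
    count_policy: str = "all",
) -> SpacingDistribution:
    """Spacing distribution in the promoters of genes NOT in the target set."""
    non_targets = [g for g in genes if g.id not in target_gene_ids]
    if not non_targets:
        raise ValueError("no non-target genes to build a background from")
    hits: list[MotifHit] = []
    for g in non_targets:
        seq = promoter_sequence(g, genome, promoter_window)
        hits.extend(scan_motif(seq, spec, region_id=g.id, count_policy=count_policy))
    return spacing_distances(hits, bin_width=bin_width)


@dataclass
class CentralEnrichmentResult:
    motif_name: str
    window_halfwidth: int
    hits_in_window: int
    hits_total: int
    expected_fraction: float
    p: float  # binomial upper tail, Bonferroni-adjusted over candidate windows
    best: bool = False


def central_enrichment(
    hits: Sequence[MotifHit],
    peaks: Sequence[Peak],
    spec: MotifSpec,
    candidate_halfwidths: Sequence[int] = (25, 50, 100, 150),
) -> list[CentralEnrichmentResult]:
    """Test whether hits of one motif concentrate near peak centers.

    For each half-width w a hit counts as central when the center of its
    match lies within w bp of its peak's center.  The expected central
    fraction under uniform placement is the mean over peaks of
    min(2w, placeable span) / placeable span; the one-sided binomial
    upper-tail p is Bonferroni-adjusted over the candidate windows and the
    smallest adjusted p is flagged best.  Windows wider than every peak half
    are skipped as uninformative.
    """
    peak_len = {p.id: p.length for p in peaks}
    peak_lengths = np.array([p.length for p in peaks], dtype=float)
    motif_len = len(spec)
    n_total = len(hits)
    offsets = np.array([h.offset for h in hits], dtype=float)
    hit_peak_len = np.array([peak_len[h.region_id] for h in hits], dtype=float)
    span = np.maximum(peak_lengths - motif_len + 1, 1.0)  # placeable starts
    center_dev = np.abs(offsets + motif_len / 2 - hit_peak_len / 2)

    usable = [w for w in candidate_halfwidths if not (w > peak_lengths / 2).all()]
    n_windows = max(len(usable), 1)
    results: list[CentralEnrichmentResult] = []
    for w in usable:
        k = int((center_dev <= w).sum()) if n_total else 0
        expected = float(np.mean(np.minimum(2 * w, span) / span))
        if n_total == 0:
            p = 1.0
        else:
            p = float(stats.binom.sf(k - 1, n_total, min(expected, 1.0)))
            p = min(1.0, p * n_windows)
        results.append(
            CentralEnrichmentResult(spec.name, int(w), k, n_total, expected, p)
        )
    if results and n_total:
        best = min(range(len(results)), key=lambda i: results[i].p)
        results[best].best = True
    return results
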
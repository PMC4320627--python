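"""Placement of merged peaks relative to gene structure.

Each merged peak is classified as coding or non-coding, assigned the gene
whose predicted translation start codon (TSC) is nearest, given a signed
distance in the gene's reading orientation (negative = upstream of the start
codon), and linked to every gene whose promoter window — default 400 bp
upstream to 100 bp downstream of the TSC, both ends inclusive — contains the
peak.  A peak sitting between two opposite-strand genes transcribed away
from each other is flagged divergent and counts toward both genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from chipregulon.concordance import MergedPeak
from chipregulon.formats import (
    FORWARD,
    GeneList,
    GeneRecord,
    GenomeModel,
    ValidationError,
)


@dataclass
class PeakAnnotation:
    peak: MergedPeak
    region_class: str  # "coding" | "noncoding"
    nearest_genes: list[tuple[str, int]]  # (gene_id, signed distance); 2 iff tied
    promoter_hits: list[tuple[str, int]]
    divergent: bool


def signed_distance(peak_coordinate: int, gene: GeneRecord) -> int:
    """Signed peak-to-TSC distance in the gene's reading orientation.

    Negative values are upstream of the start codon; on a reverse-strand
    gene "upstream" lies genomically rightward, so the sign flips.
    """
    if gene.strand == FORWARD:
        return peak_coordinate - gene.tsc
    return gene.tsc - peak_coordinate


class _GenomeIndex:
    """Sorted TSC array + merged coding intervals for fast lookups."""

    def __init__(self, genome: GenomeModel):
        if not genome.genes:
            raise ValidationError("genome has no genes")
        self.genome = genome
        order = sorted(range(len(genome.genes)),
                       key=lambda i: genome.genes[i].tsc)
        self.tsc = np.array([genome.genes[i].tsc for i in order])
        self.gene_order = [genome.genes[i] for i in order]
        starts, ends = [], []
        for g in genome.genes:  # genes sorted by coding_start
            if starts and g.coding_start <= ends[-1]:
                ends[-1] = max(ends[-1], g.coding_end)
            else:
                starts.append(g.coding_start)
                ends.append(g.coding_end)
        self.coding_starts = np.array(starts)
        self.coding_ends = np.array(ends)


def _index(genome) -> _GenomeIndex:
    if isinstance(genome, _GenomeIndex):
        return genome
    return _GenomeIndex(genome)


def nearest_tsc(peak_coordinate: int, genome) -> list[tuple[str, int]]:
    """Gene(s) whose TSC is nearest the peak; exact |distance| ties return both."""
    ix = _index(genome)
    i = np.searchsorted(ix.tsc, peak_coordinate)
    cand = {int(j) for j in (i - 1, i, i + 1) if 0 <= j < len(ix.tsc)}
    best = min(abs(peak_coordinate - int(ix.tsc[j])) for j in cand)
    hits = [
        (ix.gene_order[j].gene_id, signed_distance(peak_coordinate, ix.gene_order[j]))
        for j in sorted(cand)
        if abs(peak_coordinate - int(ix.tsc[j])) == best
    ]
    return hits


def classify_region(peak_coordinate: int, genome) -> str:
    """'coding' iff the coordinate falls inside any gene's half-open coding span."""
    ix = _index(genome)
    i = np.searchsorted(ix.coding_starts, peak_coordinate, side="right") - 1
    if i >= 0 and peak_coordinate < ix.coding_ends[i]:
        return "coding"
    return "noncoding"


def promoter_hits(
    peak_coordinate: int, genome, window: tuple[int, int] = (-400, 100)
) -> tuple[list[tuple[str, int]], bool]:
    """All genes whose promoter window (inclusive bounds) contains the peak.

    Returns the hits and a divergence flag: true iff the hits include an
    opposite-strand pair whose TSCs flank the peak (a forward gene with TSC
    at or right of the peak and a reverse gene with TSC at or left of it) —
    the shared intergenic region of two divergently transcribed genes.
    """
    ix = _index(genome)
    lo, hi = window
    reach = max(abs(lo), abs(hi))
    i0 = np.searchsorted(ix.tsc, peak_coordinate - reach, side="left")
    i1 = np.searchsorted(ix.tsc, peak_coordinate + reach, side="right")
    hits = []
    for j in range(i0, i1):
        g = ix.gene_order[j]
        d = signed_distance(peak_coordinate, g)
        if lo <= d <= hi:
            hits.append((g.gene_id, d))
    gene_of = {g.gene_id: g for g in ix.gene_order}
    fwd_right = any(
        gene_of[gid].strand == FORWARD and gene_of[gid].tsc >= peak_coordinate
        for gid, _ in hits
    )
    rev_left = any(
        gene_of[gid].strand != FORWARD and gene_of[gid].tsc <= peak_coordinate
        for gid, _ in hits
    )
    return hits, (fwd_right and rev_left)


def collapse_to_promoter_regions(
    gene_list: GeneList, operon_map: dict[str, tuple[str, int]]
) -> GeneList:
    """Drop list members that sit downstream of the first gene of an operon.

    Genes without operon information are retained; an operon's promoter is
    the region upstream of its first gene only.
    """
    kept = set()
    for gid in gene_list.members:
        op = operon_map.get(gid)
        if op is None or op[1] == 1:
            kept.add(gid)
    return GeneList(f"{gene_list.name}_promoter_regions", kept)


def annotate_all(
    merged_peaks: Sequence[MergedPeak],
    genome: GenomeModel,
    window: tuple[int, int] = (-400, 100),
) -> tuple[list[PeakAnnotation], dict]:
    """Annotate every merged peak; returns annotations plus summary counts.

    The summary reports how many peaks are coding vs non-coding, how many
    sit in a promoter window ("promoter sites"), how many of those are
    divergent, the number of distinct promoter-hit genes (divergent sites
    contribute both flanking genes), and the nearest-TSC signed distances
    for histogramming.
    """
    ix = _GenomeIndex(genome)
    annotations = []
    distances = []
    hit_genes: set[str] = set()
    n_coding = n_promoter = n_divergent = 0
    for mp in merged_peaks:
        near = nearest_tsc(mp.coordinate, ix)
        region = classify_region(mp.coordinate, ix)
        hits, divergent = promoter_hits(mp.coordinate, ix, window)
        ann = PeakAnnotation(mp, region, near, hits, divergent)
        annotations.append(ann)
        distances.append(near[0][1])
        if region == "coding":
            n_coding += 1
        if hits:
            n_promoter += 1
            if divergent:
                n_divergent += 1
            hit_genes.update(g for g, _ in hits)
    summary = {
        "n_peaks": len(annotations),
        "n_coding": n_coding,
        "n_noncoding": len(annotations) - n_coding,
        "n_promoter_sites": n_promoter,
        "n_divergent_sites": n_divergent,
        "n_promoter_genes": len(hit_genes),
        "promoter_genes": sorted(hit_genes),
        "tsc_distances": np.array(distances),
    }
    return annotations, summary


def distance_histogram(distances, bin_width: int = 50,
                       span: tuple[int, int] = (-1000, 1000)):
    """Histogram of signed nearest-TSC distances (figure-style summary)."""
    edges = np.arange(span[0], span[1] + bin_width, bin_width)
    counts, edges = np.histogram(np.clip(distances, span[0], span[1] - 1), bins=edges)
    return counts, edges
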
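"""Functional-category and gene-list enrichment among promoter-hit genes.

Counting is gene-level: a gene counts once toward the "observed" column no
matter how many peaks land in its promoter window, and a divergent site
contributes both flanking genes.  The expected count for a category of size
``n_genome`` is ``n_genome * near_total / genome_total`` where ``near_total``
is the number of distinct genes with a binding site in their promoter window
and ``genome_total`` the number of genes in the universe (categorized genes
for category tables, all annotated genes for arbitrary lists).  Association
is tested per row with a two-sided Fisher's exact test on

    [[n_observed, n_genome - n_observed],
     [near_total - n_observed, (genome_total - n_genome) - (near_total - n_observed)]]

No multiple-testing correction is applied by default (raw p-values per row,
matching the published presentation); an optional Benjamini-Hochberg column
can be requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chipregulon.annotate import PeakAnnotation
from chipregulon.formats import GeneList, GenomeModel, ValidationError, round_half_up


@dataclass
class EnrichmentRow:
    label: str
    n_genome: int
    n_observed: int
    n_expected_raw: float
    n_expected: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p_value outside [0, 1]")
        if self.n_observed > self.n_genome:
            raise ValidationError("n_observed cannot exceed n_genome")


def expected_count(n_genome: int, near_total: int, genome_total: int
                   ) -> tuple[float, int]:
    """Expected promoter-hit genes in a category of size ``n_genome``.

    raw = n_genome * near_total / genome_total; the displayed value is the
    raw value rounded half away from zero.
    """
    if genome_total <= 0:
        raise ValidationError("genome_total must be positive")
    if n_genome > genome_total:
        raise ValidationError("n_genome cannot exceed genome_total")
    raw = n_genome * near_total / genome_total
    return raw, round_half_up(raw)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    The two-sided p sums the hypergeometric probabilities of all tables with
    the same margins that are no more likely than the observed one
    (minimum-likelihood rule, as implemented by scipy).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("counts must be nonnegative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def _promoter_hit_genes(annotations: Iterable[PeakAnnotation]) -> set[str]:
    genes: set[str] = set()
    for ann in annotations:
        genes.update(g for g, _ in ann.promoter_hits)
    return genes


def _row(label: str, universe: set[str], members: set[str], hit_genes: set[str]
         ) -> EnrichmentRow:
    near_total = len(hit_genes & universe)
    genome_total = len(universe)
    n_genome = len(members & universe)
    n_observed = len(members & hit_genes & universe)
    raw, rounded = expected_count(n_genome, near_total, genome_total)
    p = fisher_2x2(
        n_observed,
        n_genome - n_observed,
        near_total - n_observed,
        (genome_total - n_genome) - (near_total - n_observed),
    )
    return EnrichmentRow(label, n_genome, n_observed, raw, rounded, p)


def category_table(
    annotations: Sequence[PeakAnnotation],
    genome: GenomeModel,
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Per-functional-category enrichment of promoter-hit genes.

    The universe is the set of genes carrying a category label; genes
    without one are excluded from both margins, mirroring analyses restricted
    to the categorized fraction of the genome.  A ``Total`` row is appended;
    its raw expected value equals ``near_total`` exactly (the expected
    counts are linear in category size and the categories partition the
    universe).
    """
    universe = {g.gene_id for g in genome.genes if g.category is not None}
    if not universe:
        raise ValidationError("no gene in the genome carries a category")
    hit_genes = _promoter_hit_genes(annotations) & universe
    by_cat: dict[str, set[str]] = {}
    for g in genome.genes:
        if g.category is not None:
            by_cat.setdefault(g.category, set()).add(g.gene_id)

    rows = [_row(cat, universe, members, hit_genes)
            for cat, members in sorted(by_cat.items())]
    df = _to_frame(rows, add_fdr)
    total = pd.DataFrame([{
        "label": "Total",
        "n_genome": len(universe),
        "n_observed": len(hit_genes),
        "n_expected_raw": float(len(hit_genes)),
        "n_expected": len(hit_genes),
        "p_value": np.nan,
    }])
    return pd.concat([df, total], ignore_index=True)


def genelist_enrichment(
    annotations: Sequence[PeakAnnotation],
    gene_list: GeneList,
    genome: GenomeModel,
    operon_map: dict[str, tuple[str, int]] | None = None,
    collapse_operons: bool = False,
) -> EnrichmentRow:
    """Enrichment of one gene list among promoter-hit genes (whole-genome universe).

    With ``collapse_operons`` the list is first reduced to operon promoter
    regions (members downstream of the first gene of an operon dropped).
    """
    if not gene_list.members:
        raise ValidationError(f"gene list {gene_list.name} is empty")
    if collapse_operons:
        from chipregulon.annotate import collapse_to_promoter_regions
        gene_list = collapse_to_promoter_regions(gene_list, operon_map or {})
        if not gene_list.members:
            raise ValidationError(f"gene list {gene_list.name} empty after collapsing")
    universe = set(genome.gene_ids)
    validated = gene_list.validate(genome)
    if not validated.members:
        raise ValidationError(
            f"gene list {gene_list.name} has no members in the genome")
    hit_genes = _promoter_hit_genes(annotations) & universe
    return _row(gene_list.name, universe, validated.members, hit_genes)


def genelist_table(
    annotations: Sequence[PeakAnnotation],
    gene_lists: Sequence[GeneList],
    genome: GenomeModel,
    operon_map: dict[str, tuple[str, int]] | None = None,
    add_fdr: bool = False,
) -> pd.DataFrame:
    rows = [genelist_enrichment(annotations, gl, genome) for gl in gene_lists]
    return _to_frame(rows, add_fdr)


def compare_lists(list_a: GeneList, list_b: GeneList
                  ) -> tuple[list[str], list[str], list[str]]:
    """Set comparison of two gene lists: (intersection, A-only, B-only), sorted."""
    inter = sorted(list_a.members & list_b.members)
    a_only = sorted(list_a.members - list_b.members)
    b_only = sorted(list_b.members - list_a.members)
    return inter, a_only, b_only


def _to_frame(rows: Sequence[EnrichmentRow], add_fdr: bool) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows],
                      columns=["label", "n_genome", "n_observed",
                               "n_expected_raw", "n_expected", "p_value"])
    if add_fdr and len(df):
        # Benjamini-Hochberg: not part of the published presentation
        from statsmodels.stats.multitest import multipletests

        df["fdr_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
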
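"""Domain types and file I/O for the pipeline.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open.  GFF3 (1-based inclusive)
is converted at the boundary.  A site ``s`` lies inside gene ``g`` iff
``g.coding_start <= s < g.coding_end``.  The predicted translation start
codon (TSC) of a forward-strand gene is ``coding_start``; for a
reverse-strand gene it is ``coding_end - 1`` (the first transcribed base
on forward genomic coordinates).

The genome model is single-chromosome: the target organisms are bacteria
with one circular chromosome.  The ``circular`` flag is carried as metadata
only; all distance computations are linear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml

FORWARD = "+"
REVERSE = "-"


class ParseError(ValueError):
    """Malformed input file (carries the offending line number when known)."""


class ValidationError(ValueError):
    """Input parsed but violates a documented precondition."""


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene on the single chromosome.

    ``coding_start``/``coding_end`` are 0-based half-open on forward genomic
    coordinates regardless of strand.
    """

    gene_id: str
    strand: str
    coding_start: int
    coding_end: int
    category: str | None = None
    operon_id: str | None = None
    operon_position: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.coding_start < self.coding_end:
            raise ValidationError(
                f"{self.gene_id}: coding_start must be < coding_end "
                f"({self.coding_start} >= {self.coding_end})"
            )
        if self.operon_position is not None and self.operon_position < 1:
            raise ValidationError(f"{self.gene_id}: operon_position must be >= 1")

    @property
    def tsc(self) -> int:
        """Predicted translation start codon position (0-based)."""
        if self.strand == FORWARD:
            return self.coding_start
        return self.coding_end - 1

    @property
    def length(self) -> int:
        return self.coding_end - self.coding_start


@dataclass
class GenomeModel:
    """Single-chromosome genome: length plus annotated genes, sorted by start."""

    chromosome_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("genome length must be positive")
        for g in self.genes:
            if g.coding_start < 0 or g.coding_end > self.length:
                raise ValidationError(
                    f"gene {g.gene_id} [{g.coding_start}, {g.coding_end}) outside "
                    f"genome [0, {self.length})"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.coding_start, g.gene_id))
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def coding_fraction(self) -> float:
        """Fraction of the chromosome covered by at least one coding span."""
        if not self.genes:
            return 0.0
        covered = 0
        cur_start, cur_end = self.genes[0].coding_start, self.genes[0].coding_end
        for g in self.genes[1:]:
            if g.coding_start <= cur_end:
                cur_end = max(cur_end, g.coding_end)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = g.coding_start, g.coding_end
        covered += cur_end - cur_start
        return covered / self.length


@dataclass(frozen=True, order=True)
class Peak:
    """A single-replicate peak maximum with its enrichment score."""

    coordinate: int
    enrichment: float
    replicate_id: str = ""
    rank_in_replicate: int | None = None

    def __post_init__(self) -> None:
        if self.coordinate < 0:
            raise ValidationError(f"negative peak coordinate {self.coordinate}")
        if self.enrichment < 0:
            raise ValidationError("enrichment must be nonnegative")


@dataclass
class GeneList:
    """A named set of gene identifiers (e.g. developmentally up-regulated genes)."""

    name: str
    members: set[str]

    def validate(self, genome: GenomeModel, strict: bool = False) -> "GeneList":
        known = set(genome.gene_ids)
        unknown = self.members - known
        if unknown and strict:
            raise ValidationError(
                f"list {self.name}: {len(unknown)} unknown gene ids, e.g. "
                f"{sorted(unknown)[:3]}"
            )
        return GeneList(self.name, self.members & known)


@dataclass
class AnalysisConfig:
    """Tunable constants of the pipeline.

    Defaults are the published analysis settings: a 65-bp replicate
    concordance cutoff, a promoter window from 400 bp upstream to 100 bp
    downstream of the TSC (both ends inclusive), 50 bp of flanking sequence
    around each peak maximum for motif work, motif discovery on the top 500
    ranked peaks partitioned into sets of 50.
    """

    concordance_cutoff: int = 65
    promoter_window: tuple[int, int] = (-400, 100)
    flank: int = 50
    motif_width: int = 15
    top_n_for_motif: int = 500
    partition_size: int = 50
    mc_replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.promoter_window
        if not lo < hi:
            raise ValidationError("promoter_window lower bound must be < upper")
        for name in ("flank", "motif_width", "top_n_for_motif", "partition_size",
                     "mc_replicates"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.concordance_cutoff < 0:
            raise ValidationError("concordance_cutoff must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "promoter_window" in raw:
            raw["promoter_window"] = tuple(raw["promoter_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["promoter_window"] = list(d["promoter_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    category_table: str | Path | None = None,
    operon_table: str | Path | None = None,
    length: int | None = None,
) -> GenomeModel:
    """Read gene annotations from a GFF3 file into a :class:`GenomeModel`.

    Uses ``gene`` features (falling back to ``CDS`` when no genes are
    present).  Coordinates are converted from 1-based inclusive to 0-based
    half-open.  The chromosome length is taken from the ``##sequence-region``
    pragma unless ``length`` is given.  Functional categories and operon
    membership rarely travel in GFF3 attributes, so they are joined from
    separate two/three-column TSVs keyed by gene id.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", force=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: not parseable as GFF3 ({exc})") from exc

    feature_types = set(db.featuretypes())
    ftype = "gene" if "gene" in feature_types else "CDS"
    features = list(db.features_of_type(ftype, order_by="start"))
    if not features:
        raise ParseError(f"{path}: no gene/CDS features found")

    seqids = {f.seqid for f in features}
    if len(seqids) > 1:
        raise ValidationError(
            f"{path}: multi-chromosome input not supported (seqids: {sorted(seqids)})"
        )
    chrom = seqids.pop()

    declared = _sequence_region_length(path, chrom)
    genome_length = length or declared
    if genome_length is None:
        genome_length = max(f.end for f in features)

    categories = _read_two_col(category_table, "category") if category_table else {}
    operons = read_operon_table(operon_table) if operon_table else {}

    genes = []
    for f in features:
        gid = f.attributes.get("ID", [None])[0] or f.attributes.get(
            "locus_tag", [None])[0] or f.id
        op = operons.get(gid, (None, None))
        rec = GeneRecord(
            gene_id=gid,
            strand=f.strand,
            coding_start=f.start - 1,  # GFF3 is 1-based inclusive
            coding_end=f.end,
            category=categories.get(gid),
            operon_id=op[0],
            operon_position=op[1],
        )
        if rec.coding_end > genome_length:
            raise ValidationError(
                f"{path}: gene {gid} extends past declared sequence region "
                f"({rec.coding_end} > {genome_length})"
            )
        genes.append(rec)

    return GenomeModel(chromosome_id=chrom, length=genome_length, genes=genes)


def _sequence_region_length(path: Path, chrom: str) -> int | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4 and parts[1] == chrom:
                    return int(parts[3])
            elif not line.startswith("#"):
                break
    return None


def write_gff3(genome: GenomeModel, path: str | Path) -> None:
    """Write the gene annotations back out as GFF3 (gene features only)."""
    lines = ["##gff-version 3",
             f"##sequence-region {genome.chromosome_id} 1 {genome.length}"]
    for g in genome.genes:
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join([
                genome.chromosome_id, "chip-regulon", "gene",
                str(g.coding_start + 1), str(g.coding_end), ".", g.strand, ".",
                attrs,
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (sequence_id, uppercase sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise ValidationError(f"{path}: multi-record FASTA not supported")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(seq_id: str, sequence: str, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, replicate_id: str = "") -> list[Peak]:
    """Read per-replicate peak calls from a 2-column TSV or a BED file.

    TSV rows are ``coordinate<TAB>enrichment``; BED rows are
    ``chrom start end score`` with the peak maximum taken as the interval
    midpoint.  Ranks are assigned by descending enrichment, ties broken by
    ascending coordinate; the returned list is sorted by coordinate.
    """
    path = Path(path)
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if _is_number(parts[0]):  # TSV: coordinate, enrichment
                if lineno == 1 and len(parts) >= 2 and not _is_number(parts[1]):
                    continue  # header
                coord_f, score_f = parts[0], parts[1]
                try:
                    coord = int(float(coord_f))
                    score = float(score_f)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            else:
                if len(parts) < 3:
                    if lineno == 1:
                        continue  # header line
                    raise ParseError(f"{path}:{lineno}: too few BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                    score = float(parts[3]) if len(parts) > 3 else 0.0
                except ValueError:
                    if lineno == 1:
                        continue  # header with column names
                    raise ParseError(f"{path}:{lineno}: non-numeric field")
                coord = (start + end) // 2
            if coord < 0:
                raise ValidationError(f"{path}:{lineno}: negative coordinate")
            rows.append((coord, score))
    return build_peaks(rows, replicate_id)


def build_peaks(rows: Iterable[tuple[int, float]], replicate_id: str = "") -> list[Peak]:
    """Assemble ranked, coordinate-sorted :class:`Peak` objects."""
    rows = list(rows)
    order = sorted(range(len(rows)), key=lambda i: (-rows[i][1], rows[i][0]))
    ranks = {}
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    peaks = [
        Peak(coordinate=c, enrichment=s, replicate_id=replicate_id,
             rank_in_replicate=ranks[i])
        for i, (c, s) in enumerate(rows)
    ]
    return sorted(peaks, key=lambda p: p.coordinate)


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    df = pd.DataFrame(
        {"coordinate": [p.coordinate for p in peaks],
         "enrichment": [p.enrichment for p in peaks]}
    )
    df.to_csv(path, sep="\t", index=False)


PEAK_TABLE_COLUMNS = [
    "overall_rank", "coordinate", "rank_rep1", "rank_rep2",
    "coordinate_rep1", "coordinate_rep2", "nearest_gene", "distance_to_tsc",
    "region_class", "promoter_genes", "divergent",
]


def write_peak_table(annotations, path: str | Path) -> pd.DataFrame:
    """Write the final annotated peak table.

    One row per merged peak, sorted by overall rank, reproducing the
    published supplementary layout: overall rank, averaged coordinate,
    per-replicate ranks and maxima, nearest-TSC gene and signed distance —
    plus the region class, promoter-window gene hits and the divergent flag.
    """
    rows = []
    for ann in annotations:
        if ann.nearest_genes is None:
            raise ValidationError("write_peak_table requires annotated peaks")
        mp = ann.peak
        nearest_ids = ";".join(g for g, _ in ann.nearest_genes)
        rows.append({
            "overall_rank": mp.overall_rank,
            "coordinate": mp.coordinate,
            "rank_rep1": mp.replicate_ranks[0],
            "rank_rep2": mp.replicate_ranks[1],
            "coordinate_rep1": mp.replicate_coordinates[0],
            "coordinate_rep2": mp.replicate_coordinates[1],
            "nearest_gene": nearest_ids,
            "distance_to_tsc": ann.nearest_genes[0][1],
            "region_class": ann.region_class,
            "promoter_genes": ";".join(f"{g}:{d}" for g, d in ann.promoter_hits),
            "divergent": ann.divergent,
        })
    df = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    df = df.sort_values("overall_rank").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_merged_peaks(path: str | Path):
    """Re-read a merged-peak table written by :func:`write_peak_table`.

    Also accepts a minimal TSV export of a published peak table with at
    least ``overall_rank``, ``coordinate``, ``coordinate_rep1``,
    ``coordinate_rep2`` columns.
    """
    from chipregulon.concordance import MergedPeak

    df = pd.read_csv(path, sep="\t")
    required = {"overall_rank", "coordinate", "coordinate_rep1", "coordinate_rep2"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    merged = []
    for _, row in df.iterrows():
        c1, c2 = int(row["coordinate_rep1"]), int(row["coordinate_rep2"])
        merged.append(MergedPeak(
            coordinate=int(row["coordinate"]),
            replicate_coordinates=(c1, c2),
            replicate_ranks=(int(row.get("rank_rep1", 0) or 0),
                             int(row.get("rank_rep2", 0) or 0)),
            replicate_distance=abs(c1 - c2),
            overall_rank=int(row["overall_rank"]),
            mean_enrichment=float(row.get("mean_enrichment", 0.0) or 0.0),
        ))
    return sorted(merged, key=lambda m: m.overall_rank)


# ---------------------------------------------------------------------------
# Gene lists, categories, operons
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list (one id per line; '#' comments allowed)."""
    path = Path(path)
    members = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#")[0].strip()
            if token:
                members.add(token.split("\t")[0])
    return GeneList(name or path.stem, members)


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gene_list.members)) + "\n")


def read_category_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene_id, functional category."""
    return _read_two_col(path, "category")


def read_operon_table(path: str | Path) -> dict[str, tuple[str, int]]:
    """Three-column TSV: gene_id, operon_id, position (1 = first gene)."""
    out: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and not _is_number(parts[2]):
                continue  # header
            out[parts[0]] = (parts[1], int(parts[2]))
    return out


def write_operon_table(operons: dict[str, tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\toperon_id\tposition\n")
        for gid in sorted(operons):
            op, pos = operons[gid]
            fh.write(f"{gid}\t{op}\t{pos}\n")


def _read_two_col(path: str | Path, what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns for {what}")
            if lineno == 1 and parts[0].lower() in ("gene_id", "gene", "id"):
                continue
            out[parts[0]] = parts[1]
    return out


def write_category_table(categories: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gid in sorted(categories):
            fh.write(f"{gid}\t{categories[gid]}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
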
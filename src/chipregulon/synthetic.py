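"""Synthetic genomes, planted binding sites, replicate peaks and gene lists.

The generator emulates the regime of a gene-dense, GC-rich bacterial genome
bound genome-wide by a dimeric transcription factor:

* a single chromosome, ~90% coding, genes on both strands, with functional
  categories and partial operon structure;
* true binding sites biased toward promoter regions (a configurable signed
  distance upstream of a random gene's start codon), each carrying a sampled
  instance of the degenerate palindrome TGTYN8RAC written into the sequence
  (reverse-complemented half the time);
* two replicate peak lists in which shared true sites recur with independent
  Laplace positional jitter while unshared true sites and uniformly scattered
  false peaks appear in one replicate only, with true sites drawn from a
  higher enrichment-score distribution;
* gene lists with a planted fold over/under-representation among
  promoter-hit genes;
* strand-aware read-start positions around each site for the peak caller.

Every output is reproducible from (parameters, seed), and the full ground
truth is recorded so downstream modules can be tested closed-loop.
Defaults are a ~1 Mb, 800-gene toy genome: the density regime of the real
organism at a scale the whole pipeline traverses in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from chipregulon.formats import (
    FORWARD,
    REVERSE,
    GeneList,
    GeneRecord,
    GenomeModel,
    Peak,
    ValidationError,
    build_peaks,
)
from chipregulon.motif import reverse_complement
from chipregulon.peakcall import ReadSet

DEFAULT_CATEGORY_WEIGHTS = {
    "Hypothetical proteins": 0.30,
    "Unknown function": 0.14,
    "Cell envelope": 0.09,
    "Regulatory functions": 0.08,
    "Energy metabolism": 0.08,
    "Transport and binding proteins": 0.08,
    "Signal transduction": 0.07,
    "Protein fate": 0.06,
    "Protein synthesis": 0.05,
    "Transcription": 0.05,
}

MOTIF_PATTERN = "TGTYN8RAC"


def expand_pattern(pattern: str = MOTIF_PATTERN) -> str:
    """Expand run-length digits in a compact IUPAC pattern: TGTYN8RAC -> TGTYNNNNNNNNRAC."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        i += 1
        digits = ""
        while i < len(pattern) and pattern[i].isdigit():
            digits += pattern[i]
            i += 1
        out.append(ch * int(digits) if digits else ch)
    return "".join(out)


@dataclass
class TrueSite:
    site_id: int
    coordinate: int  # the "peak maximum" position (motif center)
    motif_offset: int  # 0-based start of the motif text in the genome
    motif_text: str  # as written on the forward strand
    strand: str
    target_gene: str | None  # gene whose promoter the site was planted in
    signed_distance: int | None
    strength: float  # latent enrichment strength shared across replicates


@dataclass
class SyntheticTruth:
    genome: GenomeModel
    sequence: str
    true_sites: list[TrueSite]
    replicate_peaks: tuple[list[Peak], list[Peak]] | None = None
    shared_site_ids: list[int] = field(default_factory=list)
    gene_lists: dict[str, GeneList] = field(default_factory=dict)
    planted_enrichment: dict[str, float] = field(default_factory=dict)
    enriched_category: str | None = None
    generator_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {
            "chromosome_id": self.genome.chromosome_id,
            "length": self.genome.length,
            "true_sites": [dataclasses.asdict(s) for s in self.true_sites],
            "shared_site_ids": self.shared_site_ids,
            "planted_enrichment": self.planted_enrichment,
            "enriched_category": self.enriched_category,
            "gene_lists": {k: sorted(v.members) for k, v in self.gene_lists.items()},
            "generator_params": self.generator_params,
        }
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(
    n_genes: int = 800,
    mean_gene_length: int = 1000,
    coding_fraction: float = 0.9,
    gc_content: float = 0.69,
    seed: int = 0,
    forward_probability: float = 0.5,
    category_weights: dict[str, float] | None = None,
    operon_probability: float = 0.3,
    mean_operon_size: float = 3.0,
) -> tuple[GenomeModel, str, dict[str, tuple[str, int]]]:
    """Alternating gene/gap layout with sampled lengths and random strands.

    Gene lengths are Gamma-distributed (shape 10) around ``mean_gene_length``;
    intergenic gaps around ``mean_gene_length * (1 - f) / f`` so the realized
    coding fraction lands within ~2% of the request.  Runs of consecutive
    same-strand genes are grouped into operons with probability
    ``operon_probability`` per gene of continuing the current operon run.
    Returns (genome, sequence, operon_map).
    """
    if not 0 < coding_fraction < 1:
        raise ValidationError("coding_fraction must be in (0, 1)")
    if n_genes < 1:
        raise ValidationError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    shape = 10.0
    gene_lengths = np.maximum(
        90, rng.gamma(shape, mean_gene_length / shape, n_genes)).astype(int)
    mean_gap = mean_gene_length * (1 - coding_fraction) / coding_fraction
    gap_lengths = np.maximum(
        1, rng.gamma(2.0, mean_gap / 2.0, n_genes + 1)).astype(int)

    strands = np.where(rng.random(n_genes) < forward_probability, FORWARD, REVERSE)

    # operon assembly: same-strand adjacency + geometric run lengths
    operon_map: dict[str, tuple[str, int]] = {}
    operon_of = [None] * n_genes
    i = 0
    op_counter = 0
    while i < n_genes:
        if rng.random() < operon_probability:
            size = 2 + rng.geometric(1.0 / max(1.0, mean_operon_size - 1))
            size = min(size, n_genes - i)
            # truncate at the first strand switch to keep operons same-strand
            run = []
            for j in range(i, i + size):
                if strands[j] != strands[i]:
                    break
                run.append(j)
            if len(run) >= 2:
                op_counter += 1
                op_id = f"op{op_counter:04d}"
                ordered = run if strands[i] == FORWARD else run[::-1]
                for pos, j in enumerate(ordered, start=1):
                    operon_of[j] = (op_id, pos)
                i += len(run)
                continue
        i += 1

    weights = category_weights or DEFAULT_CATEGORY_WEIGHTS
    cats = list(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    probs /= probs.sum()
    assigned = rng.choice(len(cats), size=n_genes, p=probs)

    genes = []
    pos = int(gap_lengths[0])
    for k in range(n_genes):
        start = pos
        end = start + int(gene_lengths[k])
        op = operon_of[k] or (None, None)
        gid = f"gene_{k + 1:05d}"
        genes.append(GeneRecord(
            gene_id=gid,
            strand=str(strands[k]),
            coding_start=start,
            coding_end=end,
            category=cats[assigned[k]],
            operon_id=op[0],
            operon_position=op[1],
        ))
        if op[0] is not None:
            operon_map[gid] = (op[0], op[1])
        pos = end + int(gap_lengths[k + 1])
    length = pos

    p_gc = gc_content / 2
    p_at = (1 - gc_content) / 2
    seq = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    sequence = "".join(seq)

    genome = GenomeModel("chr", length, genes)
    realized = genome.coding_fraction()
    if abs(realized - coding_fraction) > 0.02:
        raise ValidationError(
            f"realized coding fraction {realized:.3f} misses request "
            f"{coding_fraction:.3f} by more than 0.02; adjust parameters"
        )
    return genome, sequence, operon_map


# ---------------------------------------------------------------------------
# Binding sites
# ---------------------------------------------------------------------------

def sample_motif_instance(rng: np.random.Generator,
                          pattern: str = MOTIF_PATTERN) -> str:
    """A concrete DNA instance of the degenerate pattern, N/Y/R sampled uniformly."""
    from chipregulon.motif import IUPAC

    expanded = expand_pattern(pattern)
    return "".join(code if code in "ACGT"
                   else rng.choice(list(IUPAC[code])) for code in expanded)


def plant_sites(
    genome: GenomeModel,
    sequence: str,
    n_sites: int = 150,
    promoter_bias: float = 0.66,
    distance_range: tuple[int, int] = (-250, 0),
    seed: int = 0,
    pattern: str = MOTIF_PATTERN,
    max_retries: int = 200,
) -> tuple[str, list[TrueSite]]:
    """Write motif instances into the sequence at promoter-biased positions.

    With probability ``promoter_bias`` a site's coordinate is placed at a
    signed distance drawn uniformly from ``distance_range`` relative to a
    random gene's TSC (in that gene's reading orientation); otherwise it is
    uniform on the chromosome.  The motif text is centered on the site
    coordinate and reverse-complemented with probability 1/2.  Planted
    motifs never overlap; colliding draws are retried.
    """
    if n_sites <= 0:
        raise ValidationError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    width = len(expand_pattern(pattern))
    half = width // 2
    seq = list(sequence)
    L = len(sequence)
    occupied: list[tuple[int, int]] = []
    sites: list[TrueSite] = []
    genes = genome.genes
    # latent strengths: log-normal, heavy right tail like real occupancy
    strengths = np.exp(rng.normal(2.5, 0.8, size=n_sites))
    for sid in range(n_sites):
        placed = False
        for _ in range(max_retries):
            target = d = None
            if rng.random() < promoter_bias:
                g = genes[rng.integers(len(genes))]
                d = int(rng.integers(distance_range[0], distance_range[1] + 1))
                coord = g.tsc + d if g.strand == FORWARD else g.tsc - d
                target = g.gene_id
            else:
                coord = int(rng.integers(0, L))
            start = coord - half
            end = start + width
            if start < 0 or end > L:
                continue
            if any(s < end and start < e for s, e in occupied):
                continue
            text = sample_motif_instance(rng, pattern)
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            written = text if strand == FORWARD else reverse_complement(text)
            seq[start:end] = list(written)
            occupied.append((start, end))
            sites.append(TrueSite(
                site_id=sid, coordinate=int(coord), motif_offset=start,
                motif_text=written, strand=strand, target_gene=target,
                signed_distance=d, strength=float(strengths[sid]),
            ))
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"could not place site {sid} without collision after "
                f"{max_retries} retries")
    return "".join(seq), sites


# ---------------------------------------------------------------------------
# Replicate peaks
# ---------------------------------------------------------------------------

def simulate_replicate_peaks(
    true_sites: list[TrueSite],
    genome_length: int,
    shared_fraction: float = 0.8,
    jitter_scale: float = 6.0,
    n_false_per_replicate: int = 50,
    false_enrichment_mean: float = 1.0,
    replicate_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[list[Peak], list[Peak], list[int]]:
    """Two replicate peak lists with shared jittered true sites and scattered noise.

    A ``shared_fraction`` of true sites appears in both replicates, each
    occurrence jittered independently by Laplace(0, jitter_scale) bp; the
    remaining true sites appear in one replicate each, as do
    ``n_false_per_replicate`` uniformly placed false peaks per replicate.
    Enrichment scores are the site's latent strength times log-normal
    replicate noise; false peaks draw from a low log-normal.  Returns
    (peaks_rep1, peaks_rep2, shared_site_ids).
    """
    if not 0 <= shared_fraction <= 1:
        raise ValidationError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(true_sites)
    n_shared = int(round(shared_fraction * n))
    perm = rng.permutation(n)
    shared_ids = sorted(int(true_sites[i].site_id) for i in perm[:n_shared])
    shared_set = set(shared_ids)

    rep_rows: tuple[list, list] = ([], [])
    for site in true_sites:
        reps = (0, 1) if site.site_id in shared_set else (int(rng.integers(2)),)
        for r in reps:
            jitter = int(round(rng.laplace(0, jitter_scale))) if jitter_scale > 0 else 0
            coord = int(np.clip(site.coordinate + jitter, 0, genome_length - 1))
            score = site.strength * float(np.exp(rng.normal(0, replicate_noise_sd)))
            rep_rows[r].append((coord, score))
    for r in range(2):
        for _ in range(n_false_per_replicate):
            coord = int(rng.integers(0, genome_length))
            score = false_enrichment_mean * float(np.exp(rng.normal(0, 0.5)))
            rep_rows[r].append((coord, score))

    rep1 = build_peaks(rep_rows[0], replicate_id="rep1")
    rep2 = build_peaks(rep_rows[1], replicate_id="rep2")
    return rep1, rep2, shared_ids


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def make_gene_lists(
    genome: GenomeModel,
    hit_genes: set[str],
    list_specs: list[tuple[str, int, float]],
    seed: int = 0,
) -> tuple[dict[str, GeneList], dict[str, float]]:
    """Sample gene lists with a planted fold of promoter-hit representation.

    Each entry is ``(name, size, fold)``: fold f means the expected fraction
    of hit genes in the list is f times the genome-wide hit fraction.
    Sampling is sequential without replacement with per-gene odds
    ``w = f*(G-h) / (G - f*h)`` on hit genes (1 on the rest), which makes the
    expected first-draw hit probability exactly ``f * h/G``.  fold = 1 gives
    a list independent of the hits.
    """
    rng = np.random.default_rng(seed)
    all_genes = np.array(genome.gene_ids)
    G = len(all_genes)
    is_hit = np.array([g in hit_genes for g in all_genes])
    h = int(is_hit.sum())
    lists: dict[str, GeneList] = {}
    folds: dict[str, float] = {}
    for name, size, fold in list_specs:
        if size <= 0:
            raise ValidationError(f"list {name}: size must be positive")
        if size > G:
            raise ValidationError(f"list {name}: size exceeds gene count")
        if fold < 0 or fold * h >= G:
            raise ValidationError(f"list {name}: infeasible fold {fold}")
        odds = fold * (G - h) / (G - fold * h) if h else 1.0
        if fold == 1.0 or h == 0:
            members = set(map(str, rng.choice(all_genes, size, replace=False)))
        else:
            weights = np.where(is_hit, odds, 1.0).astype(float)
            members = set()
            available = np.arange(G)
            w = weights.copy()
            for _ in range(size):
                p = w[available] / w[available].sum()
                pick = rng.choice(len(available), p=p)
                members.add(str(all_genes[available[pick]]))
                available = np.delete(available, pick)
        lists[name] = GeneList(name, members)
        folds[name] = fold
    return lists, folds


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome_length: int,
    true_sites: list[TrueSite],
    reads_per_site: int = 300,
    background_depth: float = 0.02,
    fragment_size: int = 100,
    control_depth: float | None = None,
    seed: int = 0,
) -> tuple[ReadSet, ReadSet]:
    """Strand-aware read starts around each true site plus uniform background.

    Forward-strand reads start upstream of the site, reverse-strand reads
    downstream, at offsets ~ Normal(fragment_size/2, fragment_size/4), so
    shifting by half the fragment size collapses both strands onto the site.
    The control sample is uniform at ``control_depth`` (default: matched to
    the total ChIP depth).
    """
    if reads_per_site < 0 or background_depth < 0:
        raise ValidationError("depths must be nonnegative")
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    for site in true_sites:
        n = reads_per_site
        fwd = rng.random(n) < 0.5
        offsets = np.abs(rng.normal(fragment_size / 2, fragment_size / 4, n))
        pos = np.where(fwd, site.coordinate - offsets, site.coordinate + offsets)
        positions.append(np.clip(np.round(pos), 0, genome_length - 1).astype(int))
        strands.append(np.where(fwd, "+", "-"))
    n_bg = int(round(background_depth * genome_length))
    if n_bg:
        positions.append(rng.integers(0, genome_length, n_bg))
        strands.append(np.where(rng.random(n_bg) < 0.5, "+", "-"))
    chip = ReadSet(
        np.concatenate(positions) if positions else np.array([], dtype=int),
        np.concatenate(strands) if strands else np.array([], dtype="<U1"),
        label="chip",
    )
    n_ctrl = int(round((control_depth * genome_length) if control_depth is not None
                       else len(chip)))
    ctrl = ReadSet(
        rng.integers(0, genome_length, n_ctrl),
        np.where(rng.random(n_ctrl) < 0.5, "+", "-"),
        label="control",
    )
    return chip, ctrl


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def make_dataset(
    seed: int = 0,
    n_genes: int = 800,
    coding_fraction: float = 0.9,
    gc_content: float = 0.69,
    n_sites: int = 150,
    promoter_bias: float = 0.66,
    shared_fraction: float = 0.8,
    jitter_scale: float = 6.0,
    n_false_per_replicate: int = 50,
    enriched_category: str = "Regulatory functions",
    category_fold: float = 3.0,
    list_specs: list[tuple[str, int, float]] | None = None,
    window: tuple[int, int] = (-400, 100),
) -> SyntheticTruth:
    """One coherent synthetic world: genome, planted sites, replicates, lists.

    The planted category enrichment is realized by re-targeting a fraction
    of promoter sites at genes of ``enriched_category`` so that category's
    genes are ~``category_fold`` times over-represented among promoter-hit
    genes.  Gene-list specs default to a developmental trio mirroring the
    published contrasts: an up-regulated list with a 1.7x planted excess and
    two null lists.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    genome, sequence, operon_map = make_genome(
        n_genes=n_genes, coding_fraction=coding_fraction, gc_content=gc_content,
        seed=sub())

    # bias promoter-site targets toward the enriched category
    cat_ids = [g.gene_id for g in genome.genes if g.category == enriched_category]
    seq2, sites = _plant_sites_with_category_bias(
        genome, sequence, n_sites, promoter_bias, set(cat_ids), category_fold,
        seed=sub())

    rep1, rep2, shared = simulate_replicate_peaks(
        sites, genome.length, shared_fraction, jitter_scale,
        n_false_per_replicate, seed=sub())

    hit_genes = {s.target_gene for s in sites if s.target_gene is not None}
    specs = list_specs or [
        ("up_regulated", min(200, n_genes // 4), 1.7),
        ("down_regulated", min(200, n_genes // 4), 1.0),
        ("directly_involved", min(50, n_genes // 10), 1.0),
    ]
    lists, folds = make_gene_lists(genome, hit_genes, specs, seed=sub())

    return SyntheticTruth(
        genome=genome,
        sequence=seq2,
        true_sites=sites,
        replicate_peaks=(rep1, rep2),
        shared_site_ids=shared,
        gene_lists=lists,
        planted_enrichment=folds,
        enriched_category=enriched_category,
        generator_params={
            "seed": seed, "n_genes": n_genes, "coding_fraction": coding_fraction,
            "gc_content": gc_content, "n_sites": n_sites,
            "promoter_bias": promoter_bias, "shared_fraction": shared_fraction,
            "jitter_scale": jitter_scale,
            "n_false_per_replicate": n_false_per_replicate,
            "enriched_category": enriched_category, "category_fold": category_fold,
            "window": list(window),
        },
    )


def _plant_sites_with_category_bias(
    genome: GenomeModel,
    sequence: str,
    n_sites: int,
    promoter_bias: float,
    category_genes: set[str],
    fold: float,
    seed: int,
    distance_range: tuple[int, int] = (-250, 0),
    pattern: str = MOTIF_PATTERN,
) -> tuple[str, list[TrueSite]]:
    """plant_sites variant whose promoter-site target genes over-sample a category.

    The target gene of each promoter site is drawn with odds ``fold`` on
    category members, 1 elsewhere, so category genes end up about ``fold``
    times over-represented among site-carrying genes.
    """
    rng = np.random.default_rng(seed)
    width = len(expand_pattern(pattern))
    half = width // 2
    seq = list(sequence)
    L = len(sequence)
    genes = genome.genes
    w = np.array([fold if g.gene_id in category_genes else 1.0 for g in genes])
    w /= w.sum()
    occupied: list[tuple[int, int]] = []
    sites: list[TrueSite] = []
    strengths = np.exp(rng.normal(2.5, 0.8, size=n_sites))
    for sid in range(n_sites):
        placed = False
        for _ in range(200):
            target = d = None
            if rng.random() < promoter_bias:
                g = genes[rng.choice(len(genes), p=w)]
                d = int(rng.integers(distance_range[0], distance_range[1] + 1))
                coord = g.tsc + d if g.strand == FORWARD else g.tsc - d
                target = g.gene_id
            else:
                coord = int(rng.integers(0, L))
            start = coord - half
            end = start + width
            if start < 0 or end > L:
                continue
            if any(s < end and start < e for s, e in occupied):
                continue
            text = sample_motif_instance(rng, pattern)
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            written = text if strand == FORWARD else reverse_complement(text)
            seq[start:end] = list(written)
            occupied.append((start, end))
            sites.append(TrueSite(sid, int(coord), start, written, strand,
                                  target, d, float(strengths[sid])))
            placed = True
            break
        if not placed:
            raise ValidationError(f"could not place site {sid} without collision")
    return "".join(seq), sites
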
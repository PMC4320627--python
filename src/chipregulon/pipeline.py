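"""End-to-end orchestration with a reproducibility manifest.

Stages hand data to each other through plain files (TSV/FASTA/GFF3/JSON) so
any intermediate can be inspected or re-entered.  All randomness flows from
one top-level seed via per-stage derived seeds recorded in the manifest,
and every output file is listed with a SHA-256 digest so a re-run can be
checked for bitwise reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chipregulon import annotate as ann_mod
from chipregulon import concordance, enrich, formats, motif as motif_mod
from chipregulon import nullmodel, synthetic
from chipregulon.formats import AnalysisConfig

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, seed: int | None, inputs: list[str],
                     outputs: list[str], wall_time: float) -> None:
        self.stages.append({
            "stage": name, "seed": seed, "inputs": inputs, "outputs": outputs,
            "wall_time_s": round(wall_time, 3),
        })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def write_dataset(truth: synthetic.SyntheticTruth, outdir: str | Path) -> list[Path]:
    """Write a synthetic dataset to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, seq = truth.genome, truth.sequence
    written = []

    def _w(path: Path):
        written.append(path)
        return path

    formats.write_fasta(genome.chromosome_id, seq, _w(outdir / "genome.fasta"))
    formats.write_gff3(genome, _w(outdir / "genome.gff3"))
    formats.write_category_table(
        {g.gene_id: g.category for g in genome.genes if g.category},
        _w(outdir / "categories.tsv"))
    operons = {g.gene_id: (g.operon_id, g.operon_position)
               for g in genome.genes if g.operon_id}
    formats.write_operon_table(operons, _w(outdir / "operons.tsv"))
    if truth.replicate_peaks:
        formats.write_peaks(truth.replicate_peaks[0], _w(outdir / "peaks_rep1.tsv"))
        formats.write_peaks(truth.replicate_peaks[1], _w(outdir / "peaks_rep2.tsv"))
    lists_dir = outdir / "lists"
    lists_dir.mkdir(exist_ok=True)
    for name, gl in truth.gene_lists.items():
        formats.write_gene_list(gl, _w(lists_dir / f"{name}.txt"))
    truth.to_json(_w(outdir / "truth.json"))
    return written


def run_pipeline(
    rep1: str | Path,
    rep2: str | Path,
    gff: str | Path,
    outdir: str | Path,
    fasta: str | Path | None = None,
    categories: str | Path | None = None,
    operons: str | Path | None = None,
    gene_lists: list[str | Path] | None = None,
    config: AnalysisConfig | None = None,
    make_plots: bool = True,
) -> RunManifest:
    """concord -> annotate -> nullcmp -> enrich -> motif, with manifest.

    Motif discovery runs only when a genome FASTA is provided.  On stage
    failure a FAILED marker naming the stage is left in the output directory
    and the partial outputs are retained.
    """
    cfg = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from chipregulon import __version__

    manifest = RunManifest(version=__version__, config={
        **{k: (list(v) if isinstance(v, tuple) else v)
           for k, v in cfg.__dict__.items()}})
    for name, p in [("rep1", rep1), ("rep2", rep2), ("gff", gff),
                    ("fasta", fasta), ("categories", categories),
                    ("operons", operons)]:
        if p is not None:
            manifest.input_digests[name] = sha256_file(p)

    current = "load"
    try:
        peaks_a = formats.read_peaks(rep1, "rep1")
        peaks_b = formats.read_peaks(rep2, "rep2")
        genome = formats.read_gff3(gff, category_table=categories,
                                   operon_table=operons)
        operon_map = formats.read_operon_table(operons) if operons else {}

        # --- concordance -------------------------------------------------
        current = "concord"
        t0 = time.perf_counter()
        merged = concordance.filter_concordant(peaks_a, peaks_b,
                                               cfg.concordance_cutoff)
        report = concordance.concordance_report(peaks_a, peaks_b,
                                                cfg.concordance_cutoff)
        (outdir / "concordance_report.txt").write_text(
            concordance.format_report(report))
        manifest.record_stage("concord", None, [str(rep1), str(rep2)],
                              ["concordance_report.txt"],
                              time.perf_counter() - t0)

        # --- annotation --------------------------------------------------
        current = "annotate"
        t0 = time.perf_counter()
        annotations, summary = ann_mod.annotate_all(merged, genome,
                                                    cfg.promoter_window)
        formats.write_peak_table(annotations, outdir / "annotated_peaks.tsv")
        manifest.record_stage("annotate", None, [str(gff)],
                              ["annotated_peaks.tsv"], time.perf_counter() - t0)

        # --- Monte Carlo null -------------------------------------------
        current = "nullcmp"
        t0 = time.perf_counter()
        seed = derive_seed(cfg.rng_seed, "nullcmp")
        null = nullmodel.null_comparison(merged, genome,
                                         n_replicates=cfg.mc_replicates,
                                         seed=seed)
        null_df = pd.DataFrame({
            "dataset": ["observed", "random"],
            "noncoding": [null.observed_noncoding, null.region_counts[0][1]],
            "coding": [null.observed_coding, null.region_counts[0][0]],
        })
        null_df.to_csv(outdir / "region_table.tsv", sep="\t", index=False)
        (outdir / "null_summary.json").write_text(json.dumps({
            "fisher_p": null.fisher_p, **null.summary,
            "n_sites": null.n_sites, "seed": seed,
        }, indent=1))
        manifest.record_stage("nullcmp", seed, [], ["region_table.tsv",
                              "null_summary.json"], time.perf_counter() - t0)

        # --- enrichment --------------------------------------------------
        current = "enrich"
        t0 = time.perf_counter()
        outputs = []
        if categories is not None:
            cat_df = enrich.category_table(annotations, genome)
            cat_df.to_csv(outdir / "category_enrichment.tsv", sep="\t",
                          index=False)
            outputs.append("category_enrichment.tsv")
        if gene_lists:
            gls = [formats.read_gene_list(p) for p in gene_lists]
            gl_df = enrich.genelist_table(annotations, gls, genome, operon_map)
            gl_df.to_csv(outdir / "genelist_enrichment.tsv", sep="\t",
                         index=False)
            outputs.append("genelist_enrichment.tsv")
        manifest.record_stage("enrich", None, [], outputs,
                              time.perf_counter() - t0)

        # --- motif -------------------------------------------------------
        if fasta is not None:
            current = "motif"
            t0 = time.perf_counter()
            _, sequence = formats.read_fasta(fasta)
            flanks = motif_mod.extract_flanks(merged, sequence, cfg.flank)
            top = [f for part in motif_mod.partition_ranked(
                flanks, cfg.top_n_for_motif, cfg.partition_size) for f in part]
            seed = derive_seed(cfg.rng_seed, "motif")
            mot, ll = motif_mod.em_discover(top, width=cfg.motif_width,
                                            rng_seed=seed)
            (outdir / "motif.meme.txt").write_text(mot.to_meme_text())
            consensus = mot.consensus_iupac()
            hits = motif_mod.scan_many(top, consensus)
            pd.DataFrame([h.__dict__ for h in hits]).to_csv(
                outdir / "motif_hits.tsv", sep="\t", index=False)
            (outdir / "motif_summary.json").write_text(json.dumps({
                "consensus": consensus, "log_likelihood": ll,
                "n_sequences": len(top), "n_hits": len(hits), "seed": seed,
            }, indent=1))
            outputs = ["motif.meme.txt", "motif_hits.tsv", "motif_summary.json"]
            if make_plots:
                motif_mod.plot_logo(mot, outdir / "motif_logo.png")
                outputs.append("motif_logo.png")
            manifest.record_stage("motif", seed, [str(fasta)], outputs,
                                  time.perf_counter() - t0)

        if make_plots:
            _plots(peaks_a, peaks_b, summary, null, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise StageFailure(current, exc) from exc

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[p.name] = sha256_file(p)
    manifest.save(outdir / "manifest.json")
    return manifest


def _plots(peaks_a, peaks_b, summary, null, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d_ab, d_ba = concordance.nearest_replicate_distances(peaks_a, peaks_b)
    pooled = np.concatenate([d_ab, d_ba])
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    xs = np.sort(pooled)
    axes[0].step(xs, np.arange(1, len(xs) + 1) / len(xs), where="post")
    axes[0].set(xlabel="distance to nearest replicate peak (bp)",
                ylabel="cumulative fraction", xscale="symlog")
    axes[1].hist(np.clip(summary["tsc_distances"], -1000, 1000), bins=40)
    axes[1].set(xlabel="observed distance to nearest TSC (bp)", ylabel="peaks")
    axes[2].hist(np.clip(null.distance_samples, -1000, 1000), bins=40,
                 color="gray")
    axes[2].set(xlabel="random-site distance to nearest TSC (bp)",
                ylabel="sites")
    fig.tight_layout()
    fig.savefig(outdir / "figures.png", dpi=120)
    plt.close(fig)


def run_demo(outdir: str | Path, seed: int = 0, scale: float = 1.0,
             make_plots: bool = True) -> RunManifest:
    """Generate a synthetic dataset and run the whole pipeline on it.

    ``scale`` < 1 shrinks the synthetic world proportionally (genes, sites,
    false peaks) for quick smoke runs.
    """
    outdir = Path(outdir)
    data_dir = outdir / "data"
    truth = synthetic.make_dataset(
        seed=derive_seed(seed, "simulate"),
        n_genes=max(50, int(800 * scale)),
        n_sites=max(20, int(150 * scale)),
        n_false_per_replicate=max(5, int(50 * scale)),
    )
    write_dataset(truth, data_dir)
    cfg = AnalysisConfig(rng_seed=seed,
                         top_n_for_motif=min(500, len(truth.true_sites)))
    return run_pipeline(
        rep1=data_dir / "peaks_rep1.tsv",
        rep2=data_dir / "peaks_rep2.tsv",
        gff=data_dir / "genome.gff3",
        fasta=data_dir / "genome.fasta",
        categories=data_dir / "categories.tsv",
        operons=data_dir / "operons.tsv",
        gene_lists=sorted((data_dir / "lists").glob("*.txt")),
        outdir=outdir / "results",
        config=cfg,
        make_plots=make_plots,
    )
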
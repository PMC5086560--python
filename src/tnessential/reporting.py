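"""Functional-category enrichment, pipeline orchestration, and exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from . import __version__
from .essentiality import CALL_ESSENTIAL, CALL_NOT_EVALUATED, analyze, bh_adjust
from .genome_index import (
    ReferenceGenome,
    assign_informative_sites,
    build_flank_index,
    gene_table,
    read_gff3,
)
from .library_quant import (
    align_libraries,
    aligned_percent,
    apply_noise_threshold,
    collapse_to_sites,
    demultiplex,
    library_stats,
    noise_cutoff,
    pooled_unique_insertions,
    position_track,
)

#: Analysis stages recorded in the run manifest, in execution order.
PIPELINE_STAGES = (
    "demux", "align", "noise_cutoff", "loess", "tmm", "expected",
    "log2fc", "cutoff", "nb_bh", "classify", "enrich",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


# ---------------------------------------------------------------------------
# COG enrichment
# ---------------------------------------------------------------------------

def storey_qvalues(p_values, lambdas=None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid; a cubic
    polynomial smoother is evaluated at the largest lambda.  If the estimate
    leaves (0, 1] the procedure falls back to pi0 = 1, in which case the
    q-values equal Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0 = 1.0
    if m >= 10:
        try:
            pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
        except Exception:
            pi0 = 1.0
    if not (0.0 < pi0 <= 1.0):
        pi0 = 1.0
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def cog_enrichment(records: pd.DataFrame, cogs_by_locus: dict) -> pd.DataFrame:
    """Per-COG-category enrichment of essential genes (Fisher exact + q).

    The universe is the evaluable genes with at least one COG assignment;
    genes belonging to several categories contribute to each.  Each category
    gets a 2x2 table {essential, not} x {in, out of category}, a two-sided
    Fisher exact p (hypergeometric point-mass summation), and a Storey
    q-value.
    """
    ev = records[records["call"] != CALL_NOT_EVALUATED]
    universe = [(loc, set(cogs_by_locus.get(loc, ()))) for loc in ev.index]
    universe = [(loc, cats) for loc, cats in universe if cats]
    if not universe:
        raise ValueError("empty category universe: no evaluable gene has a COG")
    all_cats = sorted(set().union(*(cats for _, cats in universe)))
    ess = {loc for loc in ev.index if ev.loc[loc, "call"] == CALL_ESSENTIAL}
    n_total = len(universe)
    n_ess = sum(1 for loc, _ in universe if loc in ess)
    rows = []
    for cat in all_cats:
        in_cat = [loc for loc, cats in universe if cat in cats]
        a = sum(1 for loc in in_cat if loc in ess)         # essential, in cat
        b = n_ess - a                                      # essential, out
        c = len(in_cat) - a                                # non-essential, in
        d = (n_total - n_ess) - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({
            "category": cat,
            "essential_in_category": a,
            "total_in_category": len(in_cat),
            "essential_overall": n_ess,
            "total_overall": n_total,
            "odds_ratio": odds,
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    out["q_value"] = storey_qvalues(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_tracks(records: pd.DataFrame, genes, track: pd.DataFrame,
                  genome: ReferenceGenome, outdir) -> dict:
    """Write a BED of essential genes and a wig-like log2 count track."""
    outdir = Path(outdir)
    bed_path = outdir / "essential_genes.bed"
    by_locus = {g.locus_tag: g for g in genes}
    rows = []
    for loc in records.index[records["call"] == CALL_ESSENTIAL]:
        g = by_locus[loc]
        start0, end0 = g.start - 1, g.end  # 0-based half-open
        if start0 < 0 or end0 > genome.length:
            raise ValueError(f"gene {loc} outside genome")
        rows.append((genome.id, start0, end0, loc, 0, g.strand))
    rows.sort(key=lambda r: r[1])
    with open(bed_path, "w") as fh:
        fh.write('track name=essential_genes description="essential gene calls"\n')
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    track_path = outdir / "insertion_track.tsv"
    track.sort_values("position").to_csv(track_path, sep="\t", index=False)
    return {"bed": str(bed_path), "track": str(track_path)}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_DEFAULTS = dict(
    flank_k=16, min_match=16, max_mismatch=0, barcode_mismatch=0,
    trim_3prime=0.1, loess_span=0.3, loess_window=10_000, prior=1.0,
    alpha=0.05, p_hit_min=0.95, cutoff=None, seed=0,
)


def default_config() -> dict:
    d = dict(_DEFAULTS)
    d.update(genome_fasta=None, annotation_gff=None, fastq=None,
             counts_tsv=None, barcodes=[], outdir="results")
    return d


def _site_counts_to_flanks(site_df: pd.DataFrame, fidx) -> pd.DataFrame:
    """Map a per-TA-site count table onto flank rows (counts placed on each
    site's first unique flank; gene-level sums are unaffected by the side)."""
    out = np.zeros((fidx.n_flanks, site_df.shape[1]), dtype=np.int64)
    first_flank = {}
    for i, (p, u) in enumerate(zip(fidx.site_pos, fidx.unique)):
        if u and int(p) not in first_flank:
            first_flank[int(p)] = i
    for pos, row in site_df.iterrows():
        i = first_flank.get(int(pos))
        if i is not None:
            out[i] += row.to_numpy(dtype=np.int64)
    return pd.DataFrame(out, columns=site_df.columns)


def run_pipeline(config: dict) -> dict:
    """Run the full analysis per the config; write outputs and a manifest.

    Accepts either a FASTQ file (demux + align stages) or a per-TA-site
    count table TSV (those two stages recorded as skipped).  Deterministic
    given identical config and inputs.
    """
    cfg = default_config()
    cfg.update(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name, records=None, status="ok", **extra):
        stages.append({"name": name, "status": status,
                       "records": records, **extra})

    # --- input loading (errors attributed to the genome_index stage) -------
    try:
        if not cfg["genome_fasta"] or not Path(cfg["genome_fasta"]).exists():
            raise FileNotFoundError(f"genome FASTA not found: {cfg['genome_fasta']}")
        genome = ReferenceGenome.from_fasta(cfg["genome_fasta"])
        if not cfg["annotation_gff"] or not Path(cfg["annotation_gff"]).exists():
            raise FileNotFoundError(f"annotation GFF3 not found: {cfg['annotation_gff']}")
        genes = read_gff3(cfg["annotation_gff"])
        fidx = build_flank_index(genome, k=cfg["flank_k"])
        genes = assign_informative_sites(genes, genome, fidx,
                                         trim_3prime=cfg["trim_3prime"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("genome_index", "input_error", str(exc)) from exc

    # --- demux / align -----------------------------------------------------
    if cfg.get("fastq"):
        try:
            tag_counts, unassigned, total = demultiplex(
                cfg["fastq"], cfg["barcodes"], cfg["barcode_mismatch"])
            record("demux", records=total, unassigned=unassigned)
        except Exception as exc:
            raise PipelineError("demux", "demux_error", str(exc)) from exc
        try:
            matrix, tallies = align_libraries(
                tag_counts, fidx, cfg["min_match"], cfg["max_mismatch"])
            record("align", records=int(sum(t["mapped"] for t in tallies.values())),
                   tallies=tallies)
        except Exception as exc:
            raise PipelineError("align", "align_error", str(exc)) from exc
    elif cfg.get("counts_tsv"):
        site_df = pd.read_csv(cfg["counts_tsv"], sep="\t").set_index("position")
        matrix = _site_counts_to_flanks(site_df, fidx)
        mapped = {lib: int(matrix[lib].sum()) for lib in matrix.columns}
        tallies = {lib: {"total": mapped[lib], "mapped": mapped[lib],
                         "repeat_filtered": 0, "unmapped": 0}
                   for lib in matrix.columns}
        record("demux", status="skipped")
        record("align", status="skipped")
    else:
        raise PipelineError("demux", "no_input", "neither fastq nor counts_tsv given")

    # --- noise cutoff ------------------------------------------------------
    try:
        thresholds = {lib: noise_cutoff(matrix[lib].to_numpy())
                      for lib in matrix.columns}
        record("noise_cutoff", records=len(thresholds), thresholds=thresholds)
    except Exception as exc:
        raise PipelineError("noise_cutoff", "cutoff_error", str(exc)) from exc

    # --- statistics (loess, tmm, expected, log2fc, cutoff, NB/BH, classify)
    try:
        results, diag = analyze(
            matrix, genes, fidx,
            thresholds=thresholds,
            loess_span=cfg["loess_span"], loess_window=cfg["loess_window"],
            prior=cfg["prior"], alpha=cfg["alpha"],
            p_hit_min=cfg["p_hit_min"], cutoff=cfg["cutoff"],
        )
    except Exception as exc:
        raise PipelineError("nb_bh", "stats_error", str(exc)) from exc
    record("loess", records=len(matrix))
    record("tmm", records=matrix.shape[1],
           factors={k: float(v) for k, v in diag.tmm.items()})
    n_eval = int((results["u_g"] > 0).sum())
    record("expected", records=n_eval)
    record("log2fc", records=n_eval)
    record("cutoff", records=1, value=diag.cutoff)
    record("nb_bh", records=n_eval, dispersion=diag.dispersion)
    record("classify", records=len(results),
           n_essential=int((results["call"] == CALL_ESSENTIAL).sum()),
           n_unique_mutants=diag.n_unique_mutants)

    # --- enrichment --------------------------------------------------------
    cogs_by_locus = {g.locus_tag: "".join(sorted(g.cogs)) for g in genes}
    enrichment = None
    if any(cogs_by_locus.values()):
        try:
            enrichment = cog_enrichment(results, {g.locus_tag: g.cogs for g in genes})
            record("enrich", records=len(enrichment))
        except ValueError:
            record("enrich", status="skipped")
    else:
        record("enrich", status="skipped")

    # --- exports -----------------------------------------------------------
    stats = library_stats(matrix, tallies, thresholds, fidx)
    track = position_track(apply_noise_threshold(matrix, thresholds), fidx)
    flank_out = matrix.copy()
    flank_out.insert(0, "site_pos", fidx.site_pos[matrix.index.to_numpy()])
    flank_out.insert(1, "side", fidx.side[matrix.index.to_numpy()])
    flank_out[flank_out[matrix.columns].sum(axis=1) > 0].to_csv(
        outdir / "flank_counts.tsv", sep="\t", index=False)
    stats.to_csv(outdir / "library_stats.tsv", sep="\t")
    gene_table(genes).to_csv(outdir / "gene_table.tsv", sep="\t", index=False)
    results.to_csv(outdir / "gene_results.tsv", sep="\t")
    diag.density_curve.assign(cutoff=diag.cutoff).to_csv(
        outdir / "log2fc_density.tsv", sep="\t", index=False)
    if enrichment is not None:
        enrichment.to_csv(outdir / "cog_enrichment.tsv", sep="\t", index=False)
    export_tracks(results, genes, track, genome, outdir)

    manifest = {
        "inputs": {k: str(cfg[k]) for k in
                   ("genome_fasta", "annotation_gff", "fastq", "counts_tsv")
                   if cfg.get(k)},
        "parameters": {k: cfg[k] for k in _DEFAULTS},
        "seed": cfg["seed"],
        "versions": {"tnessential": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"results": results, "diagnostics": diag, "stats": stats,
            "enrichment": enrichment, "manifest": manifest, "genes": genes,
            "genome": genome, "flank_index": fidx, "matrix": matrix}
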
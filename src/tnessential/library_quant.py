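"""From raw reads to per-site/per-library counts and library summaries.

Covers barcode demultiplexing, exact-prefix tag alignment against the unique
flank index (with repeat filtering), the kernel-density read-count noise
cutoff that separates true insertions from noise reads, per-library summary
statistics, the cumulative unique-insertion curve, and rarefaction of
intragenic insertions.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.special import gammaln

from .density import first_valley_between, kde_profile
from .genome_index import FlankIndex


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def demultiplex(fastq, barcodes, max_mismatch: int = 0):
    """Split reads by their leading 6-nt barcode; discard the 2 random nt.

    Returns (dict barcode -> Counter of genomic tags, unassigned_count,
    total_reads).  Raises ValueError for an ambiguous barcode set (two
    barcodes within 2*max_mismatch of each other).
    """
    barcodes = list(barcodes)
    blen = len(barcodes[0])
    if any(len(b) != blen for b in barcodes):
        raise ValueError("all barcodes must have equal length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if _hamming(a, b) <= 2 * max_mismatch:
                raise ValueError(
                    f"ambiguous barcode set: {a} and {b} are within "
                    f"{2 * max_mismatch} mismatches"
                )
    tag_counts = {b: Counter() for b in barcodes}
    unassigned = 0
    total = 0
    exact = {b: b for b in barcodes}

    def match(prefix):
        if max_mismatch == 0:
            return exact.get(prefix)
        hits = [b for b in barcodes if _hamming(prefix, b) <= max_mismatch]
        return hits[0] if len(hits) == 1 else None

    if hasattr(fastq, "read"):
        handle = fastq
        own = False
    else:
        handle = _open_text(fastq)
        own = True
    try:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            total += 1
            bc = match(seq[:blen])
            if bc is None:
                unassigned += 1
                continue
            tag_counts[bc][seq[blen + 2 :]] += 1
    finally:
        if own:
            handle.close()
    return tag_counts, unassigned, total


def align_tags(
    tag_counts: Counter,
    flank_index: FlankIndex,
    min_match: int = 16,
    max_mismatch: int = 0,
):
    """Count tags against unique flanks by exact-prefix dictionary lookup.

    A tag whose first ``min_match`` nt equal the prefix of exactly one unique
    flank increments that flank.  Tags matching a non-unique flank (or an
    ambiguous prefix) are repeat-filtered; everything else is unmapped.  An
    optional single-mismatch rescue scans the Hamming-1 neighbourhood.

    Returns (per-flank count array, tallies dict).
    """
    pm = flank_index.prefix_map(min_match)
    counts = np.zeros(flank_index.n_flanks, dtype=np.int64)
    mapped = repeat = unmapped = 0
    for tag, c in tag_counts.items():
        if len(tag) < min_match:
            unmapped += c
            continue
        pre = tag[:min_match]
        hit = pm.get(pre)
        if hit is None and max_mismatch >= 1:
            found = set()
            for i in range(min_match):
                for alt in "ACGT":
                    if alt == pre[i]:
                        continue
                    h = pm.get(pre[:i] + alt + pre[i + 1 :])
                    if h is not None:
                        found.add(h)
            if len(found) == 1:
                hit = found.pop()
            elif found:
                hit = -1
        if hit is None:
            unmapped += c
        elif hit == -1:
            repeat += c
        else:
            counts[hit] += c
            mapped += c
    tallies = {
        "total": mapped + repeat + unmapped,
        "mapped": mapped,
        "repeat_filtered": repeat,
        "unmapped": unmapped,
    }
    return counts, tallies


def align_libraries(tag_counts_by_lib: dict, flank_index: FlankIndex,
                    min_match: int = 16, max_mismatch: int = 0):
    """Align every library's tag Counter; returns (flank x library count
    DataFrame, per-library tallies dict)."""
    cols, tallies = {}, {}
    for bc, tc in tag_counts_by_lib.items():
        counts, t = align_tags(tc, flank_index, min_match, max_mismatch)
        cols[f"lib_{bc}"] = counts
        tallies[f"lib_{bc}"] = t
    return pd.DataFrame(cols), tallies


def noise_cutoff(counts, min_nonzero: int = 50) -> float:
    """Read-count threshold separating true insertions from noise reads.

    Gaussian KDE (Silverman bandwidth) on log2 of the nonzero counts; the
    threshold is the count at the first local density minimum between the
    first two modes.  If the density is unimodal the fallback is
    max(2, 1st percentile of nonzero counts); a degenerate all-equal input
    returns the minimal threshold 2.  Counts below the threshold are treated
    as noise for unique-insertion accounting.
    """
    counts = np.asarray(counts)
    nz = counts[counts > 0].astype(float)
    if len(nz) < min_nonzero:
        raise ValueError(
            f"only {len(nz)} nonzero flanks (< {min_nonzero}); "
            "supply a manual threshold"
        )
    if np.ptp(nz) == 0:
        return 2.0
    x = np.log2(nz)
    # weight by multiplicity of distinct values so the estimate (and hence
    # the threshold) is invariant to duplicating every record
    vals, mult = np.unique(x, return_counts=True)
    grid, _dens, maxima, minima = kde_profile(vals, weights=mult / mult.sum())
    if len(maxima) >= 2:
        v = first_valley_between(grid, minima, maxima[0], maxima[1])
        if v is not None:
            return float(2.0 ** grid[v])
    return float(max(2.0, np.percentile(nz, 1)))


def apply_noise_threshold(matrix: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Zero every flank count below its library's noise threshold."""
    out = matrix.copy()
    for lib, thr in thresholds.items():
        col = out[lib].to_numpy()
        out[lib] = np.where(col < thr, 0, col)
    return out


def collapse_to_sites(matrix: pd.DataFrame, flank_index: FlankIndex) -> pd.DataFrame:
    """Sum flank-level counts to TA-site level (rows indexed by position)."""
    df = matrix.copy()
    df["position"] = flank_index.site_pos[df.index.to_numpy()]
    return df.groupby("position").sum()


def aligned_percent(total_reads: int, aligned_reads: int) -> float:
    """Aligned-read percentage, one decimal (Table-3-style arithmetic)."""
    if total_reads <= 0:
        return 0.0
    return round(100.0 * aligned_reads / total_reads, 1)


def mean_reads_per_flank(assigned_reads: int, flanks_hit: int):
    """Average reads per hit flanking sequence, rounded to integer."""
    if flanks_hit == 0:
        return None
    return int(round(assigned_reads / flanks_hit))


@dataclass
class LibraryStats:
    name: str
    total_reads: int
    aligned_reads: int
    aligned_pct: float
    flanks_hit: int
    unique_insertions: int       # TA sites with >=1 above-threshold flank
    mean_reads_per_flank: object # int or None


def library_stats(matrix: pd.DataFrame, tallies: dict, thresholds: dict,
                  flank_index: FlankIndex) -> pd.DataFrame:
    """Per-library summary statistics (total/aligned reads, hit flanks,
    unique insertion mutants after the noise cutoff, mean reads per flank)."""
    rows = []
    for lib in matrix.columns:
        t = tallies[lib]
        col = matrix[lib].to_numpy()
        hit = int((col > 0).sum())
        above = apply_noise_threshold(matrix[[lib]], {lib: thresholds[lib]})
        uniq = int((collapse_to_sites(above, flank_index)[lib] > 0).sum())
        rows.append(
            LibraryStats(
                name=lib,
                total_reads=t["total"],
                aligned_reads=t["mapped"],
                aligned_pct=aligned_percent(t["total"], t["mapped"]),
                flanks_hit=hit,
                unique_insertions=uniq,
                mean_reads_per_flank=mean_reads_per_flank(t["mapped"], hit),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("name")


def pooled_unique_insertions(matrix: pd.DataFrame, thresholds: dict,
                             flank_index: FlankIndex) -> int:
    """N: TA sites with at least one above-threshold flank in any library."""
    above = apply_noise_threshold(matrix, thresholds)
    sites = collapse_to_sites(above, flank_index)
    return int((sites.sum(axis=1) > 0).sum())


def cumulative_unique(matrix: pd.DataFrame, thresholds: dict,
                      flank_index: FlankIndex, order=None) -> np.ndarray:
    """Running size of the union of above-threshold TA-site sets as
    libraries are amalgamated in the given column order."""
    order = list(order) if order is not None else list(matrix.columns)
    above = apply_noise_threshold(matrix, {k: thresholds[k] for k in order})
    pos = flank_index.site_pos[matrix.index.to_numpy()]
    seen: set = set()
    out = []
    for lib in order:
        col = above[lib].to_numpy()
        seen.update(pos[col > 0].tolist())
        out.append(len(seen))
    return np.asarray(out, dtype=np.int64)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction(gene_read_counts, subsample_sizes, n_reps: int = 0,
                seed: int = 0) -> pd.DataFrame:
    """Expected number of distinct genes hit vs reads subsampled.

    Analytic hypergeometric expectation
    E[genes](s) = sum_g (1 - C(R - r_g, s) / C(R, s)) over genes with r_g of
    the R total intragenic reads, at subsample size s.  With ``n_reps`` > 0 a
    Monte-Carlo verification by repeated subsampling without replacement is
    added (columns mc_mean, mc_sd).
    """
    r = np.asarray(gene_read_counts, dtype=np.int64)
    r = r[r > 0]
    R = int(r.sum())
    grid = np.asarray(subsample_sizes, dtype=np.int64)
    if (grid < 0).any() or (grid > R).any():
        raise ValueError(f"subsample sizes must lie in [0, {R}]")
    exp = np.empty(len(grid), dtype=float)
    for i, s in enumerate(grid):
        if s == 0:
            exp[i] = 0.0
            continue
        keep = R - r >= s
        term = np.zeros(len(r))
        term[keep] = np.exp(_log_comb(R - r[keep], s) - _log_comb(R, s))
        exp[i] = float(np.sum(1.0 - term))
    out = pd.DataFrame({"subsample": grid, "expected_genes": exp})
    if n_reps > 0:
        rng = np.random.default_rng(seed)
        mc = np.empty((n_reps, len(grid)))
        for rep in range(n_reps):
            for i, s in enumerate(grid):
                if s == 0:
                    mc[rep, i] = 0
                elif s == R:
                    mc[rep, i] = len(r)
                else:
                    draw = rng.multivariate_hypergeometric(r, int(s))
                    mc[rep, i] = int((draw > 0).sum())
        out["mc_mean"] = mc.mean(axis=0)
        out["mc_sd"] = mc.std(axis=0, ddof=1)
    return out


def position_track(matrix: pd.DataFrame, flank_index: FlankIndex) -> pd.DataFrame:
    """Flat per-position track: TA position and log2 pooled read count."""
    sites = collapse_to_sites(matrix, flank_index)
    pooled = sites.sum(axis=1)
    pooled = pooled[pooled > 0]
    return pd.DataFrame(
        {"position": pooled.index.to_numpy(),
         "log2_count": np.log2(pooled.to_numpy())}
    ).sort_values("position").reset_index(drop=True)
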
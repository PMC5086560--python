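# Methods

This document specifies the statistical model, algorithms, parameter
defaults and known limitations of `tnessential`. Notation: gene *g*, TA
site *s*, library *k*.

## 1. Genome index (`tnessential.genome_index`)

**TA sites.** All positions `p` with `seq[p:p+2] == "TA"` on the forward
strand, overlapping occurrences included (`TATA` → p = 0 and 2). The TA is
palindromic, so forward-strand enumeration covers both orientations.
Sequences must be unambiguous A/C/G/T; violations are reported with the
offending symbol and position.

**Flanks.** Each TA site contributes up to two k-mers (default `k = 16`,
minimum 8, matching the MmeI-digest product length of the mariner
construct): the reverse complement of the k bases 5' of the TA ("left") and
the k bases 3' of it ("right"). Both are the sequence a read would contain.
Sites closer than k to a contig end contribute fewer flanks. A flank is
**unique** when its sequence occurs exactly once in the pooled multiset of
all flanks; `U` is the genome-wide count of unique flanks. Uniqueness is
exact string multiplicity — no alignment heuristics.

**Gene assignment.** Genes come from GFF3 (1-based, inclusive). For each
gene the distal `trim_3prime` fraction (default 0.1) of its length at the
3' end (strand-aware) is excluded, since insertions there often do not
disrupt function. `u_g` is the number of unique flanks of TA sites in the
retained interval; genes with `u_g = 0` are flagged non-evaluable.

## 2. Library quantification (`tnessential.library_quant`)

**Read structure.** `6-nt barcode | 2 random nt | 16-nt genomic tag`.
Demultiplexing is exact prefix matching (optional Hamming-distance rescue;
barcode sets whose pairwise distance is ≤ 2·max_mismatch are rejected as
ambiguous). Tags are aligned by exact dictionary lookup against the flank
index; tags matching a repeated flank are counted as `repeat_filtered`,
non-matching tags as `unmapped`. Tallies satisfy
`mapped + repeat_filtered + unmapped = total` per library.

**Noise cutoff.** Low-count spurious flanks are removed per library with a
data-driven threshold: a Gaussian KDE (Silverman bandwidth) of the log2
counts of nonzero flanks, weighted by multiplicity so the threshold is
invariant to duplicating records; the threshold is the first density
minimum between the first two modes, back-transformed to count scale.
Fallbacks: all-equal counts → 2.0; unimodal density → max(2, 1st percentile
of nonzero counts), with a warning. Fewer than 50 nonzero flanks → refuse
and request a manual threshold. Counts below the threshold are set to zero
*before* normalization and gene aggregation; raw counts are kept only for
the library-statistics table.

**Library statistics.** `aligned_pct = round(100·aligned/total, 1)`;
`mean_reads_per_flank = round(aligned / flanks_hit)` (integer). Unique
insertions per library = TA sites with at least one above-threshold flank;
`N` (pool size for the hit probability) is the same count on the pooled
libraries.

**Saturation curves.** Cumulative-unique counts over an ordered list of
libraries (running union of above-threshold site sets), and analytic
rarefaction: for subsample size `s` of `R` total reads with per-gene reads
`r_g`, `E[genes](s) = Σ_g (1 − C(R − r_g, s)/C(R, s))`, computed with
`gammaln`; a multivariate-hypergeometric Monte-Carlo estimate is available
for cross-checking.

## 3. Essentiality (`tnessential.essentiality`)

Pipeline order: noise threshold → Loess position correction → TMM → per-gene
aggregation → log2FC → KDE cutoff → NB test + BH → hit probability →
classification.

**Position correction.** Log2(count+1) means in 10 kb windows are smoothed
with lowess (tricube, degree 1, `frac = 0.3`, one robustness iteration);
each flank's count is divided by `2^(fit − mean fit)` and the library is
rescaled to preserve its total. Identity when the profile is flat or has
fewer than 3 windows.

**Between-library normalization (TMM).** The reference library is the one
whose 75th percentile of nonzero counts is closest to the mean. M (log
ratio) and A (log abundance) are computed on raw counts over flanks nonzero
in both libraries; the factor is the precision-weighted mean of M after
two-sided quantile trimming (30% on M, 5% on A), with edgeR-style inverse
asymptotic-variance weights; factors are rescaled to geometric mean 1, and
normalized counts are raw/factor. Note this is TMM on *raw* counts, so the
factor absorbs sequencing depth: a library with exactly doubled counts gets
factor √2 and the reference 1/√2. Errors: an all-zero library, or no flank
nonzero in both libraries.

**Expected reads and log2FC.** `E_g = T · u_g / U` with `T` the total
normalized reads over unique flanks; `log2FC_g = log2((O_g + 1)/(E_g + 1))`
(prior count 1, so zero-read genes are well defined).

**Essentiality cutoff.** KDE over evaluable genes' log2FC; the cutoff is
the density valley between the leftmost (depleted) mode and the global
(neutral) mode. Unimodal fallback: leftmost mode + 2, with a warning. Fewer
than 100 evaluable genes → refuse. The cutoff is translation-equivariant:
shifting all log2FC by c shifts the cutoff by c.

**NB test with common dispersion.** One-sample two-sided test of
`O_g ~ NB(E_g, φ)`: `p = 2·min(P(X ≤ O_g), P(X ≥ O_g), ½)`; Poisson limit
at `φ = 0`. The common dispersion maximizes the Cox–Reid adjusted profile
likelihood. The mean model is an intercept-only GLM with per-gene offsets
`log E_g`, so the only fitted mean parameter is the common intercept and
the adjustment is a single term:

    APL(φ) = Σ_g log NB(O_g; E_g, φ) − ½ log Σ_g E_g/(1 + φ E_g)

maximized over a log-spaced grid (1e-6 … 10) refined by bounded scalar
minimization. Genes in the extreme 5% of each log2FC tail are excluded from
estimation. On simulated NB data (n = 800, φ = 0.15) the estimate is
φ̂ ≈ 0.16. (Penalizing every gene's mean — correct only when each mean is
itself estimated — inflates φ̂ about 5-fold and is deliberately not done.)
P-values are BH-adjusted.

**Hit probability.** `P(hit) = 1 − (1 − u_g/U)^N`, computed as
`−expm1(N·log1p(−f))` for numerical stability.

**Classification.**

| condition | call |
|---|---|
| `u_g = 0` | not-evaluated |
| `O_g = 0` and `P(hit) > 0.95` | essential |
| `log2FC < cutoff` and `p_adj < 0.05` and `P(hit) > 0.95` | essential |
| otherwise | non-essential |

## 4. Enrichment and reporting (`tnessential.reporting`)

COG functional-category enrichment of essential genes: universe = evaluable
genes with at least one COG letter (genes may carry several); per category a
2×2 Fisher exact test (two-sided), with Storey q-values (π0 from a cubic
smoother over λ ∈ {0.05…0.95}; π0 = 1 — i.e. plain BH — when fewer than 10
tests or the estimate is invalid). `run_pipeline` executes 11 stages
(demux, align, noise_cutoff, loess, tmm, expected, log2fc, cutoff, nb_bh,
classify, enrich), records them in `manifest.json` together with inputs,
parameters, seed and library versions (no timestamps: reruns are
byte-identical), and exports a BED of essential genes plus a per-site
insertion track. Input failures raise `PipelineError(stage="genome_index",
code="input_error")`.

## 5. Synthetic data generator (`tnessential.synthgen`)

Defaults (`SimulationConfig`): genome 500 kb, GC 0.60 (≈20k TA sites under
the iid base model), 400 genes with gamma-distributed lengths (shape 4,
minimum 150 bp), 10% essential, N = 5,600 unique mutants, mean 300
reads/insertion with NB dispersion 0.3, 5% of hit sites spurious at 1–2
reads, a sinusoidal 2× position bias, three libraries with read weights
1:2:3 and barcodes ATCACG/CGATGT/TGACCA. Streams are seeded as
`default_rng([seed, stream])`, so genome, library, flank-split and FASTQ
randomness are independent and reproducible.

Essential genes receive zero true insertions (hard model; a soft-depletion
option exists). True insertions are sampled from TA sites whose two flanks
both exist and are unique genome-wide, which makes the perfect-read round
trip exact; noise sites are unrestricted. Reads are emitted with per-read
random flank side, optional per-base error rate, and constant quality.

Known limitations:

- the iid base model over-produces TA sites relative to real genomes, so
  the default saturation (~28%) is below values seen in deeply sequenced
  real libraries (~64%); parameter recovery does not depend on this;
- no insertion-site sequence preference beyond the TA requirement;
- genes are non-overlapping and single-contig;
- sequencing error is uniform and substitution-only.

## 6. Numerical choices

- All tail probabilities via scipy (`nbinom`, `poisson`, `hypergeom`);
  rarefaction binomial ratios in log space via `gammaln`.
- `1 − (1−f)^N` via `expm1`/`log1p`.
- KDE: `scipy.stats.gaussian_kde`, Silverman bandwidth, 512-point grid
  padded by half a bandwidth; plateau-tolerant extremum detection.
- BH via statsmodels `multipletests`; lowess via statsmodels; GFF3 via
  gffutils; FASTA/FASTQ via Biopython.

## 7. Open design decisions

- Noise filtering precedes normalization and gene aggregation; without it,
  the zero-read rule could never fire on genes containing spurious reads.
- The dispersion-estimation exclusion is 5% per log2FC tail (not 5% total).
- TMM on raw counts (depth folded into the factor) rather than on
  library-size-normalized counts; normalized counts are `raw/factor`.
- Degenerate all-equal count vectors get noise threshold 2.0 (the KDE and
  the percentile fallback are both undefined/degenerate there).
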
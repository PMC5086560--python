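"""The statistical core of the essentiality analysis.

Per-gene essentiality is inferred from the log2 fold change between observed
and expected reads under a uniform-insertion null.  Counts are first
corrected for smooth genomic-position bias (Loess on binned log2 counts) and
scaled between libraries (trimmed mean of M values), the essentiality cutoff
is located at the valley of the log2FC kernel density, significance comes
from a one-sample negative-binomial goodness-of-fit test with a common
Cox-Reid-estimated dispersion and Benjamini-Hochberg correction, and a
Poisson-law hit probability 1 - (1-f)^N guards small genes against chance
zero coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import nbinom, poisson
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .density import first_valley_between, kde_profile
from .genome_index import FlankIndex, GeneModel
from .library_quant import (
    apply_noise_threshold,
    collapse_to_sites,
    noise_cutoff,
    pooled_unique_insertions,
)

CALL_ESSENTIAL = "essential"
CALL_NON_ESSENTIAL = "non-essential"
CALL_NOT_EVALUATED = "not-evaluated"


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def loess_position_correct(counts, positions, span: float = 0.3,
                           window: int = 10_000):
    """Remove smooth genomic-position bias from per-site counts.

    Sites are binned into fixed-width windows; a locally weighted regression
    (tricube weights, degree 1) of mean log2(count+1) against window midpoint
    is interpolated back to each site, and each count is divided by
    2^(fit - mean fit).  Corrected counts are rescaled so the total read
    count is preserved.  Returns (corrected counts, curve DataFrame).
    """
    counts = np.asarray(counts, dtype=float)
    positions = np.asarray(positions, dtype=float)
    identity = pd.DataFrame({"position": positions, "factor": np.ones_like(positions)})
    if len(counts) == 0 or np.ptp(counts) == 0:
        return counts.copy(), identity
    bins = (positions // window).astype(int)
    logc = np.log2(counts + 1.0)
    df = pd.DataFrame({"bin": bins, "logc": logc, "pos": positions})
    win = df.groupby("bin").agg(mid=("pos", "mean"), mean_logc=("logc", "mean"))
    if len(win) < 3:
        return counts.copy(), identity
    fit = lowess(win["mean_logc"].to_numpy(), win["mid"].to_numpy(),
                 frac=span, it=1, return_sorted=True)
    site_fit = np.interp(positions, fit[:, 0], fit[:, 1])
    factor = 2.0 ** (site_fit - site_fit.mean())
    corrected = counts / factor
    total = counts.sum()
    if corrected.sum() > 0:
        corrected *= total / corrected.sum()
    curve = pd.DataFrame({"position": fit[:, 0],
                          "factor": 2.0 ** (fit[:, 1] - site_fit.mean())})
    return corrected, curve


def tmm_factors(matrix: pd.DataFrame, logratio_trim: float = 0.30,
                abs_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    M and A statistics are computed on raw counts against the reference
    library (the one whose 75th percentile of nonzero counts is closest to
    the mean of those percentiles); the extreme ``logratio_trim`` of M and
    ``abs_trim`` of A are trimmed two-sided, and the remaining M values are
    averaged with inverse-variance (delta-method) precision weights.  The
    factor folds sequencing depth and composition into one scale: normalized
    counts are raw counts divided by the factor.
    """
    if matrix.shape[1] < 2:
        return pd.Series(1.0, index=matrix.columns)
    arr = matrix.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        bad = matrix.columns[arr.sum(axis=0) == 0][0]
        raise ValueError(f"library {bad} has no nonzero counts")
    p75 = np.array([np.percentile(arr[arr[:, j] > 0, j], 75)
                    for j in range(arr.shape[1])])
    ref_j = int(np.argmin(np.abs(p75 - p75.mean())))
    lib_sizes = arr.sum(axis=0)
    log_factors = np.zeros(arr.shape[1])
    yr = arr[:, ref_j]
    for j in range(arr.shape[1]):
        if j == ref_j:
            continue
        yk = arr[:, j]
        use = (yk > 0) & (yr > 0)
        if not use.any():
            raise ValueError(
                f"library {matrix.columns[j]} shares no co-nonzero flanks "
                f"with reference {matrix.columns[ref_j]}"
            )
        m = np.log2(yk[use]) - np.log2(yr[use])
        a = 0.5 * (np.log2(yk[use]) + np.log2(yr[use]))
        # quantile-based two-sided trim (invariant to row order and ties)
        m_lo, m_hi = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        a_lo, a_hi = np.quantile(a, [abs_trim, 1 - abs_trim])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        w = 1.0 / (
            (lib_sizes[j] - yk[use]) / (lib_sizes[j] * yk[use])
            + (lib_sizes[ref_j] - yr[use]) / (lib_sizes[ref_j] * yr[use])
        )
        log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=matrix.columns)


# ---------------------------------------------------------------------------
# per-gene statistics
# ---------------------------------------------------------------------------

def expected_reads(u_g, total_unique_flanks: int, total_reads: float):
    """E_g = T * u_g / U: reads land uniformly on unique informative flanks
    under the null of no selection."""
    if total_unique_flanks <= 0:
        raise ValueError("genome-wide unique flank count U must be > 0")
    return np.asarray(u_g, dtype=float) * total_reads / total_unique_flanks


def log2fc(observed, expected, prior: float = 1.0):
    """log2((observed + prior) / (expected + prior)); prior avoids -inf at
    zero observed reads."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if (expected <= 0).any():
        raise ValueError("expected reads must be > 0")
    return np.log2((observed + prior) / (expected + prior))


def essentiality_cutoff(values, min_n: int = 100):
    """Locate the log2FC cutoff at the density valley below the main mode.

    Gaussian KDE (Silverman bandwidth); the cutoff is the value at the local
    density minimum between the leftmost mode (the depleted, putatively
    essential population) and the global mode.  If no such valley exists the
    fallback is leftmost mode + 2, with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < min_n:
        raise ValueError(
            f"only {len(values)} finite log2FC values (< {min_n}); "
            "supply a manual cutoff"
        )
    grid, dens, maxima, minima = kde_profile(values)
    leftmost = maxima[0]
    global_mode = maxima[np.argmax(dens[maxima])]
    if leftmost != global_mode:
        v = first_valley_between(grid, minima, leftmost, global_mode)
        if v is not None:
            return float(grid[v])
    warnings.warn(
        "log2FC density has no valley below the main mode; "
        "falling back to leftmost mode + 2", UserWarning)
    return float(grid[leftmost] + 2.0)


def _nb_logpmf(x, mu, phi):
    if phi <= 1e-12:
        return poisson.logpmf(x, mu)
    size = 1.0 / phi
    return nbinom.logpmf(x, size, size / (size + mu))


def estimate_dispersion(observed, expected, tail_exclude: float = 0.05,
                        prior: float = 1.0) -> float:
    """Common NB dispersion by Cox-Reid adjusted profile likelihood.

    The mean model is an intercept-only GLM with per-gene offsets log E_g,
    so the only fitted mean parameter is the common intercept; the Cox-Reid
    adjustment is -0.5 log I(phi) with I = sum_g E_g / (1 + phi E_g), the
    Fisher information for that intercept under the log link. The adjusted
    likelihood is maximized over a log-spaced grid refined by bounded
    golden-section search. Genes in the extreme ``tail_exclude`` of each
    log2FC tail are excluded.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.sum() == 0:
        raise ValueError("all-zero observed counts: dispersion is uninformative")
    fc = log2fc(observed, expected, prior)
    lo, hi = np.quantile(fc, [tail_exclude, 1 - tail_exclude])
    keep = (fc >= lo) & (fc <= hi)
    o = np.round(observed[keep])
    mu = expected[keep]

    def neg_adj_ll(log_phi):
        phi = np.exp(log_phi)
        ll = _nb_logpmf(o, mu, phi).sum()
        info = (mu / (1.0 + phi * mu)).sum()
        return -(ll - 0.5 * np.log(info))

    grid = np.log(np.logspace(-6, 1, 40))
    vals = [neg_adj_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_adj_ll, bounds=(lo_b, hi_b), method="bounded")
    return float(np.exp(res.x))


def nb_test(observed, expected, dispersion: float):
    """Two-sided p-values for observed counts under NB(E_g, phi).

    p = 2 * min(P(X <= obs), P(X >= obs), 1/2); the NB reduces to Poisson as
    phi -> 0.
    """
    observed = np.round(np.asarray(observed, dtype=float))
    expected = np.asarray(expected, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if (expected <= 0).any():
        raise ValueError("expected reads must be > 0")
    if dispersion <= 1e-12:
        lower = poisson.cdf(observed, expected)
        upper = poisson.sf(observed - 1, expected)
    else:
        size = 1.0 / dispersion
        p = size / (size + expected)
        lower = nbinom.cdf(observed, size, p)
        upper = nbinom.sf(observed - 1, size, p)
    return 2.0 * np.minimum.reduce([lower, upper, np.full_like(lower, 0.5)])


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hit_probability(n_mutants, f):
    """Probability a gene with unique-flank fraction f is hit at least once
    among N unique mutants: 1 - (1-f)^N, computed stably."""
    f = np.asarray(f, dtype=float)
    n = np.asarray(n_mutants, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("f must lie in [0, 1]")
    if (n < 0).any():
        raise ValueError("N must be >= 0")
    with np.errstate(divide="ignore"):
        out = -np.expm1(n * np.log1p(-f))
    return np.where(f >= 1.0, 1.0, out)


def classify_genes(records: pd.DataFrame, cutoff: float, alpha: float = 0.05,
                   p_hit_min: float = 0.95) -> pd.Series:
    """Final essentiality call per gene.

    not-evaluated if u_g = 0; essential if (log2fc < cutoff AND adjusted
    p < alpha AND hit probability > p_hit_min) OR (observed = 0 AND hit
    probability > p_hit_min); else non-essential.
    """
    calls = []
    for _, r in records.iterrows():
        if r["u_g"] == 0:
            calls.append(CALL_NOT_EVALUATED)
        elif (
            (r["log2fc"] < cutoff and r["p_adj"] < alpha
             and r["hit_probability"] > p_hit_min)
            or (r["observed"] == 0 and r["hit_probability"] > p_hit_min)
        ):
            calls.append(CALL_ESSENTIAL)
        else:
            calls.append(CALL_NON_ESSENTIAL)
    return pd.Series(calls, index=records.index, name="call")


# ---------------------------------------------------------------------------
# end-to-end analysis of a count matrix
# ---------------------------------------------------------------------------

@dataclass
class AnalysisDiagnostics:
    thresholds: dict
    tmm: pd.Series
    cutoff: float
    dispersion: float
    n_unique_mutants: int
    total_unique_flanks: int
    total_normalized_reads: float
    loess_curves: dict
    density_curve: pd.DataFrame


def analyze(
    flank_matrix: pd.DataFrame,
    genes: list[GeneModel],
    flank_index: FlankIndex,
    *,
    thresholds: dict | None = None,
    loess_span: float = 0.3,
    loess_window: int = 10_000,
    prior: float = 1.0,
    alpha: float = 0.05,
    p_hit_min: float = 0.95,
    cutoff: float | None = None,
    n_unique_mutants: int | None = None,
    cutoff_on_evaluable_only: bool = True,
):
    """Run the full per-gene essentiality analysis on a flank count matrix.

    Rows of ``flank_matrix`` are positional indices into ``flank_index``;
    genes must already carry informative flanks (assign_informative_sites).
    Returns (records DataFrame, AnalysisDiagnostics).
    """
    if thresholds is None:
        thresholds = {lib: noise_cutoff(flank_matrix[lib].to_numpy())
                      for lib in flank_matrix.columns}
    denoised = apply_noise_threshold(flank_matrix, thresholds)

    if n_unique_mutants is None:
        n_unique_mutants = pooled_unique_insertions(
            flank_matrix, thresholds, flank_index)

    positions = flank_index.site_pos[denoised.index.to_numpy()]
    corrected = denoised.astype(float).copy()
    loess_curves = {}
    for lib in corrected.columns:
        corrected[lib], loess_curves[lib] = loess_position_correct(
            corrected[lib].to_numpy(), positions,
            span=loess_span, window=loess_window)

    tmm = tmm_factors(denoised) if denoised.shape[1] >= 2 else pd.Series(
        1.0, index=denoised.columns)
    normalized = corrected / tmm

    # pooled normalized reads on unique flanks only
    uniq_mask = flank_index.unique[normalized.index.to_numpy()]
    pooled = normalized.sum(axis=1).to_numpy()
    total_reads = float(pooled[uniq_mask].sum())
    U = flank_index.n_unique

    u_g = np.array([g.u_g for g in genes])
    observed = np.array([pooled[g.informative_flanks].sum() for g in genes])
    evaluable = u_g > 0
    exp_reads = np.full(len(genes), np.nan)
    exp_reads[evaluable] = expected_reads(u_g[evaluable], U, total_reads)
    fc = np.full(len(genes), np.nan)
    fc[evaluable] = log2fc(observed[evaluable], exp_reads[evaluable], prior)

    if cutoff is None:
        pool_fc = fc[evaluable] if cutoff_on_evaluable_only else fc
        cutoff = essentiality_cutoff(pool_fc[np.isfinite(pool_fc)])

    dispersion = estimate_dispersion(observed[evaluable], exp_reads[evaluable],
                                     prior=prior)
    pvals = np.full(len(genes), np.nan)
    pvals[evaluable] = nb_test(observed[evaluable], exp_reads[evaluable],
                               dispersion)
    padj = np.full(len(genes), np.nan)
    padj[evaluable] = bh_adjust(pvals[evaluable])

    f = np.where(evaluable, u_g / U, 0.0)
    p_hit = hit_probability(n_unique_mutants, f)

    records = pd.DataFrame(
        {
            "locus_tag": [g.locus_tag for g in genes],
            "u_g": u_g,
            "observed": observed,
            "expected": exp_reads,
            "log2fc": fc,
            "p_value": pvals,
            "p_adj": padj,
            "hit_probability": p_hit,
        }
    ).set_index("locus_tag")
    records["call"] = classify_genes(records, cutoff, alpha, p_hit_min)

    fin = fc[np.isfinite(fc)]
    grid, dens, _, _ = kde_profile(fin)
    density_curve = pd.DataFrame({"log2fc": grid, "density": dens})

    diag = AnalysisDiagnostics(
        thresholds=thresholds,
        tmm=tmm,
        cutoff=float(cutoff),
        dispersion=float(dispersion),
        n_unique_mutants=int(n_unique_mutants),
        total_unique_flanks=int(U),
        total_normalized_reads=total_reads,
        loess_curves=loess_curves,
        density_curve=density_curve,
    )
    return records, diag
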
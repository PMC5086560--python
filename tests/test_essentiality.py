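"""Normalization, per-gene statistics, and the essentiality call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom, poisson

from tnessential.essentiality import (
    CALL_ESSENTIAL,
    CALL_NON_ESSENTIAL,
    CALL_NOT_EVALUATED,
    bh_adjust,
    classify_genes,
    essentiality_cutoff,
    estimate_dispersion,
    expected_reads,
    hit_probability,
    loess_position_correct,
    log2fc,
    nb_test,
    tmm_factors,
)


class TestLoess:
    def test_flat_counts_identity(self):
        counts = np.full(500, 20.0)
        pos = np.linspace(0, 499_000, 500)
        corrected, curve = loess_position_correct(counts, pos)
        assert np.allclose(corrected, counts, atol=1e-6)
        assert np.allclose(curve["factor"], 1.0, atol=1e-6)

    def test_sinusoidal_bias_reduced_80_percent(self, rng):
        pos = np.sort(rng.uniform(0, 500_000, 4000))
        bias = 2.0 ** (0.5 * np.sin(2 * np.pi * pos / 500_000))
        counts = rng.poisson(100 * bias).astype(float)
        corrected, curve_before = loess_position_correct(counts, pos)
        _, curve_after = loess_position_correct(corrected, pos)
        amp_before = np.ptp(np.log2(curve_before["factor"]))
        amp_after = np.ptp(np.log2(curve_after["factor"]))
        assert amp_after <= 0.2 * amp_before

    def test_total_reads_preserved(self, rng):
        pos = np.sort(rng.uniform(0, 300_000, 2000))
        counts = rng.poisson(50 * 2.0 ** np.sin(pos / 30_000)).astype(float)
        corrected, _ = loess_position_correct(counts, pos)
        assert corrected.sum() == pytest.approx(counts.sum(), rel=5e-3)


class TestTmm:
    def test_identical_libraries_give_unit_factors(self, rng):
        a = rng.poisson(100, 500) + 1
        m = pd.DataFrame({"a": a, "b": a, "c": a})
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-12)

    def test_doubled_library_gives_sqrt2_factors(self, rng):
        a = rng.poisson(100, 500) + 1
        m = pd.DataFrame({"a": a, "b": 2 * a})
        f = tmm_factors(m)
        assert f["b"] / f["a"] == pytest.approx(2.0, abs=1e-6)
        assert f["a"] * f["b"] == pytest.approx(1.0, abs=1e-9)  # geometric mean 1
        assert f["b"] == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_invariant_to_row_permutation(self, rng):
        m = pd.DataFrame(rng.poisson(80, (400, 3)) + 1, columns=list("abc"))
        perm = m.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_series_equal(tmm_factors(m), tmm_factors(perm))

    def test_disjoint_support_rejected(self):
        m = pd.DataFrame({"a": [5, 5, 0, 0], "b": [0, 0, 5, 5]})
        with pytest.raises(ValueError, match="co-nonzero"):
            tmm_factors(m)


class TestExpectedAndLog2fc:
    def test_expected_proportional_and_conserved(self):
        e = expected_reads([10], 1000, 100_000)
        assert e[0] == pytest.approx(1000.0)
        u = np.array([3, 7, 15, 25])  # tiles 50 unique flanks
        total = float(u.sum())
        e = expected_reads(u, int(total), 9999.0)
        assert e.sum() == pytest.approx(9999.0)
        assert np.allclose(2 * e, expected_reads(u, int(total), 2 * 9999.0))

    def test_log2fc_examples_and_monotonicity(self):
        assert log2fc(100, 100) == pytest.approx(0.0)
        assert log2fc(0, 127, prior=1) == pytest.approx(-7.0)
        obs = np.arange(0, 500, 10)
        fc = log2fc(obs, np.full_like(obs, 100.0))
        assert (np.diff(fc) > 0).all()
        with pytest.raises(ValueError):
            log2fc(5, 0.0)


class TestEssentialityCutoff:
    def test_bimodal_mixture_recovers_valley(self, rng):
        vals = np.concatenate([rng.normal(-8, 0.5, 400),
                               rng.normal(0, 1, 3600)])
        cut = essentiality_cutoff(vals)
        assert -7 < cut < -3
        truth = np.concatenate([np.ones(400, bool), np.zeros(3600, bool)])
        assert ((vals < cut) != truth).mean() <= 0.02

    def test_unimodal_falls_back_with_warning(self, rng):
        vals = rng.normal(0, 1, 1000)
        with pytest.warns(UserWarning, match="no valley"):
            cut = essentiality_cutoff(vals)
        grid_min = vals.min()
        assert grid_min - 1 < cut < vals.max()

    def test_translation_equivariance(self, rng):
        vals = np.concatenate([rng.normal(-8, 0.5, 400),
                               rng.normal(0, 1, 3600)])
        assert essentiality_cutoff(vals + 2.5) == pytest.approx(
            essentiality_cutoff(vals) + 2.5, abs=1e-9)

    def test_too_few_values_refused(self, rng):
        with pytest.raises(ValueError, match="manual cutoff"):
            essentiality_cutoff(rng.normal(0, 1, 50))


class TestNbTest:
    def test_central_observations_not_significant(self, rng):
        expected = rng.uniform(50, 500, 200)
        p = nb_test(np.round(expected), expected, dispersion=0.2)
        assert (p >= 0.3).all()

    def test_zero_observed_matches_pmf_summation(self):
        phi, mu = 0.1, 500.0
        p = nb_test([0.0], [mu], phi)[0]
        size = 1 / phi
        pr = size / (size + mu)
        # direct pmf summation of the lower tail at 0
        direct = 2 * nbinom.pmf(0, size, pr)
        assert p == pytest.approx(direct, rel=1e-12)

    def test_two_sided_tail_matches_bruteforce_summation(self):
        phi, mu, obs = 0.3, 40.0, 12
        size = 1 / phi
        pr = size / (size + mu)
        k = np.arange(0, 10_000)
        pmf = nbinom.pmf(k, size, pr)
        lower = pmf[: obs + 1].sum()
        upper = pmf[obs:].sum()
        expected_p = 2 * min(lower, upper, 0.5)
        assert nb_test([obs], [mu], phi)[0] == pytest.approx(expected_p, rel=1e-9)

    def test_poisson_limit(self):
        obs, mu = np.array([3.0, 20.0, 80.0]), np.array([10.0, 20.0, 30.0])
        p_nb = nb_test(obs, mu, 1e-8)
        p_pois = 2 * np.minimum.reduce([
            poisson.cdf(obs, mu), poisson.sf(obs - 1, mu),
            np.full_like(mu, 0.5)])
        assert np.allclose(p_nb, p_pois, atol=1e-3)

    def test_dispersion_estimation_recovers_truth(self, rng):
        mu = rng.uniform(100, 1000, 800)
        phi_true = 0.15
        size = 1 / phi_true
        obs = rng.negative_binomial(size, size / (size + mu))
        phi_hat = estimate_dispersion(obs, mu)
        assert 0.5 * phi_true < phi_hat < 2.0 * phi_true

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            estimate_dispersion(np.zeros(100), np.full(100, 50.0))


class TestBhAdjust:
    def test_step_up_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        # brute force: q_i = min over j with p_j >= p_i of m*p_j/rank_j
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        q = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, m * ranked[i] / (i + 1))
            q[i] = running
        brute = np.empty(m)
        brute[order] = q
        assert np.allclose(bh_adjust(p), brute, atol=1e-12)


class TestHitProbability:
    @pytest.mark.parametrize(
        "n,f,expected",
        [(1000, 0.0, 0.0), (1, 0.5, 0.5), (100, 0.01, 1 - 0.99**100),
         (5, 1.0, 1.0)],
    )
    def test_closed_forms(self, n, f, expected):
        assert hit_probability(n, f) == pytest.approx(expected, rel=1e-12)

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            hit_probability(10, 1.5)
        with pytest.raises(ValueError):
            hit_probability(10, -0.1)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=10**6),
           st.floats(min_value=0, max_value=0.999))
    def test_matches_power_form_and_monotone(self, n, f):
        p = hit_probability(n, f)
        assert p == pytest.approx(1 - (1 - f) ** n, abs=1e-12)
        assert hit_probability(n + 1, f) >= p - 1e-15
        assert hit_probability(n, min(f + 1e-4, 0.999)) >= p - 1e-15

    def test_matches_monte_carlo_within_3_se(self, rng):
        n, f, reps = 5000, 2e-4, 100_000
        # a gene occupying f of the flank pool is missed by one mutant w.p. 1-f
        hits = rng.binomial(n, f, size=reps) > 0
        mc = hits.mean()
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(hit_probability(n, f) - mc) <= 3 * se


class TestClassifyGenes:
    def _records(self, **kw):
        base = dict(u_g=10, observed=500.0, log2fc=0.0, p_adj=0.5,
                    hit_probability=0.99)
        base.update(kw)
        return pd.DataFrame([base], index=["g1"])

    def test_zero_read_rule(self):
        r = self._records(observed=0.0, log2fc=-9.0, p_adj=0.9,
                          hit_probability=0.96)
        assert classify_genes(r, cutoff=-6.86).iloc[0] == CALL_ESSENTIAL

    def test_depleted_and_significant_is_essential(self):
        r = self._records(observed=3.0, log2fc=-7.5, p_adj=0.001,
                          hit_probability=0.99)
        assert classify_genes(r, cutoff=-6.86).iloc[0] == CALL_ESSENTIAL

    def test_low_hit_probability_blocks_call(self):
        r = self._records(observed=3.0, log2fc=-7.5, p_adj=0.001,
                          hit_probability=0.80)
        assert classify_genes(r, cutoff=-6.86).iloc[0] == CALL_NON_ESSENTIAL

    def test_no_informative_flanks_not_evaluated(self):
        r = self._records(u_g=0, observed=0.0, log2fc=-9.0, p_adj=0.0,
                          hit_probability=0.99)
        assert classify_genes(r, cutoff=-6.86).iloc[0] == CALL_NOT_EVALUATED

    def test_order_independence(self, rng):
        rows = pd.DataFrame({
            "u_g": rng.integers(0, 20, 50),
            "observed": rng.uniform(0, 100, 50).round(),
            "log2fc": rng.normal(-4, 3, 50),
            "p_adj": rng.uniform(0, 1, 50),
            "hit_probability": rng.uniform(0.5, 1, 50),
        }, index=[f"g{i}" for i in range(50)])
        calls = classify_genes(rows, cutoff=-6.86)
        shuffled = rows.sample(frac=1, random_state=0)
        assert classify_genes(shuffled, cutoff=-6.86).sort_index().equals(
            calls.sort_index())


class TestParameterRecovery:
    """Headline property: the pipeline recovers the simulated essential set."""

    def test_sensitivity_and_fdp(self, default_analysis):
        rec = default_analysis["records"]
        truth = default_analysis["truth"].gene_essential.loc[rec.index]
        called = rec["call"] == CALL_ESSENTIAL
        evaluable = rec["u_g"] > 0
        tp = int((called & truth).sum())
        n_true = int((truth & evaluable).sum())
        assert tp / n_true >= 0.90
        fdp = int((called & ~truth).sum()) / max(int(called.sum()), 1)
        assert fdp <= 0.10

    def test_guarded_essentials_all_called(self, default_analysis):
        # hard-depletion model: every truly essential, evaluable gene whose
        # hit probability clears the guard must be called essential
        rec = default_analysis["records"]
        truth = default_analysis["truth"].gene_essential.loc[rec.index]
        must = truth & (rec["u_g"] > 0) & (rec["hit_probability"] > 0.95)
        assert (rec.loc[must, "call"] == CALL_ESSENTIAL).all()

    def test_u_g_is_annotation_side_only(self, default_analysis):
        # dropping a library from the count matrix cannot change u_g
        before = {g.locus_tag: g.u_g for g in default_analysis["genes"]}
        from tnessential.essentiality import analyze
        fm = default_analysis["flank_matrix"].iloc[:, :2]
        rec, _ = analyze(fm, default_analysis["genes"],
                         default_analysis["fidx"])
        assert {loc: int(u) for loc, u in rec["u_g"].items()} == before
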
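"""HMM founder reconstruction and the founder-probability scan."""

import numpy as np
import pandas as pd
import pytest

from rosetteqtl.magicsim import (
    FounderPanel,
    MagicGenotypes,
    simulate_founders,
    simulate_magic_population,
)
from rosetteqtl.qtl_scan import (
    MarkerDesigns,
    _haldane_switch_probs,
    founder_effect_summary,
    infer_founder_probabilities,
    permutation_threshold,
    scan_trait,
)


def _tiny_panel(alleles: np.ndarray, spacing_cm=5.0) -> FounderPanel:
    k, m = alleles.shape
    markers = pd.DataFrame(
        {
            "marker": [f"Chr1_m{i}" for i in range(m)],
            "chrom": "Chr1",
            "pos_bp": np.arange(m) * 100_000 + 1,
            "pos_cM": np.arange(m) * spacing_cm,
        }
    )
    return FounderPanel(markers=markers, alleles=alleles.astype(np.int8),
                        founder_names=[f"F{i+1}" for i in range(k)])


def _brute_force_posterior(calls, alleles, switch_probs, error_rate):
    """Enumerate all founder paths: independent oracle for the HMM.

    Prior: uniform start, per-interval switch probability r to each other
    founder (r/(K-1) each) and 1-r of staying.  Likelihood: per-marker
    emission (1-e) on allele match, e on mismatch, 1 on missing call.
    """
    import itertools

    K, M = alleles.shape
    post = np.zeros((M, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=M):
        p = 1.0 / K
        for t in range(1, M):
            r = switch_probs[t]
            p *= (1.0 - r) if path[t] == path[t - 1] else r / (K - 1)
        for t in range(M):
            c = calls[t]
            if c >= 0:
                p *= (1.0 - error_rate) if alleles[path[t], t] == c else error_rate
        total += p
        for t in range(M):
            post[t, path[t]] += p
    return post / total


class TestFounderProbabilities:
    def test_unambiguous_emissions_recover_truth_exactly(self):
        # founders have distinct allele patterns at every marker pair such
        # that each founder is uniquely identified
        alleles = np.array([[0, 0, 0], [1, 1, 1]])
        panel = _tiny_panel(alleles)
        calls = np.array([[1, 1, 1]], dtype=np.int8)
        geno = MagicGenotypes(panel=panel, calls=calls, line_names=["L1"])
        probs = infer_founder_probabilities(geno, error_rate=0.0)
        np.testing.assert_allclose(probs.probs[0, :, 1], 1.0)

    def test_uninformative_emissions_give_uniform_posterior(self):
        alleles = np.ones((19, 4), dtype=np.int8)
        panel = _tiny_panel(alleles)
        calls = np.ones((1, 4), dtype=np.int8)
        geno = MagicGenotypes(panel=panel, calls=calls, line_names=["L1"])
        probs = infer_founder_probabilities(geno, error_rate=0.01)
        np.testing.assert_allclose(probs.probs[0], 1.0 / 19, atol=1e-12)

    def test_rows_sum_to_one(self, small_population):
        probs = infer_founder_probabilities(small_population)
        np.testing.assert_allclose(probs.probs.sum(axis=2), 1.0, atol=1e-8)

    @pytest.mark.parametrize("n_founders,n_markers,seed", [(3, 5, 0), (4, 6, 1), (2, 6, 2)])
    def test_forward_backward_equals_path_enumeration(self, n_founders, n_markers, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, size=(n_founders, n_markers))
        panel = _tiny_panel(alleles)
        calls = rng.integers(0, 2, size=(1, n_markers)).astype(np.int8)
        calls[0, n_markers // 2] = -1  # include a missing call
        geno = MagicGenotypes(panel=panel, calls=calls, line_names=["L1"])
        eps, density = 0.02, 1.5
        probs = infer_founder_probabilities(geno, error_rate=eps, mosaic_density=density)
        r = _haldane_switch_probs(panel, density)
        oracle = _brute_force_posterior(calls[0], alleles, r, eps)
        np.testing.assert_allclose(probs.probs[0], oracle, atol=1e-8)

    def test_truth_recovery_above_90_percent(self, small_population):
        probs = infer_founder_probabilities(small_population, error_rate=0.01)
        amax = probs.probs.argmax(axis=2)
        accuracy = (amax == small_population.founder_truth).mean()
        assert accuracy >= 0.9

    def test_high_missingness_lines_dropped_with_warning(self, small_population):
        calls = small_population.calls.copy()
        calls[0, : int(0.5 * calls.shape[1])] = -1
        geno = MagicGenotypes(
            panel=small_population.panel, calls=calls,
            line_names=small_population.line_names,
        )
        with pytest.warns(UserWarning, match="missing"):
            probs = infer_founder_probabilities(geno)
        assert probs.n_lines == len(small_population.line_names) - 1


@pytest.fixture(scope="module")
def probs(small_population):
    return infer_founder_probabilities(small_population)


class TestScanTrait:
    def test_perfect_founder_indicator_gives_r2_one(self, probs):
        y = probs.probs[:, 30, 4].copy()  # exact copy of founder-5 column
        scan = scan_trait(probs, y)
        assert scan.table["var_explained"].iloc[30] == pytest.approx(1.0, abs=1e-6)

    def test_constant_phenotype_warns_and_gives_zero_logp(self, probs):
        with pytest.warns(UserWarning, match="constant"):
            scan = scan_trait(probs, np.ones(probs.n_lines))
        assert (scan.table["logP"] == 0).all()

    def test_logp_invariant_under_affine_phenotype_transform(self, probs):
        rng = np.random.default_rng(3)
        y = rng.normal(size=probs.n_lines)
        a = scan_trait(probs, y).table["logP"]
        b = scan_trait(probs, 10.0 - 3.0 * y).table["logP"]
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-8)

    def test_shrinkage_contracts_toward_weighted_mean(self, probs, small_population):
        rng = np.random.default_rng(4)
        y = rng.normal(size=probs.n_lines)
        scan = scan_trait(probs, y)
        j = 10
        x = probs.probs[:, j, :]
        raw = np.linalg.pinv(x) @ y
        mass = x.sum(axis=0)
        wmean = np.sum(mass * raw) / mass.sum()
        eff = scan.effects.iloc[j].to_numpy()
        assert np.max(np.abs(eff - wmean)) <= np.max(np.abs(raw - wmean)) + 1e-12

    def test_planted_founder_effect_recovered_with_correct_sign(self, small_population, probs):
        # +2 for founder 1, 0 for the others, modest noise
        rng = np.random.default_rng(5)
        causal = 25
        y = np.where(small_population.founder_truth[:, causal] == 0, 2.0, 0.0)
        y = y + rng.normal(0, 0.5, size=len(y))
        scan = scan_trait(probs, y)
        eff = scan.effects.iloc[causal]
        assert eff["F1"] == eff.max()

    def test_null_pvalues_uniform_at_each_marker(self, probs):
        # marginal calibration: at any fixed marker the p-value over
        # independent null traits is U(0,1); a genome-wide per-trait KS
        # would be confounded by linkage between markers
        from scipy import stats as ss

        designs = MarkerDesigns(probs)
        rng = np.random.default_rng(11)
        y_batch = rng.normal(size=(probs.n_lines, 80))
        logp, _ = designs.logp_r2(y_batch)
        pvals = 10.0 ** (-logp)
        crit = 1.63 / np.sqrt(pvals.shape[1])  # ~1% critical value
        n_ok = 0
        for j in (5, 27, 60, 88):
            ks = ss.ks_1samp(pvals[j], ss.uniform.cdf).statistic
            n_ok += ks < crit
        assert n_ok >= 3


@pytest.fixture(scope="module")
def perm_setup(probs):
    designs = MarkerDesigns(probs)
    y = np.random.default_rng(6).normal(size=probs.n_lines)
    return designs, y


class TestPermutationThreshold:
    def test_threshold_is_type7_quantile_of_max_distribution(self, perm_setup):
        designs, y = perm_setup
        thr = permutation_threshold(designs, y, alpha=0.05, n_perm=200, seed=1)
        expected = np.quantile(thr.max_logp_distribution, 0.95)
        assert thr.logp_threshold == pytest.approx(expected)

    def test_threshold_monotone_in_alpha(self, perm_setup):
        designs, y = perm_setup
        t1 = permutation_threshold(designs, y, alpha=0.01, n_perm=200, seed=2)
        t2 = permutation_threshold(designs, y, alpha=0.10, n_perm=200, seed=2)
        assert t1.logp_threshold >= t2.logp_threshold

    def test_deterministic_given_seed(self, perm_setup):
        designs, y = perm_setup
        a = permutation_threshold(designs, y, n_perm=150, seed=7)
        b = permutation_threshold(designs, y, n_perm=150, seed=7)
        assert a.logp_threshold == b.logp_threshold
        np.testing.assert_array_equal(a.max_logp_distribution, b.max_logp_distribution)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2])
    def test_invalid_alpha_rejected(self, perm_setup, alpha):
        designs, y = perm_setup
        with pytest.raises(ValueError):
            permutation_threshold(designs, y, alpha=alpha, n_perm=100)


class TestFounderEffectSummary:
    def test_summary_has_intervals_and_unknown_marker_raises(self, small_population):
        probs = infer_founder_probabilities(small_population)
        y = np.random.default_rng(8).normal(size=probs.n_lines)
        scan = scan_trait(probs, y)
        marker = scan.table["marker"].iloc[0]
        summary = founder_effect_summary(scan, marker)
        assert len(summary) == 19
        assert (summary["upper"] >= summary["lower"]).all()
        with pytest.raises(KeyError):
            founder_effect_summary(scan, "not_a_marker")
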
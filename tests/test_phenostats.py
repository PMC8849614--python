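"""Averaging, correlations, REML heritability and the PCA morphospace."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rosetteqtl.morphometry import DESCRIPTOR_NAMES
from rosetteqtl.phenostats import (
    average_replicates,
    build_morphospace,
    correlations_by_das,
    heritability,
    project_morphospace,
)


def _long_table(values, trait="PRA"):
    rows = []
    for line, reps in values.items():
        for j, v in enumerate(reps, start=1):
            rows.append({"line": line, "replicate": j, "das": 35, trait: v})
    return pd.DataFrame(rows)


class TestAverageReplicates:
    def test_simple_mean(self):
        out = average_replicates(_long_table({"a": [1.0, 2.0, 3.0]}))
        assert out["PRA"].iloc[0] == pytest.approx(2.0)
        assert out["n_replicates"].iloc[0] == 3

    def test_missing_values_ignored(self):
        out = average_replicates(_long_table({"a": [4.0, np.nan, 6.0]}))
        assert out["PRA"].iloc[0] == pytest.approx(5.0)
        assert out["n_replicates"].iloc[0] == 2

    def test_single_replicate_identity(self):
        out = average_replicates(_long_table({"a": [7.5]}))
        assert out["PRA"].iloc[0] == pytest.approx(7.5)

    def test_all_missing_cell_dropped_with_warning(self):
        table = pd.concat(
            [_long_table({"a": [np.nan, np.nan]}), _long_table({"b": [1.0]})]
        )
        with pytest.warns(UserWarning, match="dropping"):
            out = average_replicates(table)
        assert list(out["line"]) == ["b"]

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=6,
        )
    )
    def test_mean_matches_numpy(self, reps):
        out = average_replicates(_long_table({"x": reps}))
        assert out["PRA"].iloc[0] == pytest.approx(np.mean(reps), rel=1e-12, abs=1e-9)


class TestCorrelations:
    def _averaged(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return pd.DataFrame(
            {"line": [f"l{i}" for i in range(n)], "das": 35,
             "A": x, "B": -x, "C": rng.normal(size=n)}
        )

    def test_self_correlation_is_one_and_exact_negative(self):
        corr = correlations_by_das(self._averaged(), 35)
        assert corr.loc["A", "A"] == pytest.approx(1.0)
        assert corr.loc["A", "B"] == pytest.approx(-1.0)
        assert corr.to_numpy() == pytest.approx(corr.to_numpy().T)

    def test_positive_semidefinite(self):
        corr = correlations_by_das(self._averaged(seed=3), 35)
        eigs = np.linalg.eigvalsh(corr.to_numpy())
        assert eigs.min() >= -1e-10

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            correlations_by_das(self._averaged(n=2), 35)


class TestHeritability:
    def _simulate(self, vg, ve, n_lines, reps, seed):
        rng = np.random.default_rng(seed)
        line_eff = rng.normal(0, np.sqrt(vg), n_lines)
        rows = []
        for i in range(n_lines):
            for j in range(reps):
                rows.append(
                    {"line": f"l{i}", "replicate": j + 1, "das": 35,
                     "PRA": line_eff[i] + rng.normal(0, np.sqrt(ve))}
                )
        return pd.DataFrame(rows)

    def test_identical_replicates_give_h2_of_one(self):
        table = _long_table({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [5.0, 5.0]})
        est = heritability(table, "PRA", 35)
        assert est.h2 == pytest.approx(1.0)

    def test_all_equal_gives_h2_zero(self):
        table = _long_table({"a": [3.0, 3.0], "b": [3.0, 3.0]})
        est = heritability(table, "PRA", 35)
        assert est.h2 == 0.0

    def test_reml_matches_balanced_method_of_moments(self):
        # for balanced data the REML estimate coincides with the ANOVA
        # (method-of-moments) estimate when the latter is positive
        table = self._simulate(1.0, 2.0, 100, 3, seed=4)
        est = heritability(table, "PRA", 35)
        wide = table.pivot_table(index="line", values="PRA", aggfunc=["mean"])
        grp = table.groupby("line")["PRA"]
        j = 3
        msb = j * grp.mean().var(ddof=1)
        msw = grp.var(ddof=1).mean()
        vg_mom = (msb - msw) / j
        assert est.vg == pytest.approx(vg_mom, rel=1e-3)
        assert est.ve == pytest.approx(msw, rel=1e-3)

    def test_h2_invariant_under_affine_rescaling(self):
        table = self._simulate(1.0, 3.0, 80, 3, seed=5)
        est1 = heritability(table, "PRA", 35)
        table2 = table.copy()
        table2["PRA"] = 100.0 + 7.0 * table2["PRA"]
        est2 = heritability(table2, "PRA", 35)
        assert est1.h2 == pytest.approx(est2.h2, rel=1e-6)

    def test_simulation_recovery_vg1_ve3(self):
        h2s = [
            heritability(self._simulate(1.0, 3.0, 485, 3, seed=s), "PRA", 35).h2
            for s in range(50)
        ]
        assert np.mean(h2s) == pytest.approx(0.25, abs=0.05)

    def test_mean_bias_below_0_05_across_vg_grid(self):
        # the heritability-recovery property at the study's sample size
        for vg in (0.25, 1.0, 4.0):
            expected = vg / (vg + 1.0)
            h2s = [
                heritability(
                    self._simulate(vg, 1.0, 485, 3, seed=s), "PRA", 35
                ).h2
                for s in range(50)
            ]
            assert abs(np.mean(h2s) - expected) < 0.05, vg

    def test_unbalanced_reml_against_statsmodels(self):
        # independent cross-check on unbalanced data: MixedLM REML
        import statsmodels.formula.api as smf

        table = self._simulate(2.0, 1.0, 60, 3, seed=9)
        table = table.drop(table.index[::7])  # unbalance group sizes
        est = heritability(table, "PRA", 35)
        md = smf.mixedlm("PRA ~ 1", table, groups=table["line"])
        fit = md.fit(reml=True)
        vg_sm = float(fit.cov_re.iloc[0, 0])
        ve_sm = float(fit.scale)
        assert est.vg == pytest.approx(vg_sm, rel=0.02, abs=0.02)
        assert est.ve == pytest.approx(ve_sm, rel=0.02)


class TestMorphospace:
    def _averaged(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n, 9))
        df = pd.DataFrame(data, columns=DESCRIPTOR_NAMES)
        df.insert(0, "das", 35)
        df.insert(0, "line", [f"l{i}" for i in range(n)])
        return df

    def test_eigenvalue_sum_is_trace(self):
        model = build_morphospace(self._averaged())
        assert model.eigenvalues.sum() == pytest.approx(9.0)
        assert model.variance_fractions.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        model = build_morphospace(self._averaged(seed=2))
        ld = model.loadings.to_numpy()
        np.testing.assert_allclose(ld.T @ ld, np.eye(9), atol=1e-10)

    def test_duplicated_descriptor_gives_eigenvalue_two(self):
        df = self._averaged(seed=3)
        df["PL"] = df["PRA"]  # perfectly correlated pair
        model = build_morphospace(df)
        assert model.eigenvalues[0] == pytest.approx(2.0, abs=0.3)
        assert model.eigenvalues[-1] == pytest.approx(0.0, abs=1e-8)

    def test_scores_have_zero_mean_and_eigenvalue_variance(self):
        model = build_morphospace(self._averaged(seed=4))
        scores = model.scores[model.component_names].to_numpy()
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), model.eigenvalues, rtol=0.05
        )

    def test_projection_idempotent_and_distance_preserving(self):
        df = self._averaged(seed=5)
        model = build_morphospace(df)
        proj = project_morphospace(model, df)
        np.testing.assert_allclose(
            proj[model.component_names].to_numpy(),
            model.scores[model.component_names].to_numpy(),
            atol=1e-10,
        )
        z = (df[list(DESCRIPTOR_NAMES)].to_numpy() - model.means) / model.sds
        d_z = np.linalg.norm(z[0] - z[1])
        s = proj[model.component_names].to_numpy()
        assert np.linalg.norm(s[0] - s[1]) == pytest.approx(d_z, rel=1e-8)

    def test_mean_row_projects_to_origin(self):
        df = self._averaged(seed=6)
        model = build_morphospace(df)
        mean_row = pd.DataFrame([dict(zip(DESCRIPTOR_NAMES, model.means))])
        proj = project_morphospace(model, mean_row)
        np.testing.assert_allclose(
            proj[model.component_names].to_numpy(), 0.0, atol=1e-10
        )

    def test_zero_variance_descriptor_named_in_error(self):
        df = self._averaged(seed=7)
        df["RMS"] = 1.0
        with pytest.raises(ValueError, match="RMS"):
            build_morphospace(df)

    def test_sign_convention_dominant_loading_positive(self):
        model = build_morphospace(self._averaged(seed=8))
        ld = model.loadings.to_numpy()
        for j in range(ld.shape[1]):
            assert ld[np.argmax(np.abs(ld[:, j])), j] > 0
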
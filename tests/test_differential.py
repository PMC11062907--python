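import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trainstates.core import FeatureMatrix
from trainstates.differential import (
    bh_qvalues,
    fold_change_band_fraction,
    normalize,
    permutation_selection_counts,
    select_training_regulated,
    timewise_stats,
    training_pvalue,
)
from trainstates.synthgen import SynthConfig, generate_study

from conftest import build_design, build_matrix


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_continuous_passes_through(self, toy_design):
        matrix = build_matrix(toy_design)
        norm = normalize(matrix)
        assert norm.data.equals(matrix.data)
        assert norm.zero_variance == ()

    def test_counts_cpm_formula(self):
        """A count of 1024 in a library of 10^6 maps to log2(1024.5)."""
        design = build_design(n_per_group=2, ome="rna")
        samples = design.for_matrix("muscle", "rna").index
        data = pd.DataFrame(
            {s: [1024.0, 1_000_000.0 - 1024.0] for s in samples},
            index=["hit", "rest"],
        )
        matrix = FeatureMatrix(data, "muscle", "rna", kind="counts", log_scale=False)
        norm = normalize(matrix)
        assert norm.data.loc["hit"].iloc[0] == pytest.approx(math.log2(1024.5))
        assert norm.kind == "continuous" and norm.log_scale

    def test_zero_variance_flagged_and_excluded_from_testing(self, toy_design):
        matrix = build_matrix(toy_design, n_features=20)
        matrix.data.iloc[0] = 5.0  # constant feature
        norm = normalize(matrix)
        assert norm.zero_variance == (matrix.feature_ids[0],)
        tw = timewise_stats(norm, toy_design)
        assert matrix.feature_ids[0] not in set(tw["feature"])

    @pytest.mark.parametrize("bad", [-1.0, 2.5])
    def test_invalid_counts_rejected(self, toy_design, bad):
        design = build_design(n_per_group=2, ome="rna")
        samples = design.for_matrix("muscle", "rna").index
        data = pd.DataFrame({s: [bad, 10.0] for s in samples}, index=["a", "b"])
        matrix = FeatureMatrix(data, "muscle", "rna", kind="counts", log_scale=False)
        with pytest.raises(ValueError):
            normalize(matrix)


# ---------------------------------------------------------------------------
# timewise statistics
# ---------------------------------------------------------------------------

class TestTimewise:
    def test_eight_cells_per_feature(self, toy_design):
        tw = timewise_stats(build_matrix(toy_design), toy_design)
        assert (tw.groupby("feature").size() == 8).all()
        assert ((tw["p"] > 0) & (tw["p"] <= 1)).all()
        assert (tw["SE"] > 0).all()

    def test_constant_feature_zero_logfc_and_z(self, toy_design):
        matrix = build_matrix(toy_design, n_features=30)
        matrix.data.iloc[0] = 7.0
        tw = timewise_stats(matrix, toy_design)  # moderation supplies the SE
        sub = tw[tw["feature"] == matrix.feature_ids[0]]
        assert (sub["logFC"] == 0).all() and (sub["z"] == 0).all()

    def test_mean_shift_recovered_exactly(self, toy_design):
        matrix = build_matrix(toy_design, n_features=10, seed=4)
        base = timewise_stats(matrix, toy_design)
        meta = toy_design.for_matrix("muscle", "metabolomics")
        cols = meta.index[(meta["sex"] == "M") & (meta["group"] == "8w")]
        shifted = matrix.data.copy()
        shifted.loc[shifted.index[0], cols] += 1.0
        tw = timewise_stats(
            FeatureMatrix(shifted, "muscle", "metabolomics"), toy_design
        )
        fid = matrix.feature_ids[0]
        target = (tw["feature"] == fid) & (tw["sex"] == "M") & (tw["time"] == 8)
        before = base.loc[
            (base["feature"] == fid) & (base["sex"] == "M") & (base["time"] == 8),
            "logFC",
        ].iloc[0]
        assert tw.loc[target, "logFC"].iloc[0] == pytest.approx(before + 1.0)
        other = (tw["feature"] == fid) & ~target
        assert np.allclose(
            tw.loc[other, "logFC"].to_numpy(),
            base.loc[
                (base["feature"] == fid)
                & ~((base["sex"] == "M") & (base["time"] == 8)),
                "logFC",
            ].to_numpy(),
        )

    def test_unmoderated_t_equals_classical_two_sample_t(self):
        """prior_df=0 on a 6 vs 6 toy matches the pooled two-sample t."""
        design = build_design(n_per_group=6, sexes=("F",), groups=("control", "8w"))
        matrix = build_matrix(design, n_features=25, seed=8)
        tw = timewise_stats(matrix, design, prior_df=0)
        meta = design.for_matrix("muscle", "metabolomics")
        ctrl_cols = meta.index[meta["group"] == "control"]
        trt_cols = meta.index[meta["group"] == "8w"]
        for fid in matrix.feature_ids:
            x = matrix.data.loc[fid, trt_cols].to_numpy()
            y = matrix.data.loc[fid, ctrl_cols].to_numpy()
            # brute-force pooled two-sample t
            sp2 = ((x.var(ddof=1) * 5) + (y.var(ddof=1) * 5)) / 10
            t_direct = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 6 + 1 / 6))
            row = tw[(tw["feature"] == fid) & (tw["time"] == 8)]
            assert row["z"].iloc[0] == pytest.approx(t_direct, abs=1e-10)
            t_scipy = stats.ttest_ind(x, y, equal_var=True)
            assert row["z"].iloc[0] == pytest.approx(t_scipy.statistic, abs=1e-10)
            assert row["p"].iloc[0] == pytest.approx(t_scipy.pvalue, abs=1e-10)

    def test_zero_variance_without_moderation_errors(self, toy_design):
        matrix = build_matrix(toy_design, n_features=5)
        matrix.data.iloc[0] = 1.0
        with pytest.raises(ValueError, match="moderation disabled"):
            timewise_stats(matrix, toy_design, prior_df=0)

    def test_undersized_cell_errors(self):
        full = build_design(n_per_group=2)
        thin = build_matrix(full)
        # leave a single sample in the (F, 4w) cell
        keep = [c for c in thin.data.columns if not c.startswith("F_4w")] + ["F_4w_r1"]
        thin = FeatureMatrix(thin.data[keep], "muscle", "metabolomics")
        with pytest.raises(ValueError, match="fewer than 2"):
            timewise_stats(thin, full)

    def test_missing_control_errors(self):
        full = build_design(n_per_group=2)
        matrix = build_matrix(full)
        no_ctrl = [c for c in matrix.data.columns if not c.startswith("F_control")]
        broken = FeatureMatrix(matrix.data[no_ctrl], "muscle", "metabolomics")
        with pytest.raises(ValueError, match="control"):
            timewise_stats(broken, full)


# ---------------------------------------------------------------------------
# training p-value
# ---------------------------------------------------------------------------

class TestTrainingPvalue:
    def test_null_pvalues_uniform(self):
        cfg = SynthConfig(
            n_features=2000,
            frac_null=1.0,
            omes=(("met", "continuous"),),
            tissues=("liver",),
            seed=23,
        )
        study = generate_study(cfg)
        p, _ = training_pvalue(study.matrices[("liver", "met")], study.design)
        ks = stats.kstest(p.to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_strong_signal_is_detected(self, toy_design):
        design = build_design(n_per_group=6)
        matrix = build_matrix(design, n_features=50, noise_sd=1.0, seed=2)
        meta = design.for_matrix("muscle", "metabolomics")
        trained = meta.index[meta["group"] != "control"]
        matrix.data.loc[matrix.feature_ids[0], trained] += 5.0
        p, _ = training_pvalue(matrix, design)
        assert p[matrix.feature_ids[0]] < 1e-6

    def test_constant_feature_excluded_with_reason(self, toy_design):
        matrix = build_matrix(toy_design, n_features=20)
        matrix.data.iloc[0] = 3.0
        p, excluded = training_pvalue(matrix, toy_design)
        fid = matrix.feature_ids[0]
        assert fid not in p.index
        assert excluded[fid] == "constant across all samples"


# ---------------------------------------------------------------------------
# BH selection
# ---------------------------------------------------------------------------

class TestSelection:
    def test_bh_hand_example(self):
        p = pd.Series([0.001, 0.02, 0.9], index=["a", "b", "c"])
        out = select_training_regulated(p, fdr=0.05)
        assert np.allclose(out["q"], [0.003, 0.03, 0.9])
        assert out["selected"].tolist() == [True, True, False]

    def test_all_ones_selects_nothing(self):
        out = select_training_regulated(pd.Series([1.0] * 5), fdr=0.05)
        assert not out["selected"].any()

    def test_raising_fdr_never_shrinks_selection(self):
        rng = np.random.default_rng(0)
        p = pd.Series(rng.uniform(size=200) ** 2)
        previous: set[int] = set()
        for fdr in (0.01, 0.05, 0.1, 0.2, 0.5):
            chosen = set(
                select_training_regulated(p, fdr=fdr).query("selected").index
            )
            assert previous <= chosen
            previous = chosen

    @pytest.mark.parametrize("bad_p", [[0.0, 0.5], [0.5, 1.2], []])
    def test_invalid_pvalues_rejected(self, bad_p):
        with pytest.raises(ValueError):
            bh_qvalues(np.array(bad_p))


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------

class TestPermutation:
    def test_fixed_seed_reproducible(self, small_study):
        matrix = small_study.matrices[("liver", "metabolomics")]
        a = permutation_selection_counts(
            matrix, small_study.design, mode="group", n_perm=5, seed=7
        )
        b = permutation_selection_counts(
            matrix, small_study.design, mode="group", n_perm=5, seed=7
        )
        assert np.array_equal(a.permuted, b.permuted)
        assert a.observed == b.observed

    def test_signal_beats_group_permutations(self, small_study):
        matrix = small_study.matrices[("liver", "metabolomics")]
        result = permutation_selection_counts(
            matrix, small_study.design, mode="group", n_perm=20, seed=1
        )
        assert result.observed > 0
        assert (result.permuted < result.observed).mean() >= 0.95

    @pytest.mark.parametrize("kwargs", [dict(n_perm=0), dict(mode="tissue")])
    def test_invalid_arguments(self, small_study, kwargs):
        matrix = small_study.matrices[("liver", "metabolomics")]
        with pytest.raises(ValueError):
            permutation_selection_counts(
                matrix, small_study.design, **{"mode": "group", "n_perm": 5, **kwargs}
            )


# ---------------------------------------------------------------------------
# fold-change band
# ---------------------------------------------------------------------------

class TestFoldChangeBand:
    @staticmethod
    def _timewise_from_logfc(per_feature: dict[str, list[float]]) -> pd.DataFrame:
        rows = []
        for fid, logfcs in per_feature.items():
            for i, value in enumerate(logfcs):
                rows.append(
                    {"feature": fid, "sex": "F", "time": (1, 2, 4, 8)[i % 4],
                     "logFC": value, "SE": 1.0, "z": value, "p": 0.5}
                )
        return pd.DataFrame(rows)

    def test_all_zero_logfc_inside_band(self):
        tw = self._timewise_from_logfc({"a": [0.0] * 4})
        assert fold_change_band_fraction(tw, {"a"}) == 1.0

    def test_twofold_feature_outside_band(self):
        tw = self._timewise_from_logfc({"a": [0.1, 1.0, 0.2, 0.0]})
        assert fold_change_band_fraction(tw, {"a"}) == 0.0

    def test_mixed_fractions(self):
        tw = self._timewise_from_logfc(
            {
                "a": [math.log2(0.5), 0.0, 0.0, 0.0],
                "b": [math.log2(1.2), 0.0, 0.0, 0.0],
                "c": [-math.log2(1.49), 0.0, 0.0, 0.0],
            }
        )
        assert fold_change_band_fraction(tw, {"a", "b", "c"}) == pytest.approx(2 / 3)

    def test_empty_selection_rejected(self):
        tw = self._timewise_from_logfc({"a": [0.0] * 4})
        with pytest.raises(ValueError):
            fold_change_band_fraction(tw, set())


def test_null_z_scores_are_standard_normal():
    """Null-feature z-scores downstream of moderation behave as N(0,1)."""
    pvals = []
    for seed in (31, 32, 33):
        cfg = SynthConfig(
            n_features=1500,
            frac_null=1.0,
            omes=(("met", "continuous"),),
            tissues=("liver",),
            seed=seed,
        )
        study = generate_study(cfg)
        tw = timewise_stats(study.matrices[("liver", "met")], study.design)
        z = tw[(tw["sex"] == "F") & (tw["time"] == 8)]["z"].to_numpy()
        pvals.append(stats.kstest(z, "norm").pvalue)
    assert np.mean(pvals) > 0.01
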
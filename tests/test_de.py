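"""Unit and property tests for the dual-allele DE consistency pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curlquant.de import (
    CountExperiment,
    CpmMatrix,
    DeConfig,
    ValidationError,
    bh_rank_cutoff,
    build_design_matrix,
    compute_cpm,
    filter_low_expression,
    fit_consistency_glm,
    run_de_pipeline,
    select_reliable_replicates,
    shortlist_by_fold_change,
)
from curlquant.synthetic import CountSimConfig, simulate_counts


def _experiment_from_matrix(counts: np.ndarray) -> CountExperiment:
    """Wrap a raw matrix in a minimal valid 2-allele x 2-phenotype design."""
    n_genes, n_samples = counts.shape
    assert n_samples % 4 == 0
    reps = n_samples // 4
    cols, rows = [], []
    i = 0
    for allele in ("icm13", "icm15"):
        for phen in ("straight", "curled"):
            for r in range(1, reps + 1):
                cols.append(f"{allele}_{phen}_r{r}")
                rows.append({"sample": cols[-1], "allele": allele, "phenotype": phen, "replicate": r})
                i += 1
    return CountExperiment(
        counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=cols),
        sheet=pd.DataFrame(rows).set_index("sample"),
    )


# --- CPM ------------------------------------------------------------------


class TestComputeCpm:
    def test_forced_arithmetic(self):
        counts = np.tile([[5], [10], [985]], (1, 8))
        cpm = compute_cpm(_experiment_from_matrix(counts)).values
        np.testing.assert_allclose(cpm.iloc[:, 0], [5000, 10000, 985000])

    def test_zero_gene_row_stays_zero(self):
        counts = np.vstack([np.zeros((1, 8), dtype=int), np.full((3, 8), 7)])
        cpm = compute_cpm(_experiment_from_matrix(counts)).values
        assert (cpm.iloc[0] == 0).all()

    def test_scale_invariance_between_samples(self):
        x = np.array([[3], [9], [88]])
        counts = np.hstack([x, 2 * x] * 4)
        cpm = compute_cpm(_experiment_from_matrix(counts)).values
        np.testing.assert_allclose(cpm.iloc[:, 0], cpm.iloc[:, 1])

    def test_columns_sum_to_1e6(self, small_experiment):
        experiment, _ = small_experiment
        cpm = compute_cpm(experiment)
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_is_named(self):
        counts = np.full((3, 8), 5)
        counts[:, 1] = 0
        with pytest.raises(ValidationError, match="icm13_straight_r2"):
            compute_cpm(_experiment_from_matrix(counts))


# --- replicate reliability -------------------------------------------------


class TestSelectReliableReplicates:
    @staticmethod
    def _cpm_df(cols: dict[str, np.ndarray]) -> CpmMatrix:
        df = pd.DataFrame(cols, dtype=float)
        return CpmMatrix(df / df.sum(axis=0) * 1e6)

    def test_shuffled_outlier_dropped(self, rng):
        base = rng.uniform(1, 1000, size=300)
        shuffled = rng.permutation(base)
        cols = {}
        rows = []
        for allele in ("icm13", "icm15"):
            for phen in ("straight", "curled"):
                for r in (1, 2, 3):
                    s = f"{allele}_{phen}_r{r}"
                    bad = allele == "icm13" and phen == "straight" and r == 3
                    cols[s] = shuffled if bad else base
                    rows.append(
                        {"sample": s, "allele": allele, "phenotype": phen, "replicate": r}
                    )
        sheet = pd.DataFrame(rows).set_index("sample")
        sel = select_reliable_replicates(self._cpm_df(cols), sheet, k=2)
        assert sel.kept[("icm13", "straight")] == ["icm13_straight_r1", "icm13_straight_r2"]
        assert "icm13_straight_r3" in sel.dropped

    def test_k_equal_to_replicates_is_identity(self, small_experiment):
        experiment, _ = small_experiment
        sel = select_reliable_replicates(compute_cpm(experiment), experiment.sheet, k=3)
        assert sel.dropped == []
        assert sorted(sel.kept_samples) == sorted(experiment.samples)

    def test_k_too_large_errors(self, small_experiment):
        experiment, _ = small_experiment
        with pytest.raises(ValidationError, match="k=4"):
            select_reliable_replicates(compute_cpm(experiment), experiment.sheet, k=4)

    @pytest.mark.parametrize("seed", range(20))
    def test_pure_noise_replicate_always_ranked_last(self, seed):
        config = CountSimConfig(
            n_genes=500,
            seed=seed,
            unreliable_replicate=("icm15", "curled", 1),
            noise_inflation=2.0,
        )
        experiment, _ = simulate_counts(config)
        sel = select_reliable_replicates(compute_cpm(experiment), experiment.sheet, k=2)
        assert "icm15_curled_r1" in sel.dropped


# --- expression filter and fold-change shortlist ---------------------------


class TestFilterAndShortlist:
    def test_filter_boundaries(self):
        avg = pd.Series({"a": 0.99, "b": 1.0, "c": 5.0, "d": 0.0})
        kept = filter_low_expression(avg, threshold=1.0)
        assert set(kept) == {"b", "c"}

    def test_all_zero_gives_empty_and_pipeline_accepts(self):
        avg = pd.Series({"a": 0.0, "b": 0.0})
        assert len(filter_low_expression(avg)) == 0
        # a fully null, low-signal experiment flows through and returns a table
        counts = np.full((5, 12), 2)
        report = run_de_pipeline(_experiment_from_matrix(counts))
        assert report.table["selected"].sum() == 0

    @pytest.mark.parametrize(
        "fc, expected",
        [(0.70, "down"), (0.75, "down"), (1.00, "none"), (1.44, "none"), (1.45, "up")],
    )
    def test_direction_thresholds(self, fc, expected):
        straight = pd.Series({"g": 10.0})
        curled = pd.Series({"g": 10.0 * fc})
        table = shortlist_by_fold_change(straight, curled)
        assert table.loc["g", "direction"] == expected


# --- design matrix ---------------------------------------------------------


def _rank_by_gaussian_elimination(matrix: np.ndarray) -> int:
    """Independent rank oracle: row-reduce with partial pivoting."""
    m = matrix.astype(float).copy()
    rank = 0
    for col in range(m.shape[1]):
        pivots = np.abs(m[rank:, col])
        if pivots.size == 0 or pivots.max() < 1e-12:
            continue
        pivot_row = rank + int(pivots.argmax())
        m[[rank, pivot_row]] = m[[pivot_row, rank]]
        m[rank] /= m[rank, col]
        for r in range(m.shape[0]):
            if r != rank:
                m[r] -= m[r, col] * m[rank]
        rank += 1
        if rank == m.shape[0]:
            break
    return rank


class TestDesignMatrix:
    def test_full_design_is_rank_3(self, small_experiment):
        experiment, _ = small_experiment
        design = build_design_matrix(experiment.sheet)
        assert design.matrix.shape == (12, 4)
        assert design.rank == 3 == _rank_by_gaussian_elimination(design.matrix)

    def test_single_allele_flags_degenerate_warning(self, small_experiment):
        experiment, _ = small_experiment
        sheet = experiment.sheet[experiment.sheet["allele"] == "icm13"]
        design = build_design_matrix(sheet)
        assert any("single allele" in w for w in design.warnings)

    def test_missing_phenotype_errors(self, small_experiment):
        experiment, _ = small_experiment
        sheet = experiment.sheet[experiment.sheet["phenotype"] == "straight"]
        with pytest.raises(ValidationError, match="curled"):
            build_design_matrix(sheet)

    def test_row_permutation_leaves_statistics_unchanged(self, small_experiment):
        experiment, _ = small_experiment
        cpm = compute_cpm(experiment).values
        d1 = build_design_matrix(experiment.sheet)
        perm = np.random.default_rng(0).permutation(len(experiment.sheet))
        sheet2 = experiment.sheet.iloc[perm]
        d2 = build_design_matrix(sheet2)
        g1 = fit_consistency_glm(cpm, d1)
        g2 = fit_consistency_glm(cpm, d2)
        pd.testing.assert_frame_equal(g1, g2)


# --- GLM -------------------------------------------------------------------


def _glm_oracle(y: np.ndarray, sheet: pd.DataFrame):
    """Normal-equations oracle on a reduced full-rank parameterization.

    Columns: intercept, curled indicator, one dummy per non-reference
    allele. The curled coefficient is the curled - straight contrast.
    Solved by explicit matrix inversion.
    """
    from scipy import stats

    alleles = sorted(sheet["allele"].unique())
    X = np.column_stack(
        [np.ones(len(sheet)), (sheet["phenotype"] == "curled").to_numpy(float)]
        + [(sheet["allele"] == a).to_numpy(float) for a in alleles[1:]]
    )
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ y
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * xtx_inv[1, 1])
    t = coef[1] / se
    return coef[1], se, t, 2 * stats.t.sf(abs(t), df), df


class TestConsistencyGlm:
    def test_matches_normal_equations_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            reps = int(rng.integers(2, 6))  # up to 20 samples
            n = 4 * reps
            counts = rng.integers(1, 2000, size=(6, n))
            experiment = _experiment_from_matrix(counts)
            cpm = compute_cpm(experiment).values
            design = build_design_matrix(experiment.sheet)
            fit = fit_consistency_glm(cpm, design)
            Y = np.log2(cpm.to_numpy(float) + 0.5)
            for i, gene in enumerate(cpm.index):
                beta, se, t, p, df = _glm_oracle(Y[i], experiment.sheet)
                assert fit.loc[gene, "beta"] == pytest.approx(beta, abs=1e-10)
                assert fit.loc[gene, "se"] == pytest.approx(se, abs=1e-10)
                assert fit.loc[gene, "t"] == pytest.approx(t, abs=1e-8)
                assert fit.loc[gene, "p"] == pytest.approx(p, abs=1e-10)
                assert fit.loc[gene, "df"] == df

    def test_exact_group_shift_is_degenerate_with_beta(self, small_experiment):
        experiment, _ = small_experiment
        design = build_design_matrix(experiment.sheet)
        curled = (experiment.sheet["phenotype"] == "curled").to_numpy(float)
        # log2 cpm exactly 2 lower in curled samples of both alleles
        log2_vals = 8.0 - 2.0 * curled
        cpm = pd.DataFrame(
            2.0 ** log2_vals[None, :] - 0.5,
            index=["g"],
            columns=experiment.sheet.index,
        )
        fit = fit_consistency_glm(cpm, design)
        assert fit.loc["g", "beta"] == pytest.approx(-2.0, abs=1e-12)
        assert fit.loc["g", "flag"] == "degenerate_fit"
        assert fit.loc["g", "p"] == 0.0

    def test_constant_gene_gets_p_one(self, small_experiment):
        experiment, _ = small_experiment
        design = build_design_matrix(experiment.sheet)
        cpm = pd.DataFrame(
            np.full((1, 12), 100.0), index=["g"], columns=experiment.sheet.index
        )
        fit = fit_consistency_glm(cpm, design)
        assert fit.loc["g", "beta"] == pytest.approx(0.0, abs=1e-12)
        assert fit.loc["g", "p"] == 1.0
        assert fit.loc["g", "flag"] == "constant"


# --- BH rank rule ----------------------------------------------------------


def _bh_oracle(pvals: list[float], q: float) -> list[bool]:
    """Direct enumeration of the stop-at-first-exceedance rank rule."""
    order = sorted(range(len(pvals)), key=lambda i: (pvals[i], i))
    n = len(pvals)
    cutoff = n + 1
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] > rank / n * q:
            cutoff = rank
            break
    selected = [False] * n
    for rank, idx in enumerate(order, start=1):
        selected[idx] = rank < cutoff
    return [selected[i] for i in order]


class TestBhRankCutoff:
    def test_worked_example(self):
        sel = bh_rank_cutoff(pd.Series([0.01, 0.15, 0.5], index=list("abc")), q=0.2)
        np.testing.assert_allclose(sel["criterion"], [0.2 / 3, 0.4 / 3, 0.2])
        assert sel["selected"].tolist() == [True, False, False]

    def test_all_zero_selected_all_one_selected_none(self):
        assert bh_rank_cutoff(pd.Series([0.0] * 5))["selected"].all()
        assert not bh_rank_cutoff(pd.Series([1.0] * 5))["selected"].any()

    def test_empty_input(self):
        assert len(bh_rank_cutoff(pd.Series([], dtype=float))) == 0

    def test_matches_enumeration_on_grid_vectors(self):
        grid = [0.0, 0.02, 0.05, 0.1, 0.21, 0.5, 1.0]
        rng = np.random.default_rng(5)
        for _ in range(400):
            length = int(rng.integers(1, 7))
            pv = [grid[i] for i in rng.integers(0, len(grid), size=length)]
            sel = bh_rank_cutoff(pd.Series(pv, index=[f"g{i}" for i in range(length)]))
            assert sel["selected"].tolist() == _bh_oracle(pv, 0.2)

    @settings(derandomize=True, max_examples=100)
    @given(
        pvals=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=12),
        idx=st.integers(min_value=0, max_value=11),
    )
    def test_selection_is_monotone_in_p(self, pvals, idx):
        """Decreasing any selected gene's p-value never deselects it."""
        idx = idx % len(pvals)
        names = [f"g{i}" for i in range(len(pvals))]
        before = bh_rank_cutoff(pd.Series(pvals, index=names))
        if not before.loc[names[idx], "selected"]:
            return
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2
        after = bh_rank_cutoff(pd.Series(lowered, index=names))
        assert after.loc[names[idx], "selected"]


# --- pipeline --------------------------------------------------------------


class TestPipeline:
    def test_planted_down_genes_dominate_selected_list(self, small_experiment):
        experiment, truth = small_experiment
        report = run_de_pipeline(experiment)
        planted = truth.index[truth["gene_class"] == "shared_down"]
        selected_down = report.table.index[
            (report.table["direction"] == "down") & report.table["selected"]
        ]
        assert len(set(planted) & set(selected_down)) >= 4  # of 5 planted

    def test_report_has_per_allele_columns_and_prefix_selection(self, small_experiment):
        experiment, _ = small_experiment
        table = run_de_pipeline(experiment).table
        assert {"fc_icm13", "fc_icm15", "fc_mean", "rank", "criterion", "selected"} <= set(
            table.columns
        )
        for direction in ("down", "up"):
            sub = table[table["direction"] == direction].sort_values("rank")
            if len(sub):
                sel = sub["selected"].to_numpy()
                # selected set is a prefix of the rank-sorted list
                assert not (~sel[:-1] & sel[1:]).any()

    def test_gene_and_sample_permutation_invariance(self, small_experiment):
        experiment, _ = small_experiment
        rng = np.random.default_rng(9)
        counts2 = experiment.counts.iloc[
            rng.permutation(len(experiment.counts)),
            rng.permutation(experiment.counts.shape[1]),
        ]
        experiment2 = CountExperiment(counts=counts2, sheet=experiment.sheet.copy())
        t1 = run_de_pipeline(experiment).table
        t2 = run_de_pipeline(experiment2).table
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_zero_dispersion_round_trip_recovers_planted_fc(self):
        """Noise-free counts recover the planted 4-fold decrease.

        Counts are compositional (a library has a fixed read total), so
        the recovery is exact only up to the planted genes' library mass
        fraction; with 5 planted genes among 2000 that footprint is a few
        tenths of a percent.
        """
        config = CountSimConfig(
            n_genes=2000,
            n_shared_down=5,
            shared_log2fc_down=-2.0,
            dispersion=0.0,
            allele_batch_sd=0.0,
            baseline_log2_mean_range=(4.0, 9.0),
            library_size_range=(30_000_000, 30_000_000),
            seed=0,
        )
        experiment, truth = simulate_counts(config)
        planted = truth.index[truth["gene_class"] == "shared_down"]
        report = run_de_pipeline(experiment)
        fc = report.table.loc[planted, "fc_mean"]
        np.testing.assert_allclose(fc, 0.25, rtol=5e-3)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            DeConfig(q=0.0).validate()
        with pytest.raises(ValidationError):
            DeConfig(fc_down=2.0, fc_up=1.0).validate()
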
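import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ciber import (
    SimulationConfig,
    ValidationError,
    compute_fold_changes,
    compute_re,
    fit_line,
    gene_score,
    score_screen,
    simulate_screen,
    z_normalize,
)
from _oracle import ols, score_screen_oracle

ROLES = {"cells_plus": "cp", "cells_minus": "cm", "sevs_plus": "sp", "sevs_minus": "sm"}


def nrc_frame(rows):
    return pd.DataFrame(rows, columns=["cp", "cm", "sp", "sm"], index=[f"b{i}" for i in range(len(rows))], dtype=float)


def guide_frame(genes, fc_cells, fc_sevs):
    return pd.DataFrame(
        {
            "barcode_id": [f"b{i}" for i in range(len(genes))],
            "gene": genes,
            "sublibrary": "L",
            "fc_cells": fc_cells,
            "fc_sevs": fc_sevs,
        }
    )


class TestFoldChanges:
    @pytest.mark.parametrize(
        "quad, expected",
        [
            ((2, 1, 4, 1), (1, 2)),
            ((3, 3, 3, 3), (0, 0)),
            ((0.5, 1, 1, 1), (-1, 0)),
        ],
    )
    def test_log2_ratios(self, quad, expected):
        out = compute_fold_changes(nrc_frame([quad]), ROLES)
        assert out.iloc[0].tolist() == pytest.approx(expected)

    def test_nonpositive_nrc_is_an_error(self):
        with pytest.raises(ValidationError, match="nonpositive"):
            compute_fold_changes(nrc_frame([(0.0, 1, 1, 1)]), ROLES)


class TestFitLine:
    def test_exact_line(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        fit = fit_line(x, 2 * x + 1)
        assert (fit.slope, fit.intercept, fit.r) == pytest.approx((2, 1, 1))

    def test_symmetric_cross_has_zero_slope_and_r(self):
        fit = fit_line([-1, 1, 0, 0], [0, 0, 1, -1])
        assert (fit.slope, fit.intercept, fit.r) == pytest.approx((0, 0, 0))

    def test_matches_normal_equations_on_random_points(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        fit = fit_line(x, y)
        slope, intercept = ols(list(zip(x, y)))
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_degenerate_x_is_an_error(self):
        with pytest.raises(ValidationError, match="distinct"):
            fit_line([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestComputeRe:
    def test_collinear_guides_have_zero_re_in_both_passes(self):
        x = np.linspace(-2, 2, 12)
        guides = guide_frame(["G1"] * 4 + ["G2"] * 4 + ["G3"] * 4, x, 1.5 * x - 0.5)
        out, fit1, fit2 = compute_re(guides)
        assert out["re"].abs().max() < 1e-12
        assert fit1.slope == pytest.approx(1.5)
        assert fit2.slope == pytest.approx(1.5)

    def test_offset_gene_recovers_its_shift(self):
        rng = np.random.default_rng(0)
        genes, xs, ys = [], [], []
        for g in range(20):  # null genes exactly on y = x
            for i in range(5):
                genes.append(f"N{g}")
                x = rng.normal()
                xs.append(x)
                ys.append(x)
        for i in range(5):  # one gene offset by +1
            genes.append("HIT")
            x = rng.normal()
            xs.append(x)
            ys.append(x + 1.0)
        out, _, _ = compute_re(guide_frame(genes, xs, ys))
        hit_re = out.loc[out["gene"] == "HIT", "re"]
        null_re = out.loc[out["gene"] != "HIT", "re"]
        # the single offset gene drags the fit intercept up by ~1/21, so the
        # recovered shift is 1 minus that leakage and nulls sit just below 0
        assert hit_re.mean() == pytest.approx(1.0, abs=0.1)
        assert abs(null_re.mean()) < 0.1

    def test_three_guide_gene_trims_extremes_but_scores_all(self):
        # background genes with three collinear guides each pin the line at y = x
        genes = list(np.repeat([f"N{i}" for i in range(5)], 3)) + ["G"] * 3
        base = list(np.linspace(-1, 1, 15))
        x = base + [0.0, 0.5, 1.0]
        y = base + [0.4, 0.5, 0.2]
        out, _, fit2 = compute_re(guide_frame(genes, x, y))
        assert (fit2.slope, fit2.intercept) == pytest.approx((1, 0))
        g = out[out["gene"] == "G"]
        assert g["trimmed"].tolist() == [True, False, True]  # max (+0.4 resid) and min (-0.8)
        assert g["re"].tolist() == pytest.approx([0.4, 0.0, -0.8])

    def test_pass2_residuals_sum_to_zero_over_untrimmed(self):
        rng = np.random.default_rng(5)
        genes = np.repeat([f"G{i}" for i in range(30)], 5)
        x = rng.normal(size=150)
        y = x + rng.normal(scale=0.3, size=150)
        out, _, _ = compute_re(guide_frame(genes, x, y))
        assert out.loc[~out["trimmed"], "re"].sum() == pytest.approx(0, abs=1e-9)

    def test_single_guide_gene_is_trimmed_once(self):
        genes = list(np.repeat([f"N{i}" for i in range(3)], 3)) + ["SOLO"]
        base = list(np.linspace(-1, 1, 9))
        x = base + [0.3]
        y = base + [0.9]
        out, _, _ = compute_re(guide_frame(genes, x, y))
        solo = out[out["gene"] == "SOLO"]
        assert int(solo["trimmed"].sum()) == 1  # the guide is both max and min
        assert int(out["trimmed"].sum()) == 3 * 2 + 1
        assert solo["re"].notna().all()


class TestGeneScore:
    @pytest.mark.parametrize(
        "res, expected",
        [([1, 2, 10], 2), ([1, 2, 3, 4], 2.5), ([5], 5)],
    )
    def test_median_conventions(self, res, expected):
        guides = pd.DataFrame(
            {
                "gene": "G",
                "sublibrary": "L",
                "re": res,
                "trimmed": [False] * len(res),
            }
        )
        out = gene_score(guides)
        assert out["re_gene"].iloc[0] == pytest.approx(expected)
        assert out["n_guides"].iloc[0] == len(res)

    def test_trimmed_guides_enter_median_by_default_only(self):
        guides = pd.DataFrame(
            {
                "gene": "G",
                "sublibrary": "L",
                "re": [0.0, 1.0, 10.0],
                "trimmed": [True, False, True],
            }
        )
        assert gene_score(guides)["re_gene"].iloc[0] == 1.0
        strict = gene_score(guides, include_trimmed=False)
        assert strict["re_gene"].iloc[0] == 1.0
        assert strict["n_guides"].iloc[0] == 3  # count reports all retained guides


class TestZNormalize:
    def frame(self, scores, sublibrary="L"):
        return pd.DataFrame({"gene": [f"g{i}" for i in range(len(scores))], "sublibrary": sublibrary, "re_gene": scores, "n_guides": 3})

    def test_sample_sd_convention(self):
        out = z_normalize(self.frame([-1.0, 0.0, 1.0]))
        assert out["z_re"].tolist() == pytest.approx([-1, 0, 1])

    def test_location_invariance(self):
        base = z_normalize(self.frame([0.3, -0.2, 0.9, 1.4]))["z_re"]
        shifted = z_normalize(self.frame([x + 5 for x in [0.3, -0.2, 0.9, 1.4]]))["z_re"]
        assert shifted.tolist() == pytest.approx(base.tolist())

    def test_mean_zero_sd_one_within_sublibrary(self):
        rng = np.random.default_rng(2)
        frame = pd.concat([self.frame(rng.normal(size=40).tolist(), "A"), self.frame(rng.normal(2, 3, size=25).tolist(), "B")], ignore_index=True)
        out = z_normalize(frame)
        for _, group in out.groupby("sublibrary"):
            assert group["z_re"].mean() == pytest.approx(0, abs=1e-9)
            assert group["z_re"].std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_normal_scores_put_five_percent_above_165(self):
        rng = np.random.default_rng(3)
        out = z_normalize(self.frame(rng.normal(size=100_000).tolist()))
        assert (out["z_re"] > 1.645).mean() == pytest.approx(0.05, abs=0.005)

    def test_zero_sd_is_an_error(self):
        with pytest.raises(ValidationError, match="zero RE variance"):
            z_normalize(self.frame([1.0, 1.0, 1.0]))

    def test_population_sd_flag(self):
        out = z_normalize(self.frame([-1.0, 0.0, 1.0]), ddof=0)
        sd_pop = np.std([-1.0, 0.0, 1.0])
        assert out["z_re"].tolist() == pytest.approx([-1 / sd_pop, 0, 1 / sd_pop])


def as_oracle_inputs(screen):
    counts = {b: screen.counts.loc[b].to_dict() for b in screen.counts.index}
    gene_of = {r.barcode_id: r.gene for r in screen.reference}
    sublib_of = {r.barcode_id: r.sublibrary for r in screen.reference}
    sublib = screen.reference[0].sublibrary
    roles = {role: f"{sublib}_{role}" for role in ("cells_plus", "cells_minus", "sevs_plus", "sevs_minus")}
    return counts, gene_of, sublib_of, roles


class TestScoreScreen:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("include_trimmed", [True, False])
    def test_equivalence_with_brute_force_oracle(self, seed, include_trimmed):
        """Vectorized pipeline equals the literal step-by-step transcription."""
        config = SimulationConfig(
            n_genes=20, guides_per_gene=5, depth=200, seed=seed, frac_release_genes=0.2
        )
        screen = simulate_screen(config)
        result = score_screen(
            screen.counts,
            screen.manifest,
            screen.reference,
            include_trimmed_in_median=include_trimmed,
        )
        counts, gene_of, sublib_of, roles = as_oracle_inputs(screen)
        guide_rows, gene_rows = score_screen_oracle(
            counts, gene_of, sublib_of, roles, include_trimmed_in_median=include_trimmed
        )
        assert set(result.guides["barcode_id"]) == set(guide_rows)
        for row in result.guides.itertuples():
            oracle = guide_rows[row.barcode_id]
            assert row.fc_cells == pytest.approx(oracle["fc_cells"], abs=1e-9)
            assert row.fc_sevs == pytest.approx(oracle["fc_sevs"], abs=1e-9)
            assert row.re == pytest.approx(oracle["re"], abs=1e-9)
            assert row.trimmed == oracle["trimmed"]
        assert set(result.genes["gene"]) == set(gene_rows)
        for row in result.genes.itertuples():
            oracle = gene_rows[row.gene]
            assert row.re_gene == pytest.approx(oracle["re_gene"], abs=1e-9)
            assert row.z_re == pytest.approx(oracle["z_re"], abs=1e-9)
            assert row.n_guides == oracle["n_guides"]

    def test_depth_scaling_leaves_z_re_unchanged(self):
        screen = simulate_screen(SimulationConfig(n_genes=30, guides_per_gene=4, depth=300, seed=9))
        base = score_screen(screen.counts, screen.manifest, screen.reference)
        doubled = score_screen(screen.counts * 2, screen.manifest, screen.reference)
        pd.testing.assert_frame_equal(base.genes, doubled.genes)

    def test_barcode_order_invariance(self):
        screen = simulate_screen(SimulationConfig(n_genes=30, guides_per_gene=4, depth=300, seed=10))
        base = score_screen(screen.counts, screen.manifest, screen.reference)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(screen.counts))
        shuffled_counts = screen.counts.iloc[order]
        shuffled = score_screen(shuffled_counts, screen.manifest, screen.reference)
        merged = base.genes.merge(shuffled.genes, on="gene", suffixes=("_a", "_b"))
        assert merged["z_re_a"].to_numpy() == pytest.approx(merged["z_re_b"].to_numpy(), abs=1e-9)

    def test_perfectly_proportional_fold_changes_hit_zero_sd_path(self, small_reference, four_sample_manifest):
        # FC_sEVs = FC_cells exactly => all REs 0 => z undefined
        counts = pd.DataFrame(
            {
                "LIB1_cells_plus": np.arange(1, 10) * 100,
                "LIB1_cells_minus": [100] * 9,
                "LIB1_sevs_plus": np.arange(1, 10) * 100,
                "LIB1_sevs_minus": [100] * 9,
            },
            index=pd.Index([r.barcode_id for r in small_reference], name="barcode_id"),
        )
        with pytest.raises(ValidationError, match="zero RE variance"):
            score_screen(counts, four_sample_manifest, small_reference)

    def test_multi_sublibrary_z_normalization_is_per_pool(self):
        config = SimulationConfig(
            n_genes=40,
            guides_per_gene=4,
            depth=300,
            sublibraries={"POOLA": 20, "POOLB": 20},
            seed=4,
        )
        screen = simulate_screen(config)
        result = score_screen(screen.counts, screen.manifest, screen.reference)
        for _, group in result.genes.groupby("sublibrary"):
            assert group["z_re"].mean() == pytest.approx(0, abs=1e-9)
            assert group["z_re"].std(ddof=1) == pytest.approx(1, abs=1e-9)
        assert set(result.fits) == {"POOLA", "POOLB"}
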
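"""Imputation, differential testing, BH adjustment, and hit filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chipms import (
    ImputationParams,
    IntensityMatrix,
    ProteomicsSimSpec,
    bh_adjust,
    differential_test,
    filter_hits,
    impute_missing,
    simulate_intensity_matrix,
)
from chipms.ipms import fit_variance_prior


def make_matrix(values: np.ndarray, n_treat: int = 3) -> IntensityMatrix:
    n_samples = values.shape[1]
    samples = [f"t{i}" for i in range(n_treat)] + [f"c{i}" for i in range(n_samples - n_treat)]
    groups = {s: ("treatment" if s.startswith("t") else "control") for s in samples}
    df = pd.DataFrame(values, columns=samples, index=[f"P{i}" for i in range(values.shape[0])])
    return IntensityMatrix(values=df, groups=groups)


# ---------------------------------------------------------------------------
# imputation


def test_impute_complete_matrix_is_identity():
    m = make_matrix(np.arange(24, dtype=float).reshape(4, 6))
    out = impute_missing(m, ImputationParams(seed=0))
    assert out.values.equals(m.values)


def test_impute_defaults_are_downshift_1p8_width_0p8():
    p = ImputationParams()
    assert p.shift == 1.8 and p.width == 0.8 and p.scope == "per_sample"


def test_impute_preserves_observed_and_is_seed_reproducible():
    rng = np.random.default_rng(0)
    vals = rng.normal(20, 1, size=(30, 6))
    vals[rng.random(vals.shape) < 0.3] = np.nan
    m = make_matrix(vals)
    out1 = impute_missing(m, ImputationParams(seed=5))
    out2 = impute_missing(m, ImputationParams(seed=5))
    assert out1.values.equals(out2.values)
    obs = ~np.isnan(vals)
    assert np.array_equal(out1.values.to_numpy()[obs], vals[obs])
    assert not out1.values.isna().to_numpy().any()
    assert np.array_equal(out1.missing_mask.to_numpy(), ~obs)  # provenance kept


def test_impute_moments_match_downshifted_normal():
    """Column with observed mu=20, sigma=1: imputed draws have mean ~18.2
    (within 3 se) and sd within 5% of 0.8."""
    n_missing = 10_000
    observed = np.array([18.0, 19.0, 20.0, 21.0, 22.0])
    observed = (observed - observed.mean()) / observed.std(ddof=1) + 20.0  # mu=20, sd=1 exactly
    col = np.concatenate([observed, np.full(n_missing, np.nan)])
    other = np.full(col.size, 20.0)
    m = make_matrix(np.column_stack([col, other, other, other]), n_treat=2)
    out = impute_missing(m, ImputationParams(seed=123))
    imputed = out.values.iloc[observed.size :, 0].to_numpy()
    assert abs(imputed.mean() - 18.2) <= 3 * 0.8 / np.sqrt(n_missing)
    assert abs(imputed.std(ddof=1) - 0.8) <= 0.05 * 0.8


def test_impute_global_scope_uses_whole_matrix_moments():
    vals = np.full((10, 4), 10.0)
    vals[0, 0] = np.nan
    vals[1, 1] = 30.0  # makes global sigma nonzero
    m = make_matrix(vals, n_treat=2)
    out = impute_missing(m, ImputationParams(scope="global", seed=0))
    assert np.isfinite(out.values.iloc[0, 0])


def test_impute_errors_on_scope_with_too_few_observed():
    vals = np.full((3, 4), 20.0)
    vals[:, 0] = np.nan
    vals[0, 0] = 19.0  # only one observed value in the first column
    m = make_matrix(vals, n_treat=2)
    with pytest.raises(ValueError, match="t0"):
        impute_missing(m, ImputationParams(seed=0))


# ---------------------------------------------------------------------------
# differential test


def test_constant_protein_gives_zero_fc_and_p_one():
    vals = np.vstack([np.full(6, 20.0), np.random.default_rng(0).normal(20, 1, 6)])
    t = differential_test(make_matrix(vals), moderation="ordinary")
    assert t.loc["P0", "log2FC"] == 0.0
    assert t.loc["P0", "t"] == 0.0
    assert t.loc["P0", "p"] == 1.0


def test_ordinary_t_matches_textbook_pooled_formula():
    """3-vs-3 toy protein against the hand-computed pooled-variance t."""
    x = np.array([22.0, 23.0, 21.5])
    y = np.array([20.0, 19.5, 20.5])
    vals = np.vstack([np.concatenate([x, y]), np.random.default_rng(1).normal(20, 1, 6)])
    table = differential_test(make_matrix(vals), moderation="ordinary")
    sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
    t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    p_hand = 2 * stats.t.sf(abs(t_hand), 4)
    assert table.loc["P0", "log2FC"] == pytest.approx(x.mean() - y.mean())
    assert table.loc["P0", "t"] == pytest.approx(t_hand)
    assert table.loc["P0", "p"] == pytest.approx(p_hand)
    # and the scipy cross-check
    ref = stats.ttest_ind(x, y)
    assert table.loc["P0", "t"] == pytest.approx(ref.statistic)
    assert table.loc["P0", "p"] == pytest.approx(ref.pvalue)


def test_differential_requires_complete_matrix_and_group_sizes():
    vals = np.full((2, 6), 20.0)
    vals[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        differential_test(make_matrix(vals))
    with pytest.raises(ValueError, match="treatment"):
        differential_test(make_matrix(np.full((2, 3), 20.0), n_treat=1))


def test_moderated_converges_to_ordinary_when_prior_vanishes():
    rng = np.random.default_rng(2)
    vals = rng.normal(20, 1, size=(40, 6))
    m = make_matrix(vals)
    ordinary = differential_test(m, moderation="ordinary")
    s2 = ((vals[:, :3].var(axis=1, ddof=1) * 2) + (vals[:, 3:].var(axis=1, ddof=1) * 2)) / 4
    # direct check of the posterior formula at d0 -> 0: recovers s2
    s2_post = (4 * s2 + 0.0) / (4 + 0.0)
    assert np.allclose(s2_post, s2)
    # moderated t uses a shrunken variance: |t_mod| between 0 and a bounded
    # inflation of |t_ord| and p no more extreme on average for null proteins
    moderated = differential_test(m, moderation="moderated")
    assert (moderated["p"] >= 0).all() and (moderated["p"] <= 1).all()
    assert moderated["p"].mean() >= ordinary["p"].mean() - 0.05  # shrinkage sanity


def test_variance_prior_moment_fit_recovers_known_prior():
    """Variances drawn from the scaled-F marginal: MoM recovers (s0^2, d0)."""
    rng = np.random.default_rng(3)
    d, d0_true, s0_true = 4, 10.0, 0.25
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=60_000)
    s2 = sigma2 * rng.chisquare(d, size=60_000) / d
    s0_fit, d0_fit = fit_variance_prior(s2, d)
    assert s0_fit == pytest.approx(s0_true, rel=0.1)
    assert d0_fit == pytest.approx(d0_true, rel=0.25)


def test_planted_large_effects_all_significant():
    """log2FC=5 at sd=0.5: every planted hit reaches p < 0.05."""
    m, is_hit = simulate_intensity_matrix(
        ProteomicsSimSpec(effect_log2fc=5.0, within_group_sd=0.5, seed=4)
    )
    imputed = impute_missing(m, ImputationParams(seed=5))
    table = filter_hits(differential_test(imputed))
    assert (table["p"].to_numpy()[is_hit] < 0.05).all()


# ---------------------------------------------------------------------------
# BH adjustment and filtering


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        candidates = [p[j] * n / ranks[j] for j in range(n) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


def test_bh_single_value_and_hand_worked_vector():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@settings(max_examples=500, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_matches_brute_force_step_up(p_list):
    p = np.array(p_list)
    got = bh_adjust(p)
    expected = brute_force_bh(p)
    assert got == pytest.approx(expected)
    assert (got >= p - 1e-12).all()
    # permutation equivariance + statsmodels cross-check on the same vector
    perm = np.random.default_rng(0).permutation(len(p))
    assert bh_adjust(p[perm]) == pytest.approx(got[perm])


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    p = rng.random(200)
    assert bh_adjust(p) == pytest.approx(multipletests(p, method="fdr_bh")[1])


def test_filter_hits_defaults_and_strict_boundaries():
    table = pd.DataFrame(
        {
            "log2FC": [2.0, 2.1, 5.0, -3.0],
            "t": [1.0, 2.0, 8.0, -8.0],
            "p": [0.01, 0.04, 0.001, 0.001],
        },
        index=["boundary_fc", "ok", "strong", "depleted"],
    )
    out = filter_hits(table)
    assert list(out["hit"]) == [False, True, True, False]  # strict > and <
    assert (out["q"] >= out["p"] - 1e-15).all()
    empty = filter_hits(table.iloc[:0])
    assert len(empty) == 0 and "hit" in empty.columns


def test_filter_hits_legend_threshold_variant():
    """fold change > 50 on the natural scale == log2 threshold log2(50)."""
    table = pd.DataFrame({"log2FC": [5.0, 6.0], "t": [5, 5], "p": [0.01, 0.01]}, index=["a", "b"])
    out = filter_hits(table, fc_threshold=np.log2(50))
    assert list(out["hit"]) == [False, True]  # 2^5=32 < 50 < 2^6=64


def test_moderated_t_tracks_limma_ebayes(tmp_path):
    """Independent cross-check: our moderated t against limma's eBayes on
    the same matrix. The variance-prior fits differ (raw-variance moments
    here, log-variance moments in limma) so agreement is close but not
    exact: identical log2FC, highly correlated t and p ranks."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    m, _ = simulate_intensity_matrix(ProteomicsSimSpec(seed=5, n_proteins=200, n_hits=20))
    imp = impute_missing(m, ImputationParams(seed=6))
    mat = tmp_path / "mat.tsv"
    imp.values.to_csv(mat, sep="\t")
    script = tmp_path / "limma.R"
    out = tmp_path / "limma.tsv"
    script.write_text(
        "suppressMessages(library(limma))\n"
        f"x <- as.matrix(read.delim('{mat}', row.names=1))\n"
        "design <- cbind(Intercept=1, treat=c(1,1,1,0,0,0))\n"
        "fit <- eBayes(lmFit(x, design))\n"
        "out <- data.frame(t=fit$t[,'treat'], p=fit$p.value[,'treat'], fc=fit$coefficients[,'treat'])\n"
        f"write.table(out, '{out}', sep='\\t', quote=FALSE, row.names=FALSE)\n"
    )
    proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    if proc.returncode != 0:
        pytest.skip(f"limma unavailable: {proc.stderr[:200]}")
    ref = pd.read_csv(out, sep="\t")
    mine = differential_test(imp, moderation="moderated")
    assert np.allclose(mine["log2FC"].to_numpy(), ref["fc"].to_numpy())
    assert np.corrcoef(mine["t"], ref["t"])[0, 1] > 0.98
    assert stats.spearmanr(mine["p"], ref["p"]).statistic > 0.95
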
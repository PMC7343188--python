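import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from arthromethyl.expression import (
    cv_contrast,
    exon_count_contrast,
    expression_groups,
    fpkm,
    housekeeping_enrichment,
    orthogroup_methylation,
    tissue_cv,
    upstream_meth_expression,
    zscore_coupling,
)


# -- FPKM -------------------------------------------------------------------

def test_fpkm_basic_value():
    counts = pd.DataFrame({"s1": [100, 0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 2000, "g2": 500})
    out = fpkm(counts, lengths, 10_000_000)
    assert out.loc["g1", "s1"] == pytest.approx(5.0)
    assert out.loc["g2", "s1"] == 0.0


def test_fpkm_total_mapped_scaling():
    counts = pd.DataFrame({"s1": [10, 30]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 1000, "g2": 1500})
    a = fpkm(counts, lengths, 1e6)
    b = fpkm(counts, lengths, 2e6)
    pd.testing.assert_frame_equal(b * 2, a)


def test_fpkm_zero_length_errors():
    counts = pd.DataFrame({"s1": [1]}, index=["g1"])
    with pytest.raises(ValueError):
        fpkm(counts, pd.Series({"g1": 0}), 1e6)


@given(scale=st.floats(0.5, 10))
@settings(max_examples=20, deadline=None)
def test_fpkm_linear_in_counts(scale):
    counts = pd.DataFrame({"s1": [10.0, 20.0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 1000, "g2": 2000})
    a = fpkm(counts, lengths, 1e6)
    b = fpkm(counts * scale, lengths, 1e6)
    pd.testing.assert_frame_equal(b, a * scale)


# -- groups -----------------------------------------------------------------

def test_expression_groups_exact_counts():
    expr = pd.DataFrame({"s": np.arange(10.0)}, index=[f"g{i}" for i in range(10)])
    high, low = expression_groups(expr, q=0.2)
    assert len(high) == len(low) == 2
    assert set(high) == {"g8", "g9"}
    assert set(low) == {"g0", "g1"}


def test_expression_groups_degenerate_ties_warn():
    expr = pd.DataFrame({"s": np.ones(6)}, index=[f"g{i}" for i in range(6)])
    with pytest.warns(UserWarning):
        high, low = expression_groups(expr, q=0.5)
    assert len(high) == len(low) == 3


def test_expression_groups_half_partition():
    expr = pd.DataFrame({"s": np.arange(8.0)}, index=[f"g{i}" for i in range(8)])
    high, low = expression_groups(expr, q=0.5)
    assert sorted(high + low) == sorted(expr.index)


# -- upstream bins ----------------------------------------------------------

def test_upstream_bins_null_calibration():
    rng = np.random.default_rng(0)
    rejections = 0
    for _ in range(200):
        genes = [f"g{i}" for i in range(150)]
        meth = pd.Series(rng.random(150), index=genes)
        expr = pd.DataFrame({"s1": rng.lognormal(1, 1, 150)}, index=genes)
        res = upstream_meth_expression(meth, expr, n_bins=5)
        rejections += res.p <= 0.05
    assert 0.02 <= rejections / 200 <= 0.09


def test_upstream_bins_silencing_signal():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(200)]
    meth = pd.Series(rng.random(200), index=genes)
    expr_vals = rng.lognormal(2, 0.5, 200)
    expr_vals[meth > 0.9] *= 0.01  # top decile silenced
    expr = pd.DataFrame({"s1": expr_vals}, index=genes)
    res = upstream_meth_expression(meth, expr, n_bins=5)
    assert np.nanargmin(res.medians) == len(res.medians) - 1
    assert res.p < 0.01


def test_upstream_bins_single_bin_errors():
    genes = ["g1", "g2", "g3"]
    meth = pd.Series([0.5, 0.5, 0.5], index=genes)
    expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=genes)
    with pytest.raises(ValueError):
        upstream_meth_expression(meth, expr, n_bins=1)


# -- CV ---------------------------------------------------------------------

def test_cv_identical_expression_zero():
    expr = pd.DataFrame({"t1": [5.0], "t2": [5.0], "t3": [5.0]}, index=["g"])
    assert tissue_cv(expr)["g"] == 0.0


def test_cv_sample_sd_convention():
    expr = pd.DataFrame({"t1": [1.0], "t2": [3.0]}, index=["g"])
    assert tissue_cv(expr)["g"] == pytest.approx(np.sqrt(2) / 2)


def test_cv_zero_mean_undefined():
    expr = pd.DataFrame({"t1": [0.0], "t2": [0.0]}, index=["g"])
    assert np.isnan(tissue_cv(expr)["g"])


def test_cv_contrast_ordering():
    rng = np.random.default_rng(2)
    lo_cv = rng.normal(0.1, 0.01, 50)
    hi_cv = rng.normal(1.0, 0.05, 50)
    cv = pd.Series(
        np.concatenate([lo_cv, hi_cv]),
        index=[f"m{i}" for i in range(50)] + [f"u{i}" for i in range(50)],
    )
    res = cv_contrast(cv, [f"m{i}" for i in range(50)], [f"u{i}" for i in range(50)])
    assert res.median_high < res.median_low
    assert res.p < 1e-10


# -- z-score coupling -------------------------------------------------------

def _coupling_frame(rng, n=200, species=("sp1", "sp2")):
    rows = []
    for sp in species:
        meth = rng.random(n)
        expr = rng.lognormal(1, 1, n)
        for i in range(n):
            rows.append((sp, f"{sp}_g{i}", meth[i], expr[i]))
    return pd.DataFrame(rows, columns=["species", "gene", "meth", "expr"])


def test_zscore_identities_within_species():
    df = _coupling_frame(np.random.default_rng(3))
    z = zscore_coupling(df)
    for _, grp in z.groupby("species"):
        assert grp["z_meth"].mean() == pytest.approx(0.0, abs=1e-12)
        assert grp["z_meth"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        assert grp["z_expr"].mean() == pytest.approx(0.0, abs=1e-12)


def test_zscore_pooling_preserves_per_species_standardization():
    rng = np.random.default_rng(4)
    df = _coupling_frame(rng)
    solo = zscore_coupling(df[df["species"] == "sp1"].reset_index(drop=True))
    pooled = zscore_coupling(df)
    merged = pooled[pooled["species"] == "sp1"].reset_index(drop=True)
    np.testing.assert_allclose(merged["z_meth"], solo["z_meth"], atol=1e-12)


def test_zscore_zero_variance_errors():
    df = pd.DataFrame(
        {"species": ["a", "a"], "gene": ["g1", "g2"], "meth": [0.5, 0.5], "expr": [1, 2]}
    )
    with pytest.raises(ValueError):
        zscore_coupling(df)


def test_null_coupling_near_zero_correlation():
    rng = np.random.default_rng(5)
    df = _coupling_frame(rng, n=2500)
    z = zscore_coupling(df)
    assert abs(np.corrcoef(z["z_meth"], z["z_expr"])[0, 1]) < 0.05


# -- housekeeping enrichment ------------------------------------------------

def test_fisher_matches_hypergeometric_enumeration():
    top = [f"t{i}" for i in range(20)]
    bot = [f"b{i}" for i in range(20)]
    hk = set(top[:10]) | set(bot[:3])
    res = housekeeping_enrichment(top, bot, hk)
    assert res.table.tolist() == [[10, 10], [3, 17]]
    # direct two-sided hypergeometric-sum oracle
    a, n1, n2, k = 10, 20, 20, 13
    probs = [stats.hypergeom.pmf(x, n1 + n2, n1, k) for x in range(0, k + 1)]
    p_obs = stats.hypergeom.pmf(a, n1 + n2, n1, k)
    p_oracle = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
    assert res.p == pytest.approx(p_oracle, abs=1e-12)


def test_fisher_identical_fractions_or_one():
    top = [f"t{i}" for i in range(20)]
    bot = [f"b{i}" for i in range(20)]
    hk = set(top[:5]) | set(bot[:5])
    res = housekeeping_enrichment(top, bot, hk)
    assert res.odds_ratio == pytest.approx(1.0, rel=1e-6)
    assert res.p == pytest.approx(1.0)


def test_fisher_row_swap_inverts_or():
    top = [f"t{i}" for i in range(30)]
    bot = [f"b{i}" for i in range(30)]
    hk = set(top[:18]) | set(bot[:6])
    fwd = housekeeping_enrichment(top, bot, hk)
    rev = housekeeping_enrichment(bot, top, hk)
    assert fwd.odds_ratio == pytest.approx(1 / rev.odds_ratio, rel=1e-4)
    assert fwd.p == pytest.approx(rev.p, rel=1e-9)


# -- orthogroups ------------------------------------------------------------

def test_orthogroup_single_gene_score_equals_z():
    meth = pd.DataFrame(
        {
            "species": ["a"] * 3 + ["b"] * 3,
            "gene": ["a1", "a2", "a3", "b1", "b2", "b3"],
            "meth": [0.1, 0.5, 0.9, 0.2, 0.4, 0.6],
        }
    )
    ortho = pd.DataFrame(
        {
            "orthogroup": ["og1", "og1", "og2", "og2", "og3", "og3"],
            "species": ["a", "b", "a", "b", "a", "b"],
            "gene": ["a1", "b1", "a2", "b2", "a3", "b3"],
        }
    )
    res = orthogroup_methylation(meth, ortho)
    za = (np.array([0.1, 0.5, 0.9]) - 0.5) / np.std([0.1, 0.5, 0.9], ddof=1)
    zb = (np.array([0.2, 0.4, 0.6]) - 0.4) / np.std([0.2, 0.4, 0.6], ddof=1)
    assert res.scores["og1"] == pytest.approx((za[0] + zb[0]) / 2)
    assert list(res.scores.index)[0] == "og3"  # highest score ranked first


def test_orthogroup_species_permutation_invariant():
    rng = np.random.default_rng(6)
    rows, orows = [], []
    for og in range(30):
        for sp in ("a", "b", "c"):
            g = f"{sp}_g{og}"
            rows.append((sp, g, rng.random()))
            orows.append((f"og{og}", sp, g))
    meth = pd.DataFrame(rows, columns=["species", "gene", "meth"])
    ortho = pd.DataFrame(orows, columns=["orthogroup", "species", "gene"])
    r1 = orthogroup_methylation(meth, ortho)
    r2 = orthogroup_methylation(
        meth.iloc[::-1].reset_index(drop=True), ortho.iloc[::-1].reset_index(drop=True)
    )
    pd.testing.assert_series_equal(r1.scores, r2.scores)


def test_orthogroup_paralogs_averaged_first():
    meth = pd.DataFrame(
        {
            "species": ["a", "a", "a", "b", "b"],
            "gene": ["a1", "a1b", "a2", "b1", "b2"],
            "meth": [0.9, 0.7, 0.1, 0.8, 0.2],
        }
    )
    ortho = pd.DataFrame(
        {
            "orthogroup": ["og1", "og1", "og2", "og1", "og2"],
            "species": ["a", "a", "a", "b", "b"],
            "gene": ["a1", "a1b", "a2", "b1", "b2"],
        }
    )
    res = orthogroup_methylation(meth, ortho)
    z_a = (meth.loc[:2, "meth"] - meth.loc[:2, "meth"].mean()) / meth.loc[:2, "meth"].std(ddof=1)
    expected_a = (z_a[0] + z_a[1]) / 2  # paralogs averaged within species
    z_b = (meth.loc[3:, "meth"] - meth.loc[3:, "meth"].mean()) / meth.loc[3:, "meth"].std(ddof=1)
    assert res.scores["og1"] == pytest.approx((expected_a + z_b[3]) / 2)


def test_orthogroup_gene_in_two_groups_errors():
    meth = pd.DataFrame({"species": ["a"], "gene": ["g"], "meth": [0.5]})
    ortho = pd.DataFrame(
        {"orthogroup": ["og1", "og2"], "species": ["a", "a"], "gene": ["g", "g"]}
    )
    with pytest.raises(ValueError):
        orthogroup_methylation(meth, ortho)


# -- exon-count contrast ----------------------------------------------------

def test_exon_count_null_calibration():
    rng = np.random.default_rng(7)
    rejections = 0
    for _ in range(200):
        meth = pd.Series(rng.random(120), index=[f"g{i}" for i in range(120)])
        counts = pd.Series(
            rng.integers(1, 5, 120), index=[f"g{i}" for i in range(120)]
        )
        res = exon_count_contrast(meth, counts)
        rejections += res.p <= 0.05
    assert 0.02 <= rejections / 200 <= 0.09


def test_exon_count_all_single_undefined():
    meth = pd.Series([0.1, 0.2], index=["g1", "g2"])
    counts = pd.Series([1, 1], index=["g1", "g2"])
    with pytest.warns(UserWarning):
        res = exon_count_contrast(meth, counts)
    assert res.mean_multi is None
    assert res.p is None


def test_exon_count_implanted_difference_power():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(400)]
    meth_vals = np.concatenate(
        [rng.normal(0.3, 0.1, 200), rng.normal(0.6, 0.1, 200)]
    ).clip(0, 1)
    counts = pd.Series([1] * 200 + [3] * 200, index=genes)
    res = exon_count_contrast(pd.Series(meth_vals, index=genes), counts)
    assert res.p < 1e-6
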
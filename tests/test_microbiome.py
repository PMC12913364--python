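"""Community profiling: aggregation, diversity, ordination, biomarkers."""

import numpy as np
import pandas as pd
import pytest

from gutbrain.microbiome import (
    CountTable,
    aggregate_rank,
    alpha_diversity,
    bray_curtis,
    diff_abundance,
    lda_effect_size,
    pcoa,
    permanova,
    read_count_table,
    relative_abundance,
)


def make_table(counts, genera=None, samples=None, groups=None):
    counts = np.asarray(counts)
    genera = genera or [f"Genus{i}" for i in range(counts.shape[0])]
    lineages = [f"k__Bacteria;p__P{i % 2};c__C;o__O;f__F;g__{g};s__"
                for i, g in enumerate(genera)]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    sg = pd.Series(groups, index=samples) if groups is not None else None
    return CountTable(lineages, samples, counts, sg)


# ------------------------------------------------------------ aggregation


def test_aggregate_phylum_additivity():
    t = make_table([[3], [4]], genera=["A", "B"])  # both in phylum P0? no: P0, P1
    agg = aggregate_rank(t, "phylum")
    assert agg.counts.sum() == 7
    # two genera in different phyla stay separate; same phylum sums
    t2 = CountTable(
        ["k__B;p__X;c__;o__;f__;g__A;s__", "k__B;p__X;c__;o__;f__;g__B;s__"],
        ["s0"], np.array([[3], [4]]),
    )
    agg2 = aggregate_rank(t2, "phylum")
    assert agg2.counts.tolist() == [[7]]


def test_aggregate_genus_of_genus_table_is_identity(bundle):
    t = bundle.counts
    agg = aggregate_rank(t, "genus")
    assert agg.counts.shape[0] == t.counts.shape[0]
    np.testing.assert_array_equal(np.sort(agg.counts, axis=0), np.sort(t.counts, axis=0))


def test_aggregate_conserves_column_sums(rng):
    for _ in range(20):
        t = make_table(rng.integers(0, 50, size=(12, 5)))
        for rank in ("kingdom", "phylum", "family"):
            agg = aggregate_rank(t, rank)
            np.testing.assert_array_equal(agg.counts.sum(axis=0), t.counts.sum(axis=0))


def test_aggregate_unknown_rank_rejected(bundle):
    with pytest.raises(ValueError, match="unknown rank"):
        aggregate_rank(bundle.counts, "strain")


def test_missing_rank_pools_unclassified():
    t = CountTable(
        ["k__B;p__X;c__;o__;f__;g__A;s__", "k__B;p__;c__;o__;f__;g__;s__"],
        ["s0"], np.array([[3], [4]]),
    )
    agg = aggregate_rank(t, "phylum")
    assert "unclassified" in agg.lineages
    assert agg.counts.sum() == 7


# ------------------------------------------------------- relative abundance


def test_relative_abundance_columns_sum_to_one(rng):
    t = make_table(rng.integers(1, 100, size=(8, 6)))
    rel = relative_abundance(t)
    np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)
    single = make_table([[2], [2]])
    np.testing.assert_allclose(relative_abundance(single).values.ravel(), [0.5, 0.5])


def test_relative_abundance_names_zero_sample():
    t = make_table([[0, 1], [0, 2]], samples=["bad", "ok"])
    with pytest.raises(ValueError, match="bad"):
        relative_abundance(t)


# --------------------------------------------------------- alpha diversity


def test_alpha_uniform_closed_forms():
    t = make_table([[10], [10], [10], [10]])
    a = alpha_diversity(t).iloc[0]
    assert a["shannon"] == pytest.approx(np.log(4), rel=1e-12)
    assert a["evenness"] == pytest.approx(1.0, rel=1e-12)
    assert a["simpson"] == pytest.approx(0.75, rel=1e-12)


def test_alpha_single_taxon_zeroes():
    a = alpha_diversity(make_table([[7]])).iloc[0]
    assert a["shannon"] == 0 and a["simpson"] == 0 and a["evenness"] == 0


def test_alpha_direct_formula_values():
    a = alpha_diversity(make_table([[5], [3], [2]])).iloc[0]
    p = np.array([5, 3, 2]) / 10
    assert a["shannon"] == pytest.approx(-(p * np.log(p)).sum(), rel=1e-9)
    assert a["shannon"] == pytest.approx(1.0297, abs=1e-4)
    # chao1 bias-corrected on S=5, F1=2, F2=1
    a2 = alpha_diversity(make_table([[1], [1], [2], [5], [9]])).iloc[0]
    assert a2["chao1"] == pytest.approx(5.5, rel=1e-12)
    assert a2["chao1"] >= a2["observed_species"]


def test_alpha_invariant_to_taxon_order(rng):
    counts = rng.integers(0, 40, size=(10, 3))
    a = alpha_diversity(make_table(counts))
    b = alpha_diversity(make_table(counts[::-1]))
    pd.testing.assert_frame_equal(a, b)


def test_shannon_increases_when_count_is_split():
    before = alpha_diversity(make_table([[8], [4]])).iloc[0]["shannon"]
    after = alpha_diversity(make_table([[4], [4], [4]])).iloc[0]["shannon"]
    assert after > before


# ------------------------------------------------------------- Bray-Curtis


def test_bray_curtis_examples():
    m = pd.DataFrame({"a": [1, 2], "b": [2, 0], "c": [1, 2]})
    d = bray_curtis(m)
    assert d.loc["a", "c"] == 0.0
    assert d.loc["a", "b"] == pytest.approx(0.6)
    disjoint = pd.DataFrame({"x": [1, 0], "y": [0, 3]})
    assert bray_curtis(disjoint).loc["x", "y"] == 1.0


def test_bray_curtis_symmetric_zero_diagonal(rng):
    m = pd.DataFrame(rng.uniform(size=(6, 5)))
    d = bray_curtis(m).values
    np.testing.assert_allclose(d, d.T, atol=1e-15)
    np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-15)


def test_bray_curtis_all_zero_pair_is_zero_with_warning():
    m = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 1]})
    with pytest.warns(UserWarning, match="all-zero"):
        d = bray_curtis(m)
    assert d.loc["a", "b"] == 0.0


def test_bray_curtis_triangle_inequality_may_fail():
    """Bray-Curtis is a semi-metric: exhibit a triangle violation."""
    m = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 1.0], "c": [0.0, 1.0]})
    d = bray_curtis(m)
    assert d.loc["a", "c"] > d.loc["a", "b"] + d.loc["b", "c"]


# -------------------------------------------------------------------- PCoA


def test_pcoa_embeds_line():
    labels = ["p", "q", "r"]
    d = pd.DataFrame(
        [[0, 1, 3], [1, 0, 2], [3, 2, 0]], index=labels, columns=labels, dtype=float
    )
    res = pcoa(d)
    x = res.coordinates["PCo1"]
    recon = np.abs(np.subtract.outer(x.values, x.values))
    np.testing.assert_allclose(recon, d.values, atol=1e-9)


def test_pcoa_euclidean_input_nonnegative_eigenvalues(rng):
    for _ in range(5):
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(pd.DataFrame(d))
        assert (res.eigenvalues >= -1e-9).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9


def test_pcoa_duplicated_sample_coincides():
    d = np.array([[0, 0, 2.0], [0, 0, 2.0], [2.0, 2.0, 0]])
    res = pcoa(pd.DataFrame(d))
    np.testing.assert_allclose(
        res.coordinates.iloc[0].values, res.coordinates.iloc[1].values, atol=1e-9
    )


def test_pcoa_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    pts = rng.normal(size=(9, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ours = pcoa(pd.DataFrame(d))
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
    np.testing.assert_allclose(
        np.sort(ours.eigenvalues[ours.eigenvalues > 1e-9]),
        np.sort(theirs.eigvals.values[theirs.eigvals.values > 1e-9]),
        rtol=1e-6,
    )


# --------------------------------------------------------------- PERMANOVA


def permanova_exhaustive_p(d, groups):
    """Enumerate every relabelling with the observed group sizes."""
    from itertools import combinations

    from gutbrain.microbiome import _permanova_f

    d2 = np.asarray(d, float) ** 2
    codes, _ = pd.factorize(pd.Series(groups))
    n = len(codes)
    k = codes.max() + 1
    size_a = int((codes == 0).sum())
    f_obs = _permanova_f(d2, codes, k)
    count = total = 0
    for combo in combinations(range(n), size_a):
        lab = np.ones(n, dtype=int)
        lab[list(combo)] = 0
        total += 1
        if _permanova_f(d2, lab, k) >= f_obs - 1e-12:
            count += 1
    return count / total


def test_permanova_separated_groups_exhaustive():
    # two tight clusters of 3: zero within-group, positive between-group
    pts = np.array([[0.0], [0.0], [0.0], [5.0], [5.0], [5.0]])
    d = pd.DataFrame(np.abs(pts - pts.T))
    groups = ["a"] * 3 + ["b"] * 3
    exact = permanova_exhaustive_p(d, groups)
    assert exact == pytest.approx(2 / 20)  # both extreme splits of C(6,3)
    res = permanova(d, groups, n_perm=4999, seed=5)
    se = np.sqrt(exact * (1 - exact) / 4999)
    assert abs(res["p"] - exact) < max(3 * se, 2e-3) + 1 / 5000


def test_permanova_matches_exhaustive_on_random_problem(rng):
    pts = rng.normal(size=(7, 2))
    d = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1))
    groups = ["a"] * 3 + ["b"] * 4
    exact = permanova_exhaustive_p(d, groups)
    res = permanova(d, groups, n_perm=4999, seed=7)
    se = np.sqrt(exact * (1 - exact) / 4999)
    assert abs(res["p"] - exact) < 3 * se + 1 / 5000


def test_permanova_pseudo_f_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    pts = rng.normal(size=(12, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    groups = ["a"] * 6 + ["b"] * 6
    ours = permanova(pd.DataFrame(d), groups, n_perm=99, seed=1)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(d), grouping=groups, permutations=99
    )
    assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_permanova_rejects_singleton_group():
    d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
    with pytest.raises(ValueError):
        permanova(d, ["a", "b", "b", "b"], seed=0)


def test_permanova_requires_seed():
    d = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
    with pytest.raises(ValueError, match="seed"):
        permanova(d, ["a", "a", "b", "b"])


# ---------------------------------------------------- differential taxa


def test_diff_abundance_null_and_degenerate(rng):
    rel = pd.DataFrame(rng.uniform(size=(6, 12)),
                       index=[f"t{i}" for i in range(6)],
                       columns=[f"s{j}" for j in range(12)])
    rel.loc["t0"] = 0.3  # constant taxon
    res = diff_abundance(rel, ["a"] * 6 + ["b"] * 6)
    assert res.loc["t0", "p"] == 1.0
    assert (res["q"] >= res["p"] - 1e-12).all()
    same = pd.concat([rel.iloc[:, :6]] * 2, axis=1)
    same.columns = [f"s{j}" for j in range(12)]
    res2 = diff_abundance(same, ["a"] * 6 + ["b"] * 6)
    assert (res2["q"] > 0.9).all()


def test_diff_abundance_three_groups_uses_kruskal(rng):
    rel = pd.DataFrame(rng.uniform(size=(4, 15)))
    res = diff_abundance(rel, ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    assert {"mean_a", "mean_b", "mean_c"} <= set(res.columns)


# ------------------------------------------------------------------ LEfSe


def test_lefse_stage_one_gatekeeping(rng):
    rel = pd.DataFrame(rng.uniform(size=(5, 20)),
                       index=[f"t{i}" for i in range(5)])
    rel.loc["t0"] = 0.2  # identically distributed across classes
    res = lda_effect_size(rel, ["a"] * 10 + ["b"] * 10, seed=0)
    assert "t0" not in res.index  # constant taxon never clears the rank filter
    assert (res["kw_p"] < 0.05).all()  # everything reported passed stage 1


def test_lefse_single_discriminative_taxon_oracle():
    """One-feature problem: the discriminant is the feature itself.

    The feature is present only in class A; the unit-norm discriminant
    direction is the feature axis, so the effect is exactly the rescaled
    between-class mean difference (1e6 here) and the score is
    log10(1 + 1e6) ~ 6, far above the reporting threshold.
    """
    a = np.full(10, 0.1)
    b = np.zeros(10)
    rel = pd.DataFrame([np.concatenate([a, b])], index=["marker"])
    rel.loc["noise"] = 0.05  # constant, filtered at stage 1
    res = lda_effect_size(rel, ["A"] * 10 + ["B"] * 10, seed=0, rescale_to=1e6)
    assert "marker" in res.index
    row = res.loc["marker"]
    assert row["enriched"] == "A"
    assert row["lda_score"] == pytest.approx(np.log10(1 + 1e6), abs=0.35)
    assert row["lda_score"] > 2


def test_lefse_rejects_small_class(rng):
    rel = pd.DataFrame(rng.uniform(size=(3, 5)))
    with pytest.raises(ValueError):
        lda_effect_size(rel, ["a", "a", "b", "b", "b"], seed=0)


def test_lefse_three_group_biomarker_recovery(bundle):
    """The planted diarrhea-subgroup biomarker is recovered with LDA > 2."""
    from gutbrain.microbiome import aggregate_rank as agg, relative_abundance as ra

    rel = ra(agg(bundle.counts, "genus"))
    sub = bundle.clinical["subgroup"]
    res = lda_effect_size(rel, sub, seed=3)
    mega = [t for t in res.index if "Megamonas" in t]
    assert mega, "planted ASD_D biomarker not reported"
    assert res.loc[mega[0], "enriched"] == "ASD_D"
    assert res.loc[mega[0], "lda_score"] > 2


# ---------------------------------------------------------------- reader


def test_read_count_table_roundtrip(tmp_path, bundle):
    path = tmp_path / "counts.tsv"
    bundle.counts.to_frame().rename_axis("lineage").to_csv(path, sep="\t")
    t = read_count_table(path)
    np.testing.assert_array_equal(t.counts, bundle.counts.counts)
    assert t.lineages == bundle.counts.lineages


def test_read_count_table_names_bad_line(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text("lineage\ts1\ts2\nk__B;g__A\t3\t4\nk__B;g__B\t5\toops\n")
    with pytest.raises(ValueError, match=r"counts\.tsv:3"):
        read_count_table(path)
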
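"""Synthetic cohort generator: determinism, planted effects, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gutbrain.synthetic import (
    ModuleSpec,
    SyntheticConfig,
    gen_clinical,
    gen_metabolome,
    gen_microbiome,
    gen_variants,
    simulate,
    write_bundle,
)
from gutbrain.variants import classify_trio_origin


# ------------------------------------------------------------- validation


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_cases=1).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(burden_cars_rho=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(module_spec=(ModuleSpec(30, 1.0),)).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(prevalences={"diarrhea": 1.2}).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(depth=50).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(n_metabolites=10).validate()  # module sizes exceed


# ------------------------------------------------------------ determinism


def test_same_seed_identical_bundle(small_config, tmp_path):
    b1 = simulate(small_config)
    b2 = simulate(small_config)
    pd.testing.assert_frame_equal(b1.clinical, b2.clinical)
    np.testing.assert_array_equal(b1.carriers.genotype, b2.carriers.genotype)
    np.testing.assert_array_equal(b1.counts.counts, b2.counts.counts)
    pd.testing.assert_frame_equal(b1.intensities, b2.intensities)
    assert b1.truth == b2.truth
    # byte-identical on disk
    p1 = write_bundle(b1, tmp_path / "a")
    p2 = write_bundle(b2, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()


# --------------------------------------------------------------- clinical


def test_clinical_groups_and_prevalences(bundle):
    clin = bundle.clinical
    cases = clin[clin["group"] == "ASD"]
    assert len(cases) == 51 and (clin["group"] == "TD").sum() == 51
    assert set(clin["subgroup"]) <= {"ASD_D", "ASD_noD", "TD"}
    assert ((clin["CARS"] >= 15) & (clin["CARS"] <= 60)).all()
    assert ((clin["ABC"] >= 0) & (clin["ABC"] <= 158)).all()


def test_case_constipation_count_near_table_value():
    """Binomial mean of the planted 36/51 prevalence."""
    counts = []
    for seed in range(15):
        clin = gen_clinical(SyntheticConfig(seed=seed))
        counts.append(clin.loc[clin["group"] == "ASD", "constipation"].sum())
    # mean 36, sd ~3.2 per draw -> sample mean well inside +/-3
    assert abs(np.mean(counts) - 36) < 3


def test_zero_prevalence_means_no_flags():
    cfg = SyntheticConfig(
        seed=0,
        prevalences={k: 0.0 for k in SyntheticConfig().prevalences},
        control_prevalences={k: 0.0 for k in SyntheticConfig().control_prevalences},
    )
    clin = gen_clinical(cfg)
    for flag in ("constipation", "diarrhea", "insomnia", "hypersomnia"):
        assert (clin[flag] == 0).all()


def test_nonpositive_n_rejected():
    with pytest.raises(ValueError):
        gen_clinical(SyntheticConfig(n_cases=0))


# ---------------------------------------------------------------- variants


def test_truth_qualifying_pass_annotation_stages(bundle):
    from gutbrain.variants import is_deleterious

    by_id = {v.variant_id: v for v in bundle.variants}
    for vid in bundle.truth["variants"]["qualifying_variants"]:
        v = by_id[vid]
        assert v.region == "exonic"
        assert is_deleterious(v)
        assert (v.gnomad_af or 0.0) < 0.05


def test_decoys_fail_at_least_one_stage(bundle):
    from gutbrain.variants import is_deleterious

    qualifying = set(bundle.truth["variants"]["qualifying_variants"])
    for v in bundle.variants:
        if v.variant_id in qualifying:
            continue
        af = v.gnomad_af or 0.0
        balanced = abs(v.case_carriers - v.control_carriers) <= 12
        assert (
            v.region != "exonic" or not is_deleterious(v) or af >= 0.05 or balanced
        )


def test_null_rho_gives_near_zero_burden_correlation():
    for seed in range(6):
        cfg = SyntheticConfig.null(seed=seed)
        clin = gen_clinical(cfg)
        _, _, _, truth = gen_variants(cfg, clin)
        burden = np.array([truth["true_burden"][s] for s in clin.index])
        if np.ptp(burden) == 0:
            continue
        rho = spearmanr(burden, clin["CARS"]).statistic
        assert abs(rho) < 0.2


def test_planted_rho_recovered(bundle):
    clin = bundle.clinical
    burden = np.array(
        [bundle.truth["variants"]["true_burden"][s] for s in clin.index]
    )
    rho = spearmanr(burden, clin["CARS"]).statistic
    assert rho == pytest.approx(0.32, abs=0.15)


def test_trios_are_mostly_de_novo_with_one_maternal(bundle):
    origins = [classify_trio_origin(t) for t in bundle.trios]
    assert origins.count("de_novo") == 11
    assert origins.count("maternal") == 1
    # and the de novo definition holds on the raw genotypes
    for t in bundle.trios:
        if classify_trio_origin(t) == "de_novo":
            assert t.proband > 0 and t.mother == 0 and t.father == 0


def test_carrier_matrix_entries_valid(bundle):
    assert np.isin(bundle.carriers.genotype, (0, 1, 2)).all()
    assert list(bundle.carriers.subjects) == list(bundle.clinical.index)


def test_invalid_rho_rejected(bundle):
    cfg = SyntheticConfig(burden_cars_rho=-2.0)
    with pytest.raises(ValueError):
        gen_variants(cfg, bundle.clinical)


# -------------------------------------------------------------- microbiome


def test_microbiome_columns_sum_to_depth(small_config):
    clin = gen_clinical(small_config)
    counts, _ = gen_microbiome(small_config, clin)
    np.testing.assert_array_equal(
        counts.counts.sum(axis=0), np.full(len(clin), small_config.depth)
    )


def test_microbiome_depth_floor():
    cfg = SyntheticConfig(depth=50)
    with pytest.raises(ValueError):
        gen_microbiome(cfg, gen_clinical(SyntheticConfig()))


def test_null_shannon_shift_near_zero():
    from gutbrain.microbiome import aggregate_rank, alpha_diversity

    diffs = []
    for seed in range(4):
        cfg = SyntheticConfig.null(seed=seed, n_taxa=80, depth=5000)
        clin = gen_clinical(cfg)
        counts, truth = gen_microbiome(cfg, clin)
        assert truth["n_knockout_taxa"] == 0
        alpha = alpha_diversity(aggregate_rank(counts, "genus"))
        g = clin["group"]
        diffs.append(
            alpha.loc[g == "TD", "shannon"].mean()
            - alpha.loc[g == "ASD", "shannon"].mean()
        )
    assert abs(np.mean(diffs)) < 0.1


def test_planted_fold_change_realized():
    """The 5-fold ASD-enriched taxon shows a mean abundance ratio in [3, 7].

    Tested with the diversity knockout disabled: the knockout removes
    mass from case samples, so compositional closure would otherwise
    inflate every surviving case-side ratio beyond the planted fold.
    """
    from gutbrain.microbiome import relative_abundance

    ratios = []
    for seed in range(10):
        cfg = SyntheticConfig(seed=seed, shannon_shift=0.0)
        clin = gen_clinical(cfg)
        counts, truth = gen_microbiome(cfg, clin)
        rel = relative_abundance(counts)
        g = clin["group"]
        target = truth["asd_enriched"][0]
        row = [lin for lin in rel.index if target in lin][0]
        ratios.append(
            rel.loc[row, g[g == "ASD"].index].mean()
            / rel.loc[row, g[g == "TD"].index].mean()
        )
    assert 3.0 < np.mean(ratios) < 7.0


def test_planted_shannon_shift_realized():
    from gutbrain.microbiome import aggregate_rank, alpha_diversity

    diffs = []
    for seed in range(6):
        cfg = SyntheticConfig(seed=seed)
        clin = gen_clinical(cfg)
        counts, _ = gen_microbiome(cfg, clin)
        alpha = alpha_diversity(aggregate_rank(counts, "genus"))
        g = clin["group"]
        diffs.append(
            alpha.loc[g == "TD", "shannon"].mean()
            - alpha.loc[g == "ASD", "shannon"].mean()
        )
    assert np.mean(diffs) == pytest.approx(0.2, abs=0.1)


# -------------------------------------------------------------- metabolome


def test_within_module_correlation_matches_spec():
    cfg = SyntheticConfig(
        seed=5,
        n_metabolites=120,
        module_spec=(ModuleSpec(40, 0.7, None, 0.0),),
        n_up_metabolites=0,
        n_down_metabolites=0,
    )
    means = []
    for seed in range(6):
        cfg = SyntheticConfig(
            seed=seed, n_metabolites=120,
            module_spec=(ModuleSpec(40, 0.7, None, 0.0),),
            n_up_metabolites=0, n_down_metabolites=0,
        )
        clin = gen_clinical(cfg)
        intens, truth = gen_metabolome(cfg, clin)
        members = truth["modules"]["module_01"]
        C = np.corrcoef(np.log(intens[members].values), rowvar=False)
        means.append(C[np.triu_indices_from(C, 1)].mean())
    assert 0.6 < np.mean(means) < 0.8


def test_module_trait_factor_correlation():
    """Planted factor-diarrhea coupling within the case samples."""
    rs = []
    for seed in range(8):
        cfg = SyntheticConfig(seed=seed)
        clin = gen_clinical(cfg)
        intens, truth = gen_metabolome(cfg, clin)
        members = truth["modules"]["module_01"]
        # the common factor estimated as the mean standardized member profile
        cases = [s for s in intens.index if clin.loc[s, "group"] == "ASD"]
        logm = np.log(intens.loc[cases, members].values)
        z = (logm - logm.mean(0)) / logm.std(0)
        factor = z.mean(axis=1)
        d = clin.loc[cases, "diarrhea"].values
        rs.append(np.corrcoef(factor, d)[0, 1])
    assert np.mean(rs) == pytest.approx(-0.52, abs=0.15)


def test_zero_modules_pure_noise():
    cfg = SyntheticConfig(
        seed=3, n_metabolites=80, module_spec=(),
        n_up_metabolites=0, n_down_metabolites=0,
    )
    clin = gen_clinical(cfg)
    intens, truth = gen_metabolome(cfg, clin)
    assert truth["modules"] == {}
    C = np.corrcoef(np.log(intens.values), rowvar=False)
    off = C[np.triu_indices_from(C, 1)]
    assert abs(off.mean()) < 0.05


def test_metabolome_subject_subset(bundle):
    assert len(bundle.intensities) == 50
    groups = bundle.clinical.loc[bundle.intensities.index, "group"]
    assert (groups == "ASD").sum() == 25 and (groups == "TD").sum() == 25


# ------------------------------------------------------------------ truth


def test_truth_references_existing_entities(bundle):
    variant_ids = {v.variant_id for v in bundle.variants}
    assert set(bundle.truth["variants"]["qualifying_variants"]) <= variant_ids
    assert set(bundle.truth["variants"]["true_burden"]) == set(bundle.clinical.index)
    metab_names = set(bundle.intensities.columns)
    for members in bundle.truth["metabolome"]["modules"].values():
        assert set(members) <= metab_names
    genus_names = "".join(bundle.counts.lineages)
    for g in bundle.truth["microbiome"]["asd_enriched"]:
        assert g in genus_names
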
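"""End-to-end pipeline stages over the synthetic (or user-supplied) cohort.

Each stage is a plain function taking in-memory objects and an output
directory; the CLI and the numbered analysis drivers are thin wrappers
around these.  Every output table carries a one-line ``#`` metadata header
(version, seed, thresholds) and JSON outputs embed the same metadata, so
any artifact can be reproduced from its own header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import integration as integ
from . import metabolome as metab
from . import microbiome as micro
from . import networks as nets
from . import variants as var
from .synthetic import MUC_GENES, SyntheticBundle, SyntheticConfig, simulate, write_bundle


def _meta_line(**kv) -> str:
    parts = [f"gutbrain={__version__}"] + [f"{k}={v}" for k, v in kv.items()]
    return "# " + " ".join(parts)


def _write_tsv(df: pd.DataFrame, path, index=True, **meta) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line(**meta) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_json(obj: dict, path, **meta) -> None:
    obj = {"metadata": {"gutbrain": __version__, **meta}, **obj}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_gmt(path) -> list[var.GeneSet]:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(var.GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    return sets


def builtin_collection() -> list[var.GeneSet]:
    """Small built-in gene-set collection for the pathway enrichment stage.

    Mucin-anchored pathways plus unrelated background sets; a user GMT
    can replace it via the CLI.
    """
    muc = set(MUC_GENES)
    return [
        var.GeneSet("O_GLYCOSYLATION", frozenset(muc | {"GALNT2", "GALNT3", "B3GNT6", "C1GALT1"})),
        var.GeneSet("DECTIN_2_FAMILY", frozenset(muc | {"CLEC6A", "CLEC4E", "CLEC4D", "FCER1G"})),
        var.GeneSet("NOTCH_SIGNALING", frozenset({"NOTCH1", "NOTCH2", "DLL1", "JAG1", "HES1"})),
        var.GeneSet("KERATINIZATION", frozenset({"KRT1", "KRT5", "KRT14", "IVL", "LOR"})),
        var.GeneSet("INTERFERON_GAMMA", frozenset({"IFNG", "IFNGR1", "JAK1", "JAK2", "STAT1"})),
    ]


# ---------------------------------------------------------------- stages


def stage_simulate(config: SyntheticConfig, outdir) -> SyntheticBundle:
    bundle = simulate(config)
    write_bundle(bundle, outdir)
    return bundle


def stage_variants(
    bundle: SyntheticBundle,
    outdir,
    alpha: float = 0.05,
    max_af: float = 0.05,
    collection=None,
) -> dict:
    """Filter cascade, trio annotation, MUC-pathway burden, enrichment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qualifying = var.filter_variants(bundle.variants, alpha=alpha, max_af=max_af)
    qual_ids = [v.variant_id for v in qualifying]
    variant_gene = {v.variant_id: v.gene for v in bundle.variants}
    gene_set = var.GeneSet("MUC_pathway", frozenset(MUC_GENES))
    scores = var.burden_scores(bundle.carriers, qual_ids, gene_set, variant_gene)
    result = var.stratify_and_compare(scores, bundle.clinical)
    origins = {t.variant: var.classify_trio_origin(t) for t in bundle.trios}

    collection = collection or builtin_collection()
    query = sorted({variant_gene[q] for q in qual_ids})
    universe = sorted({v.gene for v in bundle.variants} | {g for s in collection for g in s.genes})
    enrichment = var.geneset_enrichment(query, collection, universe)

    meta = dict(seed=bundle.truth["config_seed"], alpha=alpha, max_af=max_af)
    qdf = pd.DataFrame(
        [{"variant_id": v.variant_id, "gene": v.gene, "vtype": v.vtype,
          "gnomad_af": v.gnomad_af, "case_carriers": v.case_carriers,
          "control_carriers": v.control_carriers} for v in qualifying]
    )
    _write_tsv(qdf, outdir / "qualifying_variants.tsv", index=False, **meta)
    _write_tsv(
        pd.DataFrame({"burden": scores, "stratum": result.stratum}),
        outdir / "burden.tsv", **meta,
    )
    _write_tsv(enrichment, outdir / "enrichment.tsv", index=False, **meta)
    report = {
        "n_qualifying": len(qual_ids),
        "median_burden": result.median,
        "cars_p": result.cars_p,
        "abc_p": result.abc_p,
        "gi_tests": result.gi_tests,
        "degenerate": result.degenerate,
        "trio_origins": origins,
    }
    _write_json(report, outdir / "burden_report.json", **meta)
    return {"qualifying": qual_ids, "scores": scores, "burden": result,
            "enrichment": enrichment, "trio_origins": origins}


def stage_microbiome(
    bundle: SyntheticBundle, outdir, seed: int, n_perm: int = 999
) -> dict:
    """Diversity, ordination, PERMANOVA, differential taxa, LEfSe (2 and 3 group)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = bundle.counts
    genus = micro.aggregate_rank(counts, "genus")
    rel = micro.relative_abundance(genus)
    alpha = micro.alpha_diversity(genus)
    groups = bundle.clinical.loc[counts.samples, "group"]
    subgroups = bundle.clinical.loc[counts.samples, "subgroup"]

    from ._stats import mann_whitney_p

    alpha_tests = {
        idx: mann_whitney_p(alpha.loc[groups == "ASD", idx], alpha.loc[groups == "TD", idx])
        for idx in alpha.columns
    }
    bc = micro.bray_curtis(rel)
    ordn = micro.pcoa(bc)
    perm = micro.permanova(bc, groups, n_perm=n_perm, seed=seed)
    diff = micro.diff_abundance(rel, groups)
    lefse2 = micro.lda_effect_size(rel, groups, seed=seed)
    lefse3 = micro.lda_effect_size(rel, subgroups, seed=seed + 1)

    meta = dict(seed=seed, n_perm=n_perm)
    _write_tsv(alpha, outdir / "alpha.tsv", **meta)
    _write_tsv(bc, outdir / "bray_curtis.tsv", **meta)
    _write_tsv(ordn.coordinates.iloc[:, :10], outdir / "pcoa.tsv", **meta)
    _write_json({"permanova": perm, "alpha_tests": alpha_tests}, outdir / "permanova.json", **meta)
    _write_tsv(diff, outdir / "diff_abundance.tsv", **meta)
    _write_tsv(lefse2, outdir / "lefse_2group.tsv", **meta)
    _write_tsv(lefse3, outdir / "lefse_3group.tsv", **meta)
    return {"rel": rel, "alpha": alpha, "alpha_tests": alpha_tests, "bc": bc,
            "pcoa": ordn, "permanova": perm, "diff": diff,
            "lefse2": lefse2, "lefse3": lefse3}


def stage_network(
    bundle: SyntheticBundle, outdir, seed: int,
    rho_min: float = 0.6, fdr: float = 0.05, min_prevalence: float = 0.2,
) -> dict:
    """Per-group co-occurrence networks, topology, robustness curves."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genus = micro.aggregate_rank(bundle.counts, "genus")
    rel = micro.relative_abundance(genus)
    groups = bundle.clinical.loc[genus.samples, "group"]
    out = {}
    metrics = {}
    meta = dict(seed=seed, rho_min=rho_min, fdr=fdr, min_prevalence=min_prevalence)
    for grp in ("ASD", "TD"):
        sub = rel.loc[:, groups.index[groups == grp]]
        net = nets.build_network(sub, rho_min=rho_min, fdr=fdr, min_prevalence=min_prevalence)
        topo = nets.topology(net)
        nc = nets.natural_connectivity(net)
        curve = nets.robustness(net, mode="random", seed=seed) if len(net.nodes) >= 10 else None
        _write_tsv(net.edges, outdir / f"edges_{grp}.tsv", index=False, **meta)
        if curve is not None:
            _write_tsv(curve.to_frame(), outdir / f"robustness_{grp}.tsv", index=False, **meta)
        nets.export_graphml(net, outdir / f"network_{grp}.graphml")
        metrics[grp] = {
            "n_nodes": topo.n_nodes, "n_edges": topo.n_edges,
            "connectance": topo.connectance, "average_degree": topo.average_degree,
            "negative_ratio": topo.negative_ratio, "natural_connectivity": nc,
        }
        out[grp] = {"network": net, "topology": topo, "natural_connectivity": nc, "robustness": curve}
    _write_json({"groups": metrics}, outdir / "network_metrics.json", **meta)
    out["metrics"] = metrics
    return out


def stage_metabolome(
    bundle: SyntheticBundle, outdir, seed: int,
    top_k: int = 1000, min_size: int = 30, fc_min: float = 1.0, alpha: float = 0.05,
) -> dict:
    """Volcano, PLS-DA VIP, soft threshold, TOM, modules, module-trait grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = bundle.intensities
    groups = bundle.clinical.loc[m.index, "group"]
    vol = metab.volcano(m, groups, fc_min=fc_min, alpha=alpha)
    vip = metab.pls_da_vip(m, groups)
    pre = metab.preprocess(m, top_k=top_k)
    fit = metab.pick_soft_threshold(pre)
    adj = metab.correlation_adjacency(pre, fit.power)
    T = metab.tom(adj)
    partition = metab.refine_modules(pre, metab.detect_modules(T, min_size=min_size))
    eig = metab.eigenprofiles(pre, partition)
    traits = [c for c in ("CARS", "ABC", "diarrhea", "constipation", "insomnia") if c in bundle.clinical.columns]
    # module-trait correlations over the case samples (severity scores and
    # GI phenotypes are case phenotypes)
    cases = bundle.clinical[bundle.clinical["group"] == "ASD"]
    mt = metab.module_trait(eig, cases, traits=traits)

    meta = dict(seed=seed, top_k=top_k, min_size=min_size, beta=fit.power)
    _write_tsv(vol.join(vip), outdir / "volcano.tsv", **meta)
    _write_tsv(fit.table, outdir / "scale_free_fit.tsv", index=False, **meta)
    _write_tsv(partition.labels.to_frame(), outdir / "modules.tsv", **meta)
    _write_tsv(eig.profiles, outdir / "eigenprofiles.tsv", **meta)
    _write_tsv(mt, outdir / "module_trait.tsv", index=False, **meta)
    return {"volcano": vol, "vip": vip, "scale_free": fit, "partition": partition,
            "eigen": eig, "module_trait": mt}


def stage_integrate(
    bundle: SyntheticBundle, outdir, seed: int,
    variant_result: dict | None = None,
    metab_result: dict | None = None,
    n_perm: int = 10000,
) -> dict:
    """Procrustes/PROTEST microbiome vs metabolome, dbRDA, grids, regressions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical = bundle.clinical.copy()
    if variant_result is not None:
        clinical["gene_score"] = variant_result["scores"].reindex(clinical.index)

    genus = micro.aggregate_rank(bundle.counts, "genus")
    rel = micro.relative_abundance(genus)
    met_subjects = list(bundle.intensities.index)
    rel_sub = rel[met_subjects]
    bc_micro = micro.bray_curtis(rel_sub)

    if metab_result is not None:
        called = metab_result["volcano"].query("call != 'ns'").index
    else:
        called = bundle.intensities.columns
    M = bundle.intensities[called] if len(called) else bundle.intensities
    logm = np.log1p(M)
    rng_span = logm.max() - logm.min()
    scaled = (logm - logm.min()) / rng_span.replace(0, 1.0)
    bc_metab = micro.bray_curtis(scaled.T)

    nm_micro = integ.nmds(bc_micro, seed=seed)
    nm_metab = integ.nmds(bc_metab, seed=seed + 1)
    proc = integ.procrustes_protest(
        nm_micro["coordinates"], nm_metab["coordinates"], n_perm=n_perm, seed=seed + 2
    )

    constraint_cols = [c for c in ("CARS", "ABC", "gene_score") if c in clinical.columns]
    constraints = clinical.loc[met_subjects, constraint_cols].astype(float)
    rda = integ.db_rda(bc_micro, constraints)

    cases = clinical[clinical["group"] == "ASD"]
    X_cars = pd.DataFrame(
        {"diarrhea": cases["diarrhea"].astype(float),
         "sex_male": (cases["sex"] == "male").astype(float),
         "age": cases["age"].astype(float)}
    )
    reg_cars = integ.multivariable_ols(cases["CARS"], X_cars)
    X_abc = X_cars.assign(insomnia=cases["insomnia"].astype(float))
    reg_abc = integ.multivariable_ols(cases["ABC"], X_abc)

    alpha = micro.alpha_diversity(genus)
    gs = (
        integ.gene_score_association(clinical, alpha[["shannon", "simpson"]])
        if "gene_score" in clinical.columns else None
    )

    meta = dict(seed=seed, n_perm=n_perm)
    _write_json(
        {"procrustes": {"m2": proc.m2, "p": proc.p, "n_perm": proc.n_perm},
         "nmds_stress": {"microbiome": nm_micro["stress"], "metabolome": nm_metab["stress"]}},
        outdir / "procrustes.json", **meta,
    )
    _write_tsv(
        pd.DataFrame({"constrained_proportion": [rda.constrained_proportion]}),
        outdir / "dbrda.tsv", index=False, **meta,
    )
    _write_tsv(
        pd.concat([reg_cars.table.assign(outcome="CARS"), reg_abc.table.assign(outcome="ABC")]),
        outdir / "regression_forest.tsv", **meta,
    )
    if gs is not None:
        _write_tsv(gs, outdir / "gene_score_association.tsv", index=False, **meta)
    return {"procrustes": proc, "nmds_micro": nm_micro, "nmds_metab": nm_metab,
            "dbrda": rda, "reg_cars": reg_cars, "reg_abc": reg_abc,
            "gene_score_association": gs}


def run_all(config: SyntheticConfig, outdir, n_perm_permanova: int = 999,
            n_perm_protest: int = 10000) -> dict:
    """Chain simulate -> variants -> microbiome -> network -> metabolome -> integrate.

    Writes every stage's artifacts plus a cross-stage ``summary.json``;
    idempotent for a fixed config.
    """
    outdir = Path(outdir)
    seed = int(config.seed)
    bundle = stage_simulate(config, outdir / "simulate")
    vres = stage_variants(bundle, outdir / "variants")
    mres = stage_microbiome(bundle, outdir / "microbiome", seed=seed, n_perm=n_perm_permanova)
    nres = stage_network(bundle, outdir / "network", seed=seed)
    metres = stage_metabolome(bundle, outdir / "metabolome", seed=seed)
    ires = stage_integrate(
        bundle, outdir / "integration", seed=seed,
        variant_result=vres, metab_result=metres, n_perm=n_perm_protest,
    )
    summary = {
        "burden": {
            "n_qualifying": len(vres["qualifying"]),
            "cars_p": vres["burden"].cars_p,
            "abc_p": vres["burden"].abc_p,
        },
        "permanova_p": mres["permanova"]["p"],
        "alpha_tests": mres["alpha_tests"],
        "network": nres["metrics"],
        "n_modules": len(metres["partition"].modules),
        "n_volcano_calls": int((metres["volcano"]["call"] != "ns").sum()),
        "procrustes": {"m2": ires["procrustes"].m2, "p": ires["procrustes"].p},
        "dbrda_constrained_proportion": ires["dbrda"].constrained_proportion,
    }
    _write_json(summary, outdir / "summary.json", seed=seed)
    return {"bundle": bundle, "variants": vres, "microbiome": mres,
            "network": nres, "metabolome": metres, "integration": ires,
            "summary": summary}
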
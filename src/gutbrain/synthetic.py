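"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the statistical structure of a 51-case / 51-control
autism-spectrum-disorder (ASD) versus typically-developing (TD) cohort:

* clinical phenotypes (CARS and ABC severity scores, gastrointestinal and
  sleep flags, demographics) with planted diarrhea and insomnia effects;
* a rare-variant layer with qualifying deleterious MUC-pathway variants
  whose per-subject burden is coupled to CARS through a Gaussian copula,
  plus non-qualifying decoys and trio genotypes;
* a genus-level 16S count table drawn from a log-normal relative-abundance
  model with multinomial sampling, planted differential taxa, a planted
  alpha-diversity deficit in cases, and per-group block-correlation
  structure with configurable negative-association fractions;
* a metabolite intensity matrix built from a latent factor model with
  planted co-expression modules correlated with clinical traits, plus
  planted group-shifted metabolites.

Every planted quantity is recorded in a ground-truth ledger so downstream
stages can be tested for parameter recovery.  The same configuration
(including seed) always produces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .microbiome import CountTable, format_lineage
from .variants import CarrierMatrix, TrioGenotype, VariantRecord

# one fixed rng stream id per generator stage, so the stages are
# individually deterministic regardless of call order
_STREAM = {"clinical": 1, "variants": 2, "microbiome": 3, "metabolome": 4, "shared": 5}

MUC_GENES = ("MUC21", "MUC12", "MUC17", "MUC6")

#: genus names given to the first taxa; planted effects use the named ones
NAMED_GENERA = (
    "Faecalibacterium", "Bifidobacterium", "Megamonas", "Prevotella",
    "Bacteroides", "Aeromonas", "Coprococcus", "Lactobacillus",
    "Ruminococcus", "Blautia", "Streptococcus", "Fusicatenibacter",
)

PHYLA = (
    "Firmicutes", "Bacteroidota", "Proteobacteria", "Actinobacteriota",
    "Patescibacteria", "Verrucomicrobiota", "Desulfobacterota", "Fusobacteriota",
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted metabolite co-expression module."""

    size: int
    within_corr: float
    trait: str | None = None  # clinical column the factor tracks, or None
    trait_corr: float = 0.0


def default_module_spec() -> tuple:
    # nine modules, echoing the study's module count; the three
    # diarrhea-linked and one CARS-linked module carry the printed
    # module-trait correlation magnitudes
    return (
        ModuleSpec(150, 0.7, "diarrhea", -0.52),
        ModuleSpec(120, 0.7, "diarrhea", -0.49),
        ModuleSpec(100, 0.7, None, 0.0),
        ModuleSpec(80, 0.7, None, 0.0),
        ModuleSpec(70, 0.7, "diarrhea", 0.41),
        ModuleSpec(60, 0.7, "CARS", 0.40),
        ModuleSpec(50, 0.7, None, 0.0),
        ModuleSpec(40, 0.7, None, 0.0),
        ModuleSpec(35, 0.7, None, 0.0),
    )


def default_case_prevalences() -> dict:
    # ASD-group phenotype frequencies of the study's clinical table
    return {
        "constipation": 36 / 51,
        "diarrhea": 18 / 51,
        "insomnia": 18 / 51,
        "hypersomnia": 11 / 51,
        "luts": 21 / 51,
        "repetitive_behaviors": 42 / 51,
    }


def default_control_prevalences() -> dict:
    # typical background paediatric rates for the TD group
    return {
        "constipation": 0.10,
        "diarrhea": 0.08,
        "insomnia": 0.10,
        "hypersomnia": 0.05,
        "luts": 0.05,
        "repetitive_behaviors": 0.02,
    }


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_cases: int = 51
    n_controls: int = 51
    n_taxa: int = 200
    n_metabolites: int = 1000
    n_variants: int = 200
    # clinical
    burden_effect: float = 0.0  # extra CARS shift per unit planted burden
    burden_cars_rho: float = 0.32
    diarrhea_beta: float = 3.47
    insomnia_beta: float = 14.82
    cars_noise_sd: float = 4.0
    abc_noise_sd: float = 18.0
    prevalences: dict = field(default_factory=default_case_prevalences)
    control_prevalences: dict = field(default_factory=default_control_prevalences)
    male_fraction: float = 36 / 51
    # variants
    n_qualifying: int = 9
    burden_lambda: float = 1.87  # geometric-mean Poisson rate of the true burden
    qualifying_case_enrichment: float = 3.5  # case/control rate ratio of qualifying carriage
    # microbiome
    depth: int = 20_000
    lognormal_sigma: float = 1.5
    shannon_shift: float = 0.2
    n_diff_taxa: int = 10
    diff_fold: float = 5.0
    block_size: int = 8
    block_corr: float = 0.75
    # per-subject shared latent ("gut axis") loading on both a taxon
    # subset and the differential metabolites; drives the cross-omics
    # concordance that Procrustes/PROTEST measures
    omics_coupling: float = 0.8
    n_coupled_taxa: int = 40
    network_negedge_ratio: dict = field(
        default_factory=lambda: {"ASD": 0.25, "TD": 0.45}
    )
    # metabolome
    module_spec: tuple = field(default_factory=default_module_spec)
    n_up_metabolites: int = 20
    n_down_metabolites: int = 68
    diff_log2fc: float = 2.0
    metabolome_per_group: int = 25

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("n_cases and n_controls must both be at least 2")
        if not -1.0 <= self.burden_cars_rho <= 1.0:
            raise ValueError("burden_cars_rho must lie in [-1, 1]")
        for spec in self.module_spec:
            if spec.within_corr >= 1.0 or spec.within_corr < 0.0:
                raise ValueError("within-module correlation must lie in [0, 1)")
            if not -1.0 <= spec.trait_corr <= 1.0:
                raise ValueError("module trait correlation must lie in [-1, 1]")
        for pmap in (self.prevalences, self.control_prevalences):
            for name, frac in pmap.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"prevalence {name} outside [0, 1]")
        for grp, frac in self.network_negedge_ratio.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"negative-edge ratio for {grp} outside [0, 1]")
        if sum(s.size for s in self.module_spec) > self.n_metabolites:
            raise ValueError("module sizes exceed n_metabolites")
        if self.depth < 100:
            raise ValueError("sequencing depth below 100 reads is too sparse")
        if self.qualifying_case_enrichment <= 0:
            raise ValueError("qualifying_case_enrichment must be positive")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """A configuration with every planted effect set to zero.

        Useful for type-I-error calibration of the downstream tests: no
        burden-severity coupling, no case enrichment of qualifying
        variants, no clinical betas, no diversity shift, no differential
        taxa or metabolites, no module-trait coupling, equal
        negative-edge fractions.
        """
        spec = tuple(
            ModuleSpec(s.size, s.within_corr, None, 0.0)
            for s in default_module_spec()
        )
        defaults = dict(
            seed=seed,
            burden_cars_rho=0.0,
            qualifying_case_enrichment=1.0,
            diarrhea_beta=0.0,
            insomnia_beta=0.0,
            shannon_shift=0.0,
            n_diff_taxa=0,
            n_up_metabolites=0,
            n_down_metabolites=0,
            module_spec=spec,
            network_negedge_ratio={"ASD": 0.35, "TD": 0.35},
            omics_coupling=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticBundle:
    clinical: pd.DataFrame
    variants: list
    carriers: CarrierMatrix
    trios: list
    counts: CountTable
    intensities: pd.DataFrame
    truth: dict


def _rng(config: SyntheticConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stage]])


def _shared_axis(config: SyntheticConfig) -> np.ndarray:
    """Per-subject latent gut-axis score shared by microbiome and metabolome."""
    rng = _rng(config, "shared")
    return rng.standard_normal(config.n_cases + config.n_controls)


# ---------------------------------------------------------------- clinical


def gen_clinical(config: SyntheticConfig) -> pd.DataFrame:
    """Clinical table: group labels, phenotype flags, CARS and ABC scores.

    CARS = baseline + diarrhea_beta * diarrhea + N(0, cars_noise_sd);
    ABC = baseline + insomnia_beta * insomnia + N(0, abc_noise_sd); both
    clipped to their scale ranges ([15, 60] and [0, 158]).  The noise
    scales give the planted effects detection power >= 0.8 at the default
    cohort size.
    """
    config.validate()
    rng = _rng(config, "clinical")
    n_cases, n_controls = config.n_cases, config.n_controls
    ids = [f"A{i+1:03d}" for i in range(n_cases)] + [
        f"T{i+1:03d}" for i in range(n_controls)
    ]
    group = ["ASD"] * n_cases + ["TD"] * n_controls
    n = n_cases + n_controls

    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age = np.clip(rng.normal(5.0, 1.5, size=n), 2.0, 10.0).round(1)
    income = rng.choice(
        ["<50k", "50-100k", "100-500k"], size=n, p=[21 / 51, 25 / 51, 5 / 51]
    )
    father_edu = rng.choice(
        ["junior_high", "senior_high", "junior_college", "bachelor", "master"],
        size=n,
        p=[18 / 51, 14 / 51, 15 / 51, 3 / 51, 1 / 51],
    )
    mother_edu = rng.choice(
        ["junior_high", "senior_high", "junior_college", "bachelor", "master"],
        size=n,
        p=[18 / 51, 12 / 51, 6 / 51, 12 / 51, 3 / 51],
    )

    flags = {}
    for name in default_case_prevalences():
        p_case = config.prevalences.get(name, 0.0)
        p_ctrl = config.control_prevalences.get(name, 0.0)
        draw = rng.random(n)
        flags[name] = (
            draw < np.where(np.arange(n) < n_cases, p_case, p_ctrl)
        ).astype(int)

    is_case = np.arange(n) < n_cases
    cars = np.where(
        is_case,
        35.5 + config.diarrhea_beta * flags["diarrhea"] + rng.normal(0, config.cars_noise_sd, n),
        17.5 + rng.normal(0, 1.5, n),
    )
    abc = np.where(
        is_case,
        55.0 + config.insomnia_beta * flags["insomnia"] + rng.normal(0, config.abc_noise_sd, n),
        12.0 + rng.normal(0, 6.0, n),
    )
    cars = np.clip(cars, 15.0, 60.0).round(2)
    abc = np.clip(abc, 0.0, 158.0).round(2)

    df = pd.DataFrame(
        {
            "group": group,
            "sex": sex,
            "age": age,
            "income": income,
            "father_edu": father_edu,
            "mother_edu": mother_edu,
            **flags,
            "CARS": cars,
            "ABC": abc,
        },
        index=pd.Index(ids, name="subject"),
    )
    df["subgroup"] = np.where(
        df["group"] == "TD", "TD", np.where(df["diarrhea"] == 1, "ASD_D", "ASD_noD")
    )
    return df


# ---------------------------------------------------------------- variants


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def _calibrate_copula_mixing(
    cars: np.ndarray,
    lam_subject: np.ndarray,
    rho_target: float,
    n_qual: int,
    n_rep: int = 150,
) -> float:
    """Numerically solve the Gaussian-copula mixing coefficient.

    The true burden is qpois(Phi(a*v + sqrt(1-a^2)*eps), lam_i) with v the
    normal scores of the CARS ranks.  Because the Poisson discretization
    and any case enrichment of lam_i both distort the rank correlation,
    the mixing ``a`` is found by bisection against a Monte-Carlo estimate
    (internal fixed-seed stream) of E[Spearman(burden, CARS)], so the
    cohort-level coupling hits ``rho_target`` regardless of those
    distortions.
    """
    n = len(cars)
    cars_ranks = stats.rankdata(cars)
    v = stats.norm.ppf((cars_ranks - 0.5) / n)
    cal_rng = np.random.default_rng(987654321)
    eps = cal_rng.standard_normal((n_rep, n))
    rc = (cars_ranks - cars_ranks.mean()) / np.sqrt(((cars_ranks - cars_ranks.mean()) ** 2).sum())

    def mean_rho(a: float) -> float:
        u = a * v + np.sqrt(max(1.0 - a * a, 0.0)) * eps
        b = np.minimum(stats.poisson.ppf(stats.norm.cdf(u), lam_subject), n_qual)
        rb = stats.rankdata(b, axis=1)
        rb = rb - rb.mean(axis=1, keepdims=True)
        norms = np.sqrt((rb**2).sum(axis=1))
        ok = norms > 0
        if not ok.any():
            return 0.0
        return float(((rb[ok] / norms[ok, None]) @ rc).mean())

    lo, hi = -0.999, 0.999
    if mean_rho(lo) >= rho_target:
        return lo
    if mean_rho(hi) <= rho_target:
        return hi
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if mean_rho(mid) < rho_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _copula_burden(
    rng: np.random.Generator,
    cars: np.ndarray,
    is_case: np.ndarray,
    rho_s: float,
    lam: float,
    enrichment: float,
    n_qual: int,
) -> np.ndarray:
    """True burden counts: Gaussian copula against CARS plus case enrichment.

    Per-subject Poisson rates are lam*sqrt(enrichment) for cases and
    lam/sqrt(enrichment) for controls; the copula mixing is calibrated so
    the realized cohort-level Spearman(burden, CARS) matches ``rho_s``.
    """
    n = len(cars)
    lam_subject = np.where(is_case, lam * np.sqrt(enrichment), lam / np.sqrt(enrichment))
    a = _calibrate_copula_mixing(cars, lam_subject, rho_s, n_qual)
    v = stats.norm.ppf((stats.rankdata(cars) - 0.5) / n)
    u = a * v + np.sqrt(max(1.0 - a * a, 0.0)) * rng.standard_normal(n)
    b = stats.poisson.ppf(stats.norm.cdf(u), lam_subject).astype(int)
    return np.minimum(b, n_qual)


def _qualifying_records(n_qualifying: int) -> list[dict]:
    """Annotation skeletons for the planted MUC-pathway qualifying variants."""
    base = [
        # gene, vtype, revel, n_damaging_tools, gnomad_af
        ("MUC17", "missense", 0.81, 4, 0.0225),
        ("MUC17", "missense", None, 3, 0.0312),
        ("MUC6", "missense", 0.92, 5, 0.0),
        ("MUC6", "missense", 0.85, 4, 1.878e-05),
        ("MUC6", "missense", None, 4, 5.531e-06),
        ("MUC6", "missense", 0.78, 2, 0.0),
        ("MUC6", "missense", None, 3, 0.0065),
        ("MUC21", "frameshift", None, 0, 0.0081),
        ("MUC12", "missense", 0.88, 3, 0.0023),
    ]
    reps = [base[i % len(base)] for i in range(n_qualifying)]
    return [
        {
            "gene": g,
            "vtype": t,
            "revel": r,
            "n_damaging": nd,
            "gnomad_af": af,
        }
        for g, t, r, nd, af in reps
    ]


_TOOLS = ("SIFT", "PolyPhen2_HDIV", "PolyPhen2_HVAR", "LRT", "MutationTaster")


def _tool_calls(n_damaging: int) -> dict:
    return {
        tool: ("damaging" if i < n_damaging else "benign")
        for i, tool in enumerate(_TOOLS)
    }


def gen_variants(
    config: SyntheticConfig, clinical: pd.DataFrame
) -> tuple[list, CarrierMatrix, list]:
    """Variant annotations, subject carrier matrix, and trio genotypes.

    Qualifying variants (deleterious, rare, exonic, in MUC-pathway genes)
    are carried so that the per-subject true burden follows the CARS
    copula at ``burden_cars_rho``; decoys fail at least one cascade stage
    and are carried symmetrically between groups.  Trios follow the
    study's mix: mostly de novo plus one maternally inherited variant.
    """
    config.validate()
    rng = _rng(config, "variants")
    subjects = list(clinical.index)
    n = len(subjects)
    n_cases = int((clinical["group"] == "ASD").sum())

    qual = _qualifying_records(config.n_qualifying)
    n_qual = len(qual)
    burden = _copula_burden(
        rng,
        clinical["CARS"].values,
        (clinical["group"] == "ASD").values,
        config.burden_cars_rho,
        config.burden_lambda,
        config.qualifying_case_enrichment,
        n_qual,
    )

    geno = np.zeros((n, config.n_variants), dtype=int)
    for i in range(n):
        carried = rng.choice(n_qual, size=burden[i], replace=False)
        for j in carried:
            geno[i, j] = 2 if rng.random() < 0.05 else 1

    # decoys: one disqualifying feature each, carriage symmetric by group
    decoy_kinds = ("intronic", "synonymous", "common", "benign_missense",
                   "utr", "inframe", "balanced_deleterious")
    records: list[VariantRecord] = []
    variant_ids = []
    for j in range(config.n_variants):
        vid = f"var{j+1:04d}"
        variant_ids.append(vid)
    for j, spec in enumerate(qual):
        vid = variant_ids[j]
        case_c = int((geno[:n_cases, j] > 0).sum())
        ctrl_c = int((geno[n_cases:, j] > 0).sum())
        records.append(
            VariantRecord(
                variant_id=vid,
                gene=spec["gene"],
                region="exonic",
                vtype=spec["vtype"],
                case_carriers=case_c,
                control_carriers=ctrl_c,
                n_cases=n_cases,
                n_controls=n - n_cases,
                revel=spec["revel"],
                tool_calls=_tool_calls(spec["n_damaging"]),
                gnomad_af=spec["gnomad_af"] if spec["gnomad_af"] > 0 else None,
            )
        )
    for j in range(n_qual, config.n_variants):
        kind = decoy_kinds[(j - n_qual) % len(decoy_kinds)]
        p_carry = rng.uniform(0.02, 0.2)
        col = (rng.random(n) < p_carry).astype(int)
        col[col > 0] = np.where(rng.random(int(col.sum())) < 0.05, 2, 1)
        geno[:, j] = col
        gene = f"GENE{j+1:04d}"
        region, vtype, revel, nd, af = "exonic", "missense", 0.2, 1, rng.uniform(1e-4, 0.04)
        if kind == "intronic":
            region = "intronic"
            nd = 3
        elif kind == "synonymous":
            vtype = "synonymous"
            revel, nd = None, 0
        elif kind == "common":
            nd, af = 4, rng.uniform(0.05, 0.4)
            revel = 0.9
        elif kind == "benign_missense":
            revel, nd = 0.3, 1
        elif kind == "utr":
            region, vtype, revel, nd = "UTR", "other", None, 0
        elif kind == "inframe":
            vtype = "nonframeshift_indel"
            revel, nd = None, 0
        elif kind == "balanced_deleterious":
            revel, nd = 0.85, 4  # deleterious and rare but group-balanced
        records.append(
            VariantRecord(
                variant_id=variant_ids[j],
                gene=gene,
                region=region,
                vtype=vtype,
                case_carriers=int((geno[:n_cases, j] > 0).sum()),
                control_carriers=int((geno[n_cases:, j] > 0).sum()),
                n_cases=n_cases,
                n_controls=n - n_cases,
                revel=revel,
                tool_calls=_tool_calls(nd),
                gnomad_af=float(af) if af else None,
            )
        )

    carriers = CarrierMatrix(subjects, variant_ids, geno)

    # trios for the first 12 case probands: 11 de novo, 1 maternal
    trio_variants = variant_ids[n_qual : n_qual + 12]
    trios = []
    for k, vid in enumerate(trio_variants):
        if k == 8:  # the study's single maternally inherited variant
            trios.append(TrioGenotype(vid, 1, 1, 0))
        else:
            trios.append(TrioGenotype(vid, 1, 0, 0))

    truth = {
        "qualifying_variants": variant_ids[:n_qual],
        "true_burden": {s: int(b) for s, b in zip(subjects, burden)},
        "trio_origins": {
            t.variant: ("maternal" if t.mother > 0 else "de_novo") for t in trios
        },
    }
    return records, carriers, trios, truth


# -------------------------------------------------------------- microbiome


def _negedge_member_fraction(target: float) -> float:
    """Fraction of negatively-signed block members giving the target
    negative-pair fraction 2f(1-f) within a block."""
    target = min(target, 0.5)
    return 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * target))


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def gen_microbiome(config: SyntheticConfig, clinical: pd.DataFrame) -> tuple:
    """Genus-level count table with planted group structure.

    Counts are multinomial draws at the configured depth from per-sample
    log-normal relative abundances.  Planted differential taxa get the
    configured fold change; cases carry a calibrated suppression of
    low-abundance taxa so the expected Shannon difference approximates
    ``shannon_shift``; per-group block-correlated latent noise with a
    signed pattern realizes the configured negative-association fraction.
    """
    config.validate()
    rng = _rng(config, "microbiome")
    n_taxa = config.n_taxa
    samples = list(clinical.index)
    groups = clinical["group"]

    genus_names = list(NAMED_GENERA[: min(len(NAMED_GENERA), n_taxa)])
    genus_names += [f"Genus_{i+1:03d}" for i in range(len(genus_names), n_taxa)]
    phyla = rng.choice(PHYLA, size=n_taxa, p=[0.35, 0.25, 0.12, 0.12, 0.04, 0.04, 0.04, 0.04])
    lineages = [
        format_lineage(
            ["Bacteria", phyla[i], f"Class_{phyla[i][:4]}", f"Order_{i % 30 + 1:02d}",
             f"Family_{i % 60 + 1:02d}", genus_names[i], ""]
        )
        for i in range(n_taxa)
    ]

    mu = rng.normal(0.0, 2.0, size=n_taxa)

    # planted differential taxa: named genera, decently abundant
    n_diff = min(config.n_diff_taxa, n_taxa)
    half = n_diff // 2
    asd_up = [genus_names.index(g) for g in ("Bifidobacterium", "Aeromonas", "Prevotella", "Lactobacillus", "Streptococcus")][: n_diff - half]
    td_up = [genus_names.index(g) for g in ("Faecalibacterium", "Bacteroides", "Coprococcus", "Ruminococcus", "Blautia")][:half]
    megamonas = (
        genus_names.index("Megamonas")
        if n_diff > 0 and "Megamonas" in genus_names
        else None
    )
    abundant_floor = np.quantile(mu, 0.6)
    for idx in asd_up + td_up + ([megamonas] if megamonas is not None else []):
        mu[idx] = max(mu[idx], abundant_floor)

    log_fold = np.log(config.diff_fold)
    mu_case = mu.copy()
    for idx in asd_up:
        mu_case[idx] += log_fold
    for idx in td_up:
        mu_case[idx] -= log_fold

    # calibrate the number of case-absent taxa for the planted Shannon
    # deficit: knock out k randomly chosen (non-planted) taxa in case
    # samples, with k solved against a Monte-Carlo estimate of the
    # expected per-sample Shannon under the log-normal noise
    planted = set(asd_up + td_up + ([megamonas] if megamonas is not None else []))
    eligible = np.array([i for i in range(n_taxa) if i not in planted], dtype=int)
    eligible = eligible[rng.permutation(len(eligible))]
    sigma = config.lognormal_sigma
    cal_rng = np.random.default_rng(24681357)
    z_cal = cal_rng.standard_normal((60, n_taxa))

    def expected_shannon(base: np.ndarray, knockout: np.ndarray) -> float:
        logw = base + sigma * z_cal
        logw[:, knockout] -= 12.0  # effectively absent
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        p = w / w.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
        return float(h.mean())

    n_knockout = 0
    if config.shannon_shift > 0:
        h_td = expected_shannon(mu, np.array([], dtype=int))
        target = h_td - config.shannon_shift
        lo, hi = 0, len(eligible)
        if expected_shannon(mu_case, eligible) <= target:
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if expected_shannon(mu_case, eligible[:mid]) > target:
                    lo = mid
                else:
                    hi = mid
            n_knockout = hi
        else:
            n_knockout = len(eligible)
    suppress_set = eligible[:n_knockout]

    # per-group signed block-correlation structure
    order = rng.permutation(n_taxa)
    blocks = [order[i : i + config.block_size] for i in range(0, n_taxa, config.block_size)]
    # one sign vector per group; identical target fractions share one
    # realization so the two groups stay exchangeable under the null
    f_asd = _negedge_member_fraction(config.network_negedge_ratio.get("ASD", 0.0))
    f_td = _negedge_member_fraction(config.network_negedge_ratio.get("TD", 0.0))
    signs = {"ASD": np.where(rng.random(n_taxa) < f_asd, -1.0, 1.0)}
    signs["TD"] = (
        signs["ASD"] if f_td == f_asd else np.where(rng.random(n_taxa) < f_td, -1.0, 1.0)
    )

    # taxa loading on the shared gut-axis latent (abundant, non-planted)
    axis = _shared_axis(config)
    coupled = np.array([], dtype=int)
    coupled_signs = np.array([])
    if config.omics_coupling > 0 and config.n_coupled_taxa > 0:
        abundant = [i for i in np.argsort(mu)[::-1] if i not in planted]
        coupled = np.array(abundant[: config.n_coupled_taxa], dtype=int)
        coupled_signs = np.where(rng.random(len(coupled)) < 0.5, -1.0, 1.0)

    counts = np.zeros((n_taxa, len(samples)), dtype=int)
    diarrhea = clinical["diarrhea"].values
    for j, subj in enumerate(samples):
        grp = groups.iloc[j]
        z = rng.standard_normal(n_taxa)
        latent = np.sqrt(1.0 - config.block_corr) * z
        s_vec = signs[grp]
        for block in blocks:
            shared = rng.standard_normal()
            latent[block] += np.sqrt(config.block_corr) * shared * s_vec[block]
        base = mu_case.copy() if grp == "ASD" else mu.copy()
        if grp == "ASD" and megamonas is not None and diarrhea[j] == 1:
            base[megamonas] += log_fold
        logw = base + sigma * latent
        if coupled.size:
            logw[coupled] += config.omics_coupling * axis[j] * coupled_signs
        if grp == "ASD" and suppress_set.size:
            logw[suppress_set] -= 12.0
        w = np.exp(logw - logw.max())
        counts[:, j] = rng.multinomial(config.depth, w / w.sum())

    table = CountTable(lineages, samples, counts, sample_groups=groups)
    truth = {
        "asd_enriched": [genus_names[i] for i in asd_up],
        "td_enriched": [genus_names[i] for i in td_up],
        "asd_d_biomarker": genus_names[megamonas] if megamonas is not None else None,
        "diff_fold": config.diff_fold,
        "n_knockout_taxa": int(n_knockout),
        "expected_shannon_shift": config.shannon_shift,
        "negedge_member_fraction": {
            g: float(_negedge_member_fraction(config.network_negedge_ratio.get(g, 0.0)))
            for g in ("ASD", "TD")
        },
    }
    return table, truth


# -------------------------------------------------------------- metabolome


def gen_metabolome(config: SyntheticConfig, clinical: pd.DataFrame) -> tuple:
    """Metabolite intensity matrix from a planted factor model.

    Each planted module has one latent factor, correlated with its
    configured clinical trait; member metabolites load on the factor so
    pairwise within-module correlation equals the configured level.
    Remaining metabolites are independent noise, a planted subset of which
    is group-shifted (the differential metabolites).  Intensities are
    exp-transformed to the non-negative raw scale.
    """
    config.validate()
    rng = _rng(config, "metabolome")
    cases = clinical.index[clinical["group"] == "ASD"][: config.metabolome_per_group]
    ctrls = clinical.index[clinical["group"] == "TD"][: config.metabolome_per_group]
    subjects = list(cases) + list(ctrls)
    clin = clinical.loc[subjects]
    n = len(subjects)
    p = config.n_metabolites
    names = [f"M{j+1:04d}" for j in range(p)]

    log_int = np.zeros((n, p))
    mu_m = rng.normal(12.0, 1.5, size=p)
    truth_modules = {}
    truth_traits = {}
    case_mask = (clin["group"] == "ASD").values
    col = 0
    for k, spec in enumerate(config.module_spec):
        label = f"module_{k+1:02d}"
        if spec.trait is not None:
            # the trait coupling is planted within the case subset only
            # (severity scores and GI flags are case phenotypes); control
            # samples get pure factor noise, so trait-linked modules are
            # not group-differential by construction
            t = clin[spec.trait].astype(float).values
            t_case = t[case_mask]
            if np.ptp(t_case) == 0:
                t_std = np.zeros(case_mask.sum())
            else:
                t_std = (t_case - t_case.mean()) / t_case.std()
            rho = spec.trait_corr
            factor = rng.standard_normal(n)
            factor[case_mask] = (
                rho * t_std
                + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(case_mask.sum())
            )
        else:
            factor = rng.standard_normal(n)
        loading = np.sqrt(spec.within_corr)
        members = names[col : col + spec.size]
        for j in range(spec.size):
            noise = rng.standard_normal(n)
            latent = loading * factor + np.sqrt(1.0 - spec.within_corr) * noise
            log_int[:, col + j] = mu_m[col + j] + 0.8 * latent
        truth_modules[label] = members
        truth_traits[label] = {"trait": spec.trait, "r": spec.trait_corr}
        col += spec.size

    # planted differential metabolites among the leftover noise features;
    # they also load on the shared gut-axis latent (aligned with their
    # shift direction), giving the continuous between-subject variation
    # that couples the metabolome to the microbiome
    is_case = np.array([s in set(cases) for s in subjects], dtype=float)
    positions = [list(clinical.index).index(s) for s in subjects]
    axis = _shared_axis(config)[positions]
    shift = config.diff_log2fc * np.log(2.0)
    n_up, n_down = config.n_up_metabolites, config.n_down_metabolites
    up_idx = list(range(col, min(col + n_up, p)))
    down_idx = list(range(col + n_up, min(col + n_up + n_down, p)))
    for j in range(col, p):
        log_int[:, j] = mu_m[j] + 0.8 * rng.standard_normal(n)
    for j in up_idx:
        log_int[:, j] += shift * is_case + 0.5 * config.omics_coupling * axis
    for j in down_idx:
        log_int[:, j] -= shift * is_case + 0.5 * config.omics_coupling * axis

    intensities = pd.DataFrame(
        np.exp(log_int), index=pd.Index(subjects, name="subject"), columns=names
    )
    truth = {
        "modules": truth_modules,
        "module_traits": truth_traits,
        "diff_up": [names[j] for j in up_idx],
        "diff_down": [names[j] for j in down_idx],
        "diff_log2fc": config.diff_log2fc,
        # the group-shifted metabolites are mutually correlated through
        # the case indicator, so an unsigned co-expression analysis will
        # legitimately see them as one extra module
        "group_module": [names[j] for j in up_idx + down_idx],
    }
    return intensities, truth


# ---------------------------------------------------------------- bundle


def simulate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full synthetic cohort with its ground-truth ledger."""
    config.validate()
    clinical = gen_clinical(config)
    records, carriers, trios, vtruth = gen_variants(config, clinical)
    if config.burden_effect != 0.0:
        extra = np.array([vtruth["true_burden"][s] for s in clinical.index], float)
        clinical = clinical.copy()
        clinical["CARS"] = np.clip(
            clinical["CARS"] + config.burden_effect * extra, 15.0, 60.0
        )
    counts, mtruth = gen_microbiome(config, clinical)
    intensities, metruth = gen_metabolome(config, clinical)
    truth = {
        "config_seed": int(config.seed),
        "variants": vtruth,
        "microbiome": mtruth,
        "metabolome": metruth,
    }
    return SyntheticBundle(clinical, records, carriers, trios, counts, intensities, truth)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict:
    """Write the bundle as the pipeline's on-disk interchange formats.

    Tab-separated tables (counts.tsv carries the semicolon lineage in its
    first column), intensities as CSV, truth as JSON; deterministic row
    order; UTF-8.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["clinical"] = outdir / "clinical.tsv"
    bundle.clinical.to_csv(paths["clinical"], sep="\t")

    vrows = []
    for v in bundle.variants:
        row = {
            "variant_id": v.variant_id, "gene": v.gene, "cytoband": v.cytoband,
            "region": v.region, "vtype": v.vtype, "transcript": v.transcript,
            "cdna_change": v.cdna_change, "aa_change": v.aa_change,
            "revel": "" if v.revel is None else v.revel,
            "gnomad_af": "" if v.gnomad_af is None else v.gnomad_af,
            "case_carriers": v.case_carriers, "control_carriers": v.control_carriers,
            "n_cases": v.n_cases, "n_controls": v.n_controls,
        }
        for tool in _TOOLS:
            row[tool] = v.tool_calls.get(tool, "missing")
        vrows.append(row)
    paths["variants"] = outdir / "variants.tsv"
    pd.DataFrame(vrows).to_csv(paths["variants"], sep="\t", index=False)

    paths["carriers"] = outdir / "carriers.tsv"
    bundle.carriers.to_frame().rename_axis("subject").to_csv(paths["carriers"], sep="\t")

    paths["trios"] = outdir / "trios.tsv"
    pd.DataFrame(
        [{"variant": t.variant, "proband": t.proband, "mother": t.mother, "father": t.father}
         for t in bundle.trios]
    ).to_csv(paths["trios"], sep="\t", index=False)

    paths["counts"] = outdir / "counts.tsv"
    bundle.counts.to_frame().rename_axis("lineage").to_csv(paths["counts"], sep="\t")

    paths["intensities"] = outdir / "intensities.csv"
    bundle.intensities.to_csv(paths["intensities"])

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return paths
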
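"""Rare deleterious variant filtering and pathway burden scoring.

Implements the susceptibility-variant cascade used for the mucin (MUC)
pathway analysis: a per-variant case/control Fisher exact test, restriction
to protein-coding exons, a deleteriousness rule (protein-truncating
variants, or missense calls supported by REVEL > 0.75 or a two-tool
consensus), a gnomAD rarity filter (< 5%), trio-origin annotation,
per-subject burden scores over a gene set, median stratification with
phenotype comparison, and a hypergeometric gene-set over-representation
test.

Conventions (all configurable where noted):

* The Fisher test operates on carrier counts (subjects with at least one
  alternate allele), not allele counts.
* Burden counts distinct qualifying variants per subject, not allele
  dosage.
* Ties at the median burden fall into the LOW stratum ("high burden" is a
  strict exceedance).
* Missing prediction scores never count as damaging; a missing gnomAD
  frequency is treated as 0 (a novel variant passes the rarity filter).
* Mode of inheritance is annotation only and never filters variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, mann_whitney_p

PTV_TYPES = frozenset({"frameshift", "nonsense", "stoploss"})
PREDICTION_TOOLS = (
    "SIFT",
    "PolyPhen2_HDIV",
    "PolyPhen2_HVAR",
    "LRT",
    "MutationTaster",
)
REVEL_CUTOFF = 0.75
MIN_DAMAGING_TOOLS = 2


@dataclass
class VariantRecord:
    """One annotated variant with cohort carrier counts."""

    variant_id: str
    gene: str
    region: str  # exonic / intronic / UTR / regulatory / intergenic / splicing
    vtype: str  # missense / nonsense / stoploss / frameshift / nonframeshift_indel / synonymous / other
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    cytoband: str = ""
    transcript: str = ""
    cdna_change: str = ""
    aa_change: str = ""
    revel: float | None = None
    tool_calls: Mapping[str, str] = field(default_factory=dict)
    gnomad_af: float | None = None

    def __post_init__(self) -> None:
        if self.case_carriers > self.n_cases or self.control_carriers > self.n_controls:
            raise ValueError(f"{self.variant_id}: carrier count exceeds cohort size")
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"{self.variant_id}: gnomAD AF outside [0, 1]")
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError(f"{self.variant_id}: REVEL outside [0, 1]")


@dataclass
class CarrierMatrix:
    """Subjects x variants genotype counts in {0, 1, 2}."""

    subjects: list[str]
    variants: list[str]
    genotype: np.ndarray

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=int)
        if self.genotype.shape != (len(self.subjects), len(self.variants)):
            raise ValueError("genotype matrix shape does not match labels")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject identifiers")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant identifiers")
        if not np.isin(self.genotype, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genotype, index=self.subjects, columns=self.variants)


@dataclass(frozen=True)
class TrioGenotype:
    """Allele counts for one variant in a proband-mother-father trio."""

    variant: str
    proband: int
    mother: int
    father: int

    def __post_init__(self) -> None:
        for v in (self.proband, self.mother, self.father):
            if v not in (0, 1, 2):
                raise ValueError("trio allele counts must be in {0, 1, 2}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums the hypergeometric probabilities of all tables
    (with the observed margins) at most as likely as the observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def is_deleterious(v: VariantRecord) -> bool:
    """Deleteriousness rule: PTV, or missense with REVEL > 0.75 or >=2 damaging tool calls."""
    if v.vtype in PTV_TYPES:
        return True
    if v.vtype != "missense":
        return False
    if v.revel is not None and v.revel > REVEL_CUTOFF:
        return True
    n_damaging = sum(
        1 for tool in PREDICTION_TOOLS if v.tool_calls.get(tool) == "damaging"
    )
    return n_damaging >= MIN_DAMAGING_TOOLS


def filter_variants(
    variants: Sequence[VariantRecord],
    alpha: float = 0.05,
    max_af: float = 0.05,
    include_splicing: bool = False,
    include_inframe: bool = False,
) -> list[VariantRecord]:
    """Apply the full susceptibility cascade, preserving input order.

    Stages: Fisher exact carrier-count test (p < alpha), coding-region
    restriction (exonic, optionally splicing), deleteriousness, gnomAD
    rarity (< max_af; missing treated as 0).  ``include_inframe`` admits
    non-frameshift indels as deleterious.
    """
    regions = {"exonic"} | ({"splicing"} if include_splicing else set())
    out = []
    for v in variants:
        if v.region not in regions:
            continue
        deleterious = is_deleterious(v) or (
            include_inframe and v.vtype == "nonframeshift_indel"
        )
        if not deleterious:
            continue
        af = 0.0 if v.gnomad_af is None else v.gnomad_af
        if af >= max_af:
            continue
        p = fisher_exact_2x2(
            v.case_carriers,
            v.n_cases - v.case_carriers,
            v.control_carriers,
            v.n_controls - v.control_carriers,
        )
        if p < alpha:
            out.append(v)
    return out


def classify_trio_origin(t: TrioGenotype) -> str:
    """de_novo / maternal / paternal / biparental / uncertain from trio allele counts."""
    if t.proband == 0:
        return "uncertain"
    if t.mother == 0 and t.father == 0:
        return "de_novo"
    if t.mother > 0 and t.father > 0:
        return "biparental"
    return "maternal" if t.mother > 0 else "paternal"


def burden_scores(
    carriers: CarrierMatrix,
    qualifying: Iterable[str],
    gene_set: GeneSet,
    variant_gene: Mapping[str, str],
    count_alleles: bool = False,
) -> pd.Series:
    """Per-subject burden: qualifying variants in gene-set genes carried.

    With ``count_alleles`` the score sums genotype dosage instead of
    counting distinct carried variants.
    """
    qualifying = list(qualifying)
    unknown = [q for q in qualifying if q not in set(carriers.variants)]
    if unknown:
        raise ValueError(f"unknown variant identifiers: {unknown}")
    cols = [
        q
        for q in qualifying
        if variant_gene.get(q) in gene_set.genes
    ]
    idx = [carriers.variants.index(c) for c in cols]
    geno = carriers.genotype[:, idx] if idx else np.zeros((len(carriers.subjects), 0), dtype=int)
    if count_alleles:
        scores = geno.sum(axis=1)
    else:
        scores = (geno > 0).sum(axis=1)
    return pd.Series(scores, index=carriers.subjects, name="burden")


@dataclass
class BurdenResult:
    scores: pd.Series
    median: float
    stratum: pd.Series  # "high" / "low"
    cars_p: float
    abc_p: float
    gi_tests: dict  # phenotype -> {"odds_ratio": ..., "p": ...}
    degenerate: bool = False


def stratify_and_compare(scores: pd.Series, clinical: pd.DataFrame) -> BurdenResult:
    """Median split of burden scores and phenotype comparison across strata.

    The high stratum is a strict exceedance of the median.  CARS and ABC
    are compared by two-sided Mann-Whitney; binary GI phenotypes
    (constipation, diarrhea) by Fisher exact test with odds ratio.
    """
    common = scores.index.intersection(clinical.index)
    if len(common) < 4:
        raise ValueError("need at least 4 subjects with clinical data")
    scores = scores.loc[common]
    clin = clinical.loc[common]
    med = float(scores.median())
    stratum = pd.Series(
        np.where(scores.values > med, "high", "low"), index=scores.index, name="stratum"
    )
    if (stratum == "high").sum() == 0 or (stratum == "low").sum() == 0:
        return BurdenResult(
            scores, med, stratum, float("nan"), float("nan"), {}, degenerate=True
        )
    hi = stratum == "high"
    cars_p = mann_whitney_p(clin.loc[hi, "CARS"], clin.loc[~hi, "CARS"])
    abc_p = mann_whitney_p(clin.loc[hi, "ABC"], clin.loc[~hi, "ABC"])
    gi_tests = {}
    for pheno in ("constipation", "diarrhea"):
        if pheno not in clin.columns:
            continue
        flag = clin[pheno].astype(bool)
        a = int((hi & flag).sum())
        b = int((hi & ~flag).sum())
        c = int((~hi & flag).sum())
        d = int((~hi & ~flag).sum())
        orat, p = stats.fisher_exact([[a, b], [c, d]])
        gi_tests[pheno] = {"odds_ratio": float(orat), "p": float(p)}
    return BurdenResult(scores, med, stratum, cars_p, abc_p, gi_tests)


def geneset_enrichment(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of query genes per set.

    Gene sets are intersected with the universe; p is the upper tail of the
    hypergeometric distribution of the observed overlap; q is BH-adjusted
    across the collection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    rows = []
    for gs in collection:
        genes = gs.genes & universe
        overlap = len(query & genes)
        # upper-tail P(X >= overlap) for X ~ Hypergeom(M=|U|, n=|set|, N=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(genes), len(query)))
        rows.append(
            {
                "set": gs.name,
                "overlap": overlap,
                "set_size": len(genes),
                "universe_size": len(universe),
                "query_size": len(query),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = np.maximum(bh_adjust(df["p"].values), df["p"].values)
    return df
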
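"""Recessive ultra-rare variant prioritization.

Implements the gene-discovery chain used for consanguineous proband cohorts:
ultra-rare filtering against a population allele-frequency reference,
bi-allelic genotype calling (homozygous or compound heterozygous), exact
cross-proband gene intersection restricted to coding or non-coding genes,
and screening of a candidate gene panel across a cohort.

Conventions
-----------
* Allele frequencies are per-alt (multi-allelic records must be decomposed
  upstream); a *missing* frequency means the allele is absent from the
  reference panel and is treated as ultra-rare.
* The MAF threshold is a strict inequality.
* Compound-het calls without phase information are reported but flagged as
  ``compound_het_phase_unknown``; they are never silently promoted to
  in-trans calls.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "VariantCall",
    "BiallelicCall",
    "PanelDefinition",
    "filter_ultra_rare",
    "call_biallelic",
    "intersect_candidate_genes",
    "screen_panel",
]

Genotype = Literal["het", "hom_alt"]
Origin = Literal["maternal", "paternal", "unknown"]
Mechanism = Literal["homozygous", "compound_het_trans", "compound_het_phase_unknown"]


@dataclass(frozen=True)
class VariantCall:
    """One observed alt allele in one sample."""

    sample_id: str
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    genotype: Genotype
    gene: str
    coding: bool
    population_af: float | None = None  # None = absent from the reference panel
    parental_origin: Origin = "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref ({self.ref}) at {self.chromosome}:{self.position}")
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError(f"population_af out of [0,1]: {self.population_af}")


@dataclass(frozen=True)
class BiallelicCall:
    """A gene in one sample with both copies plausibly affected."""

    sample_id: str
    gene: str
    mechanism: Mechanism
    variants: tuple[VariantCall, ...]

    def __post_init__(self) -> None:
        if self.mechanism == "homozygous":
            if len(self.variants) != 1 or self.variants[0].genotype != "hom_alt":
                raise ValueError("homozygous call requires exactly one hom_alt variant")
        else:
            hets = [v for v in self.variants if v.genotype == "het"]
            if len(hets) < 2:
                raise ValueError("compound het call requires >= 2 het variants")

    @property
    def coding(self) -> bool:
        return any(v.coding for v in self.variants)


@dataclass
class PanelDefinition:
    """A candidate gene panel with per-gene coding flags."""

    genes: dict[str, bool] = field(default_factory=dict)  # gene -> coding

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must contain at least one gene")

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "PanelDefinition":
        """Parse a one-gene-per-line panel; optional tab field 'coding'/'noncoding'."""
        genes: dict[str, bool] = {}
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip()
            coding = len(parts) > 1 and parts[1].strip().lower() == "coding"
            if gene in genes:
                raise ValueError(f"duplicate panel gene: {gene}")
            genes[gene] = coding
        return cls(genes=genes)


def filter_ultra_rare(
    variants: Iterable[VariantCall], maf_threshold: float = 1e-5
) -> list[VariantCall]:
    """Keep ultra-rare variants: population AF strictly below threshold or missing.

    A missing allele frequency (absent from the reference panel) is retained —
    dropping it would discard exactly the private pathogenic alleles the
    procedure is designed to find.
    """
    if not (0.0 < maf_threshold < 1.0):
        raise ValueError(f"maf_threshold must be in (0,1), got {maf_threshold}")
    return [
        v for v in variants if v.population_af is None or v.population_af < maf_threshold
    ]


def call_biallelic(variants: Iterable[VariantCall]) -> list[BiallelicCall]:
    """Call bi-allelic genotypes per (sample, gene).

    Rules, applied per sample per gene:

    * any ``hom_alt`` variant → one ``homozygous`` call per such variant;
    * ≥ 2 ``het`` variants with both maternal and paternal origins present
      → ``compound_het_trans`` (supported by all hets in the gene);
    * ≥ 2 ``het`` variants with any unknown origin → ``compound_het_phase_unknown``;
    * ≥ 2 ``het`` variants all of identical known origin → no call (in cis).

    Input variants are expected to be ultra-rare-filtered already; the function
    itself applies no frequency filter.
    """
    by_key: dict[tuple[str, str], list[VariantCall]] = defaultdict(list)
    for v in variants:
        by_key[(v.sample_id, v.gene)].append(v)

    calls: list[BiallelicCall] = []
    for (sample_id, gene) in sorted(by_key):
        vs = sorted(by_key[(sample_id, gene)], key=lambda v: (v.chromosome, v.position, v.alt))
        for v in vs:
            if v.genotype == "hom_alt":
                calls.append(BiallelicCall(sample_id, gene, "homozygous", (v,)))
        hets = tuple(v for v in vs if v.genotype == "het")
        if len(hets) >= 2:
            origins = {v.parental_origin for v in hets}
            if {"maternal", "paternal"} <= origins:
                calls.append(BiallelicCall(sample_id, gene, "compound_het_trans", hets))
            elif "unknown" in origins:
                calls.append(BiallelicCall(sample_id, gene, "compound_het_phase_unknown", hets))
            # all hets sharing one known origin: in cis, no call
    return calls


def intersect_candidate_genes(
    probands: Sequence[Iterable[BiallelicCall]],
    gene_class: Literal["coding", "noncoding", "any"] = "any",
    mechanisms: Iterable[Mechanism] | None = None,
) -> set[str]:
    """Genes with a qualifying bi-allelic call in *every* proband.

    ``gene_class`` restricts to coding or non-coding genes (a gene is coding if
    any supporting variant is flagged coding). ``mechanisms`` optionally
    restricts the qualifying call mechanisms (e.g. homozygous only).
    """
    if len(probands) == 0:
        raise ValueError("at least one proband is required")
    allowed = set(mechanisms) if mechanisms is not None else None

    def qualifies(c: BiallelicCall) -> bool:
        if allowed is not None and c.mechanism not in allowed:
            return False
        if gene_class == "coding":
            return c.coding
        if gene_class == "noncoding":
            return not c.coding
        return True

    gene_sets = [{c.gene for c in calls if qualifies(c)} for calls in probands]
    return set.intersection(*gene_sets)


def screen_panel(
    cohort: Iterable[VariantCall],
    panel: PanelDefinition,
    maf_threshold: float = 1e-5,
) -> dict[str, list[BiallelicCall]]:
    """Screen a cohort for bi-allelic ultra-rare genotypes in panel genes.

    Returns a mapping gene → calls, sorted by gene then sample. Panel genes
    with no carriers map to empty lists; genes appearing in the cohort but not
    the panel are ignored. Unknown panel genes (never seen in the cohort) only
    trigger a warning.
    """
    ultra = filter_ultra_rare(cohort, maf_threshold=maf_threshold)
    seen_genes = {v.gene for v in ultra}
    missing = sorted(set(panel.genes) - seen_genes)
    if missing:
        warnings.warn(
            f"panel genes with no variants in the cohort: {', '.join(missing)}",
            stacklevel=2,
        )
    calls = call_biallelic(v for v in ultra if v.gene in panel.genes)
    report: dict[str, list[BiallelicCall]] = {g: [] for g in sorted(panel.genes)}
    for c in sorted(calls, key=lambda c: (c.gene, c.sample_id)):
        report[c.gene].append(c)
    return report
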
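"""Clinical cohort schema and summary statistics.

Models the per-individual clinical tables of the two snRNA cohorts and
recomputes every printed cohort summary from them: medians with IQR,
autoantibody positivity, feature fractions under explicit denominator
policies, the birthweight-Z IUGR rule, distinct-allele counts, and the
transcript↔genomic coordinate anchor of each snRNA gene.

Missingness is preserved, never imputed, and comes in two kinds mirroring the
source tables: ``N/A`` (not applicable) and ``N/R`` (not recorded). Bundled
fixtures for both cohorts ship with the package (`load_table1`,
`load_table2`).
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Missing",
    "Allele",
    "ClinicalRecord",
    "ClinicalCohort",
    "SnrnaGeneAnchor",
    "load_cohort",
    "load_table1",
    "load_table2",
    "load_combined",
    "median_iqr",
    "positivity_rate",
    "count_feature",
    "classify_iugr",
    "count_distinct_alleles",
    "fit_gene_anchor",
    "anchor_from_cohort",
    "has_immune_dysregulation",
    "has_humoral_defect",
    "summarize_cohort",
]


class Missing(enum.Enum):
    """Distinct missing-value kinds used by the clinical tables."""

    NOT_APPLICABLE = "N/A"
    NOT_RECORDED = "N/R"


def is_missing(value: object) -> bool:
    return value is None or isinstance(value, Missing) or (
        isinstance(value, float) and math.isnan(value)
    )


_HGVS_RE = re.compile(r"^(\d+)\s*([ACGT])\s*>\s*([ACGT])$")


def parse_hgvs_substitution(desc: str) -> tuple[int, str, str]:
    """Parse a substitution descriptor like ``6G>A`` into (position, ref, alt)."""
    m = _HGVS_RE.match(desc.strip())
    if not m:
        raise ValueError(f"unparseable substitution descriptor: {desc!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def normalize_allele(desc: str) -> str:
    """Canonical form of an allele descriptor (whitespace stripped, bases upper)."""
    pos, ref, alt = parse_hgvs_substitution(desc)
    return f"{pos}{ref}>{alt}"


@dataclass(frozen=True)
class Allele:
    """One variant allele: transcript-level n. and genomic g. descriptions."""

    n_desc: str
    g_desc: str


@dataclass
class ClinicalRecord:
    individual_id: str
    family_id: str
    gene: str  # cohort gene: RNU6ATAC or RNU4ATAC
    sex: str
    genetic_ancestry: str
    age_last_assessment_years: float | Missing
    deceased: bool
    bw_z: float | Missing
    age_dx_weeks: float | Missing
    glucose_dx: float | Missing  # mmol/L
    hba1c: float | Missing  # mmol/mol
    insulin_dose: float | Missing  # U/kg/day
    autoantibody_status: Literal["positive", "negative", "not_assessed"]
    autoantibody_titer: float | None
    autoantibody_threshold: float | None
    immune_features: list[str] | Missing
    microcephaly: str  # yes / no / N/R / N/A
    developmental_delay: str
    additional_features: list[str] | Missing
    zygosity: Literal["homozygous", "compound_het"]
    chromosome: str
    alleles: tuple[Allele, Allele] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("age_dx_weeks", "glucose_dx", "insulin_dose"):
            v = getattr(self, name)
            if not is_missing(v) and v < 0:
                raise ValueError(f"{self.individual_id}: {name} must be non-negative, got {v}")
        if self.zygosity not in ("homozygous", "compound_het"):
            raise ValueError(f"{self.individual_id}: bad zygosity {self.zygosity!r}")
        if self.zygosity == "homozygous" and self.alleles[0].n_desc != self.alleles[1].n_desc:
            raise ValueError(f"{self.individual_id}: homozygous record with two different alleles")


@dataclass
class ClinicalCohort:
    records: list[ClinicalRecord]

    def __post_init__(self) -> None:
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")
        for r in self.records:
            if not r.family_id:
                raise ValueError(f"{r.individual_id}: empty family_id")

    def __len__(self) -> int:
        return len(self.records)

    def __add__(self, other: "ClinicalCohort") -> "ClinicalCohort":
        return ClinicalCohort(records=self.records + other.records)

    @property
    def n_individuals(self) -> int:
        return len({r.individual_id for r in self.records})

    @property
    def n_families(self) -> int:
        return len({r.family_id for r in self.records})

    def subset(self, gene: str) -> "ClinicalCohort":
        return ClinicalCohort([r for r in self.records if r.gene == gene])


@dataclass(frozen=True)
class SnrnaGeneAnchor:
    """Affine map between transcript n. positions and genomic g. coordinates.

    plus strand:  g = offset + n
    minus strand: g = offset - n
    """

    gene: str
    chromosome: str
    strand: Literal["+", "-"]
    offset: int

    def to_genomic(self, n_position: int) -> int:
        return self.offset + n_position if self.strand == "+" else self.offset - n_position


# --- loading ---------------------------------------------------------------


def _parse_numeric(raw: str, where: str) -> float | Missing:
    s = raw.strip()
    if s in ("N/A", "NA"):
        return Missing.NOT_APPLICABLE
    if s in ("N/R", "NR", ""):
        return Missing.NOT_RECORDED
    try:
        return float(s.replace(",", ""))
    except ValueError as exc:
        raise ValueError(f"unparseable numeric at {where}: {raw!r}") from exc


_AUTOAB_RE = re.compile(r"positive\s*\(([\d,\.]+)\s*,\s*>\s*([\d\.]+)\)", re.IGNORECASE)


def _parse_autoantibodies(raw: str) -> tuple[str, float | None, float | None]:
    s = raw.strip()
    if s in ("N/A", "N/R", ""):
        return "not_assessed", None, None
    if s.lower() == "negative":
        return "negative", None, None
    m = _AUTOAB_RE.search(s)
    if m:
        titer = float(m.group(1).replace(",", ""))
        return "positive", titer, float(m.group(2))
    if "positive" in s.lower():
        return "positive", None, None
    raise ValueError(f"unparseable autoantibody entry: {raw!r}")


def _parse_feature_list(raw: str) -> list[str] | Missing:
    s = raw.strip()
    if s == "N/R":
        return Missing.NOT_RECORDED
    if s == "N/A":
        return Missing.NOT_APPLICABLE
    if s.lower() in ("none reported", "none", ""):
        return []
    return [t.strip() for t in s.split(";") if t.strip()]


def load_cohort(path: str | Path) -> ClinicalCohort:
    """Load a clinical cohort CSV (one row per individual; '#' lines are comments)."""
    df = pd.read_csv(path, comment="#", keep_default_na=False, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty clinical table")
    required = {
        "individual_id", "family_id", "gene", "sex", "genetic_ancestry",
        "age_last_assessment_years", "deceased", "bw_z", "age_dx_weeks",
        "glucose_dx_mmol_l", "hba1c_mmol_mol", "insulin_dose_u_kg_day",
        "autoantibodies", "immune_features", "microcephaly", "developmental_delay",
        "additional_features", "zygosity", "chromosome",
        "allele1_n", "allele1_g", "allele2_n", "allele2_g",
    }
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")

    records = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 1}"
        status, titer, threshold = _parse_autoantibodies(row["autoantibodies"])
        rec = ClinicalRecord(
            individual_id=row["individual_id"].strip(),
            family_id=row["family_id"].strip(),
            gene=row["gene"].strip(),
            sex=row["sex"].strip(),
            genetic_ancestry=row["genetic_ancestry"].strip(),
            age_last_assessment_years=_parse_numeric(row["age_last_assessment_years"], where),
            deceased=row["deceased"].strip().lower() == "yes",
            bw_z=_parse_numeric(row["bw_z"], f"{where} col bw_z"),
            age_dx_weeks=_parse_numeric(row["age_dx_weeks"], f"{where} col age_dx_weeks"),
            glucose_dx=_parse_numeric(row["glucose_dx_mmol_l"], f"{where} col glucose_dx_mmol_l"),
            hba1c=_parse_numeric(row["hba1c_mmol_mol"], f"{where} col hba1c_mmol_mol"),
            insulin_dose=_parse_numeric(row["insulin_dose_u_kg_day"], f"{where} col insulin_dose_u_kg_day"),
            autoantibody_status=status,
            autoantibody_titer=titer,
            autoantibody_threshold=threshold,
            immune_features=_parse_feature_list(row["immune_features"]),
            microcephaly=row["microcephaly"].strip(),
            developmental_delay=row["developmental_delay"].strip(),
            additional_features=_parse_feature_list(row["additional_features"]),
            zygosity=row["zygosity"].strip(),  # type: ignore[arg-type]
            chromosome=row["chromosome"].strip(),
            alleles=(
                Allele(normalize_allele(row["allele1_n"]), normalize_allele(row["allele1_g"])),
                Allele(normalize_allele(row["allele2_n"]), normalize_allele(row["allele2_g"])),
            ),
        )
        records.append(rec)
    return ClinicalCohort(records=records)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("minorsplice").joinpath("data", name)))


def load_table1() -> ClinicalCohort:
    """Bundled RNU6ATAC cohort fixture (7 individuals, 4 families)."""
    return load_cohort(_fixture_path("rnu6atac_cohort.csv"))


def load_table2() -> ClinicalCohort:
    """Bundled RNU4ATAC cohort fixture (12 unrelated individuals)."""
    return load_cohort(_fixture_path("rnu4atac_cohort.csv"))


def load_combined() -> ClinicalCohort:
    return load_table1() + load_table2()


# --- summary statistics -----------------------------------------------------


@dataclass(frozen=True)
class MedianIQR:
    median: float | None
    q1: float | None
    q3: float | None
    n_used: int

    @property
    def defined(self) -> bool:
        return self.n_used > 0


def median_iqr(
    values: Iterable[object], method: Literal["linear", "tukey"] = "linear"
) -> MedianIQR:
    """Median and quartiles over the non-missing values.

    The median is the middle order statistic (odd n) or the mean of the two
    middle ones (even n). Quartiles use the inclusive linear-interpolation
    convention by default; ``method="tukey"`` instead takes medians of the
    lower/upper halves (median excluded for odd n). The source tables do not
    state their convention, so it is parameter-exposed.

    All-missing input yields an undefined (flagged) result, never zero.
    """
    xs = sorted(float(v) for v in values if not is_missing(v))
    n = len(xs)
    if n == 0:
        return MedianIQR(None, None, None, 0)
    med = xs[n // 2] if n % 2 == 1 else (xs[n // 2 - 1] + xs[n // 2]) / 2.0
    if n == 1:
        return MedianIQR(xs[0], xs[0], xs[0], 1)
    if method == "linear":
        q1, q3 = (float(q) for q in np.quantile(xs, [0.25, 0.75], method="linear"))
    elif method == "tukey":
        lower = xs[: n // 2]
        upper = xs[(n + 1) // 2:]
        q1 = median_iqr(lower, method="linear").median
        q3 = median_iqr(upper, method="linear").median
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    return MedianIQR(med, q1, q3, n)


def positivity_rate(cohort: ClinicalCohort) -> tuple[int, int, float | None]:
    """Islet-autoantibody positivity: (n_positive, n_assessed, percent).

    Only assessed individuals enter the denominator; percent is None when
    nobody was assessed.
    """
    assessed = [r for r in cohort.records if r.autoantibody_status != "not_assessed"]
    n_pos = sum(1 for r in assessed if r.autoantibody_status == "positive")
    n_assessed = len(assessed)
    pct = 100.0 * n_pos / n_assessed if n_assessed else None
    return n_pos, n_assessed, pct


def count_feature(
    cohort: ClinicalCohort,
    predicate: Callable[[ClinicalRecord], bool | None],
    denominator_policy: Literal["recorded_only", "all"] = "all",
) -> tuple[int, int]:
    """Count records satisfying a predicate; returns (numerator, denominator).

    The predicate returns True/False, or None when the underlying datum was
    not recorded. Under ``recorded_only`` the None records are excluded from
    the denominator; under ``all`` they stay in it (and never count in the
    numerator).
    """
    num = den = 0
    for r in cohort.records:
        verdict = predicate(r)
        if verdict is None:
            if denominator_policy == "all":
                den += 1
            continue
        den += 1
        if verdict:
            num += 1
    return num, den


IUGR_Z_THRESHOLD = -1.28


def classify_iugr(record: ClinicalRecord, z_threshold: float = IUGR_Z_THRESHOLD) -> bool | None:
    """IUGR iff the birthweight Z score is recorded and strictly below threshold."""
    if is_missing(record.bw_z):
        return None
    return record.bw_z < z_threshold


def has_immune_dysregulation(record: ClinicalRecord) -> bool | None:
    """True iff at least one immune dysregulatory feature was recorded.

    An explicitly empty feature list is a recorded negative; a not-recorded
    cell returns None.
    """
    if isinstance(record.immune_features, Missing):
        return None
    return len(record.immune_features) > 0


_HUMORAL_TERMS = ("b cell lymphopenia", "agammaglobulinemia", "hypogammaglobulinemia")


def has_humoral_defect(record: ClinicalRecord) -> bool | None:
    """Humoral immune defect: B cell lymphopenia and/or a/hypogammaglobulinemia."""
    if isinstance(record.immune_features, Missing):
        return None
    joined = "; ".join(record.immune_features).lower()
    return any(term in joined for term in _HUMORAL_TERMS)


def count_distinct_alleles(cohort: ClinicalCohort, gene: str) -> int:
    """Distinct transcript-level n. descriptions across all records of a gene."""
    alleles: set[str] = set()
    for r in cohort.records:
        if r.gene != gene:
            continue
        for a in r.alleles:
            alleles.add(normalize_allele(a.n_desc))
    return len(alleles)


def fit_gene_anchor(
    pairs: Sequence[tuple[int, int]], gene: str = "", chromosome: str = ""
) -> SnrnaGeneAnchor:
    """Infer the strand and offset mapping n. positions to g. coordinates.

    Requires at least two pairs. Tries both orientations (g = offset + n and
    g = offset − n) and returns the one reproducing *every* pair exactly;
    raises listing the first violating pair if neither is consistent.
    """
    if len(pairs) < 2:
        raise ValueError("at least two (n, g) pairs are required")
    for strand in ("+", "-"):
        sign = 1 if strand == "+" else -1
        offset = pairs[0][1] - sign * pairs[0][0]
        bad = next(((n, g) for n, g in pairs if offset + sign * n != g), None)
        if bad is None:
            return SnrnaGeneAnchor(gene=gene, chromosome=chromosome, strand=strand, offset=offset)
    violations = []
    for strand, sign in (("+", 1), ("-", -1)):
        offset = pairs[0][1] - sign * pairs[0][0]
        violations += [(strand, n, g) for n, g in pairs if offset + sign * n != g]
    raise ValueError(f"no consistent anchor; violating pairs (strand, n, g): {violations}")


def anchor_from_cohort(cohort: ClinicalCohort, gene: str) -> SnrnaGeneAnchor:
    """Fit the coordinate anchor of a gene from every allele in a cohort."""
    pairs: list[tuple[int, int]] = []
    chromosome = ""
    for r in cohort.records:
        if r.gene != gene:
            continue
        chromosome = r.chromosome
        for a in r.alleles:
            n_pos, _, _ = parse_hgvs_substitution(a.n_desc)
            g_pos, _, _ = parse_hgvs_substitution(a.g_desc)
            pairs.append((n_pos, g_pos))
    # distinct pairs only: repeated alleles add no information
    unique = sorted(set(pairs))
    return fit_gene_anchor(unique, gene=gene, chromosome=chromosome)


def summarize_cohort(cohort: ClinicalCohort, quartile_method: str = "linear") -> dict:
    """Recompute the cohort summary statistics as a JSON-ready report.

    Includes per-gene onset medians, pooled glucose/insulin medians with the
    number of parseable values actually used (surfacing any discrepancy with
    externally printed sample sizes rather than resolving it), autoantibody
    positivity, feature fractions, IUGR counts, and distinct-allele counts.
    """
    report: dict = {
        "n_individuals": cohort.n_individuals,
        "n_families": cohort.n_families,
        "genes": {},
    }
    for gene in sorted({r.gene for r in cohort.records}):
        sub = cohort.subset(gene)
        onset = median_iqr([r.age_dx_weeks for r in sub.records], method=quartile_method)
        iugr = count_feature(sub, classify_iugr, "recorded_only")
        report["genes"][gene] = {
            "n_individuals": sub.n_individuals,
            "n_families": sub.n_families,
            "median_onset_weeks": onset.median,
            "onset_iqr": [onset.q1, onset.q3],
            "onset_n_used": onset.n_used,
            "iugr": {"numerator": iugr[0], "denominator": iugr[1]},
            "humoral_defect": dict(
                zip(("numerator", "denominator"), count_feature(sub, has_humoral_defect, "all"))
            ),
            "distinct_alleles": count_distinct_alleles(sub, gene),
        }
        try:
            anchor = anchor_from_cohort(sub, gene)
            report["genes"][gene]["anchor"] = {
                "strand": anchor.strand,
                "offset": anchor.offset,
                "chromosome": anchor.chromosome,
            }
        except ValueError:
            report["genes"][gene]["anchor"] = None

    glucose = median_iqr([r.glucose_dx for r in cohort.records], method=quartile_method)
    insulin = median_iqr([r.insulin_dose for r in cohort.records], method=quartile_method)
    n_pos, n_assessed, pct = positivity_rate(cohort)
    immune = count_feature(cohort, has_immune_dysregulation, "all")
    report.update(
        {
            "glucose_mmol_l": {
                "median": glucose.median,
                "iqr": [glucose.q1, glucose.q3],
                "n_used": glucose.n_used,
            },
            "insulin_u_kg_day": {
                "median": insulin.median,
                "iqr": [insulin.q1, insulin.q3],
                "n_used": insulin.n_used,
            },
            "autoantibody_positivity": {
                "n_positive": n_pos,
                "n_assessed": n_assessed,
                "percent": pct,
            },
            "immune_dysregulation": {"numerator": immune[0], "denominator": immune[1]},
        }
    )
    return report
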
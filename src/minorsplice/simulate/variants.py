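"""Synthetic variant cohorts with planted bi-allelic genotypes.

Every case sample carries a qualifying bi-allelic genotype in the target
gene (allele frequencies drawn log-uniform in [1e-8, 5e-6], comfortably below
the 1e-5 ultra-rare threshold); controls carry none. Background variants are
drawn from a log-uniform allele-frequency spectrum over the configured range,
plus an explicit stream of ultra-rare background variants (some absent from
the reference panel entirely) to exercise filter specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .._seeds import stream_rng
from ..variants import VariantCall

__all__ = ["VariantSimConfig", "VariantSimTruth", "simulate_variant_cohort"]

_PLANTED_AF_RANGE = (1e-8, 5e-6)  # always passes the 1e-5 filter with margin


@dataclass
class VariantSimConfig:
    n_cases: int = 3
    n_controls: int = 20
    target_gene: str = "RNU6ATAC"
    case_genotype_mode: Literal["homozygous", "compound_het", "mixed"] = "homozygous"
    panel: tuple[str, ...] = ("RNU6ATAC", "RNU4ATAC", "RNU11", "RNU12")
    n_background_genes: int = 500
    background_variants_per_sample: float = 30.0
    af_spectrum: tuple[float, float] = (1e-6, 0.5)  # log-uniform support
    ultra_rare_background_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_background_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("background_variants_per_sample", "ultra_rare_background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.target_gene not in self.panel:
            raise ValueError(
                f"target_gene {self.target_gene!r} must be a member of the panel"
            )
        lo, hi = self.af_spectrum
        if not (0 < lo < hi <= 1):
            raise ValueError(f"af_spectrum must satisfy 0 < lo < hi <= 1, got {self.af_spectrum}")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")


@dataclass
class VariantSimTruth:
    """Ground truth of a simulated variant cohort."""

    target_gene: str
    case_samples: list[str]
    control_samples: list[str]
    # sample -> list of planted (position, genotype, parental_origin, af)
    planted: dict[str, list[tuple[int, str, str, float]]]
    # keys of every generated variant with AF < 1e-5 or absent, as
    # (sample_id, chromosome, position, alt)
    ultra_rare_keys: set[tuple[str, str, int, str]] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "target_gene": self.target_gene,
            "case_samples": self.case_samples,
            "control_samples": self.control_samples,
            "planted": {
                s: [list(v) for v in vs] for s, vs in sorted(self.planted.items())
            },
            "ultra_rare_keys": sorted(list(k) for k in self.ultra_rare_keys),
        }


def _gene_locus(gene: str, panel: tuple[str, ...]) -> tuple[str, int]:
    """Deterministic synthetic locus per gene: (chromosome, base position)."""
    if gene in panel:
        return "chrP", 1_000_000 + panel.index(gene) * 100_000
    # background genes are named BG<index>
    idx = int(gene[2:])
    return "chrB", 1_000_000 + idx * 100_000

def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int | None = None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_variant_cohort(config: VariantSimConfig) -> tuple[list[VariantCall], VariantSimTruth]:
    """Generate an annotated variant cohort plus its ground truth.

    Deterministic given ``config.seed``. Case genotype modes: ``homozygous``
    (one hom_alt target-gene variant per case, distinct positions across
    cases), ``compound_het`` (two het variants on opposite parental
    haplotypes), or ``mixed`` (alternating).
    """
    rng_plant = stream_rng(config.seed, "variants.planted")
    rng_bg = stream_rng(config.seed, "variants.background")
    rng_ur = stream_rng(config.seed, "variants.ultrarare")

    cases = [f"case_{i:03d}" for i in range(config.n_cases)]
    controls = [f"control_{i:03d}" for i in range(config.n_controls)]
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    if config.n_cases > 0 and config.n_background_genes == 0 and not config.panel:
        raise ValueError("no genes to place variants in")

    calls: list[VariantCall] = []
    truth = VariantSimTruth(
        target_gene=config.target_gene, case_samples=cases, control_samples=controls, planted={}
    )
    target_chrom, target_base = _gene_locus(config.target_gene, config.panel)

    # distinct positions in the target gene for all planted alleles
    n_slots = 2 * config.n_cases + 4
    offsets = rng_plant.choice(np.arange(1, max(n_slots * 4, 200)), size=n_slots, replace=False)
    slot = 0
    bases = "ACGT"
    for i, sample in enumerate(cases):
        mode = config.case_genotype_mode
        if mode == "mixed":
            mode = "homozygous" if i % 2 == 0 else "compound_het"
        planted: list[tuple[int, str, str, float]] = []
        if mode == "homozygous":
            pos = int(target_base + offsets[slot]); slot += 1
            ref, alt = rng_plant.choice(list(bases), size=2, replace=False)
            af = float(_loguniform(rng_plant, *_PLANTED_AF_RANGE))
            calls.append(
                VariantCall(sample, target_chrom, pos, ref, alt, "hom_alt",
                            config.target_gene, False, af, "unknown")
            )
            planted.append((pos, "hom_alt", "unknown", af))
        else:
            for origin in ("maternal", "paternal"):
                pos = int(target_base + offsets[slot]); slot += 1
                ref, alt = rng_plant.choice(list(bases), size=2, replace=False)
                af = float(_loguniform(rng_plant, *_PLANTED_AF_RANGE))
                calls.append(
                    VariantCall(sample, target_chrom, pos, ref, alt, "het",
                                config.target_gene, False, af, origin)
                )
                planted.append((pos, "het", origin, af))
        truth.planted[sample] = planted

    # Background spectrum + explicit ultra-rare background, cases and controls
    # alike. Site-level annotations (ref/alt, AF) are deterministic functions
    # of (gene, position) so that samples drawing the same site never disagree.
    # Common-spectrum sites live at odd offsets, ultra-rare sites at even ones.
    def _site(gene: str, pos: int, ultra_rare: bool) -> tuple[str, str, float | None]:
        srng = stream_rng(config.seed, f"variants.site:{gene}:{pos}")
        ref, alt = srng.choice(list(bases), size=2, replace=False)
        if ultra_rare:
            af = None if srng.random() < 0.5 else float(_loguniform(srng, 1e-8, 9.9e-6))
        else:
            af = float(_loguniform(srng, *config.af_spectrum))
        return str(ref), str(alt), af

    for sample in cases + controls:
        if bg_genes:
            n_bg = int(rng_bg.poisson(config.background_variants_per_sample))
            for _ in range(n_bg):
                gene = bg_genes[int(rng_bg.integers(len(bg_genes)))]
                chrom, base = _gene_locus(gene, config.panel)
                pos = int(base + 2 * rng_bg.integers(1, 25_000) + 1)
                ref, alt, af = _site(gene, pos, ultra_rare=False)
                genotype = "hom_alt" if rng_bg.random() < 0.05 else "het"
                calls.append(VariantCall(sample, chrom, pos, ref, alt, genotype, gene, True, af))
            n_ur = int(rng_ur.poisson(config.ultra_rare_background_rate))
            for _ in range(n_ur):
                gene = bg_genes[int(rng_ur.integers(len(bg_genes)))]
                chrom, base = _gene_locus(gene, config.panel)
                pos = int(base + 2 * rng_ur.integers(1, 25_000))
                ref, alt, af = _site(gene, pos, ultra_rare=True)
                genotype = "hom_alt" if rng_ur.random() < 0.2 else "het"
                calls.append(VariantCall(sample, chrom, pos, ref, alt, genotype, gene, True, af))

    truth.ultra_rare_keys = {
        (c.sample_id, c.chromosome, c.position, c.alt)
        for c in calls
        if c.population_af is None or c.population_af < 1e-5
    }
    calls.sort(key=lambda c: (c.sample_id, c.chromosome, c.position, c.alt))
    return calls, truth
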
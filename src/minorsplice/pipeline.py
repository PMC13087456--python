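"""Pipeline orchestration: stage execution, manifests, determinism.

Stages run in dependency order: ``simulate`` → ``prioritize`` → ``ir`` →
``network`` → ``deconvolve`` → ``clinical``. Every stage writes its outputs
under ``<out_dir>/<stage>/`` together with a JSON manifest recording the
parameters, the seed, and a SHA-256 digest of each output file; rerunning
with an identical config is byte-identical. All randomness flows through the
single config seed — no stage reads a clock or an entropy source.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import clinical as clin
from . import coexpression as coex
from . import deconvolution as deconv
from . import formats
from . import intron_retention as ir
from . import variants as vp
from .simulate import (
    ExprSimConfig,
    IRSimConfig,
    MethSimConfig,
    VariantSimConfig,
    simulate_expression,
    simulate_intron_counts,
    simulate_methylation,
    simulate_variant_cohort,
)

__all__ = ["STAGES", "validate_config", "run_pipeline"]

log = logging.getLogger("minorsplice")

STAGES = ("simulate", "prioritize", "ir", "network", "deconvolve", "clinical")

_ALLOWED_KEYS = {
    "stages", "seed", "out_dir", "log_level",
    "simulate", "prioritize", "ir", "network", "deconvolve", "clinical",
}
_ALLOWED_STAGE_KEYS: dict[str, set[str]] = {
    "simulate": {"variant", "introns", "expression", "methylation"},
    "prioritize": {"maf_threshold", "gene_class"},
    "ir": {"min_coverage", "alpha", "min_effect", "gene_rule"},
    "network": {"power", "signed", "cut_height", "min_module_size"},
    "deconvolve": {"test"},
    "clinical": {"tables", "quartile_method"},
}


def validate_config(config: Mapping) -> dict:
    """Validate a pipeline config dict; unknown keys are rejected."""
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(config)
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("seed", 0)
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")
        block = cfg.get(stage, {})
        bad = set(block) - _ALLOWED_STAGE_KEYS.get(stage, set())
        if bad:
            raise ValueError(f"unknown keys in stage {stage!r}: {sorted(bad)}")
    tables = cfg.get("clinical", {}).get("tables")
    if tables:
        for t in tables:
            if not Path(t).exists():
                raise ValueError(f"clinical table does not exist: {t}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: Mapping, seed: int) -> dict:
    outputs = {
        p.name: _sha256(p)
        for p in sorted(stage_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"stage": stage, "parameters": dict(params), "seed": seed, "outputs": outputs}
    formats.write_json_report(manifest, stage_dir / "manifest.json")
    return manifest


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream output {path}; run the simulate stage first"
        )
    return path


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Execute the selected stages; returns a report of per-stage manifests."""
    cfg = validate_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "minorsplice_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"stages": {}}
    sim_dir = out / "simulate"

    for stage in STAGES:  # dependency order regardless of listing order
        if stage not in cfg["stages"]:
            continue
        stage_dir = out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        params = dict(cfg.get(stage, {}))
        log.info("running stage %s", stage)

        if stage == "simulate":
            vcfg = VariantSimConfig(seed=seed, **params.get("variant", {}))
            calls, vtruth = simulate_variant_cohort(vcfg)
            formats.write_vcf(calls, stage_dir / "variants.vcf",
                              samples=vtruth.case_samples + vtruth.control_samples)
            formats.write_json_report(vtruth.to_json(), stage_dir / "truth_variants.json")

            icfg = IRSimConfig(seed=seed, **params.get("introns", {}))
            retained, spliced, annotation, itruth = simulate_intron_counts(icfg)
            formats.write_counts_tsv(retained, spliced, stage_dir / "intron_counts.tsv")
            formats.write_bed(annotation, stage_dir / "introns.bed")
            formats.write_json_report(itruth.to_json(), stage_dir / "truth_introns.json")

            ecfg = ExprSimConfig(seed=seed, **params.get("expression", {}))
            expr, etruth = simulate_expression(ecfg)
            formats.write_matrix_tsv(expr, stage_dir / "expression.tsv", index_label="gene")
            formats.write_sample_sheet(etruth.status.to_frame(), stage_dir / "expr_samples.csv")
            formats.write_json_report(etruth.to_json(), stage_dir / "truth_expression.json")

            mcfg = MethSimConfig(seed=seed, **params.get("methylation", {}))
            beta, reference, mtruth = simulate_methylation(mcfg)
            formats.write_matrix_tsv(beta, stage_dir / "methylation_beta.tsv", index_label="cpg")
            formats.write_matrix_tsv(reference, stage_dir / "methylation_reference.tsv",
                                     index_label="cpg")
            formats.write_json_report(mtruth.to_json(), stage_dir / "truth_methylation.json")

        elif stage == "prioritize":
            calls, _samples = formats.read_vcf(_require(sim_dir / "variants.vcf", stage))
            maf = params.get("maf_threshold", 1e-5)
            gene_class = params.get("gene_class", "noncoding")
            ultra = vp.filter_ultra_rare(calls, maf_threshold=maf)
            by_sample: dict[str, list] = {}
            for c in ultra:
                by_sample.setdefault(c.sample_id, []).append(c)
            case_calls = [
                vp.call_biallelic(vs)
                for s, vs in sorted(by_sample.items())
                if s.startswith("case_")
            ]
            shared = (
                sorted(vp.intersect_candidate_genes(case_calls, gene_class=gene_class))
                if case_calls
                else []
            )
            panel = vp.PanelDefinition.from_lines(
                clin._fixture_path("minor_spliceosome_panel.txt").read_text().splitlines()
            )
            screen = vp.screen_panel(calls, panel, maf_threshold=maf)
            formats.write_json_report(
                {
                    "shared_candidate_genes": shared,
                    "gene_class": gene_class,
                    "panel_screen": {
                        g: [
                            {"sample": c.sample_id, "mechanism": c.mechanism,
                             "n_variants": len(c.variants)}
                            for c in cs
                        ]
                        for g, cs in screen.items()
                    },
                },
                stage_dir / "prioritize.json",
            )

        elif stage == "ir":
            retained, spliced = formats.read_counts_tsv(_require(sim_dir / "intron_counts.tsv", stage))
            annotation = formats.read_bed(_require(sim_dir / "introns.bed", stage))
            psi = ir.compute_psi(retained, spliced, min_coverage=params.get("min_coverage", 10))
            cases = [s for s in psi.psi.columns if s.startswith("case_")]
            controls = [s for s in psi.psi.columns if s.startswith("control_")]
            results = ir.test_differential_ir(
                psi, cases, controls,
                alpha=params.get("alpha", 0.05), min_effect=params.get("min_effect", 0.05),
            )
            genes = ir.call_gene_level(results, annotation, rule=params.get("gene_rule", "any"))
            formats.write_matrix_tsv(results, stage_dir / "ir_results.tsv", index_label="intron_id")
            formats.write_json_report({"significant_genes": sorted(genes)}, stage_dir / "ir_genes.json")

        elif stage == "network":
            expr = formats.read_matrix_tsv(_require(sim_dir / "expression.tsv", stage))
            sheet = formats.read_sample_sheet(_require(sim_dir / "expr_samples.csv", stage))
            ncfg = coex.NetworkConfig(
                signed=params.get("signed", True),
                cut_height=params.get("cut_height", 0.9),
                min_module_size=params.get("min_module_size", 20),
            )
            # fixed default power: block-modular synthetic data rarely has a
            # scale-free degree distribution, so auto-pick is opt-in ("auto")
            power = params.get("power", 6)
            if power == "auto":
                power = coex.pick_soft_threshold(expr, ncfg).power
            tom = coex.compute_tom(expr, power, signed=ncfg.signed)
            assignment = coex.detect_modules(tom, ncfg)
            eigengenes = coex.module_eigengenes(expr, assignment)
            traits = sheet.loc[eigengenes.index].astype(float)
            mt = coex.module_trait_correlation(eigengenes, traits)
            formats.write_matrix_tsv(assignment.to_frame(), stage_dir / "modules.tsv",
                                     index_label="gene")
            mt.to_csv(stage_dir / "module_trait.tsv", sep="\t", index=False, lineterminator="\n")
            params["power_used"] = int(power)

        elif stage == "deconvolve":
            beta = formats.read_matrix_tsv(_require(sim_dir / "methylation_beta.tsv", stage))
            reference = formats.read_matrix_tsv(
                _require(sim_dir / "methylation_reference.tsv", stage)
            )
            est = deconv.estimate_fractions(beta, reference)
            cases = [s for s in est.weights.index if s.startswith("case_")]
            controls = [s for s in est.weights.index if s.startswith("control_")]
            comparison = deconv.compare_fractions(
                est.weights, cases, controls, test=params.get("test", "welch_t")
            )
            formats.write_matrix_tsv(est.weights, stage_dir / "fractions.tsv", index_label="sample")
            formats.write_matrix_tsv(comparison, stage_dir / "comparison.tsv",
                                     index_label="cell_type")

        elif stage == "clinical":
            tables = params.get("tables")
            if tables:
                cohort = clin.load_cohort(tables[0])
                for t in tables[1:]:
                    cohort = cohort + clin.load_cohort(t)
            else:
                cohort = clin.load_combined()
            summary = clin.summarize_cohort(
                cohort, quartile_method=params.get("quartile_method", "linear")
            )
            formats.write_json_report(summary, stage_dir / "clinical_summary.json")

        report["stages"][stage] = _write_manifest(stage_dir, stage, params, seed)

    return report
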
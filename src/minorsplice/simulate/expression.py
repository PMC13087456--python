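"""Synthetic block-correlated expression with trait-linked modules.

Genes inside a module share a latent per-sample factor; the factor loading is
chosen so that the expected pairwise within-module correlation equals the
configured value at the configured noise scale. Trait-linked modules add
``trait_effect * status`` to their factor, so their eigengenes track disease
status. Background genes are independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._seeds import stream_rng

__all__ = ["ExprSimConfig", "ExprSimTruth", "simulate_expression"]


@dataclass
class ExprSimConfig:
    n_cases: int = 20
    n_controls: int = 20
    module_sizes: tuple[int, ...] = (30,) * 8
    n_background_genes: int = 60
    within_module_correlation: float = 0.8
    n_trait_modules: int = 2
    trait_effect: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_cases + self.n_controls == 0:
            raise ValueError("at least one sample is required (both groups have size 0)")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if not (0.0 < self.within_module_correlation < 1.0):
            raise ValueError(
                f"within_module_correlation must be in (0,1), got {self.within_module_correlation}"
            )
        if not (0 <= self.n_trait_modules <= len(self.module_sizes)):
            raise ValueError("n_trait_modules must not exceed the number of modules")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background_genes


@dataclass
class ExprSimTruth:
    module_of_gene: pd.Series  # gene -> "M1".. / "background"
    trait_modules: list[str]
    status: pd.Series  # sample -> 0/1 disease status
    factors: pd.DataFrame  # samples x modules, the latent factors

    def to_json(self) -> dict:
        return {
            "module_of_gene": self.module_of_gene.to_dict(),
            "trait_modules": self.trait_modules,
            "status": {k: int(v) for k, v in self.status.items()},
        }


def simulate_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, ExprSimTruth]:
    """Generate (expression genes × samples, truth). Deterministic per seed.

    Gene model: x = a·f + noise_sd·eps with a = noise_sd·sqrt(c/(1−c)), which
    yields within-module correlation exactly c in expectation regardless of
    the noise scale.
    """
    rng = stream_rng(config.seed, "expression")
    cases = [f"case_{i:03d}" for i in range(config.n_cases)]
    controls = [f"control_{i:03d}" for i in range(config.n_controls)]
    samples = cases + controls
    n = len(samples)
    status = pd.Series([1] * len(cases) + [0] * len(controls), index=samples, name="status")

    c = config.within_module_correlation
    loading = config.noise_sd * np.sqrt(c / (1.0 - c))

    module_names = [f"M{i + 1}" for i in range(len(config.module_sizes))]
    trait_modules = module_names[: config.n_trait_modules]

    factors = {}
    gene_rows, gene_names, module_of = [], [], []
    for mi, (m, size) in enumerate(zip(module_names, config.module_sizes)):
        f = rng.standard_normal(n)
        if m in trait_modules:
            # alternate effect sign so trait modules are up- or down-regulated
            # rather than mutually correlated (which would merge them)
            sign = 1.0 if mi % 2 == 0 else -1.0
            f = f + sign * config.trait_effect * status.to_numpy()
        factors[m] = f
        eps = rng.standard_normal((size, n))
        gene_rows.append(loading * f[None, :] + config.noise_sd * eps)
        names = [f"{m}_g{j:03d}" for j in range(size)]
        gene_names.extend(names)
        module_of.extend([m] * size)
    if config.n_background_genes:
        gene_rows.append(config.noise_sd * rng.standard_normal((config.n_background_genes, n)))
        names = [f"BGX_g{j:03d}" for j in range(config.n_background_genes)]
        gene_names.extend(names)
        module_of.extend(["background"] * config.n_background_genes)

    expr = pd.DataFrame(np.vstack(gene_rows), index=gene_names, columns=samples)
    truth = ExprSimTruth(
        module_of_gene=pd.Series(module_of, index=gene_names, name="module"),
        trait_modules=trait_modules,
        status=status,
        factors=pd.DataFrame(factors, index=samples),
    )
    return expr, truth
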
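"""Synthetic methylation mixtures over cell-type reference profiles.

Reference beta profiles are drawn once per cell type from a bimodal Beta so
the columns are mutually distinguishable. Each sample is a noisy convex
mixture of the references: mixing weights come from a Dirichlet on the
simplex, with the depleted cell type's weight multiplied by the depletion
factor (then renormalized) in case samples. Measurement noise is Beta
distributed around the mixed value with the configured precision;
``beta_precision=None`` disables noise entirely (exact identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._seeds import stream_rng

__all__ = ["MethSimConfig", "MethSimTruth", "simulate_methylation", "DEFAULT_CELL_TYPES"]

DEFAULT_CELL_TYPES = (
    "naive_B", "memory_B", "naive_CD4T", "memory_CD4T", "naive_CD8T", "memory_CD8T",
    "NK", "monocyte", "neutrophil", "basophil", "eosinophil", "Treg",
)


@dataclass
class MethSimConfig:
    n_cpgs: int = 200
    n_cases: int = 17
    n_controls: int = 17
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    # Dirichlet concentration: a scalar (symmetric) or one value per cell type
    base_concentration: float | tuple[float, ...] = 5.0
    depleted_cell_type: str = "naive_B"
    depletion_factor: float = 0.4
    beta_precision: float | None = 100.0  # None disables measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be >= 0")
        if len(self.cell_types) < 2:
            raise ValueError("need at least two cell types")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell type names must be unique")
        if self.depleted_cell_type not in self.cell_types:
            raise ValueError(f"depleted_cell_type {self.depleted_cell_type!r} not in cell_types")
        if not (0.0 < self.depletion_factor <= 1.0):
            raise ValueError(f"depletion_factor must be in (0,1], got {self.depletion_factor}")
        conc = np.atleast_1d(np.asarray(self.base_concentration, dtype=float))
        if conc.size not in (1, len(self.cell_types)):
            raise ValueError(
                "base_concentration must be scalar or one value per cell type"
            )
        if (conc <= 0).any():
            raise ValueError("base_concentration values must be positive")
        if self.beta_precision is not None and self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive (or None for no noise)")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")


@dataclass
class MethSimTruth:
    weights: pd.DataFrame  # samples x cell types, exact mixing proportions
    case_samples: list[str]
    control_samples: list[str]
    depleted_cell_type: str

    def to_json(self) -> dict:
        return {
            "weights": {s: self.weights.loc[s].to_dict() for s in self.weights.index},
            "case_samples": self.case_samples,
            "control_samples": self.control_samples,
            "depleted_cell_type": self.depleted_cell_type,
        }


def simulate_methylation(
    config: MethSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, MethSimTruth]:
    """Generate (beta matrix CpGs × samples, reference CpGs × cell types, truth)."""
    rng_ref = stream_rng(config.seed, "methylation.reference")
    rng_mix = stream_rng(config.seed, "methylation.mixtures")
    rng_noise = stream_rng(config.seed, "methylation.noise")

    cpgs = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    types = list(config.cell_types)
    reference = pd.DataFrame(
        rng_ref.beta(0.5, 0.5, size=(config.n_cpgs, len(types))), index=cpgs, columns=types
    )

    cases = [f"case_{i:03d}" for i in range(config.n_cases)]
    controls = [f"control_{i:03d}" for i in range(config.n_controls)]
    samples = cases + controls
    conc = np.atleast_1d(np.asarray(config.base_concentration, dtype=float))
    alpha = np.full(len(types), conc[0]) if conc.size == 1 else conc.copy()
    weights = rng_mix.dirichlet(alpha, size=len(samples))
    dep_idx = types.index(config.depleted_cell_type)
    for i, s in enumerate(samples):
        if s in cases:
            weights[i, dep_idx] *= config.depletion_factor
            weights[i] /= weights[i].sum()

    mu = reference.to_numpy() @ weights.T  # cpgs x samples
    if config.beta_precision is None:
        beta = mu
    else:
        phi = config.beta_precision
        mu_c = np.clip(mu, 1e-6, 1.0 - 1e-6)
        beta = rng_noise.beta(mu_c * phi, (1.0 - mu_c) * phi)

    beta_df = pd.DataFrame(beta, index=cpgs, columns=samples)
    truth = MethSimTruth(
        weights=pd.DataFrame(weights, index=samples, columns=types),
        case_samples=cases,
        control_samples=controls,
        depleted_cell_type=config.depleted_cell_type,
    )
    return beta_df, reference, truth
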
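"""Synthetic intron retained/spliced counts with planted U12 retention.

Counts are generated directly as (retained, spliced) pairs — the retention
analysis operates at the count level, so simulating reads would add nothing
testable. Each U12 gene carries one U12-class intron whose case-sample PSI is
elevated by ``delta_psi`` (incomplete retention: elevated but sub-100%); all
other introns are U2 and unaffected. A configurable fraction of U12 genes is
hidden from the emitted annotation (class ``unknown``) while the truth record
keeps the full labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._seeds import stream_rng

__all__ = ["IRSimConfig", "IRSimTruth", "simulate_intron_counts", "round_half_up"]


def round_half_up(x: float) -> int:
    """Deterministic round-half-up: floor(x + 0.5)."""
    return int(np.floor(x + 0.5))


@dataclass
class IRSimConfig:
    n_cases: int = 3
    n_controls: int = 9
    n_genes: int = 100
    introns_per_gene: int = 5
    frac_u12_genes: float = 0.15
    frac_hidden_u12: float = 0.2
    baseline_psi: tuple[float, float] = (2.0, 38.0)  # Beta(a, b); mean 0.05
    delta_psi: float = 0.3
    depth_mean: float = 200.0
    depth_size: float = 10.0  # negative-binomial size (dispersion) parameter
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "introns_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frac_u12_genes", "frac_hidden_u12"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        a, b = self.baseline_psi
        if a <= 0 or b <= 0:
            raise ValueError(f"baseline_psi Beta parameters must be positive, got {self.baseline_psi}")
        mean_psi = a / (a + b)
        if not (0.0 < mean_psi + self.delta_psi <= 1.0):
            raise ValueError(
                f"mean baseline PSI ({mean_psi:.3f}) + delta_psi ({self.delta_psi}) "
                "must lie in (0, 1]"
            )
        if self.delta_psi < 0:
            raise ValueError(f"delta_psi must be >= 0, got {self.delta_psi}")
        if self.depth_mean <= 0 or self.depth_size <= 0:
            raise ValueError("depth parameters must be positive")
        if self.seed < 0:
            raise ValueError(f"seed must be >= 0, got {self.seed}")


@dataclass
class IRSimTruth:
    """Full per-intron labels and true group PSI values."""

    table: pd.DataFrame  # index intron_id; gene, true_class, hidden, psi_control, psi_case
    u12_genes: list[str]
    hidden_genes: list[str]
    case_samples: list[str]
    control_samples: list[str]

    def to_json(self) -> dict:
        return {
            "u12_genes": self.u12_genes,
            "hidden_genes": self.hidden_genes,
            "case_samples": self.case_samples,
            "control_samples": self.control_samples,
            "introns": {
                intron: {
                    "gene": r["gene"],
                    "true_class": r["true_class"],
                    "hidden": bool(r["hidden"]),
                    "psi_control": float(r["psi_control"]),
                    "psi_case": float(r["psi_case"]),
                }
                for intron, r in self.table.iterrows()
            },
        }

    @property
    def planted_introns(self) -> pd.Index:
        return self.table.index[self.table["true_class"] == "U12"]


def simulate_intron_counts(
    config: IRSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, IRSimTruth]:
    """Generate (retained, spliced, annotation, truth).

    ``retained``/``spliced`` are introns × samples integer DataFrames;
    ``annotation`` is the emitted intron annotation (hidden U12 genes carry
    class ``unknown``). Retained counts are Binomial(depth, psi) with depth
    drawn negative-binomial per (intron, sample); case-sample PSI of U12
    introns is the baseline plus ``delta_psi`` (clipped at 1).
    """
    rng_struct = stream_rng(config.seed, "introns.structure")
    rng_psi = stream_rng(config.seed, "introns.psi")
    rng_counts = stream_rng(config.seed, "introns.counts")

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    n_u12 = round_half_up(config.frac_u12_genes * config.n_genes)
    u12_genes = sorted(rng_struct.choice(genes, size=n_u12, replace=False).tolist())
    n_hidden = round_half_up(config.frac_hidden_u12 * n_u12)
    hidden_genes = sorted(rng_struct.choice(u12_genes, size=n_hidden, replace=False).tolist())
    # one U12 intron per U12 gene, at a random intron index
    u12_intron_idx = {
        g: int(rng_struct.integers(config.introns_per_gene)) for g in u12_genes
    }

    cases = [f"case_{i:03d}" for i in range(config.n_cases)]
    controls = [f"control_{i:03d}" for i in range(config.n_controls)]
    samples = cases + controls

    ann_rows, truth_rows = [], []
    for gi, gene in enumerate(genes):
        block = 10_000 + gi * 100_000
        for idx in range(config.introns_per_gene):
            intron_id = f"{gene}_i{idx}"
            is_u12 = gene in u12_genes and idx == u12_intron_idx[gene]
            true_class = "U12" if is_u12 else "U2"
            hidden = is_u12 and gene in hidden_genes
            emitted_class = "unknown" if hidden else true_class
            base = float(rng_psi.beta(*config.baseline_psi))
            psi_case = min(1.0, base + config.delta_psi) if is_u12 else base
            ann_rows.append(
                {
                    "intron_id": intron_id,
                    "gene": gene,
                    "chromosome": "chr1",
                    "start": block + idx * 1_000,
                    "end": block + idx * 1_000 + 200,
                    "intron_index": idx,
                    "spliceosome_class": emitted_class,
                }
            )
            truth_rows.append(
                {
                    "intron_id": intron_id,
                    "gene": gene,
                    "true_class": true_class,
                    "hidden": hidden,
                    "psi_control": base,
                    "psi_case": psi_case,
                }
            )

    annotation = pd.DataFrame(ann_rows).set_index("intron_id")
    truth_table = pd.DataFrame(truth_rows).set_index("intron_id")

    n_introns = len(truth_table)
    # negative binomial with mean depth_mean and size depth_size
    p_nb = config.depth_size / (config.depth_size + config.depth_mean)
    depth = rng_counts.negative_binomial(config.depth_size, p_nb, size=(n_introns, len(samples)))
    psi = np.where(
        np.isin(samples, cases)[None, :],
        truth_table["psi_case"].to_numpy()[:, None],
        truth_table["psi_control"].to_numpy()[:, None],
    )
    retained_arr = rng_counts.binomial(depth, psi)
    retained = pd.DataFrame(retained_arr, index=truth_table.index, columns=samples)
    spliced = pd.DataFrame(depth - retained_arr, index=truth_table.index, columns=samples)

    truth = IRSimTruth(
        table=truth_table,
        u12_genes=u12_genes,
        hidden_genes=hidden_genes,
        case_samples=cases,
        control_samples=controls,
    )
    return retained, spliced, annotation, truth
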
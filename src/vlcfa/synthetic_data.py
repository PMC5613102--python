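"""Ground-truth generators for every pipeline stage.

Raw chromatographic and qPCR data from heterologous-expression studies
are rarely published, so each stage of the pipeline is exercised against
simulated inputs with known truth:

* the elongation cascade is modelled as a sequential irreversible
  partition of the supplemented substrate — at steady state a fraction
  e_k of the material reaching node k−1 moves on to node k, so the
  terminal amount at node k is A0 · Π_{j≤k} e_j · (1 − e_{k+1}) (with
  e = 0 beyond the last step). Under this model the step-wise conversion
  statistic recovers 100·e_k exactly in the noiseless case.
* chromatographic areas get multiplicative lognormal noise (areas are
  positive with roughly constant CV) and a detection limit below which
  they read 0 ("N.D.").
* qPCR Cq values come from a linear log10(copies)→Cq curve per gene with
  Gaussian Cq noise; dilution-series points are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conversion_stats import PeakTable
from .fa_model import Cascade, FattyAcid, build_cascade, format_fa
from .qpcr_quant import StandardCurve

__all__ = [
    "CascadeSimConfig",
    "SfaSimConfig",
    "QpcrSimConfig",
    "simulate_cascade_areas",
    "noiseless_cascade_amounts",
    "simulate_sfa_profiles",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class CascadeSimConfig:
    """Sequential-elongation simulation settings.

    ``step_fractions[k]`` is the fraction of material reaching cascade
    node k that is elongated onward at step k+1; each must lie in
    [0, 1) — some substrate is always retained. The cascade length is
    ``len(step_fractions) + 1``.
    """

    substrate: FattyAcid
    step_fractions: tuple[float, ...]
    a0: float = 100.0
    noise_sigma: float = 0.0
    lod: float = 0.0
    seed: int = 0
    sample_id: str = "sim"
    treatment: str = "transgenic"

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError(f"initial amount must be positive, got {self.a0}")
        if self.noise_sigma < 0 or self.lod < 0:
            raise ValueError("noise_sigma and lod must be non-negative")
        for e in self.step_fractions:
            if not (0.0 <= e < 1.0):
                raise ValueError(f"step fraction {e} outside [0, 1)")

    @property
    def cascade(self) -> Cascade:
        return build_cascade(
            self.substrate, self.substrate.carbons + 2 * len(self.step_fractions)
        )


def noiseless_cascade_amounts(
    step_fractions: tuple[float, ...] | list[float], a0: float = 100.0
) -> np.ndarray:
    """Terminal node amounts of the sequential irreversible model.

    amount_k = a0 · Π_{j≤k} e_j · (1 − e_{k+1}), e beyond the last
    step taken as 0; the amounts sum to a0 (mass conservation).
    """
    e = np.concatenate([np.asarray(step_fractions, dtype=float), [0.0]])
    reach = a0 * np.concatenate([[1.0], np.cumprod(e[:-1])])
    return reach * (1.0 - e)


def simulate_cascade_areas(cfg: CascadeSimConfig) -> PeakTable:
    """Simulate one peak table for a supplemented-substrate culture.

    Lognormal noise with log-scale sd ``noise_sigma`` multiplies each
    noiseless amount; areas below ``lod`` read 0. The same seed yields a
    bit-identical table.
    """
    rng = np.random.default_rng(cfg.seed)
    amounts = noiseless_cascade_amounts(cfg.step_fractions, cfg.a0)
    if cfg.noise_sigma > 0:
        amounts = amounts * rng.lognormal(mean=0.0, sigma=cfg.noise_sigma, size=amounts.shape)
    amounts[amounts < cfg.lod] = 0.0
    areas = dict(zip(cfg.cascade.members, amounts.tolist()))
    return PeakTable(sample_id=cfg.sample_id, treatment=cfg.treatment, areas=areas)


@dataclass(frozen=True)
class SfaSimConfig:
    """Control-vs-transgenic saturate-profile simulation settings.

    ``baseline`` holds control areas for the ≥C24 saturate panel;
    ``boosts`` maps each transgenic treatment to per-fatty-acid
    multiplicative factors on the baseline area (1 = unchanged).
    Replicates get multiplicative lognormal noise of coefficient of
    variation ``noise_cv``.
    """

    baseline: dict[FattyAcid, float]
    boosts: dict[str, dict[FattyAcid, float]]
    n_replicates: int = 4
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError(f"noise cv must be non-negative, got {self.noise_cv}")
        for treatment, factors in self.boosts.items():
            for fa, b in factors.items():
                if b < 0:
                    raise ValueError(
                        f"negative boost {b} for {format_fa(fa)} in {treatment!r}"
                    )


def simulate_sfa_profiles(cfg: SfaSimConfig) -> list[PeakTable]:
    """Replicate peak tables for control and each transgenic treatment."""
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log1p(cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0
    fas = sorted(cfg.baseline)
    tables: list[PeakTable] = []
    for treatment in ["control", *cfg.boosts]:
        factors = cfg.boosts.get(treatment, {})
        for rep in range(1, cfg.n_replicates + 1):
            areas = {}
            for fa in fas:
                mean = cfg.baseline[fa] * factors.get(fa, 1.0)
                noise = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
                areas[fa] = mean * noise
            tables.append(
                PeakTable(sample_id=f"{treatment}_{rep}", treatment=treatment, areas=areas)
            )
    return tables


@dataclass(frozen=True)
class QpcrSimConfig:
    """Tissue-panel qPCR simulation settings.

    ``true_copies[tissue][gene]`` are the per-reaction template copies;
    each gene carries its own true standard curve. Sample Cq values are
    curve(copies) plus Gaussian noise of sd ``cq_sd``, read in
    ``n_duplicates`` technical replicates per reaction.
    """

    curves: dict[str, StandardCurve]
    true_copies: dict[str, dict[str, float]]
    cq_sd: float = 0.2
    fish_per_tissue: int = 4
    n_duplicates: int = 2
    dilution_copies: tuple[float, ...] = (1e3, 1e4, 1e5, 1e6, 1e7, 1e8)
    seed: int = 0
    sexes: tuple[str, ...] = ("F", "F", "M", "M")

    def __post_init__(self) -> None:
        for gene, curve in self.curves.items():
            if curve.slope >= 0:
                raise ValueError(f"gene {gene!r}: standard-curve slope must be negative")
        if self.cq_sd < 0:
            raise ValueError("cq_sd must be non-negative")
        if self.fish_per_tissue < 1 or self.n_duplicates < 1:
            raise ValueError("fish_per_tissue and n_duplicates must be >= 1")


def simulate_qpcr(cfg: QpcrSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a dilution series and a tissue-panel measurement table.

    Returns ``(dilution, measurements)`` data frames in the CSV dialects
    the readers consume: dilution has columns (gene, copies, cq) with Cq
    computed exactly from the true curve; measurements has columns
    (tissue, sex, fish_id, gene, cq_rep1, …).
    """
    rng = np.random.default_rng(cfg.seed)
    dil_rows = [
        {"gene": gene, "copies": c, "cq": curve.cq(c)}
        for gene, curve in cfg.curves.items()
        for c in cfg.dilution_copies
    ]
    meas_rows = []
    for tissue, gene_copies in cfg.true_copies.items():
        for i in range(cfg.fish_per_tissue):
            fish_id = f"{tissue}_fish{i + 1}"
            sex = cfg.sexes[i % len(cfg.sexes)]
            for gene, copies in gene_copies.items():
                if gene not in cfg.curves:
                    raise KeyError(f"tissue {tissue!r}: no curve for gene {gene!r}")
                true_cq = cfg.curves[gene].cq(copies)
                reps = true_cq + rng.normal(0.0, cfg.cq_sd, size=cfg.n_duplicates)
                row = {"tissue": tissue, "sex": sex, "fish_id": fish_id, "gene": gene}
                row.update({f"cq_rep{j + 1}": float(q) for j, q in enumerate(reps)})
                meas_rows.append(row)
    return pd.DataFrame(dil_rows), pd.DataFrame(meas_rows)
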
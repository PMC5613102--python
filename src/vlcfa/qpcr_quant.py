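"""Absolute qPCR quantification against a plasmid standard curve.

Copy numbers of serially diluted, linearized plasmid standards are
computed from DNA mass with the double-stranded molecular-weight
convention of 660 g/mol per base pair. A standard curve regresses Cq on
log10(copies); unknowns are quantified by inverting the line, and target
expression is normalized as absolute target copies divided by absolute
reference-gene (e.g. 28S rRNA) copies in the same sample. Per-tissue
summaries report mean ± SE with ANOVA/Tukey compact letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conversion_stats import anova_tukey_cld

__all__ = [
    "AVOGADRO",
    "BP_MOLAR_MASS",
    "StandardCurve",
    "QpcrMeasurement",
    "NormalizedExpression",
    "UndefinedRatioError",
    "plasmid_copy_number",
    "fit_standard_curve",
    "quantify",
    "normalize_expression",
    "normalized_ratios",
    "tissue_summary",
]

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair, g/mol.
BP_MOLAR_MASS = 660.0


class UndefinedRatioError(ZeroDivisionError):
    """Reference copies are zero — the normalized ratio is undefined."""


def plasmid_copy_number(mass_g: float, length_bp: float) -> float:
    """Copies in ``mass_g`` grams of a linearized construct of ``length_bp``.

    copies = mass / (660 g/mol/bp × length) × N_A. Linear in mass,
    inverse-linear in length.
    """
    if length_bp <= 0:
        raise ValueError(f"construct length must be positive, got {length_bp}")
    if mass_g < 0:
        raise ValueError(f"mass must be non-negative, got {mass_g}")
    return mass_g / (BP_MOLAR_MASS * length_bp) * AVOGADRO


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Cq = slope · log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10^(−1/slope) − 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq(self, copies: float) -> float:
        """Predicted Cq for a known copy number (used by simulators)."""
        return self.slope * math.log10(copies) + self.intercept


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq on log10(known copies).

    ``points`` are (copies, Cq) pairs; at least three distinct dilution
    levels are required and every copy number must be positive.
    """
    if any(c <= 0 for c, _ in points):
        bad = [c for c, _ in points if c <= 0]
        raise ValueError(f"copy numbers must be positive, got {bad}")
    copies = np.array([c for c, _ in points], dtype=float)
    cqs = np.array([q for _, q in points], dtype=float)
    if len(np.unique(copies)) < 3:
        raise ValueError(
            f"standard curve needs >= 3 distinct dilution points, got {len(np.unique(copies))}"
        )
    res = sps.linregress(np.log10(copies), cqs)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify(cq: float, curve: StandardCurve) -> float:
    """Absolute copies for an observed Cq: 10^((cq − intercept)/slope)."""
    if curve.slope >= 0:
        raise ValueError(
            f"invalid assay: standard-curve slope must be negative, got {curve.slope}"
        )
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Duplicate Cq readings for one gene in one sample."""

    tissue: str
    sex: str
    fish_id: str
    gene: str
    cq_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cq_values:
            raise ValueError("a measurement needs at least one Cq value")
        if any(q <= 0 or not math.isfinite(q) for q in self.cq_values):
            raise ValueError(
                f"{self.tissue}/{self.fish_id}/{self.gene}: Cq values must be "
                f"positive and finite, got {self.cq_values}"
            )

    @property
    def mean_cq(self) -> float:
        # Duplicates are averaged on the Cq scale (configurable upstream).
        return float(np.mean(self.cq_values))


@dataclass(frozen=True)
class NormalizedExpression:
    """Target/reference absolute-copy ratio for one sample."""

    tissue: str
    fish_id: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError(f"ratio must be non-negative, got {self.ratio}")


def normalize_expression(
    target_copies: float, reference_copies: float, *, tissue: str = "", fish_id: str = ""
) -> NormalizedExpression:
    """Normalized ratio = absolute target copies / absolute reference copies."""
    if reference_copies <= 0:
        raise UndefinedRatioError(
            f"sample {tissue}/{fish_id}: reference copies is "
            f"{reference_copies}; ratio undefined"
        )
    return NormalizedExpression(tissue=tissue, fish_id=fish_id, ratio=target_copies / reference_copies)


def normalized_ratios(
    measurements: list[QpcrMeasurement],
    curves: dict[str, StandardCurve],
    target_gene: str,
    reference_gene: str,
    *,
    cq_average: str = "cq",
) -> list[NormalizedExpression]:
    """Quantify every sample for target and reference and form ratios.

    Each gene is quantified against its own standard curve. ``cq_average``
    selects whether duplicates are averaged on the Cq scale (``"cq"``,
    default) or on the copy scale (``"copies"``).
    """
    if cq_average not in ("cq", "copies"):
        raise ValueError(f"cq_average must be 'cq' or 'copies', got {cq_average!r}")

    def copies_of(m: QpcrMeasurement) -> float:
        curve = curves[m.gene]
        if cq_average == "cq":
            return quantify(m.mean_cq, curve)
        return float(np.mean([quantify(q, curve) for q in m.cq_values]))

    by_sample: dict[tuple[str, str], dict[str, float]] = {}
    for m in measurements:
        if m.gene not in curves:
            raise KeyError(f"no standard curve fitted for gene {m.gene!r}")
        by_sample.setdefault((m.tissue, m.fish_id), {})[m.gene] = copies_of(m)

    out = []
    for (tissue, fish_id), gene_copies in sorted(by_sample.items()):
        if target_gene not in gene_copies or reference_gene not in gene_copies:
            raise ValueError(
                f"sample {tissue}/{fish_id}: needs both {target_gene!r} and "
                f"{reference_gene!r} measurements"
            )
        out.append(
            normalize_expression(
                gene_copies[target_gene],
                gene_copies[reference_gene],
                tissue=tissue,
                fish_id=fish_id,
            )
        )
    return out


def tissue_summary(
    samples: list[NormalizedExpression], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-tissue mean ± SE of normalized ratios with Tukey compact letters.

    Requires at least two tissues and at least two fish per tissue; a
    tissue with a single fish is rejected by name.
    """
    by_tissue: dict[str, list[float]] = {}
    for s in samples:
        by_tissue.setdefault(s.tissue, []).append(s.ratio)
    vc = anova_tukey_cld(
        {t: np.asarray(v) for t, v in by_tissue.items()}, alpha=alpha
    )
    rows = [
        {
            "tissue": t,
            "n": vc.ns[t],
            "mean_ratio": vc.means[t],
            "se": vc.sems[t],
            "letter": vc.letters[t],
            "anova_p": vc.anova_p,
        }
        for t in by_tissue
    ]
    return pd.DataFrame(rows)
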
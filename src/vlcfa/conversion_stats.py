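"""Step-wise elongation conversions and VLC-SFA profile statistics.

The central statistic measures, for each step of an elongation cascade,
the fraction of that step's substrate pool that was elongated to the
immediate product *or beyond*:

    conversion_k = 100 * sum(area_i, i >= k) / (area_{k-1} + sum(area_i, i >= k))

with the substrate redefined at every step — step k's substrate is cascade
member k-1. Peak areas are relative chromatographic integrals, so the
statistic is invariant to uniform rescaling.

Very long-chain saturate (VLC-SFA) profiles are expressed as area
percentages of the total saturated fatty acids at or above a carbon
threshold (default C24), and compared across treatments with one-way
ANOVA followed by Tukey's HSD and a compact letter display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .fa_model import Cascade, FattyAcid, elongate, format_fa

__all__ = [
    "PeakTable",
    "ConversionResult",
    "SFAProfile",
    "GroupComparison",
    "EmptyProfileError",
    "stepwise_conversions",
    "sfa_percentages",
    "compare_groups",
    "anova_tukey_cld",
    "compact_letter_display",
]


class EmptyProfileError(ValueError):
    """All qualifying saturate areas are zero — no profile can be formed."""


@dataclass(frozen=True)
class PeakTable:
    """Integrated GC peak areas for one culture (arbitrary area units)."""

    sample_id: str
    treatment: str
    areas: dict[FattyAcid, float]

    def __post_init__(self) -> None:
        for fa, area in self.areas.items():
            if not math.isfinite(area) or area < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative or non-finite area "
                    f"{area!r} for {format_fa(fa)}"
                )

    def area(self, fa: FattyAcid) -> float:
        return self.areas.get(fa, 0.0)


@dataclass(frozen=True)
class ConversionResult:
    """Conversion at one cascade step, or a not-detected flag.

    ``step_index`` is 1-based; ``step_substrate`` is cascade member
    ``step_index - 1`` and ``step_product`` its +2C elongation.
    """

    step_index: int
    step_substrate: FattyAcid
    step_product: FattyAcid
    conversion: float | None
    not_detected: bool

    def __post_init__(self) -> None:
        if self.step_product != elongate(self.step_substrate):
            raise ValueError("step_product must be the +2C elongation of step_substrate")
        if self.not_detected != (self.conversion is None):
            raise ValueError("conversion must be present iff not_detected is False")
        if self.conversion is not None and not (0.0 <= self.conversion <= 100.0):
            raise ValueError(f"conversion {self.conversion} outside [0, 100]")

    @property
    def label(self) -> str:
        """The elongation label, e.g. ``C22 → 24``."""
        return f"C{self.step_substrate.carbons} → {self.step_product.carbons}"


def stepwise_conversions(
    peaks: PeakTable, cascade: Cascade, lod: float = 0.0
) -> list[ConversionResult]:
    """Compute the step-wise conversion for every step of ``cascade``.

    Areas below the detection limit ``lod`` are zeroed before the
    statistic. A step whose substrate and entire downstream tail are
    undetected is flagged not-detected; a step with no substrate but
    detectable downstream product converts at 100%. Cascade members
    missing from the peak table are treated as area 0 with a warning.
    """
    if len(cascade) < 2:
        raise ValueError("cascade must have at least 2 members to define a step")
    if lod < 0:
        raise ValueError(f"detection limit must be non-negative, got {lod}")
    missing = [fa for fa in cascade if fa not in peaks.areas]
    if missing:
        warnings.warn(
            f"sample {peaks.sample_id!r}: cascade members absent from peak table "
            f"treated as area 0: {', '.join(format_fa(fa) for fa in missing)}",
            stacklevel=2,
        )
    areas = np.array([peaks.area(fa) for fa in cascade], dtype=float)
    areas[areas < lod] = 0.0

    results: list[ConversionResult] = []
    for k in range(1, len(cascade)):
        substrate_area = areas[k - 1]
        downstream = float(areas[k:].sum())
        denom = substrate_area + downstream
        if denom == 0.0:
            conv: float | None = None
        else:
            # ratio first, then scale, clamped against floating-point overshoot
            conv = min(100.0, float(100.0 * (downstream / denom)))
        results.append(
            ConversionResult(
                step_index=k,
                step_substrate=cascade.members[k - 1],
                step_product=cascade.members[k],
                conversion=conv,
                not_detected=conv is None,
            )
        )
    return results


@dataclass(frozen=True)
class SFAProfile:
    """Saturate area percentages (of total qualifying saturates) for one sample."""

    sample_id: str
    treatment: str
    percents: dict[FattyAcid, float]

    def __post_init__(self) -> None:
        if self.percents:
            total = sum(self.percents.values())
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"percentages sum to {total!r}, expected 100")


def sfa_percentages(peaks: PeakTable, min_carbons: int = 24) -> SFAProfile:
    """Express each saturate with ≥ ``min_carbons`` carbons as a percentage
    of the total qualifying saturate area."""
    qualifying = {
        fa: a for fa, a in peaks.areas.items() if fa.saturated and fa.carbons >= min_carbons
    }
    if not qualifying:
        raise EmptyProfileError(
            f"sample {peaks.sample_id!r}: no saturated fatty acid with "
            f">= {min_carbons} carbons present"
        )
    total = sum(qualifying.values())
    if total == 0:
        raise EmptyProfileError(
            f"sample {peaks.sample_id!r}: all qualifying saturate areas are zero"
        )
    percents = {fa: 100.0 * a / total for fa, a in sorted(qualifying.items())}
    return SFAProfile(peaks.sample_id, peaks.treatment, percents)


# ---------------------------------------------------------------------------
# Group comparison: ANOVA + Tukey HSD + compact letter display
# ---------------------------------------------------------------------------


@dataclass
class VariableComparison:
    """ANOVA/Tukey summary for one response variable across groups."""

    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    anova_p: float
    tukey_p: dict[tuple[str, str], float]
    letters: dict[str, str]


@dataclass
class GroupComparison:
    """Per-fatty-acid group comparison over SFA profiles."""

    alpha: float
    variables: dict[FattyAcid, VariableComparison] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format summary table: one row per (fatty acid, group)."""
        rows = []
        for fa, vc in self.variables.items():
            for group in vc.means:
                rows.append(
                    {
                        "fatty_acid": format_fa(fa),
                        "group": group,
                        "n": vc.ns[group],
                        "mean": vc.means[group],
                        "se": vc.sems[group],
                        "letter": vc.letters[group],
                        "anova_p": vc.anova_p,
                    }
                )
        return pd.DataFrame(rows)


def compact_letter_display(
    groups: list[str],
    significant: set[tuple[str, str]],
    means: dict[str, float] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds unordered pairs declared different; groups that
    share a letter are not significantly different and vice versa. Ties in
    letter ordering are broken by descending group mean (presentational).
    """
    sig = {frozenset(p) for p in significant}
    if means is not None:
        ordered = sorted(groups, key=lambda g: -means[g])
    else:
        ordered = list(groups)

    # Each column is a set of mutually non-different groups.
    columns: list[set[str]] = [set(ordered)]
    for pair in sorted(sig, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, proper subsets of another column, duplicates
        columns = []
        for col in new_columns:
            if not col or any(col < other for other in new_columns):
                continue
            if col not in columns:
                columns.append(col)

    # Order letters by the best (highest-mean) group they contain.
    rank = {g: i for i, g in enumerate(ordered)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in ordered}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, col in enumerate(columns):
        for g in ordered:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_tukey_cld(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> VariableComparison:
    """One-way ANOVA, Tukey HSD pairwise tests and compact letters.

    Requires at least two groups and at least two replicates per group;
    a singleton group is rejected by name.
    """
    if len(values_by_group) < 2:
        raise ValueError("group comparison requires at least 2 groups")
    for group, vals in values_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {group!r} has a single replicate; need >= 2")
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    sems = {g: float(np.std(a, ddof=1) / np.sqrt(len(a))) for g, a in zip(groups, arrays)}
    ns = {g: int(len(a)) for g, a in zip(groups, arrays)}

    anova_p = float(sps.f_oneway(*arrays).pvalue)

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    if np.ptp(flat) == 0:
        # Degenerate: all observations identical; no pair differs.
        tukey_p = {tuple(sorted((g1, g2))): 1.0 for i, g1 in enumerate(groups) for g2 in groups[i + 1:]}
        anova_p = 1.0
    else:
        with warnings.catch_warnings():
            # zero within-group variance yields an infinite studentized range;
            # the resulting p-values (0) are exactly what we want
            warnings.simplefilter("ignore", RuntimeWarning)
            res = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        pairs = [(str(row[0]), str(row[1])) for row in res.summary().data[1:]]
        tukey_p = {
            tuple(sorted(pair)): float(p) for pair, p in zip(pairs, res.pvalues)
        }
    significant = {pair for pair, p in tukey_p.items() if p <= alpha}
    letters = compact_letter_display(groups, significant, means)
    return VariableComparison(means, sems, ns, anova_p, tukey_p, letters)


def compare_groups(profiles: list[SFAProfile], alpha: float = 0.05) -> GroupComparison:
    """Compare SFA area-percentages across treatments, one test per fatty acid.

    A fatty acid absent from a sample's profile counts as 0% for that
    sample (it was below the qualifying set's detection).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    treatments: dict[str, list[SFAProfile]] = {}
    for p in profiles:
        treatments.setdefault(p.treatment, []).append(p)
    if len(treatments) < 2:
        raise ValueError("group comparison requires at least 2 treatment groups")
    all_fas = sorted({fa for p in profiles for fa in p.percents})
    out = GroupComparison(alpha=alpha)
    for fa in all_fas:
        values_by_group = {
            t: np.array([p.percents.get(fa, 0.0) for p in ps]) for t, ps in treatments.items()
        }
        out.variables[fa] = anova_tukey_cld(values_by_group, alpha=alpha)
    return out
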
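"""Fatty-acid shorthand nomenclature and elongation cascades.

Fatty acids are written in the lipidomics shorthand ``C:Dn-x`` — carbon
count, number of double bonds, and the n-series (position of the first
double bond counted from the methyl end). Saturates are written ``C:0``
with no series suffix, e.g. ``24:0``. An elongation cascade is the chain
substrate → substrate+2C → substrate+4C → … produced by iterative
condensation of malonyl-CoA onto the acyl chain: each step adds exactly
two carbons and leaves the double bonds and series untouched.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

__all__ = [
    "Series",
    "FattyAcid",
    "Cascade",
    "FattyAcidError",
    "parse_fa",
    "format_fa",
    "elongate",
    "build_cascade",
    "MIN_CARBONS",
    "MAX_CARBONS",
    "MAX_DOUBLE_BONDS",
    "DEFAULT_MAX_CARBONS",
]

MIN_CARBONS = 12
MAX_CARBONS = 40
MAX_DOUBLE_BONDS = 6
#: Longest product class observed in the yeast assays; per-substrate override
#: is available wherever a cascade is built.
DEFAULT_MAX_CARBONS = 36


class FattyAcidError(ValueError):
    """Raised for malformed shorthand names or invalid fatty-acid fields."""


class Series(enum.Enum):
    """Double-bond series of a fatty acid (methyl-end numbering)."""

    N3 = "n-3"
    N6 = "n-6"
    N9 = "n-9"
    SATURATED = "saturated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A straight, even-chain fatty acid in shorthand terms.

    Parameters
    ----------
    carbons
        Even carbon count, 12–40.
    double_bonds
        Number of methylene-interrupted double bonds, 0–6. Zero if and
        only if the series is saturated.
    series
        The n-series (n-3, n-6, n-9) or :attr:`Series.SATURATED`.
    """

    carbons: int
    double_bonds: int
    series: Series

    def __post_init__(self) -> None:
        if not isinstance(self.carbons, int) or isinstance(self.carbons, bool):
            raise FattyAcidError(f"carbon count must be an integer, got {self.carbons!r}")
        if self.carbons % 2 != 0:
            raise FattyAcidError(f"odd carbon count {self.carbons}: only even chains are modelled")
        if not (MIN_CARBONS <= self.carbons <= MAX_CARBONS):
            raise FattyAcidError(
                f"carbon count {self.carbons} outside the supported range "
                f"[{MIN_CARBONS}, {MAX_CARBONS}]"
            )
        if not (0 <= self.double_bonds <= MAX_DOUBLE_BONDS):
            raise FattyAcidError(
                f"double-bond count {self.double_bonds} outside [0, {MAX_DOUBLE_BONDS}]"
            )
        if (self.double_bonds == 0) != (self.series is Series.SATURATED):
            raise FattyAcidError(
                f"double_bonds={self.double_bonds} inconsistent with series "
                f"{self.series.value!r}: zero double bonds iff saturated"
            )

    @property
    def saturated(self) -> bool:
        return self.series is Series.SATURATED

    def __str__(self) -> str:
        return format_fa(self)


# Accepted dialects: "22:5n-3", "22:5 n-3", "22:5(n-3)", "22:5 (n-3)", "24:0".
_FA_RE = re.compile(
    r"""^\s*
        (?P<carbons>\d+) : (?P<db>\d+)
        (?:\s*\(\s*n-(?P<series_paren>\d)\s*\)
          |\s*n-(?P<series_plain>\d)
        )?
        \s*$""",
    re.VERBOSE,
)


def parse_fa(name: str) -> FattyAcid:
    """Parse a shorthand fatty-acid name into a :class:`FattyAcid`.

    Accepts ``22:5n-3``, ``22:5 n-3`` and ``22:5(n-3)``; saturates are
    ``24:0``. Raises :class:`FattyAcidError` citing the offending token.
    """
    if not isinstance(name, str):
        raise FattyAcidError(f"fatty-acid name must be text, got {name!r}")
    m = _FA_RE.match(name)
    if m is None:
        raise FattyAcidError(f"malformed fatty-acid name {name!r}")
    carbons = int(m.group("carbons"))
    db = int(m.group("db"))
    series_digit = m.group("series_paren") or m.group("series_plain")
    if series_digit is None:
        if db != 0:
            raise FattyAcidError(
                f"{name!r}: {db} double bond(s) but no n-series given"
            )
        series = Series.SATURATED
    else:
        if db == 0:
            raise FattyAcidError(
                f"{name!r}: a series suffix is not allowed on a saturate"
            )
        try:
            series = Series(f"n-{series_digit}")
        except ValueError:
            raise FattyAcidError(
                f"{name!r}: unknown series n-{series_digit} (expected n-3, n-6 or n-9)"
            ) from None
    return FattyAcid(carbons, db, series)


def format_fa(fa: FattyAcid) -> str:
    """Canonical shorthand: ``36:4n-3`` for PUFA, ``28:0`` for saturates."""
    if fa.saturated:
        return f"{fa.carbons}:0"
    return f"{fa.carbons}:{fa.double_bonds}{fa.series.value}"


def elongate(fa: FattyAcid, max_carbons: int = MAX_CARBONS) -> FattyAcid:
    """One +2C elongation step; double bonds and series are preserved."""
    if fa.carbons + 2 > max_carbons:
        raise FattyAcidError(
            f"elongation of {format_fa(fa)} exceeds the maximum chain length {max_carbons}"
        )
    return FattyAcid(fa.carbons + 2, fa.double_bonds, fa.series)


@dataclass(frozen=True)
class Cascade:
    """An ordered +2C elongation chain; index 0 is the supplemented substrate."""

    members: tuple[FattyAcid, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FattyAcidError("a cascade needs at least one member")
        for a, b in zip(self.members, self.members[1:]):
            if b.carbons != a.carbons + 2:
                raise FattyAcidError(
                    f"cascade step {format_fa(a)} → {format_fa(b)} is not +2 carbons"
                )
            if b.double_bonds != a.double_bonds or b.series is not a.series:
                raise FattyAcidError(
                    "double bonds and series must be constant along a cascade"
                )

    @property
    def substrate(self) -> FattyAcid:
        return self.members[0]

    @property
    def n_steps(self) -> int:
        return len(self.members) - 1

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __str__(self) -> str:
        return " → ".join(format_fa(fa) for fa in self.members)


def build_cascade(substrate: FattyAcid, max_carbons: int = DEFAULT_MAX_CARBONS) -> Cascade:
    """Build the cascade substrate, +2C, +4C, … up to ``max_carbons``.

    The member count is ``(max_carbons - substrate.carbons) / 2 + 1``.
    """
    if max_carbons % 2 != 0:
        raise FattyAcidError(f"max_carbons must be even, got {max_carbons}")
    if max_carbons < substrate.carbons:
        raise FattyAcidError(
            f"max_carbons {max_carbons} is below the substrate length {substrate.carbons}"
        )
    members = [substrate]
    while members[-1].carbons < max_carbons:
        members.append(elongate(members[-1], max_carbons=max_carbons))
    return Cascade(tuple(members))
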
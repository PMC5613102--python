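"""ORF translation and Elovl diagnostic motif scanning.

Elovl-family condensing enzymes share a small set of diagnostic motifs on
the deduced protein: the histidine box HXXHH at the catalytic core, the
C-terminal di-basic ER retrieval signal RXKXX, and several conserved
blocks (KXXEXXDT, QXXFLHXXHH, NXXXHXXMYXYY, TXXQXXQ). Patterns use the
20 amino-acid letters plus the single wildcard X; matches may overlap and
coordinates are 1-based inclusive, as in sequence figures.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "Anchor",
    "MotifPattern",
    "MotifHit",
    "OrfError",
    "NonTripletError",
    "MissingStartError",
    "MissingStopError",
    "InternalStopError",
    "DEFAULT_MOTIFS",
    "ER_RETRIEVAL",
    "translate_orf",
    "find_orf",
    "scan_motifs",
    "check_er_signal",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = set(_STANDARD_TABLE.stop_codons)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class OrfError(ValueError):
    """Base class for open-reading-frame validation failures."""


class NonTripletError(OrfError):
    """Sequence length is not divisible by three."""


class MissingStartError(OrfError):
    """Sequence does not begin with the ATG start codon."""


class MissingStopError(OrfError):
    """Sequence does not end with a stop codon."""


class InternalStopError(OrfError):
    """A stop codon occurs before the final codon."""


def _clean_nt(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise OrfError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def translate_orf(seq: str) -> str:
    """Translate a complete ORF (ATG … stop) with the standard code.

    The terminal stop codon is not translated, so the protein length is
    len(seq)/3 − 1. Codons containing N translate as ``X`` with a warning.
    Distinct errors are raised for non-triplet length, a missing ATG
    start, a missing terminal stop and internal stop codons.
    """
    s = _clean_nt(seq)
    if not s:
        raise OrfError("empty sequence")
    if len(s) % 3 != 0:
        raise NonTripletError(f"length {len(s)} is not a multiple of 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons[0] != "ATG":
        raise MissingStartError(f"ORF must start with ATG, found {codons[0]}")
    if codons[-1] not in _STOP_CODONS:
        raise MissingStopError(f"ORF must end with a stop codon, found {codons[-1]}")
    protein = []
    for i, codon in enumerate(codons[:-1], start=1):
        if "N" in codon:
            warnings.warn(
                f"ambiguous codon {codon} at codon position {i} translated as X",
                stacklevel=2,
            )
            protein.append("X")
        elif codon in _STOP_CODONS:
            raise InternalStopError(f"internal stop codon {codon} at codon position {i}")
        else:
            protein.append(_CODON_TO_AA[codon])
    return "".join(protein)


def find_orf(seq: str) -> str:
    """Longest ATG-to-stop open reading frame in the three forward frames.

    A convenience for extracting the coding region from a full-length
    cDNA before :func:`translate_orf`. Raises :class:`OrfError` when no
    complete ORF exists.
    """
    s = _clean_nt(seq)
    best = ""
    for start in range(len(s) - 2):
        if s[start : start + 3] != "ATG":
            continue
        for end in range(start + 3, len(s) - 2, 3):
            codon = s[end : end + 3]
            if codon in _STOP_CODONS:
                if end + 3 - start > len(best):
                    best = s[start : end + 3]
                break
    if not best:
        raise OrfError("no complete ATG-to-stop open reading frame found")
    return best


class Anchor(enum.Enum):
    ANYWHERE = "anywhere"
    C_TERMINAL_WINDOW = "c_terminal_window"


@dataclass(frozen=True)
class MotifPattern:
    """An X-wildcard motif over the 20 amino-acid letters."""

    name: str
    pattern: str
    anchor: Anchor = Anchor.ANYWHERE

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError(f"pattern {self.pattern!r} shorter than 3 residues")
        bad = set(self.pattern) - AA_ALPHABET - {"X"}
        if bad:
            raise ValueError(
                f"pattern {self.pattern!r} contains characters outside the "
                f"amino-acid alphabet + X: {sorted(bad)}"
            )

    def matches_at(self, protein: str, start0: int) -> bool:
        """Positional match at 0-based offset ``start0`` (X matches anything)."""
        window = protein[start0 : start0 + len(self.pattern)]
        if len(window) != len(self.pattern):
            return False
        return all(p == "X" or p == r for p, r in zip(self.pattern, window))


@dataclass(frozen=True)
class MotifHit:
    """A single motif occurrence; ``start`` is 1-based inclusive."""

    name: str
    start: int
    matched: str


#: Histidine box, ER retrieval signal and the conserved Elovl blocks.
ER_RETRIEVAL = MotifPattern("ER_retrieval", "RXKXX", Anchor.C_TERMINAL_WINDOW)
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("histidine_box", "HXXHH"),
    MotifPattern("block_i", "KXXEXXDT"),
    MotifPattern("block_ii", "QXXFLHXXHH"),
    MotifPattern("block_iii", "NXXXHXXMYXYY"),
    MotifPattern("block_iv", "TXXQXXQ"),
)


def scan_motifs(
    protein: str, patterns: list[MotifPattern] | tuple[MotifPattern, ...] = DEFAULT_MOTIFS
) -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, ascending by position.

    C-terminally anchored patterns are only reported when the match ends
    at the last residue.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()
    hits: list[MotifHit] = []
    for pat in patterns:
        if pat.anchor is Anchor.C_TERMINAL_WINDOW:
            starts: range | list[int] = [len(protein) - len(pat.pattern)]
            if starts[0] < 0:
                continue
        else:
            starts = range(len(protein) - len(pat.pattern) + 1)
        for s0 in starts:
            if pat.matches_at(protein, s0):
                hits.append(MotifHit(pat.name, s0 + 1, protein[s0 : s0 + len(pat.pattern)]))
    hits.sort(key=lambda h: (h.start, h.name))
    return hits


def check_er_signal(protein: str) -> tuple[bool, int | None]:
    """Check the C-terminal di-basic ER retrieval signal RXKXX.

    True iff the final five residues carry R at −5 and K at −3. Returns
    the 1-based start position of the terminal window on a match.
    """
    if len(protein) < 5:
        raise ValueError(
            f"protein of length {len(protein)} too short for the 5-residue ER signal"
        )
    hits = scan_motifs(protein, [ER_RETRIEVAL])
    if hits:
        return True, hits[0].start
    return False, None
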
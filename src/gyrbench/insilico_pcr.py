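"""IUPAC-aware degenerate-primer matching and in-silico amplification.

Both the reference-database builder and the read simulator rely on the same
primer semantics: a primer position matches a template base when the base is a
member of the IUPAC degeneracy set of the primer letter, and an amplicon is
the insert bracketed by a forward site and the reverse complement of the
reverse primer downstream of it.

Built-in presets cover the two marker systems used throughout the package:
``gyrB`` (degenerate F64/R353, amplifying a ~280 bp fragment of the
topoisomerase II subunit B gene and, within Firmicutes, its parE paralog) and
``V3V4`` (the 16S rDNA V3-V4 primers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC",
    "PrimerPair",
    "PrimerMatch",
    "PRIMER_PRESETS",
    "InvalidBaseError",
    "iupac_match",
    "reverse_complement",
    "find_primer_sites",
    "amplify",
]

# IUPAC nucleotide degeneracy sets.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBN", "TGCAKYWSRMBDHVN")


class InvalidBaseError(ValueError):
    """A sequence contains a character outside the IUPAC alphabet."""


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair, both primers written 5'->3' as synthesized."""

    forward: str
    reverse: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            for pos, ch in enumerate(seq):
                if ch not in IUPAC:
                    raise InvalidBaseError(
                        f"invalid IUPAC code {ch!r} at position {pos} of {name} primer"
                    )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class PrimerMatch:
    """A primer binding site on a template (0-based, end exclusive)."""

    start: int
    end: int
    strand: str = "+"
    mismatches: int = 0


#: Named presets resolvable on the CLI. ``gyrB`` is F64/R353; ``V3V4`` the
#: 16S rDNA V3-V4 pair.
PRIMER_PRESETS: dict[str, PrimerPair] = {
    "gyrB": PrimerPair("MGNCCNGSNATGTAYATHGG", "CNCCRTGNARDCCDCCNGA"),
    "V3V4": PrimerPair("ACGGRAGGCWGCAGT", "TACCAGGGTATCTAATCCT"),
}


def _validate(seq: str, what: str = "sequence") -> None:
    for pos, ch in enumerate(seq):
        if ch not in IUPAC:
            raise InvalidBaseError(f"invalid IUPAC code {ch!r} at position {pos} of {what}")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    _validate(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(primer: str, window: str, max_mismatches: int = 0) -> int | None:
    """Count mismatches between a degenerate primer and an equal-length window.

    A position matches when the window base is in the primer letter's IUPAC
    set. Returns the mismatch count, or ``None`` when it exceeds
    ``max_mismatches``.
    """
    if len(primer) != len(window):
        raise ValueError("primer and window must have equal length")
    _validate(primer, "primer")
    _validate(window, "window")
    mism = 0
    for p, w in zip(primer, window):
        if w not in IUPAC[p]:
            mism += 1
            if mism > max_mismatches:
                return None
    return mism


def _iupac_regex(primer: str) -> re.Pattern[str]:
    return re.compile("".join(f"[{''.join(sorted(IUPAC[c]))}]" for c in primer))


def find_primer_sites(primer: str, template: str, max_mismatches: int = 0) -> list[PrimerMatch]:
    """All plus-strand binding sites of ``primer`` on ``template``."""
    _validate(primer, "primer")
    _validate(template, "template")
    n, m = len(template), len(primer)
    sites: list[PrimerMatch] = []
    if max_mismatches == 0:
        # exact degenerate match: overlapping regex scan
        pat = _iupac_regex(primer)
        pos = 0
        while True:
            hit = pat.search(template, pos)
            if hit is None:
                break
            sites.append(PrimerMatch(hit.start(), hit.start() + m, "+", 0))
            pos = hit.start() + 1
        return sites
    for start in range(n - m + 1):
        mm = iupac_match(primer, template[start : start + m], max_mismatches)
        if mm is not None:
            sites.append(PrimerMatch(start, start + m, "+", mm))
    return sites


def amplify(template: str, primers: PrimerPair, keep_primers: bool = False) -> str | None:
    """In-silico PCR: extract the insert bracketed by a primer pair.

    The forward primer is located on the template as given; the reverse primer
    binds the minus strand, i.e. its reverse complement is located downstream
    of the forward site. The insert between the two sites is returned with
    primers excluded (mirroring adapter/primer trimming of real amplicons)
    unless ``keep_primers`` is set. When several site pairs exist, the
    leftmost forward site with a valid reverse site is used together with its
    nearest such reverse site. Returns ``None`` when no bracketed insert
    exists.
    """
    _validate(template, "template")
    fwd_sites = find_primer_sites(primers.forward, template, primers.max_mismatches)
    if not fwd_sites:
        return None
    rev_rc = reverse_complement(primers.reverse)
    rev_sites = find_primer_sites(rev_rc, template, primers.max_mismatches)
    if not rev_sites:
        return None
    for f in fwd_sites:  # leftmost forward with a reverse site downstream
        for r in rev_sites:  # nearest valid reverse
            if r.start >= f.end:
                if keep_primers:
                    return template[f.start : r.end]
                return template[f.end : r.start]
    return None
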
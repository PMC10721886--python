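"""Phosphodegron motif scanning.

The F-box protein beta-TrCP recognizes substrates through a phosphorylated
[D/E/S]-[S/D/E]-G-X-X-[S/E/D] degron. A DNA-damage-responsive *variant* of
this degron replaces the final phosphoacceptor with an S/T-Q pair — the
consensus substrate motif of the apical DNA-damage-response kinases
ATM/ATR — giving [D/E/S/T]-[D/E/S]-G-x(2)-[S/T]-Q. Phosphorylation of the
S/T preceding the Q primes the degron for beta-TrCP binding, coupling
degradation directly to DDR kinase activity.

Patterns are written in a PROSITE-like syntax: residue classes in square
brackets, ``x`` for any residue, ``x(2)`` for a run of wildcards, elements
separated by ``-``. Coordinates are 1-based inclusive, matching UniProt
residue numbering. All (including overlapping) occurrences are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .io_tables import ProteinSequences

__all__ = [
    "MotifPattern",
    "DegronMatch",
    "parse_prosite",
    "canonical_degron",
    "variant_degron",
    "get_motif",
    "scan_sequence",
    "scan_proteome",
    "join_phospho",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
# Ambiguous/non-standard letters tolerated in sequences; they satisfy only
# wildcard pattern positions, never a residue class.
AMBIGUOUS_AA = set("XUBZ")


@dataclass(frozen=True)
class MotifPattern:
    """An ordered list of residue classes; ``None`` marks a wildcard."""

    name: str
    elements: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern needs at least one element")
        for el in self.elements:
            if el is not None and not el:
                raise ValueError("empty residue class in pattern")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def has_stq_anchor(self) -> bool:
        """True when the motif ends in [S/T]-Q (a DDR-kinase phosphoacceptor
        immediately before the final glutamine)."""
        if len(self.elements) < 2:
            return False
        last, prev = self.elements[-1], self.elements[-2]
        return last == frozenset("Q") and prev is not None and prev <= frozenset("ST")

    def matches_window(self, window: str) -> bool:
        for aa, el in zip(window, self.elements):
            if el is None:
                continue
            if aa not in el:  # ambiguous letters are in no class
                return False
        return True


_ELEMENT_RE = re.compile(r"(\[(?P<cls>[A-Za-z]+)\]|(?P<single>[A-Za-z]))(\((?P<rep>\d+)\))?$")


def parse_prosite(pattern: str, name: str | None = None) -> MotifPattern:
    """Parse a PROSITE-like pattern string, e.g. ``[DEST]-[DES]-G-x(2)-[ST]-Q``."""
    elements: list[frozenset[str] | None] = []
    for token in pattern.strip().split("-"):
        m = _ELEMENT_RE.match(token.strip())
        if not m:
            raise ValueError(f"cannot parse pattern element {token!r}")
        rep = int(m.group("rep") or 1)
        if m.group("cls") is not None:
            letters = m.group("cls").upper()
            bad = set(letters) - STANDARD_AA
            if bad:
                raise ValueError(f"non-standard residue(s) {sorted(bad)} in class {token!r}")
            el: frozenset[str] | None = frozenset(letters)
        else:
            ch = m.group("single")
            el = None if ch in ("x", "X") else frozenset(ch.upper())
            if el is not None and ch.upper() not in STANDARD_AA:
                raise ValueError(f"non-standard residue {ch!r} in pattern")
        elements.extend([el] * rep)
    return MotifPattern(name=name or pattern, elements=tuple(elements))


def canonical_degron() -> MotifPattern:
    """The canonical beta-TrCP degron [D/E/S]-[S/D/E]-G-x-x-[S/E/D]."""
    return parse_prosite("[DES]-[SDE]-G-x-x-[SED]", name="canonical")


def variant_degron() -> MotifPattern:
    """The DDR-responsive variant degron [D/E/S/T]-[D/E/S]-G-x(2)-[S/T]-Q."""
    return parse_prosite("[DEST]-[DES]-G-x(2)-[ST]-Q", name="variant")


def get_motif(spec: str) -> MotifPattern:
    """Resolve ``canonical``, ``variant``, or ``custom:<pattern>``."""
    if spec == "canonical":
        return canonical_degron()
    if spec == "variant":
        return variant_degron()
    if spec.startswith("custom:"):
        return parse_prosite(spec[len("custom:"):])
    raise ValueError(f"unknown motif spec {spec!r}")


@dataclass(frozen=True)
class DegronMatch:
    """One motif occurrence; coordinates are 1-based inclusive."""

    accession: str
    start: int
    end: int
    matched_seq: str
    stq_position: int | None = None  # position of the S/T preceding the motif's Q
    known_phospho: bool = False
    kinase: str | None = None


def scan_sequence(seq: str, pattern: MotifPattern, accession: str = "") -> list[DegronMatch]:
    """Report every (possibly overlapping) occurrence of ``pattern`` in ``seq``.

    Input is uppercased; ambiguous residues (X, U, B, Z) match only wildcard
    positions. For patterns anchored by a terminal [S/T]-Q the position of
    the phosphoacceptor (end - 1) is recorded.
    """
    seq = seq.upper()
    L = len(pattern)
    matches: list[DegronMatch] = []
    for start0 in range(len(seq) - L + 1):
        window = seq[start0 : start0 + L]
        if pattern.matches_window(window):
            end = start0 + L  # 1-based inclusive end
            matches.append(
                DegronMatch(
                    accession=accession,
                    start=start0 + 1,
                    end=end,
                    matched_seq=window,
                    stq_position=end - 1 if pattern.has_stq_anchor else None,
                )
            )
    return matches


MATCH_COLUMNS = ["accession", "start", "end", "matched_seq", "stq_position"]


def scan_proteome(seqs: ProteinSequences, pattern: MotifPattern) -> pd.DataFrame:
    """Scan every sequence; returns one row per match.

    The number of distinct proteins with at least one match is available as
    ``result["accession"].nunique()`` and is echoed in ``result.attrs``.
    """
    rows = []
    for acc, (_, seq) in seqs:
        for match in scan_sequence(seq, pattern, accession=acc):
            rows.append(
                (match.accession, match.start, match.end, match.matched_seq, match.stq_position)
            )
    df = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    df.attrs["n_proteins_matched"] = int(df["accession"].nunique()) if len(df) else 0
    df.attrs["motif"] = pattern.name
    return df


def join_phospho(matches: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Annotate matches with known phosphorylation of the S/T-Q acceptor.

    ``annotations`` has columns ``accession``, ``position`` (1-based, same
    sequence version) and optionally ``kinase``. The join is exact on
    (accession, stq_position); unmatched annotations are ignored.
    """
    out = matches.copy()
    if annotations is None or annotations.empty:
        out["known_phospho"] = False
        out["kinase"] = None
        return out
    ann = annotations.copy()
    if "kinase" not in ann.columns:
        ann["kinase"] = None
    ann = ann.drop_duplicates(subset=["accession", "position"])
    merged = out.merge(
        ann[["accession", "position", "kinase"]],
        how="left",
        left_on=["accession", "stq_position"],
        right_on=["accession", "position"],
    )
    merged["known_phospho"] = merged["position"].notna()
    merged = merged.drop(columns=["position"])
    merged.index = out.index
    merged.attrs.update(matches.attrs)
    return merged
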
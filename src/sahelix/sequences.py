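"""Repeat-based SAH sequence design and sequence-level interrogation.

Single alpha-helix (SAH) domains are long, monomeric, highly charged helices
stabilised by intrahelical salt bridges between Glu and Lys/Arg spaced one
helical turn apart (i/i+3 and i/i+4).  This module builds de novo SAH
sequences from short repeat units (e.g. the 7-residue unit AEEEKKK), reports
their composition and average molecular mass, enumerates every potential
oriented charge pairing, and lays residues out on a helical net (an unrolled
cylinder with 100 degrees of azimuth per residue).

Pairing nomenclature: ``X->Y(+n)`` places residue type X at sequence position
i and Y at i+n (n = 3 or 4), so ``E->K(+3)`` and ``K->E(+3)`` are distinct
orientations of the same contact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: The eight oriented charge-pairing modes analysed throughout the package.
PAIRING_MODES = (
    "E->K(+3)", "E->K(+4)", "K->E(+3)", "K->E(+4)",
    "E->R(+3)", "E->R(+4)", "R->E(+3)", "R->E(+4)",
)

DEGREES_PER_RESIDUE = 100.0  # 3.6 residues per alpha-helical turn
RISE_PER_RESIDUE = 1.0       # net y-axis in residue units


def parse_mode(mode: str) -> tuple[str, str, int]:
    """Split a mode label like ``"E->K(+3)"`` into (first, second, offset)."""
    first, rest = mode.split("->")
    second = rest[0]
    offset = int(rest[rest.index("(") + 1 : rest.index(")")])
    return first, second, offset


def format_mode(first: str, second: str, offset: int) -> str:
    return f"{first}->{second}(+{offset})"


@dataclass(frozen=True)
class RepeatDesign:
    """A tiled-repeat SAH design: caps flanking a tiled core.

    Parameters
    ----------
    repeat_unit:
        Residue string tiled to fill the core (e.g. ``"AEEEKKK"``).
    core_length:
        Number of core residues; the final repeat may be truncated, keeping
        the repeat prefix.
    n_cap, c_cap:
        Flanking residues (default N-terminal Ser, C-terminal Trp, matching
        the expression constructs this design style is used for).
    """

    repeat_unit: str
    core_length: int
    n_cap: str = "S"
    c_cap: str = "W"

    def __post_init__(self) -> None:
        if len(self.repeat_unit) < 1:
            raise ValueError("repeat_unit must contain at least one residue")
        if self.core_length < 0:
            raise ValueError("core_length must be >= 0")
        for part in (self.repeat_unit, self.n_cap, self.c_cap):
            bad = set(part) - STANDARD_AA
            if bad:
                raise ValueError(f"non-standard residue letters: {sorted(bad)}")


@dataclass(frozen=True)
class PolypeptideSequence:
    """An identified one-letter amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ChargePairing:
    """One oriented charge pairing at helical spacing +3 or +4.

    ``donor_index`` is the 1-based position of the first residue of the mode
    label; ``partner_index`` = donor_index + offset holds the second.
    """

    donor_index: int
    partner_index: int
    mode: str

    def __post_init__(self) -> None:
        first, second, offset = parse_mode(self.mode)
        if self.partner_index - self.donor_index != offset:
            raise ValueError(
                f"offset mismatch: {self.mode} but indices "
                f"{self.donor_index},{self.partner_index}"
            )

    @property
    def offset(self) -> int:
        return self.partner_index - self.donor_index

    @property
    def residue_letters(self) -> tuple[str, str]:
        first, second, _ = parse_mode(self.mode)
        return first, second


@dataclass(frozen=True)
class NetCoordinate:
    """Position of one residue on the unrolled helical-net plot."""

    residue_index: int
    x: float  # unwrapped azimuth, degrees
    y: float  # axial rise, residue units
    wrap_duplicate: bool = False


def build_repeat_sequence(design: RepeatDesign, seq_id: str | None = None) -> PolypeptideSequence:
    """Tile ``design.repeat_unit`` to ``core_length`` residues and add caps.

    The final repeat is truncated keeping its prefix, so a 96-residue core of
    AEEEKKK is 13 full repeats followed by ``AEEEK``.
    """
    reps = -(-design.core_length // len(design.repeat_unit))
    core = (design.repeat_unit * reps)[: design.core_length]
    residues = design.n_cap + core + design.c_cap
    if seq_id is None:
        seq_id = f"{design.repeat_unit}x{design.core_length}"
    return PolypeptideSequence(id=seq_id, residues=residues)


def composition_percent(seq: PolypeptideSequence) -> dict[str, float]:
    """Percentage of each residue type present, summing to 100."""
    n = len(seq)
    counts: dict[str, int] = {}
    for aa in seq.residues:
        counts[aa] = counts.get(aa, 0) + 1
    return {aa: 100.0 * c / n for aa, c in sorted(counts.items())}


def molecular_mass(seq: PolypeptideSequence) -> float:
    """Average (not monoisotopic) molecular mass of the polypeptide in kDa.

    Sum of average residue masses plus one water for the free termini.
    """
    return molecular_weight(seq.residues, seq_type="protein", monoisotopic=False) / 1000.0


def molecular_mass_kda(seq: PolypeptideSequence) -> float:
    """`molecular_mass` rounded to 0.1 kDa, the precision used when quoting
    predicted monomer masses."""
    return round(molecular_mass(seq), 1)


def enumerate_pairings(
    seq: PolypeptideSequence,
    modes: tuple[str, ...] | list[str] | set[str] = PAIRING_MODES,
) -> list[ChargePairing]:
    """Every (i, i+n) index pair whose residues match a requested mode.

    Sequences are linear: no pairing crosses the termini.  Each matching
    (mode, i) appears exactly once, ordered by donor index then mode.
    """
    out: list[ChargePairing] = []
    n = len(seq)
    mode_list = [m for m in PAIRING_MODES if m in set(modes)]
    for i in range(1, n + 1):
        for mode in mode_list:
            first, second, offset = parse_mode(mode)
            j = i + offset
            if j > n:
                continue
            if seq.residues[i - 1] == first and seq.residues[j - 1] == second:
                out.append(ChargePairing(donor_index=i, partner_index=j, mode=mode))
    return out


def pairing_counts(seq: PolypeptideSequence) -> dict[str, int]:
    """Count of potential pairings per mode over the whole sequence."""
    counts = {m: 0 for m in PAIRING_MODES}
    for p in enumerate_pairings(seq):
        counts[p.mode] += 1
    return counts


def helical_net_coordinates(
    seq: PolypeptideSequence, wrap_width: float = 360.0
) -> list[NetCoordinate]:
    """Unrolled-cylinder coordinates for a helical-net plot.

    Residue i sits at x = (i-1) * 100 degrees (unwrapped; x strictly
    increases with index) and y = (i-1) rise units.  Residues whose wrapped
    azimuth falls within one residue of the cut line are additionally
    emitted as wrap duplicates, mirroring the convention of repeating
    cut-line residues in parentheses at the far edge of the plot.
    """
    coords: list[NetCoordinate] = []
    for i in range(1, len(seq) + 1):
        x = (i - 1) * DEGREES_PER_RESIDUE
        y = (i - 1) * RISE_PER_RESIDUE
        coords.append(NetCoordinate(residue_index=i, x=x, y=y))
    for c in list(coords):
        if (c.x % wrap_width) < DEGREES_PER_RESIDUE:
            coords.append(
                NetCoordinate(
                    residue_index=c.residue_index,
                    x=c.x + wrap_width,
                    y=c.y,
                    wrap_duplicate=True,
                )
            )
    return coords
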
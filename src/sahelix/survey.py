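"""Helix-survey census: charge-pair statistics over a structure set.

Mirrors the classic crystal-structure survey workflow: extract helices of
12+ residues from each structure with a secondary-structure assigner,
enumerate every potential E-K / E-R pairing at i/i+3 and i/i+4, classify
pairs by position along the helix (N-terminal / central / C-terminal),
count observed pairs against an expectation from single-residue
frequencies, apply the geometric salt-bridge criterion to the coordinates,
and tabulate chi1/chi2 rotamer-combination frequencies of central pairs
split by bridged vs non-bridged.

Resolution and redundancy culling of the input structure list is the
caller's responsibility.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import (
    PolypeptideSequence, ChargePairing, PAIRING_MODES,
    enumerate_pairings, parse_mode,
)
from .helixgeom import (
    HelixStructure, MissingAtomError, UndefinedAngleError,
    salt_bridge_geometry, measure_chi, classify_rotamer,
)
from .trajstats import Trajectory, assign_secondary_structure, HELICAL_CODES

logger = logging.getLogger(__name__)

MIN_HELIX_LENGTH = 12
POSITION_CLASSES = ("N-terminal", "central", "C-terminal")


@dataclass(frozen=True)
class HelixSegment:
    """One extracted helix: contiguous residues of a source structure."""

    structure_id: str
    chain_id: str
    start: int   # first residue id (structure numbering, inclusive)
    end: int     # last residue id (inclusive)
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("segment bounds inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


def extract_helices(
    structures: list[tuple[str, HelixStructure]],
    min_length: int = MIN_HELIX_LENGTH,
    assigner: str = "dssp",
) -> list[HelixSegment]:
    """Maximal helical runs of at least ``min_length`` residues.

    Residues are helix-assigned (DSSP H/G/I by default) per structure;
    unparseable structures are skipped with a logged warning.
    """
    segments: list[HelixSegment] = []
    for sid, structure in structures:
        try:
            traj = Trajectory.from_structures([structure])
            codes = assign_secondary_structure(traj, assigner=assigner)[0]
        except Exception as err:  # malformed input must not kill the survey
            logger.warning("structure %s skipped: %s", sid, err)
            continue
        helical = np.isin(codes, sorted(HELICAL_CODES))
        seq = structure.sequence
        chain = str(structure.atoms.chain_id[0]) if len(structure.atoms) else "A"
        run_start = None
        for i, h in enumerate(np.concatenate([helical, [False]])):
            if h and run_start is None:
                run_start = i
            elif not h and run_start is not None:
                length = i - run_start
                if length >= min_length:
                    segments.append(HelixSegment(
                        structure_id=sid, chain_id=chain,
                        start=run_start + 1, end=i,
                        sequence=seq[run_start:i]))
                run_start = None
    return segments


def classify_position(pairing: ChargePairing, helix: HelixSegment) -> str:
    """Position class of a pairing within its helix.

    Indices are helix-local (1-based).  A pair involving any of the first
    four helix residues is N-terminal and one involving any of the last
    four is C-terminal (N-terminal wins if both apply); pairs whose
    residues all lie at least four positions from both ends are central.
    """
    i, j = pairing.donor_index, pairing.partner_index
    n = len(helix)
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError("pairing outside helix bounds")
    if i <= 4 or j <= 4:
        return "N-terminal"
    if i > n - 4 or j > n - 4:
        return "C-terminal"
    return "central"


@dataclass
class PairCensus:
    """Observed/expected pair counts and salt-bridge statistics.

    All dictionaries are keyed by (mode, position class).  Rotamer tables
    (central pairs only) are keyed by mode, then by the string
    ``"<E chi1 bin><E chi2 bin>/<X chi1 bin><X chi2 bin>"``.
    """

    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    saltbridge: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)   # missing side-chain atoms
    rotamer_bridged: dict = field(default_factory=dict)
    rotamer_unbridged: dict = field(default_factory=dict)

    def observed_total(self, mode: str) -> int:
        return sum(v for (m, _), v in self.observed.items() if m == mode)

    def saltbridge_total(self, mode: str) -> int:
        return sum(v for (m, _), v in self.saltbridge.items() if m == mode)

    def fraction(self, mode: str, position: str | None = None) -> float:
        """Salt-bridge fraction (%) among pairs with measurable geometry."""
        if position is None:
            obs = self.observed_total(mode) - sum(
                v for (m, _), v in self.excluded.items() if m == mode)
            sb = self.saltbridge_total(mode)
        else:
            obs = (self.observed.get((mode, position), 0)
                   - self.excluded.get((mode, position), 0))
            sb = self.saltbridge.get((mode, position), 0)
        return 100.0 * sb / obs if obs else float("nan")

    def rotamer_frequencies(self, mode: str, bridged: bool = True) -> dict:
        table = (self.rotamer_bridged if bridged
                 else self.rotamer_unbridged).get(mode, {})
        total = sum(table.values())
        return {k: v / total for k, v in table.items()} if total else {}

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(mode, class) table with enrichment ratios."""
        rows = []
        keys = sorted(set(self.observed) | set(self.expected),
                      key=lambda k: (PAIRING_MODES.index(k[0]),
                                     POSITION_CLASSES.index(k[1])))
        for mode, cls in keys:
            obs = self.observed.get((mode, cls), 0)
            exp = self.expected.get((mode, cls), 0.0)
            sb = self.saltbridge.get((mode, cls), 0)
            rows.append({
                "mode": mode, "class": cls,
                "observed": obs, "expected": exp,
                "ratio": obs / exp if exp > 0 else np.nan,
                "n_saltbridge": sb,
                "fraction_pct": self.fraction(mode, cls),
            })
        return pd.DataFrame(rows)


def _segment_structure(structures: dict[str, HelixStructure],
                       segment: HelixSegment) -> HelixStructure:
    return structures[segment.structure_id]


def pair_census(
    segments: list[HelixSegment],
    structures: list[tuple[str, HelixStructure]] | dict[str, HelixStructure],
    modes: tuple[str, ...] = PAIRING_MODES,
    frequencies: str = "dataset",
) -> PairCensus:
    """Full census of charge pairings over extracted helix segments.

    Observed counts come from sequence enumeration on each segment,
    classified by position.  Expected counts for a (mode, class) follow the
    single-residue model: for every eligible start slot of that class the
    product of the two residue-type frequencies, with frequencies computed
    over the whole dataset (``frequencies="dataset"``) or per segment
    (``"segment"``).  Salt-bridge counts apply the geometric criterion to
    the source-structure coordinates; pairs whose side-chain atoms are
    missing stay in the observed count but are excluded from bridge and
    rotamer statistics (logged).  Rotamer-combination tables are collected
    for central pairs only.
    """
    if isinstance(structures, list):
        structures = dict(structures)
    census = PairCensus()

    dataset_counts: Counter = Counter()
    for seg in segments:
        dataset_counts.update(seg.sequence)
    total_res = sum(dataset_counts.values())

    def freq(letter: str, seg: HelixSegment) -> float:
        if frequencies == "segment":
            c = Counter(seg.sequence)
            return c[letter] / len(seg) if len(seg) else 0.0
        return dataset_counts[letter] / total_res if total_res else 0.0

    for seg in segments:
        seq = PolypeptideSequence(id=seg.structure_id, residues=seg.sequence)
        structure = structures.get(seg.structure_id)

        # expected counts: every eligible slot, classified like a real pair
        for mode in modes:
            first, second, offset = parse_mode(mode)
            p = freq(first, seg) * freq(second, seg)
            for i in range(1, len(seg) - offset + 1):
                slot = ChargePairing(donor_index=i, partner_index=i + offset,
                                     mode=mode)
                cls = classify_position(slot, seg)
                key = (mode, cls)
                census.expected[key] = census.expected.get(key, 0.0) + p

        for pairing in enumerate_pairings(seq, modes=modes):
            cls = classify_position(pairing, seg)
            key = (pairing.mode, cls)
            census.observed[key] = census.observed.get(key, 0) + 1
            if structure is None:
                census.excluded[key] = census.excluded.get(key, 0) + 1
                continue
            # map helix-local indices to structure residue ids
            struct_pairing = ChargePairing(
                donor_index=seg.start + pairing.donor_index - 1,
                partner_index=seg.start + pairing.partner_index - 1,
                mode=pairing.mode)
            try:
                geom = salt_bridge_geometry(structure, struct_pairing)
            except MissingAtomError as err:
                logger.warning("pair %s in %s excluded: %s",
                               pairing.mode, seg.structure_id, err)
                census.excluded[key] = census.excluded.get(key, 0) + 1
                continue
            if geom.formed:
                census.saltbridge[key] = census.saltbridge.get(key, 0) + 1
            if cls == "central":
                try:
                    first, _, _ = parse_mode(pairing.mode)
                    if first == "E":
                        e_res = struct_pairing.donor_index
                        x_res = struct_pairing.partner_index
                    else:
                        e_res = struct_pairing.partner_index
                        x_res = struct_pairing.donor_index
                    e1, e2 = measure_chi(structure, e_res)
                    x1, x2 = measure_chi(structure, x_res)
                except (MissingAtomError, UndefinedAngleError) as err:
                    logger.warning("rotamers for %s in %s skipped: %s",
                                   pairing.mode, seg.structure_id, err)
                    continue
                label = (f"{classify_rotamer(e1)}{classify_rotamer(e2)}/"
                         f"{classify_rotamer(x1)}{classify_rotamer(x2)}")
                table = (census.rotamer_bridged if geom.formed
                         else census.rotamer_unbridged)
                table.setdefault(pairing.mode, Counter())[label] += 1
    return census


def enrichment(census: PairCensus) -> dict[tuple[str, str], float | None]:
    """Observed/expected ratio per (mode, position class).

    ``None`` marks entries whose expectation is zero (undefined ratio).
    """
    out: dict[tuple[str, str], float | None] = {}
    for key in sorted(set(census.observed) | set(census.expected)):
        exp = census.expected.get(key, 0.0)
        obs = census.observed.get(key, 0)
        out[key] = (obs / exp) if exp > 0 else None
    return out
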
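"""Trajectory statistics for intrahelical salt bridges.

Given a trajectory of helix conformations (multi-model PDB or frames built
by the synthetic generators) and a set of potential charge pairings, this
module computes per-frame salt-bridge assignment (< 4 A centroid-to-nitrogen
rule), distance histograms at 0.1 A resolution, per-mode occupancies,
formation-event lifetime statistics at 5 ps resolution, simultaneous
(network) salt-bridge occupancies, and per-frame helicity from DSSP
secondary-structure assignment.

A formation event is a maximal run of consecutive frames with the bridge
formed; its lifetime is the run length times the frame interval.  Events are
not bridged across gaps: a single unformed frame ends the event.  Runs that
touch either end of the trajectory are flagged censored; they are included
in means by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .sequences import PolypeptideSequence, ChargePairing, parse_mode
from .helixgeom import (
    HelixStructure,
    SALT_BRIDGE_CUTOFF,
    MissingAtomError,
    THREE_LETTER,
)

logger = logging.getLogger(__name__)

DISTANCE_BIN_WIDTH = 0.1   # A
LIFETIME_BIN_WIDTH = 5.0   # ps
DEFAULT_FRAME_INTERVAL = 1.0  # ps (2 fs timestep x 500 steps between frames)

HELICAL_CODES = {"H", "G", "I"}


# -- containers ------------------------------------------------------------


@dataclass
class Trajectory:
    """Ordered frames of one helix, constant topology.

    ``frames`` is a biotite ``AtomArrayStack``; ``frame_interval`` is the
    time between recorded frames in ps.
    """

    frames: struc.AtomArrayStack
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.stack_depth()

    @property
    def sequence(self) -> str:
        return self.frame(0).sequence

    def frame(self, index: int) -> HelixStructure:
        return HelixStructure(atoms=self.frames[index])

    @classmethod
    def from_structures(cls, structures: list[HelixStructure],
                        frame_interval: float = DEFAULT_FRAME_INTERVAL) -> "Trajectory":
        stack = struc.stack([s.atoms for s in structures])
        return cls(frames=stack, frame_interval=frame_interval)


@dataclass
class SaltBridgeSeries:
    """Per-frame distance and formed/not state of one potential bridge."""

    pairing: ChargePairing
    distances: np.ndarray

    @property
    def states(self) -> np.ndarray:
        return self.distances < SALT_BRIDGE_CUTOFF

    @property
    def occupancy(self) -> float:
        """Fraction of frames formed, in [0, 1]."""
        return float(self.states.mean())


@dataclass
class LifetimeStats:
    """Formation-event statistics of one or more boolean series."""

    n_events: int
    lifetimes: np.ndarray          # ps, one entry per event
    censored: np.ndarray           # same length, True if run touches an end
    frame_interval: float
    total_frames: int

    @property
    def mean_lifetime(self) -> float:
        return float(self.lifetimes.mean()) if self.n_events else float("nan")

    @property
    def total_formed_frames(self) -> int:
        return int(round(self.lifetimes.sum() / self.frame_interval))

    def histogram(self, bin_width: float = LIFETIME_BIN_WIDTH):
        """Normalized lifetime histogram with edges at multiples of
        ``bin_width`` ps; (counts, edges), counts summing to 1."""
        if self.n_events == 0:
            return np.array([]), np.array([0.0])
        top = np.ceil(self.lifetimes.max() / bin_width) * bin_width
        edges = np.arange(0.0, top + bin_width, bin_width)
        counts, edges = np.histogram(self.lifetimes, bins=edges)
        return counts / counts.sum(), edges


# -- per-frame assignment --------------------------------------------------


def _pair_atom_indices(template: HelixStructure, pairing: ChargePairing):
    """Atom indices (into the template atom order) needed for one pairing."""
    first, second, _ = parse_mode(pairing.mode)
    if first == "E":
        e_res, x_res = pairing.donor_index, pairing.partner_index
        x_letter = second
    else:
        e_res, x_res = pairing.partner_index, pairing.donor_index
        x_letter = first
    atoms = template.atoms

    def idx(res_id, name):
        where = np.where((atoms.res_id == res_id) & (atoms.atom_name == name))[0]
        if len(where) == 0:
            raise MissingAtomError(f"residue {res_id} lacks atom {name}")
        return int(where[0])

    oe = [idx(e_res, "OE1"), idx(e_res, "OE2")]
    if x_letter == "K":
        nitrogens = [idx(x_res, "NZ")]
    else:
        nitrogens = [idx(x_res, nm) for nm in ("NE", "NH1", "NH2")]
    return oe, nitrogens


def pair_distance_series(
    traj: Trajectory,
    pairings: list[ChargePairing],
) -> list[SaltBridgeSeries]:
    """Per-frame salt-bridge distances for each pairing.

    The distance at each frame is centroid(Glu OE1, OE2) to Lys NZ, or the
    smallest of the three distances to Arg NE/NH1/NH2; the bridge is formed
    at a frame iff the distance is strictly below 4 A.  Pairings whose
    atoms are missing from the topology are excluded with a logged warning.
    """
    template = traj.frame(0)
    coords = traj.frames.coord  # (n_frames, n_atoms, 3)
    out: list[SaltBridgeSeries] = []
    for pairing in pairings:
        try:
            oe, nitro = _pair_atom_indices(template, pairing)
        except MissingAtomError as err:
            logger.warning("pairing %s at (%d,%d) skipped: %s",
                           pairing.mode, pairing.donor_index,
                           pairing.partner_index, err)
            continue
        centroid = coords[:, oe, :].mean(axis=1)             # (F, 3)
        d = np.linalg.norm(coords[:, nitro, :] - centroid[:, None, :],
                           axis=-1).min(axis=1)              # (F,)
        out.append(SaltBridgeSeries(pairing=pairing, distances=d))
    return out


def distance_histogram(
    series: SaltBridgeSeries | list[SaltBridgeSeries] | np.ndarray,
    bin_width: float = DISTANCE_BIN_WIDTH,
):
    """Normalized histogram of bridge distances with 0.1 A bins.

    Accepts one series, several series of the same pairing mode (pooled),
    or a raw distance array.  Returns (counts, edges) with bin edges at
    multiples of ``bin_width`` and counts summing to 1.
    """
    if isinstance(series, SaltBridgeSeries):
        distances = series.distances
    elif isinstance(series, np.ndarray):
        distances = series
    else:
        distances = np.concatenate([s.distances for s in series])
    if distances.size == 0:
        raise ValueError("no distances to histogram")
    lo = np.floor(distances.min() / bin_width) * bin_width
    hi = np.ceil(distances.max() / bin_width) * bin_width
    if hi == lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    return counts / counts.sum(), edges


def occupancy_summary(series: list[SaltBridgeSeries]) -> dict[str, float]:
    """Per-mode occupancy: 100 x formed frames / total frames, pooled over
    every pairing of the mode.  Modes with no series are absent."""
    formed: dict[str, int] = {}
    total: dict[str, int] = {}
    for s in series:
        formed[s.pairing.mode] = formed.get(s.pairing.mode, 0) + int(s.states.sum())
        total[s.pairing.mode] = total.get(s.pairing.mode, 0) + s.states.size
    return {mode: 100.0 * formed[mode] / total[mode] for mode in formed}


# -- lifetimes -------------------------------------------------------------


def _runs(states: np.ndarray):
    """(start, length) of each maximal run of True."""
    states = np.asarray(states, dtype=bool)
    if states.size == 0:
        return []
    padded = np.concatenate([[False], states, [False]]).astype(int)
    diff = np.diff(padded)
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    return list(zip(starts, ends - starts))


def lifetime_stats(
    series: SaltBridgeSeries | np.ndarray | list,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    drop_censored: bool = False,
) -> LifetimeStats:
    """Formation-event lifetimes of one boolean/bridge series or, for a
    list, pooled over all of them.

    Each maximal run of consecutive formed frames is one event of lifetime
    ``run length x frame_interval`` ps.  Runs touching the first or last
    frame are censored; they are included unless ``drop_censored``.
    """
    if isinstance(series, SaltBridgeSeries):
        state_arrays = [series.states]
    elif isinstance(series, np.ndarray):
        state_arrays = [series]
    else:
        state_arrays = [s.states if isinstance(s, SaltBridgeSeries)
                        else np.asarray(s, dtype=bool) for s in series]
    lifetimes, censored = [], []
    total_frames = 0
    for states in state_arrays:
        total_frames += states.size
        for start, length in _runs(states):
            cens = (start == 0) or (start + length == states.size)
            if drop_censored and cens:
                continue
            lifetimes.append(length * frame_interval)
            censored.append(cens)
    return LifetimeStats(
        n_events=len(lifetimes),
        lifetimes=np.asarray(lifetimes, dtype=float),
        censored=np.asarray(censored, dtype=bool),
        frame_interval=frame_interval,
        total_frames=total_frames,
    )


def mean_lifetime_per_pair(
    series: list[SaltBridgeSeries],
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    drop_censored: bool = False,
) -> float:
    """Alternative averaging: mean over pairings of each pairing's own mean
    event lifetime (the default, :func:`lifetime_stats` on the list, pools
    all events instead)."""
    means = []
    for s in series:
        st = lifetime_stats(s, frame_interval, drop_censored)
        if st.n_events:
            means.append(st.mean_lifetime)
    return float(np.mean(means)) if means else float("nan")


# -- simultaneous (network) salt bridges -----------------------------------


@dataclass(frozen=True)
class NetworkOccupancy:
    """Occupancy of one simultaneous two-bridge combination.

    The label reads from the shared centre residue, e.g. ``R->E(-4)&E(+3)``
    is an Arg bridging the Glu four before it and the Glu three after it
    (an E-R-E network); ``occupancy`` is the percentage of frames with both
    bridges formed, averaged over all centres with that combination.
    """

    label: str
    occupancy: float
    n_centres: int


def network_occupancy(
    series: list[SaltBridgeSeries],
    sequence: PolypeptideSequence | str | None = None,
) -> list[NetworkOccupancy]:
    """Occupancy of every simultaneous salt-bridge combination.

    Every residue that participates in two or more potential bridges is a
    candidate centre; for each unordered pair of its bridges the fraction
    of frames in which both are formed is averaged over all centres that
    share the same (centre letter, partner letters, signed offsets)
    combination.
    """
    # index bridges by participating residue with signed partner offsets
    by_centre: dict[int, list[tuple[int, str, SaltBridgeSeries]]] = {}
    letters: dict[int, str] = {}
    for s in series:
        first, second, offset = parse_mode(s.pairing.mode)
        i, j = s.pairing.donor_index, s.pairing.partner_index
        letters[i], letters[j] = first, second
        by_centre.setdefault(i, []).append((offset, second, s))
        by_centre.setdefault(j, []).append((-offset, first, s))

    sums: dict[str, list[float]] = {}
    for centre, partners in sorted(by_centre.items()):
        if len(partners) < 2:
            continue
        partners = sorted(partners, key=lambda t: t[0])
        for a in range(len(partners)):
            for b in range(a + 1, len(partners)):
                o1, l1, s1 = partners[a]
                o2, l2, s2 = partners[b]
                label = (f"{letters[centre]}->{l1}({o1:+d})&{l2}({o2:+d})")
                both = float((s1.states & s2.states).mean()) * 100.0
                sums.setdefault(label, []).append(both)
    return [
        NetworkOccupancy(label=label, occupancy=float(np.mean(vals)),
                         n_centres=len(vals))
        for label, vals in sorted(sums.items())
    ]


# -- helicity --------------------------------------------------------------


def _to_mdtraj(traj: Trajectory):
    """Convert to an mdtraj trajectory (backbone-aware topology)."""
    import mdtraj
    from mdtraj.core import element as md_element

    template = traj.frames[0]
    top = mdtraj.Topology()
    chain = top.add_chain()
    residues = {}
    for i in range(len(template)):
        rid = int(template.res_id[i])
        if rid not in residues:
            residues[rid] = top.add_residue(str(template.res_name[i]), chain,
                                            resSeq=rid)
        elem = md_element.get_by_symbol(str(template.element[i]).capitalize())
        top.add_atom(str(template.atom_name[i]), elem, residues[rid])
    xyz = traj.frames.coord / 10.0  # A -> nm
    return mdtraj.Trajectory(xyz=xyz, topology=top)


def helicity_series(traj: Trajectory,
                    assigner: str = "dssp") -> tuple[np.ndarray, float]:
    """Per-frame helical fraction and its mean over the trajectory.

    Helicity of a frame is the fraction of residues assigned a helical
    secondary structure (DSSP H, G or I).  Returns (per-frame array, mean).
    """
    codes = assign_secondary_structure(traj, assigner=assigner)
    helical = np.isin(codes, sorted(HELICAL_CODES))
    fractions = helical.mean(axis=1)
    return fractions, float(fractions.mean())


def assign_secondary_structure(traj: Trajectory,
                               assigner: str = "dssp") -> np.ndarray:
    """Per-frame, per-residue secondary-structure codes.

    ``dssp`` (default) runs the DSSP algorithm via mdtraj and returns the
    full code alphabet (H/G/I/E/B/T/S/C); ``psea`` uses the CA-only P-SEA
    assigner (codes a/b/c mapped to H/E/C).
    """
    if assigner == "dssp":
        md = _to_mdtraj(traj)
        import mdtraj
        codes = mdtraj.compute_dssp(md, simplified=False)
        codes[codes == " "] = "C"
        return codes
    if assigner == "psea":
        out = []
        for f in range(traj.n_frames):
            sse = struc.annotate_sse(traj.frames[f])
            out.append(np.array(
                [{"a": "H", "b": "E", "c": "C"}[c] for c in sse]))
        return np.array(out)
    raise ValueError(f"unknown assigner: {assigner}")
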
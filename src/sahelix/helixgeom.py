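"""Ideal alpha-helix construction and salt-bridge geometry rules.

Structures are built residue-by-residue with ideal covalent geometry
(backbone torsions phi = -57 deg, psi = -47 deg; side chains transplanted
from Chemical Component Dictionary templates and posed by explicit chi
rotations).  The same module applies the geometric definitions used for all
salt-bridge statistics in the package:

* a Glu-Lys salt bridge is formed when the centroid of the Glu OE1/OE2
  carboxylate oxygens lies strictly within 4 A of the Lys NZ atom;
* for Glu-Arg the distance is the smallest of the three distances from that
  centroid to the Arg NE, NH1 and NH2 nitrogens;
* a steric clash is any inter-residue heavy-atom contact strictly below
  2.5 A;
* chi angles are binned into three rotamer states:
  t  (chi >= 120 or chi <= -120), g+ (0 <= chi < 120), g- (-120 < chi < 0).

Hydrogens are ignored throughout; the criteria are defined on N/O heavy
atoms only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info

from .sequences import PolypeptideSequence, ChargePairing, parse_mode, format_mode

# -- constants -------------------------------------------------------------

PHI_IDEAL = -57.0
PSI_IDEAL = -47.0
OMEGA_IDEAL = 180.0

# backbone covalent geometry (Engh-Huber-style ideal values)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

SALT_BRIDGE_CUTOFF = 4.0  # A, strict
CLASH_CUTOFF = 2.5        # A, strict

ROTAMER_BINS = ("t", "g+", "g-")
#: representative chi angle used when a rotamer is requested by bin name
BIN_ANGLE = {"t": 180.0, "g+": 60.0, "g-": -60.0}

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: side-chain chi torsions (atom quadruples) per residue type
CHI_DEFINITIONS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class MissingAtomError(KeyError):
    """A residue lacks a side-chain atom required by a geometry rule."""


class UndefinedAngleError(ValueError):
    """chi angles are undefined for this residue type (Gly/Ala)."""


# -- rotamer state ---------------------------------------------------------


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def classify_rotamer(chi: float) -> str:
    """Bin a chi angle: t for |chi| >= 120, g+ for [0, 120), g- for (-120, 0).

    The bins partition (-180, 180]; both boundary values +-120 fall in t and
    0 falls in g+.
    """
    chi = normalize_angle(chi)
    if chi >= 120.0 or chi <= -120.0:
        return "t"
    if 0.0 <= chi < 120.0:
        return "g+"
    return "g-"


@dataclass(frozen=True)
class RotamerState:
    """A (chi1, chi2) side-chain conformation with its rotamer bins."""

    chi1: float
    chi2: float

    @classmethod
    def from_bins(cls, bin1: str, bin2: str) -> "RotamerState":
        return cls(chi1=BIN_ANGLE[bin1], chi2=BIN_ANGLE[bin2])

    @property
    def bin1(self) -> str:
        return classify_rotamer(self.chi1)

    @property
    def bin2(self) -> str:
        return classify_rotamer(self.chi2)

    @property
    def bins(self) -> str:
        return f"{self.bin1}{self.bin2}"


# -- structure container ---------------------------------------------------


@dataclass
class HelixStructure:
    """One helix conformation: a biotite ``AtomArray`` with contiguous
    1-based residue numbering and one-letter sequence access."""

    atoms: struc.AtomArray

    @property
    def n_residues(self) -> int:
        return int(self.atoms.res_id.max()) if len(self.atoms) else 0

    @property
    def sequence(self) -> str:
        letters = []
        inv = {v: k for k, v in THREE_LETTER.items()}
        for rid in range(1, self.n_residues + 1):
            name = self.atoms.res_name[self.atoms.res_id == rid][0]
            letters.append(inv.get(name, "X"))
        return "".join(letters)

    def residue_mask(self, res_id: int) -> np.ndarray:
        return self.atoms.res_id == res_id

    def atom_coord(self, res_id: int, atom_name: str) -> np.ndarray:
        mask = (self.atoms.res_id == res_id) & (self.atoms.atom_name == atom_name)
        if not mask.any():
            raise MissingAtomError(f"residue {res_id} has no atom {atom_name}")
        return self.atoms.coord[mask][0]

    def residue_coords(self, res_id: int) -> np.ndarray:
        return self.atoms.coord[self.residue_mask(res_id)]

    def copy(self) -> "HelixStructure":
        return HelixStructure(atoms=self.atoms.copy())


# -- geometric primitives --------------------------------------------------


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement: position atom d given chain a-b-c, the c-d bond
    length, the b-c-d angle and the a-b-c-d torsion (degrees)."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    return normalize_angle(
        float(np.rad2deg(struc.dihedral(
            np.asarray(p0), np.asarray(p1), np.asarray(p2), np.asarray(p3))))
    )


def _rotate_about_axis(coords: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    k = axis
    v = coords - origin
    rotated = (v * np.cos(theta)
               + np.cross(k, v) * np.sin(theta)
               + np.outer(v @ k, k) * (1 - np.cos(theta)))
    return rotated + origin


# -- side-chain templates --------------------------------------------------


def _template(res_name: str) -> tuple[struc.AtomArray, dict[str, set[str]]]:
    """CCD heavy-atom template and its bond adjacency for one residue type."""
    full = struc_info.residue(res_name)
    heavy = full[(full.element != "H") & (full.atom_name != "OXT") & (full.atom_name != "HXT")]
    adj: dict[str, set[str]] = {name: set() for name in heavy.atom_name}
    bonds = full.bonds.as_array()
    names = full.atom_name
    for a1, a2, _ in bonds:
        n1, n2 = names[a1], names[a2]
        if n1 in adj and n2 in adj:
            adj[n1].add(n2)
            adj[n2].add(n1)
    return heavy, adj


_TEMPLATE_CACHE: dict[str, tuple[struc.AtomArray, dict[str, set[str]]]] = {}


def _get_template(res_name: str):
    if res_name not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[res_name] = _template(res_name)
    return _TEMPLATE_CACHE[res_name]


def _distal_atoms(adj: dict[str, set[str]], axis_from: str, axis_to: str) -> set[str]:
    """Atoms on the far side of the axis_from->axis_to bond (excluding both)."""
    seen = {axis_from, axis_to}
    stack = [axis_to]
    out: set[str] = set()
    while stack:
        cur = stack.pop()
        for nxt in adj.get(cur, ()):
            if nxt not in seen:
                seen.add(nxt)
                out.add(nxt)
                stack.append(nxt)
    return out


def set_chi(structure: HelixStructure, res_id: int, chi_index: int,
            target_deg: float) -> None:
    """Rotate the side chain of one residue in place so that chi_{chi_index}
    (1-based) equals ``target_deg``."""
    res_name = structure.atoms.res_name[structure.atoms.res_id == res_id][0]
    defs = CHI_DEFINITIONS.get(res_name, [])
    if chi_index < 1 or chi_index > len(defs):
        raise UndefinedAngleError(
            f"{res_name} has no chi{chi_index}")
    a1, a2, a3, a4 = defs[chi_index - 1]
    p = [structure.atom_coord(res_id, n) for n in (a1, a2, a3, a4)]
    current = dihedral_angle(*p)
    delta = target_deg - current
    _, adj = _get_template(res_name)
    moving = _distal_atoms(adj, a2, a3) | {a4}
    mask = structure.residue_mask(res_id) & np.isin(structure.atoms.atom_name,
                                                    sorted(moving))
    structure.atoms.coord[mask] = _rotate_about_axis(
        structure.atoms.coord[mask],
        origin=structure.atom_coord(res_id, a2),
        axis=structure.atom_coord(res_id, a3) - structure.atom_coord(res_id, a2),
        angle_deg=delta,
    )


def measure_chi(structure: HelixStructure, res_id: int) -> tuple[float, float]:
    """(chi1, chi2) of one residue in degrees, each in (-180, 180].

    Residues with a single chi report chi2 = nan; Ala/Gly raise
    :class:`UndefinedAngleError`.
    """
    res_name = structure.atoms.res_name[structure.atoms.res_id == res_id][0]
    defs = CHI_DEFINITIONS.get(res_name, [])
    if not defs:
        raise UndefinedAngleError(f"{res_name} has no chi angles")
    chis = []
    for quad in defs[:2]:
        p = [structure.atom_coord(res_id, n) for n in quad]
        chis.append(dihedral_angle(*p))
    if len(chis) == 1:
        chis.append(float("nan"))
    return chis[0], chis[1]


def measure_phi_psi(structure: HelixStructure, res_id: int) -> tuple[float, float]:
    """Backbone (phi, psi) of an interior residue in degrees."""
    phi = dihedral_angle(
        structure.atom_coord(res_id - 1, "C"),
        structure.atom_coord(res_id, "N"),
        structure.atom_coord(res_id, "CA"),
        structure.atom_coord(res_id, "C"),
    )
    psi = dihedral_angle(
        structure.atom_coord(res_id, "N"),
        structure.atom_coord(res_id, "CA"),
        structure.atom_coord(res_id, "C"),
        structure.atom_coord(res_id + 1, "N"),
    )
    return phi, psi


# -- helix builder ---------------------------------------------------------


def build_ideal_helix(
    seq: PolypeptideSequence | str,
    rotamers: dict[int, RotamerState] | None = None,
    phi: float = PHI_IDEAL,
    psi: float = PSI_IDEAL,
) -> HelixStructure:
    """Build a perfect alpha-helix with ideal covalent geometry.

    Backbone torsions are set uniformly to (phi, psi) with trans peptide
    bonds.  Side chains come from ideal residue templates superimposed on
    each backbone triad; all defined chi torsions default to trans (180 deg)
    and chi1/chi2 can be posed per residue through ``rotamers``
    (1-based residue index -> :class:`RotamerState`).

    Raises
    ------
    UndefinedAngleError
        if a rotamer is requested for a residue without chi angles (Gly/Ala).
    ValueError
        for an empty or non-standard sequence.
    """
    if isinstance(seq, str):
        seq = PolypeptideSequence(id="helix", residues=seq)
    residues = seq.residues
    rotamers = rotamers or {}
    for rid in rotamers:
        res_name = THREE_LETTER[residues[rid - 1]]
        if not CHI_DEFINITIONS.get(res_name):
            raise UndefinedAngleError(
                f"rotamer requested for {res_name}{rid}, which has no chi angles")

    n_res = len(residues)
    bb = np.zeros((n_res, 3, 3))  # N, CA, C per residue
    # seed first residue in a canonical pose
    bb[0, 0] = np.array([0.0, 0.0, 0.0])
    bb[0, 1] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    bb[0, 2] = bb[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = bb[i - 1]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_IDEAL)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        bb[i] = (n_i, ca_i, c_i)

    arrays = []
    for i, letter in enumerate(residues):
        res_name = THREE_LETTER[letter]
        template, _ = _get_template(res_name)
        # pose the template on the built backbone triad
        tri_names = ["N", "CA", "C"]
        t_idx = [int(np.where(template.atom_name == nm)[0][0]) for nm in tri_names]
        fixed = struc.AtomArray(3)
        fixed.coord = bb[i].copy()
        mobile = template[t_idx]
        _, transform = struc.superimpose(fixed, mobile)
        posed = transform.apply(template)
        res = posed[~np.isin(posed.atom_name, ["O"])]
        res = res.copy()
        # exact backbone positions from the ideal build
        for nm, k in (("N", 0), ("CA", 1), ("C", 2)):
            res.coord[res.atom_name == nm] = bb[i, k]
        # carbonyl O anti to the next amide N (dihedral N-CA-C-O = psi + 180)
        o_coord = place_atom(bb[i, 0], bb[i, 1], bb[i, 2],
                             BOND_C_O, ANGLE_CA_C_O, normalize_angle(psi + 180.0))
        o_atom = struc.AtomArray(1)
        o_atom.coord = o_coord[np.newaxis, :]
        o_atom.atom_name = np.array(["O"])
        o_atom.element = np.array(["O"])
        o_atom.res_name = np.array([res_name])
        res = res + o_atom
        res.res_id = np.full(len(res), i + 1)
        res.res_name = np.full(len(res), res_name)
        res.chain_id = np.full(len(res), "A")
        res.hetero = np.zeros(len(res), dtype=bool)
        arrays.append(res)

    atoms = arrays[0]
    for arr in arrays[1:]:
        atoms = atoms + arr
    structure = HelixStructure(atoms=atoms)

    # default every defined chi to trans, then apply requested chi1/chi2
    for i, letter in enumerate(residues):
        res_name = THREE_LETTER[letter]
        defs = CHI_DEFINITIONS.get(res_name, [])
        rid = i + 1
        for k in range(len(defs)):
            set_chi(structure, rid, k + 1, 180.0)
        if rid in rotamers:
            state = rotamers[rid]
            set_chi(structure, rid, 1, state.chi1)
            if len(defs) >= 2 and not np.isnan(state.chi2):
                set_chi(structure, rid, 2, state.chi2)
    return structure


# -- salt-bridge and clash rules -------------------------------------------


@dataclass(frozen=True)
class SaltBridgeGeometry:
    """Measured geometry of one potential salt bridge."""

    pairing: ChargePairing
    distance: float
    contributing_atom: str
    formed: bool


def _bridge_atoms(structure: HelixStructure, pairing: ChargePairing):
    """(Glu centroid, [(basic N name, coord), ...]) for one pairing."""
    first, second, _ = parse_mode(pairing.mode)
    if first == "E":
        e_res, x_res = pairing.donor_index, pairing.partner_index
        x_letter = second
    else:
        e_res, x_res = pairing.partner_index, pairing.donor_index
        x_letter = first
    oe1 = structure.atom_coord(e_res, "OE1")
    oe2 = structure.atom_coord(e_res, "OE2")
    centroid = 0.5 * (oe1 + oe2)
    if x_letter == "K":
        nitrogens = [("NZ", structure.atom_coord(x_res, "NZ"))]
    else:
        nitrogens = [(nm, structure.atom_coord(x_res, nm))
                     for nm in ("NE", "NH1", "NH2")]
    return centroid, nitrogens


def is_salt_bridge_distance(distance: float,
                            cutoff: float = SALT_BRIDGE_CUTOFF) -> bool:
    """Strict rule: a bridge is formed iff distance < cutoff (4 A default);
    exactly 4 A is not a bridge."""
    return distance < cutoff


def salt_bridge_geometry(structure: HelixStructure,
                         pairing: ChargePairing) -> SaltBridgeGeometry:
    """Apply the geometric salt-bridge criterion to one charge pairing.

    Distance is from the centroid of the Glu OE1/OE2 atoms to the Lys NZ, or
    the smallest of the distances to the Arg NE/NH1/NH2; the bridge is
    formed iff that distance is strictly below 4 A.
    """
    centroid, nitrogens = _bridge_atoms(structure, pairing)
    dists = [(float(np.linalg.norm(coord - centroid)), nm)
             for nm, coord in nitrogens]
    distance, atom = min(dists)
    return SaltBridgeGeometry(
        pairing=pairing,
        distance=distance,
        contributing_atom=atom,
        formed=is_salt_bridge_distance(distance),
    )


def detect_clash(structure: HelixStructure, pairing: ChargePairing,
                 cutoff: float = CLASH_CUTOFF) -> bool:
    """True iff any heavy-atom pair between the two residues is strictly
    closer than ``cutoff`` (default 2.5 A)."""
    a = structure.residue_coords(pairing.donor_index)
    b = structure.residue_coords(pairing.partner_index)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return bool(d.min() < cutoff)


# -- theoretical rotamer-combination scan ----------------------------------


@dataclass(frozen=True)
class RotamerCombination:
    """One row of the 81-combination scan for a pairing mode.

    ``e_chi`` holds the full (chi1, chi2, chi3) pose of the Glu and
    ``x_chi`` the (chi1..chi4) pose of the Lys/Arg at which ``distance``
    and ``clash`` were evaluated (the most favourable distal-torsion
    arrangement for this chi1/chi2 bin combination).
    """

    mode: str
    e_bins: tuple[str, str]
    x_bins: tuple[str, str]
    distance: float
    clash: bool
    capable: bool
    e_chi: tuple[float, ...] = ()
    x_chi: tuple[float, ...] = ()


def _scan_context(mode: str, context_length: int):
    """Poly-Ala ideal helix with the mode's pair embedded centrally."""
    first, second, offset = parse_mode(mode)
    donor_pos = (context_length - offset) // 2 + 1
    partner_pos = donor_pos + offset
    letters = ["A"] * context_length
    letters[donor_pos - 1] = first
    letters[partner_pos - 1] = second
    seq = "".join(letters)
    e_pos = donor_pos if first == "E" else partner_pos
    x_pos = partner_pos if first == "E" else donor_pos
    x_letter = second if first == "E" else first
    pairing = ChargePairing(donor_index=donor_pos, partner_index=partner_pos,
                            mode=mode)
    return build_ideal_helix(seq), pairing, e_pos, x_pos, x_letter


def _residue_poses(base: HelixStructure, res_id: int,
                   chi12_list, distal_lists):
    """All side-chain poses of one residue over (chi1, chi2) x distal grids.

    Returns (poses, coords) where poses[i] is the full chi tuple and
    coords[i] the residue's heavy-atom coordinates in base atom order.
    """
    poses = []
    coords = []
    work = base.copy()
    mask = work.residue_mask(res_id)
    for chi1, chi2 in chi12_list:
        for distal in itertools.product(*distal_lists):
            chis = (chi1, chi2) + distal
            for k, val in enumerate(chis):
                set_chi(work, res_id, k + 1, val)
            poses.append(chis)
            coords.append(work.atoms.coord[mask].copy())
    return poses, np.array(coords)


def rotamer_combination_scan(
    mode: str,
    context_length: int = 12,
    distal_angles: tuple[float, ...] = (180.0, 60.0, -60.0),
) -> list[RotamerCombination]:
    """Model all 81 chi1/chi2 bin combinations of a Glu + Lys/Arg pair.

    The pair is embedded centrally in a poly-Ala ideal helix and each
    residue posed at the representative bin angles (t 180, g+ 60, g- -60).
    Torsions beyond chi2 (Glu chi3; Lys/Arg chi3 and chi4) are not part of
    the binned analysis: for each chi1/chi2 combination every arrangement
    of distal torsions over ``distal_angles`` is tried and the most
    favourable one reported — capable iff some arrangement both satisfies
    the bridge criterion (< 4 A) and is free of steric clash (no
    inter-residue heavy-atom contact < 2.5 A).  Pass
    ``distal_angles=(180.0,)`` to pin distal torsions trans instead.
    Deterministic: no randomness enters the scan.
    """
    base, pairing, e_pos, x_pos, x_letter = _scan_context(mode, context_length)
    chi12 = [(BIN_ANGLE[b1], BIN_ANGLE[b2])
             for b1, b2 in itertools.product(ROTAMER_BINS, repeat=2)]
    e_poses, e_coords = _residue_poses(base, e_pos, chi12, [distal_angles])
    x_poses, x_coords = _residue_poses(base, x_pos, chi12,
                                       [distal_angles, distal_angles])

    e_names = base.atoms.atom_name[base.residue_mask(e_pos)]
    x_names = base.atoms.atom_name[base.residue_mask(x_pos)]
    oe_idx = [int(np.where(e_names == nm)[0][0]) for nm in ("OE1", "OE2")]
    n_atoms = ("NZ",) if x_letter == "K" else ("NE", "NH1", "NH2")
    n_idx = [int(np.where(x_names == nm)[0][0]) for nm in n_atoms]

    centroids = e_coords[:, oe_idx].mean(axis=1)            # (nE, 3)
    nitro = x_coords[:, n_idx]                              # (nX, k, 3)
    # bridge distance matrix: min over basic nitrogens
    diff = centroids[:, None, None, :] - nitro[None, :, :, :]
    bridge = np.linalg.norm(diff, axis=-1).min(axis=-1)     # (nE, nX)
    # clash matrix: min over all heavy-atom pairs
    pair_d = np.linalg.norm(
        e_coords[:, None, :, None, :] - x_coords[None, :, None, :, :], axis=-1)
    min_atom = pair_d.min(axis=(2, 3))                      # (nE, nX)

    n_distal_e = len(distal_angles)
    n_distal_x = len(distal_angles) ** 2
    rows: list[RotamerCombination] = []
    bins9 = list(itertools.product(ROTAMER_BINS, repeat=2))
    for ie, (e1, e2) in enumerate(bins9):
        for ix, (x1, x2) in enumerate(bins9):
            es = slice(ie * n_distal_e, (ie + 1) * n_distal_e)
            xs = slice(ix * n_distal_x, (ix + 1) * n_distal_x)
            b = bridge[es, xs]
            m = min_atom[es, xs]
            ok = (b < SALT_BRIDGE_CUTOFF) & (m >= CLASH_CUTOFF)
            if ok.any():
                cand = np.where(ok, b, np.inf)
            else:
                cand = b
            k = np.unravel_index(int(np.argmin(cand)), b.shape)
            rows.append(RotamerCombination(
                mode=mode,
                e_bins=(e1, e2),
                x_bins=(x1, x2),
                distance=float(b[k]),
                clash=bool(m[k] < CLASH_CUTOFF),
                capable=bool(ok.any()),
                e_chi=e_poses[es][k[0]],
                x_chi=x_poses[xs][k[1]],
            ))
    return rows


def capable_combinations(mode: str, **kwargs) -> list[RotamerCombination]:
    """The salt-bridge-capable subset of :func:`rotamer_combination_scan`."""
    return [r for r in rotamer_combination_scan(mode, **kwargs) if r.capable]
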
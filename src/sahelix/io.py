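"""Readers, writers, packaged fixtures and run configuration.

Structures travel as PDB files (biotite-backed; multi-model files become
trajectories), sequences as FASTA, results as plain TSV/JSON.  Residue
numbering read from PDB files is remapped to contiguous 1-based indices —
all pairing offsets in this package are sequence offsets, not author
numbering — with the original numbering kept in a mapping table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib.resources import files
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequences import PolypeptideSequence
from .helixgeom import HelixStructure
from .trajstats import Trajectory, DEFAULT_FRAME_INTERVAL


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; the defaults are the package's canonical rules."""

    saltbridge_cutoff: float = 4.0   # A, strict
    clash_cutoff: float = 2.5        # A, strict
    min_helix_length: int = 12       # residues
    distance_bin: float = 0.1        # A
    lifetime_bin: float = 5.0        # ps
    frame_interval: float = DEFAULT_FRAME_INTERVAL  # ps
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("saltbridge_cutoff", "clash_cutoff", "min_helix_length",
                     "distance_bin", "lifetime_bin", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


class PDBFormatError(ValueError):
    """A PDB file could not be parsed; the message names the file."""


# -- sequences -------------------------------------------------------------


def read_fasta(path: str | Path) -> list[PolypeptideSequence]:
    return [PolypeptideSequence(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: list[PolypeptideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in sequences]
    SeqIO.write(records, str(path), "fasta")


def load_fixture_sequences() -> dict[str, PolypeptideSequence]:
    """The packaged construct sequences.

    EK3/ER3/EK2R1/EK1R2/EK2/EK1 are the 98-residue repeat designs; M6WT,
    M6K and M6R are synthetic stand-ins for the myosin-6 SAH constructs,
    built to the constructs' published length, Lys/Arg/Glu composition and
    monomer masses (the natural accession is not redistributed here).
    """
    out: dict[str, PolypeptideSequence] = {}
    data = files("sahelix") / "data"
    for name in ("denovo_constructs.fasta", "myosin6_synthetic.fasta"):
        for rec in SeqIO.parse(str(data / name), "fasta"):
            out[rec.id] = PolypeptideSequence(id=rec.id, residues=str(rec.seq))
    return out


# -- structures ------------------------------------------------------------


def _renumber(atoms):
    """Remap residue ids to contiguous 1-based; return (atoms, mapping)."""
    ids = atoms.res_id
    order = {}
    for rid in ids:
        if rid not in order:
            order[rid] = len(order) + 1
    atoms = atoms.copy()
    atoms.res_id = np.array([order[r] for r in ids])
    return atoms, {v: k for k, v in order.items()}


def read_structure(path: str | Path):
    """Read a single-model PDB file.

    Returns (HelixStructure, numbering map internal->original).  Hydrogens
    are dropped; multi-chain files keep the first chain.
    """
    try:
        pfile = pdb.PDBFile.read(str(path))
        atoms = pfile.get_structure(model=1)
    except Exception as err:
        raise PDBFormatError(f"{path}: {err}") from err
    atoms = atoms[atoms.element != "H"]
    if len(atoms) == 0:
        raise PDBFormatError(f"{path}: no atoms parsed")
    first_chain = atoms.chain_id[0]
    atoms = atoms[atoms.chain_id == first_chain]
    atoms, mapping = _renumber(atoms)
    return HelixStructure(atoms=atoms), mapping


def read_trajectory(path: str | Path,
                    frame_interval: float = DEFAULT_FRAME_INTERVAL) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (one model per frame)."""
    try:
        pfile = pdb.PDBFile.read(str(path))
        stack = pfile.get_structure()
    except Exception as err:
        raise PDBFormatError(f"{path}: {err}") from err
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    keep = stack.element != "H"
    stack = stack[..., keep]
    template, _mapping = _renumber(stack[0])
    stack = struc.from_template(template, stack.coord)
    return Trajectory(frames=stack, frame_interval=frame_interval)


def write_structure(structure: HelixStructure, path: str | Path) -> None:
    pfile = pdb.PDBFile()
    pfile.set_structure(structure.atoms)
    pfile.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    pfile = pdb.PDBFile()
    pfile.set_structure(traj.frames)
    pfile.write(str(path))


def read_structures(paths: list[str | Path]):
    """Read several single-model PDB files as (id, structure) pairs."""
    out = []
    for p in paths:
        structure, _ = read_structure(p)
        out.append((Path(p).stem, structure))
    return out
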
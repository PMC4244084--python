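"""Domain types, structure/trajectory I/O and system-preparation arithmetic.

The in-memory containers here are what every analysis stage consumes:

* :class:`SystemModel` — chains, residues and heavy-atom topology, with each
  chain labelled as ``peptide`` or ``inhibitor``.  A multi-chain inhibitor
  (e.g. the two domains of an α-crystallin-domain dimer) is treated as one
  logical inhibitor entity; per-chain breakdowns remain available because the
  chain ids are kept.
* :class:`Frame` / :class:`Trajectory` — time-stamped heavy-atom coordinates
  in Å with an orthorhombic periodic box.

Units are fixed throughout the package: Å, ns, kcal/mol, e, mM.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import constants

from .errors import (
    ConfigurationError,
    DataError,
    FormatError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "ChainRole",
    "ChainSpec",
    "SystemModel",
    "Frame",
    "Trajectory",
    "load_system",
    "iter_frames",
    "read_trajectory",
    "write_trajectory",
    "write_pdb",
    "formal_charge",
    "formal_charge_parts",
    "molar_concentration",
    "AA_THREE_TO_ONE",
    "AA_ONE_TO_THREE",
]


class ChainRole(str, Enum):
    PEPTIDE = "peptide"
    INHIBITOR = "inhibitor"


AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}

# Side-chain formal charges at pH 7; His neutral by convention.
_SIDECHAIN_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}


@dataclass(frozen=True)
class ChainSpec:
    """One chain: its id, role and ordered residue list."""

    chain_id: str
    role: ChainRole
    residues: tuple[tuple[int, str], ...]  # (seq number, 3-letter name)

    def __post_init__(self) -> None:
        if not isinstance(self.role, ChainRole):
            object.__setattr__(self, "role", ChainRole(self.role))
        nums = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValidationError(
                f"residue numbering in chain {self.chain_id!r} is not "
                "strictly increasing"
            )

    @property
    def sequence(self) -> str:
        """One-letter sequence; unknown residue names map to 'X'."""
        return "".join(AA_THREE_TO_ONE.get(name, "X") for _, name in self.residues)


@dataclass
class SystemModel:
    """Chains/residues/heavy-atom topology with per-chain role labels.

    Atom indices refer to the flat heavy-atom order (hydrogens excluded),
    which is also the coordinate order of every :class:`Frame`.
    """

    chains: list[ChainSpec]
    residue_atoms: list[np.ndarray]          # heavy-atom indices per global residue
    atom_names: list[str]
    atom_elements: list[str]

    # derived, filled in __post_init__
    residue_index: dict[tuple[str, int], int] = field(default_factory=dict)
    residue_chain: list[str] = field(default_factory=list)
    residue_names: list[str] = field(default_factory=list)
    residue_numbers: list[int] = field(default_factory=list)
    atom_residue: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.residue_index = {}
        self.residue_chain = []
        self.residue_names = []
        self.residue_numbers = []
        gi = 0
        for chain in self.chains:
            for num, name in chain.residues:
                self.residue_index[(chain.chain_id, num)] = gi
                self.residue_chain.append(chain.chain_id)
                self.residue_names.append(name)
                self.residue_numbers.append(num)
                gi += 1
        if gi != len(self.residue_atoms):
            raise ValidationError(
                f"{gi} residues declared but {len(self.residue_atoms)} "
                "heavy-atom lists given"
            )
        n_at = sum(len(a) for a in self.residue_atoms)
        if n_at != len(self.atom_names) or n_at != len(self.atom_elements):
            raise ValidationError("atom metadata length mismatch")
        self.atom_residue = np.empty(n_at, dtype=np.intp)
        seen = np.zeros(n_at, dtype=bool)
        for ri, idx in enumerate(self.residue_atoms):
            if seen[idx].any():
                raise ValidationError("an atom is assigned to two residues")
            seen[idx] = True
            self.atom_residue[idx] = ri
        if not seen.all():
            raise ValidationError("an atom belongs to no residue")
        if not any(c.role is ChainRole.PEPTIDE for c in self.chains):
            raise ValidationError("at least one chain must have role 'peptide'")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_atoms)

    @property
    def peptide_chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains if c.role is ChainRole.PEPTIDE]

    @property
    def inhibitor_chain_ids(self) -> list[str]:
        """Chains making up the single logical inhibitor entity (may be
        several, e.g. the two domains of an ACD dimer); empty for control
        systems without an inhibitor."""
        return [c.chain_id for c in self.chains if c.role is ChainRole.INHIBITOR]

    @property
    def has_inhibitor(self) -> bool:
        return bool(self.inhibitor_chain_ids)

    def chain(self, chain_id: str) -> ChainSpec:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def chain_residue_indices(self, chain_id: str) -> np.ndarray:
        """Global residue indices of one chain, in sequence order."""
        chain = self.chain(chain_id)
        return np.array(
            [self.residue_index[(chain_id, n)] for n, _ in chain.residues],
            dtype=np.intp,
        )

    def chain_atom_indices(self, chain_id: str) -> np.ndarray:
        res = self.chain_residue_indices(chain_id)
        return np.concatenate([self.residue_atoms[r] for r in res])

    def calpha_atom_indices(self, chain_ids: Sequence[str] | None = None) -> np.ndarray:
        """Indices of Cα atoms (atom name 'CA'), optionally restricted to
        given chains."""
        if chain_ids is None:
            chain_ids = [c.chain_id for c in self.chains]
        wanted = set(chain_ids)
        out = []
        for ri in range(self.n_residues):
            if self.residue_chain[ri] not in wanted:
                continue
            for ai in self.residue_atoms[ri]:
                if self.atom_names[ai] == "CA":
                    out.append(ai)
        return np.array(out, dtype=np.intp)


@dataclass
class Frame:
    """One trajectory frame: time (ns), heavy-atom coordinates (Å) and
    orthorhombic box edge lengths (Å)."""

    time: float
    coords: np.ndarray            # (n_atoms, 3) float64, Å
    box: np.ndarray               # (3,) float64, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n, 3)")
        if not (self.box > 0).all():
            raise ValidationError("all box edges must be positive")


@dataclass
class Trajectory:
    """Ordered frames over one SystemModel with strictly increasing times."""

    model: SystemModel
    frames: list[Frame]

    def __post_init__(self) -> None:
        for f in self.frames:
            if f.coords.shape[0] != self.model.n_atoms:
                raise TopologyError(
                    f"frame at t={f.time} has {f.coords.shape[0]} atoms, "
                    f"topology has {self.model.n_atoms}"
                )
        t = self.times
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise DataError("frame times are not strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        """Nominal frame spacing (ns): median of successive differences."""
        t = self.times
        if len(t) < 2:
            raise ValidationError("dt undefined for a trajectory of < 2 frames")
        return float(np.median(np.diff(t)))


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def _is_hydrogen(element: str, name: str) -> bool:
    el = (element or "").strip().upper()
    if el:
        return el == "H" or el == "D"
    # fallback: first alphabetic character of the atom name
    for ch in name:
        if ch.isalpha():
            return ch.upper() == "H"
    return False


def load_system(path: str | Path, roles: Mapping[str, ChainRole | str]) -> SystemModel:
    """Parse a PDB structure into a :class:`SystemModel`.

    Hydrogens are excluded from the heavy-atom lists.  Every chain in the
    file must be assigned a role (``peptide`` or ``inhibitor``) through
    *roles*; a missing chain raises :class:`ConfigurationError`.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("system", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"no model records in {path}")
    pdb_model = models[0]

    chains: list[ChainSpec] = []
    residue_atoms: list[np.ndarray] = []
    atom_names: list[str] = []
    atom_elements: list[str] = []
    ai = 0
    for pchain in pdb_model:
        cid = pchain.id.strip() or "A"
        if cid not in roles:
            raise ConfigurationError(
                f"chain {cid!r} present in {path} but missing from the role "
                "assignment"
            )
        residues: list[tuple[int, str]] = []
        for res in pchain:
            het, num, _icode = res.id
            if het.strip():          # skip waters / heteroatoms
                continue
            heavy = []
            for atom in res:
                if _is_hydrogen(atom.element, atom.get_name()):
                    continue
                heavy.append(ai)
                atom_names.append(atom.get_name())
                atom_elements.append((atom.element or "").strip().upper())
                ai += 1
            if not heavy:
                continue
            residues.append((num, res.get_resname().strip()))
            residue_atoms.append(np.array(heavy, dtype=np.intp))
        if residues:
            chains.append(ChainSpec(cid, ChainRole(roles[cid]), tuple(residues)))
    if not chains:
        raise FormatError(f"no polymer residues found in {path}")
    return SystemModel(chains, residue_atoms, atom_names, atom_elements)


def write_pdb(model: SystemModel, coords: np.ndarray, path: str | Path,
              box: np.ndarray | None = None) -> None:
    """Write the heavy-atom system as a minimal PDB file (fixture format)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (model.n_atoms, 3):
        raise TopologyError("coordinate shape does not match topology")
    lines = []
    if box is not None:
        b = np.asarray(box, dtype=float).reshape(3)
        lines.append(
            f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    serial = 1
    for chain in model.chains:
        last_res = None
        for num, name in chain.residues:
            ri = model.residue_index[(chain.chain_id, num)]
            for aidx in model.residue_atoms[ri]:
                x, y, z = coords[aidx]
                aname = model.atom_names[aidx]
                el = model.atom_elements[aidx] or aname[:1]
                pdb_name = f" {aname:<3s}" if len(aname) < 4 else aname[:4]
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name}{'':1s}{name:>3s} "
                    f"{chain.chain_id[:1]}{num:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {el:>2s}"
                )
                serial += 1
            last_res = num
        lines.append(f"TER   {serial:5d}      {name:>3s} {chain.chain_id[:1]}{last_res:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectory I/O: plain-text fallback format + binary formats via mdtraj
# ---------------------------------------------------------------------------

_TEXT_MAGIC = "# oligotraj-trajectory 1"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the self-describing plain-text trajectory format.

    Layout::

        # oligotraj-trajectory 1
        natoms <N>
        frame <time_ns> <Lx> <Ly> <Lz>
        <x> <y> <z>        (N rows, Å, 4 decimals)
        frame ...
    """
    buf = io.StringIO()
    buf.write(_TEXT_MAGIC + "\n")
    buf.write(f"natoms {traj.model.n_atoms}\n")
    for f in traj.frames:
        buf.write(f"frame {f.time:.6f} {f.box[0]:.4f} {f.box[1]:.4f} {f.box[2]:.4f}\n")
        np.savetxt(buf, f.coords, fmt="%.4f")
    Path(path).write_text(buf.getvalue())


def _iter_frames_text(path: Path, model: SystemModel) -> Iterator[Frame]:
    with open(path) as fh:
        first = fh.readline().strip()
        if first != _TEXT_MAGIC:
            raise FormatError(f"{path} is not an oligotraj text trajectory")
        tok = fh.readline().split()
        if len(tok) != 2 or tok[0] != "natoms":
            raise FormatError(f"bad natoms header in {path}")
        natoms = int(tok[1])
        if natoms != model.n_atoms:
            raise TopologyError(
                f"trajectory has {natoms} atoms, topology has {model.n_atoms}"
            )
        prev_t = -np.inf
        while True:
            head = fh.readline()
            if not head.strip():
                break
            tok = head.split()
            if tok[0] != "frame" or len(tok) != 5:
                raise FormatError(f"bad frame header {head!r} in {path}")
            t = float(tok[1])
            if t <= prev_t:
                raise DataError(f"non-monotonic frame times in {path}")
            prev_t = t
            box = np.array(tok[2:5], dtype=float)
            rows = []
            for _ in range(natoms):
                line = fh.readline()
                if not line:
                    raise TopologyError(
                        f"truncated frame at t={t} in {path}: fewer coordinate "
                        "rows than the topology's atom count"
                    )
                rows.append(line.split())
            coords = np.array(rows, dtype=float)
            if coords.shape != (natoms, 3):
                raise TopologyError(f"malformed coordinate block at t={t} in {path}")
            yield Frame(t, coords, box)


def _iter_frames_mdtraj(path: Path, model: SystemModel) -> Iterator[Frame]:
    import mdtraj

    top = _mdtraj_topology(model)
    traj = mdtraj.load(str(path), top=top)
    if traj.n_atoms != model.n_atoms:
        raise TopologyError(
            f"trajectory has {traj.n_atoms} atoms, topology has {model.n_atoms}"
        )
    prev_t = -np.inf
    for i in range(traj.n_frames):
        t = float(traj.time[i]) / 1000.0          # mdtraj time is ps
        if t <= prev_t:
            raise DataError(f"non-monotonic frame times in {path}")
        prev_t = t
        box = traj.unitcell_lengths[i] * 10.0     # nm -> Å
        yield Frame(t, traj.xyz[i] * 10.0, box)


def _mdtraj_topology(model: SystemModel):
    import mdtraj

    top = mdtraj.Topology()
    for chain in model.chains:
        ch = top.add_chain()
        for num, name in chain.residues:
            ri = model.residue_index[(chain.chain_id, num)]
            res = top.add_residue(name, ch, resSeq=num)
            for ai in model.residue_atoms[ri]:
                el_sym = model.atom_elements[ai] or "C"
                try:
                    el = mdtraj.element.Element.getBySymbol(el_sym.capitalize())
                except KeyError:
                    el = mdtraj.element.carbon
                top.add_atom(model.atom_names[ai], el, res)
    return top


def iter_frames(source: str | Path, model: SystemModel) -> Iterator[Frame]:
    """Stream frames from a trajectory file in time order.

    ``.dcd``/``.xtc``/``.trr`` go through mdtraj; anything else is read as
    the package's plain-text fallback format.
    """
    path = Path(source)
    if path.suffix.lower() in {".dcd", ".xtc", ".trr"}:
        yield from _iter_frames_mdtraj(path, model)
    else:
        yield from _iter_frames_text(path, model)


def read_trajectory(source: str | Path, model: SystemModel) -> Trajectory:
    return Trajectory(model, list(iter_frames(source, model)))


# ---------------------------------------------------------------------------
# System-preparation arithmetic
# ---------------------------------------------------------------------------

def formal_charge_parts(sequence: str, charged_termini: bool = True
                        ) -> tuple[int, int, int]:
    """Side-chain, N-terminal and C-terminal formal charges (e) at pH 7.

    Side chains: D, E → −1; K, R → +1; H neutral.  Charged termini carry
    +1 (N) and −1 (C), which cancel in the net charge but are reported
    separately so either bookkeeping convention can be checked.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValidationError("empty sequence")
    bad = set(seq) - set(AA_ONE_TO_THREE)
    if bad:
        raise ValidationError(f"unknown residue letters: {sorted(bad)}")
    side = sum(_SIDECHAIN_CHARGE.get(a, 0) for a in seq)
    if charged_termini:
        return side, +1, -1
    return side, 0, 0


def formal_charge(sequence: str, charged_termini: bool = True) -> int:
    """Net formal charge (e) of a sequence at pH 7 (termini cancel)."""
    side, n_term, c_term = formal_charge_parts(sequence, charged_termini)
    return side + n_term + c_term


def molar_concentration(n_molecules: int, box_edges: Sequence[float] | float) -> float:
    """Concentration (mM) of *n* molecules in an orthorhombic box (edges Å)."""
    if n_molecules < 0:
        raise ValidationError("n_molecules must be >= 0")
    edges = np.atleast_1d(np.asarray(box_edges, dtype=float))
    if edges.size == 1:
        edges = np.repeat(edges, 3)
    if edges.size != 3 or not (edges > 0).all():
        raise ValidationError("box edges must be three positive lengths")
    volume_l = float(np.prod(edges)) * 1e-27      # Å^3 -> L
    moles = n_molecules / constants.N_A
    return moles / volume_l * 1e3                 # mol/L -> mM
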
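"""Structures, trajectories, topology, superposition, dihedrals and SASA.

The in-memory model is array-backed: a :class:`Trajectory` stores one
:class:`AtomTable` (constant topology) and a ``(n_frames, n_atoms, 3)``
coordinate array.  :class:`StructureFrame` is a light view onto one frame;
:class:`AtomRecord` objects are materialised on demand for record-oriented
code and for PDB round-trips.

Geometric conventions: distances in Angstrom, angles in degrees on
(-180, 180] with the IUPAC torsion sign convention (cis = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .chemistry import SIDECHAIN_SITE, VDW_RADII
from .errors import DegenerateGeometryError, FormatError, TopologyError
from .periodic import periodic_delta, wrap_angle

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "AtomRecord",
    "AtomTable",
    "StructureFrame",
    "Trajectory",
    "StrandTopology",
    "AnnealingSchedule",
    "Transform",
    "read_trajectory",
    "write_trajectory",
    "superpose",
    "rmsd_series",
    "dihedral",
    "sasa",
    "relative_sasa",
    "classify_orientation",
    "isomer_state",
    "make_selection",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    xyz: tuple[float, float, float]


class AtomTable:
    """Per-atom metadata shared by every frame of a trajectory."""

    def __init__(self, atom_names, elements, residue_numbers, residue_names,
                 chain_ids, serials=None):
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U3")
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        n = len(self.atom_names)
        self.serials = (np.arange(1, n + 1) if serials is None
                        else np.asarray(serials, dtype=int))
        key = list(zip(self.chain_ids.tolist(), self.residue_numbers.tolist(),
                       self.atom_names.tolist()))
        if len(set(key)) != n:
            raise FormatError("duplicate (chain, residue, atom name) in atom table")
        self._index = {k: i for i, k in enumerate(key)}

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, residue_number: int, atom_name: str,
                   chain_id: str | None = None) -> int:
        if chain_id is None:
            chains = np.unique(self.chain_ids[self.residue_numbers == residue_number])
            if len(chains) == 0:
                raise TopologyError(f"residue {residue_number} not in structure")
            chain_id = str(chains[0])
        try:
            return self._index[(chain_id, residue_number, atom_name)]
        except KeyError:
            raise TopologyError(
                f"atom {atom_name} of residue {residue_number} not in structure"
            ) from None

    def residue_mask(self, residue_number: int) -> np.ndarray:
        return self.residue_numbers == residue_number

    def residue_numbers_unique(self) -> np.ndarray:
        return np.unique(self.residue_numbers)

    def residue_name_of(self, residue_number: int) -> str:
        mask = self.residue_mask(residue_number)
        if not mask.any():
            raise TopologyError(f"residue {residue_number} not in structure")
        return str(self.residue_names[mask][0])


@dataclass
class StructureFrame:
    """One frame: an atom table plus coordinates (n_atoms, 3)."""

    table: AtomTable
    coords: np.ndarray
    frame_index: int = 0
    temperature: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.table.n_atoms, 3):
            raise FormatError("coordinate array does not match atom table")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")

    @property
    def atoms(self) -> list[AtomRecord]:
        t = self.table
        return [
            AtomRecord(int(t.serials[i]), str(t.atom_names[i]), str(t.elements[i]),
                       int(t.residue_numbers[i]), str(t.residue_names[i]),
                       str(t.chain_ids[i]), tuple(self.coords[i]))
            for i in range(t.n_atoms)
        ]

    @classmethod
    def from_records(cls, records: Sequence[AtomRecord], frame_index: int = 0,
                     temperature: float | None = None) -> "StructureFrame":
        table = AtomTable(
            [r.atom_name for r in records], [r.element for r in records],
            [r.residue_number for r in records], [r.residue_name for r in records],
            [r.chain_id for r in records], [r.serial for r in records],
        )
        coords = np.array([r.xyz for r in records], dtype=float)
        return cls(table, coords, frame_index, temperature)

    def xyz(self, residue_number: int, atom_name: str) -> np.ndarray:
        return self.coords[self.table.atom_index(residue_number, atom_name)]


@dataclass(frozen=True)
class AnnealingSchedule:
    """Ordered (frame_start, frame_stop_exclusive, temperature_K) segments."""

    segments: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        segs = tuple((int(a), int(b), float(t)) for a, b, t in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_stop = 0
        for start, stop, temp in segs:
            if start != prev_stop or stop <= start:
                raise FormatError("schedule segments must partition frames")
            if temp <= 0:
                raise FormatError("schedule temperatures must be positive")
            prev_stop = stop

    @property
    def n_frames(self) -> int:
        return self.segments[-1][1]

    def temperature_at(self, frame: int) -> float:
        for start, stop, temp in self.segments:
            if start <= frame < stop:
                return temp
        raise IndexError(f"frame {frame} outside schedule")


class Trajectory:
    """Ordered frames over a constant atom table."""

    def __init__(self, table: AtomTable, coords: np.ndarray,
                 schedule: AnnealingSchedule | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[0] < 1 or coords.shape[1:] != (table.n_atoms, 3):
            raise FormatError("trajectory coordinates must be (n_frames, n_atoms, 3)")
        if schedule is not None and schedule.n_frames != coords.shape[0]:
            raise FormatError("schedule does not partition the trajectory frames")
        self.table = table
        self.coords = coords
        self.schedule = schedule

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> StructureFrame:
        i = int(np.arange(self.n_frames)[i])  # normalise negative indices
        temp = self.schedule.temperature_at(i) if self.schedule else None
        return StructureFrame(self.table, self.coords[i], i, temp)

    @property
    def frames(self) -> list[StructureFrame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def __iter__(self) -> Iterator[StructureFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class StrandTopology:
    """Residue-to-strand assignment plus chromophore dihedral definitions.

    ``strand_of`` maps residue numbers to labels (three strand labels plus
    optionally "helix"/"loop"); ``cleavage_site`` is the residue pair across
    the proteolytic cut; ``dihedral_specs`` maps {"phi_I", "phi_P"} to four
    (residue_number, atom_name) identifiers each.
    """

    strand_of: dict[int, str]
    dissociating_strand: str
    cleavage_site: tuple[int, int]
    dihedral_specs: dict[str, tuple[tuple[int, str], ...]] = field(default_factory=dict)
    chromophore_residues: frozenset[int] = frozenset()
    strand_labels: tuple[str, ...] = ("7", "10", "11")

    def __post_init__(self):
        self.strand_of = {int(k): str(v) for k, v in self.strand_of.items()}
        self.chromophore_residues = frozenset(int(r) for r in self.chromophore_residues)
        self.cleavage_site = (int(self.cleavage_site[0]), int(self.cleavage_site[1]))
        if self.dissociating_strand not in set(self.strand_of.values()):
            raise TopologyError(
                f"dissociating strand {self.dissociating_strand!r} has no residues"
            )

    def residues_of(self, label: str) -> list[int]:
        return sorted(r for r, s in self.strand_of.items() if s == label)

    @property
    def neighbor_strands(self) -> list[str]:
        return [s for s in self.strand_labels if s != self.dissociating_strand]

    def label(self, residue_number: int) -> str | None:
        return self.strand_of.get(residue_number)

    def validate_against(self, table: AtomTable) -> None:
        present = set(table.residue_numbers_unique().tolist())
        missing = sorted(set(self.strand_of) - present)
        if missing:
            raise TopologyError(f"topology residues absent from structure: {missing}")
        for name, spec in self.dihedral_specs.items():
            for res, atom in spec:
                table.atom_index(res, atom)  # raises TopologyError

    # -- JSON sidecar -------------------------------------------------------

    def to_dict(self, schedule: AnnealingSchedule | None = None) -> dict:
        data = {
            "strand_of": {str(r): s for r, s in sorted(self.strand_of.items())},
            "dissociating_strand": self.dissociating_strand,
            "cleavage_site": list(self.cleavage_site),
            "dihedral_specs": {k: [[r, a] for r, a in v]
                               for k, v in self.dihedral_specs.items()},
            "chromophore_residues": sorted(self.chromophore_residues),
            "strand_labels": list(self.strand_labels),
        }
        if schedule is not None:
            data["schedule"] = [list(seg) for seg in schedule.segments]
        return data

    @classmethod
    def from_dict(cls, data: dict) -> tuple["StrandTopology", AnnealingSchedule | None]:
        topo = cls(
            strand_of={int(r): s for r, s in data["strand_of"].items()},
            dissociating_strand=data["dissociating_strand"],
            cleavage_site=tuple(data["cleavage_site"]),
            dihedral_specs={k: tuple((int(r), a) for r, a in v)
                            for k, v in data.get("dihedral_specs", {}).items()},
            chromophore_residues=frozenset(data.get("chromophore_residues", [])),
            strand_labels=tuple(data.get("strand_labels", ("7", "10", "11"))),
        )
        schedule = None
        if data.get("schedule"):
            schedule = AnnealingSchedule(tuple(tuple(s) for s in data["schedule"]))
        return topo, schedule


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _to_atom_array_stack(traj: Trajectory) -> bst.AtomArrayStack:
    t = traj.table
    stack = bst.AtomArrayStack(traj.n_frames, t.n_atoms)
    stack.coord[:] = traj.coords
    stack.chain_id = t.chain_ids
    stack.res_id = t.residue_numbers
    stack.res_name = t.residue_names
    stack.atom_name = t.atom_names
    stack.element = t.elements
    stack.hetero = np.zeros(t.n_atoms, dtype=bool)
    return stack


def write_trajectory(traj: Trajectory, topo: StrandTopology, path, topology_path) -> None:
    """Write a multi-model PDB plus a JSON topology sidecar."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(traj))
    pdb.write(str(path))
    Path(topology_path).write_text(
        json.dumps(topo.to_dict(traj.schedule), indent=1))


def read_trajectory(path, topology_path) -> tuple[Trajectory, StrandTopology]:
    """Read a multi-model PDB and its topology sidecar.

    Raises :class:`FormatError` for inconsistent models and
    :class:`TopologyError` when dihedral atoms do not resolve.
    """
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on varying atom counts
        raise FormatError(f"inconsistent models in {path}: {exc}") from exc
    if isinstance(stack, bst.AtomArray):
        stack = bst.stack([stack])
    table = AtomTable(stack.atom_name, stack.element, stack.res_id,
                      stack.res_name, stack.chain_id)
    topo_data = json.loads(Path(topology_path).read_text())
    topo, schedule = StrandTopology.from_dict(topo_data)
    traj = Trajectory(table, np.asarray(stack.coord, dtype=float), schedule)
    topo.validate_against(table)
    return traj, topo


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def make_selection(selection, table: AtomTable) -> np.ndarray:
    """Resolve a selection into a boolean atom mask.

    ``selection`` may be one of the strings "all", "heavy", "backbone", "ca",
    a boolean mask, or a callable ``AtomRecord -> bool``.
    """
    if isinstance(selection, str):
        if selection == "all":
            return np.ones(table.n_atoms, dtype=bool)
        if selection == "heavy":
            return table.elements != "H"
        if selection == "backbone":
            return np.isin(table.atom_names, BACKBONE_ATOMS)
        if selection == "ca":
            return table.atom_names == "CA"
        raise ValueError(f"unknown selection {selection!r}")
    if callable(selection):
        frame = StructureFrame(table, np.zeros((table.n_atoms, 3)))
        return np.array([bool(selection(rec)) for rec in frame.atoms])
    mask = np.asarray(selection, dtype=bool)
    if mask.shape != (table.n_atoms,):
        raise ValueError("selection mask has wrong length")
    return mask


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    """Rigid motion x -> R (x - mobile_centroid) + reference_centroid."""

    rotation: np.ndarray
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.mobile_centroid) @ self.rotation.T \
            + self.reference_centroid


def superpose(mobile: StructureFrame, reference: StructureFrame,
              selection="heavy") -> tuple[Transform, float]:
    """Least-squares rigid superposition (Kabsch); returns (transform, RMSD)."""
    mask = make_selection(selection, mobile.table)
    ref_mask = make_selection(selection, reference.table)
    if mask.sum() != ref_mask.sum():
        raise TopologyError("selection resolves to different atom counts")
    a = reference.coords[ref_mask]
    b = mobile.coords[mask]
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    sing = np.linalg.svd(b_c, compute_uv=False)
    if sing[1] <= 1e-8 * max(sing[0], 1e-30):
        raise DegenerateGeometryError("collinear selection: rotation underdetermined")
    rot, rssd = Rotation.align_vectors(a_c, b_c)
    rmsd = float(rssd) / np.sqrt(len(a))
    transform = Transform(rot.as_matrix(), b.mean(axis=0), a.mean(axis=0))
    return transform, rmsd


def rmsd_series(traj: Trajectory, reference: StructureFrame,
                selection="heavy") -> np.ndarray:
    """Per-frame RMSD against ``reference`` after optimal superposition."""
    return np.array([superpose(f, reference, selection)[1] for f in traj])


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral(frame: StructureFrame, spec: Sequence[tuple[int, str]]) -> float:
    """Torsion angle over four (residue, atom) identifiers, degrees in (-180, 180].

    IUPAC sign convention; cis (eclipsed) = 0, trans (anti) = 180.
    """
    pts = np.array([frame.xyz(res, atom) for res, atom in spec])
    b1, b2, b3 = pts[1] - pts[0], pts[2] - pts[1], pts[3] - pts[2]
    for i, v in enumerate((b1, b2, b3)):
        if np.linalg.norm(v) < 1e-9:
            raise DegenerateGeometryError(f"coincident atoms in dihedral (bond {i})")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms in dihedral")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def isomer_state(phi_deg: float, cis_center: float = 0.0,
                 trans_center: float = 180.0) -> str:
    """Bin a twisting dihedral to the nearer of the cis/trans basins."""
    d_cis = abs(periodic_delta(phi_deg, cis_center))
    d_trans = abs(periodic_delta(phi_deg, trans_center))
    return "cis" if d_cis <= d_trans else "trans"


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def _sasa_per_atom(frame: StructureFrame, probe_radius: float,
                   point_number: int) -> np.ndarray:
    unknown = [str(frame.table.atom_names[i])
               for i, el in enumerate(frame.table.elements) if el not in VDW_RADII]
    if unknown:
        raise StrandgateSasaError(unknown)
    array = bst.AtomArray(frame.table.n_atoms)
    array.coord = frame.coords
    array.chain_id = frame.table.chain_ids
    array.res_id = frame.table.residue_numbers
    array.res_name = frame.table.residue_names
    array.atom_name = frame.table.atom_names
    array.element = frame.table.elements
    radii = np.array([VDW_RADII[el] for el in frame.table.elements])
    values = bst.sasa(array, probe_radius=probe_radius, vdw_radii=radii,
                      point_number=point_number)
    return np.nan_to_num(values)


class StrandgateSasaError(DegenerateGeometryError):
    def __init__(self, atoms):
        super().__init__(f"no van der Waals radius for atoms: {atoms}")
        self.atoms = atoms


def sasa(frame: StructureFrame, probe_radius: float = 1.4,
         point_number: int = 960) -> dict[int, float]:
    """Shrake-Rupley per-residue solvent-accessible surface area (A^2)."""
    per_atom = _sasa_per_atom(frame, probe_radius, point_number)
    out: dict[int, float] = {}
    for res in frame.table.residue_numbers_unique():
        out[int(res)] = float(per_atom[frame.table.residue_mask(int(res))].sum())
    return out


def relative_sasa(frame: StructureFrame, probe_radius: float = 1.4,
                  point_number: int = 960,
                  residues: Iterable[int] | None = None,
                  backbone_only: bool = False) -> dict[int, float]:
    """Per-residue SASA divided by the same residue's isolated SASA.

    The reference is the residue extracted alone (no neighbors), which makes
    the ratio a self-consistent burial measure for pseudo-atom residues.
    """
    table = frame.table
    if backbone_only:
        keep = np.isin(table.atom_names, BACKBONE_ATOMS)
    else:
        keep = np.ones(table.n_atoms, dtype=bool)
    per_atom = _sasa_per_atom(frame, probe_radius, point_number)
    wanted = (set(int(r) for r in residues) if residues is not None
              else set(table.residue_numbers_unique().tolist()))
    out: dict[int, float] = {}
    for res in sorted(wanted):
        mask = table.residue_mask(res) & keep
        if not mask.any():
            continue
        sub_table = AtomTable(table.atom_names[mask], table.elements[mask],
                              table.residue_numbers[mask], table.residue_names[mask],
                              table.chain_ids[mask])
        iso = _sasa_per_atom(StructureFrame(sub_table, frame.coords[mask]),
                             probe_radius, point_number).sum()
        out[res] = float(per_atom[mask].sum() / iso) if iso > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# orientation classification
# ---------------------------------------------------------------------------

def barrel_axis(frame: StructureFrame, topo: StrandTopology) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit axis): first principal component of strand CA atoms."""
    table = frame.table
    strand_residues = [r for r, s in topo.strand_of.items() if s in topo.strand_labels]
    idx = [table.atom_index(r, "CA") for r in strand_residues
           if (table.residue_mask(r) & (table.atom_names == "CA")).any()]
    if len(idx) < 3:
        raise DegenerateGeometryError("fewer than 3 strand CA atoms: axis undefined")
    pts = frame.coords[idx]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    axis = vt[0]
    return centroid, axis / np.linalg.norm(axis)


def classify_orientation(frame: StructureFrame, topo: StrandTopology,
                         exposure_threshold: float = 0.5,
                         terminal_window: int = 3,
                         probe_radius: float = 1.4,
                         point_number: int = 960) -> dict[int, str]:
    """Label strand residues "in" / "out" / "exposed".

    In/out follows the sign of (CA->CB) projected on the radial vector from
    the barrel axis.  "exposed" overrides for residues of the dissociating
    strand near the cleaved terminus whose relative SASA exceeds the
    threshold.  Glycine (no CB) follows backbone exposure only.
    """
    centroid, axis = barrel_axis(frame, topo)
    table = frame.table
    diss = topo.residues_of(topo.dissociating_strand)
    cleave_res = next((r for r in topo.cleavage_site
                       if topo.strand_of.get(r) == topo.dissociating_strand), None)
    terminal = {r for r in diss
                if cleave_res is not None and abs(r - cleave_res) < terminal_window}

    strand_residues = sorted(r for r, s in topo.strand_of.items()
                             if s in topo.strand_labels)
    rel = relative_sasa(frame, probe_radius, point_number, residues=strand_residues)
    rel_bb = None  # computed lazily for glycines

    labels: dict[int, str] = {}
    for res in strand_residues:
        ca = frame.xyz(res, "CA")
        radial = ca - (centroid + ((ca - centroid) @ axis) * axis)
        norm = np.linalg.norm(radial)
        mask = table.residue_mask(res)
        has_cb = bool((mask & (table.atom_names == "CB")).any())
        if not has_cb:
            if rel_bb is None:
                rel_bb = relative_sasa(frame, probe_radius, point_number,
                                       residues=strand_residues, backbone_only=True)
            labels[res] = "exposed" if rel_bb.get(res, 0.0) >= exposure_threshold else "out"
            continue
        cb = frame.xyz(res, "CB")
        side = float((cb - ca) @ (radial / norm)) if norm > 1e-9 else 0.0
        label = "out" if side >= 0 else "in"
        if res in terminal and rel.get(res, 0.0) >= exposure_threshold:
            label = "exposed"
        labels[res] = label
    return labels
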
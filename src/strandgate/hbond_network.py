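"""Inter-strand noncovalent interaction detection, occupancy and network diffs.

Detection operates on hydrogen-free reduced structures, so hydrogen bonds use
a heavy-atom proxy: two polar atoms within ``hbond_da_max`` whose angle
(partner, atom, antecedent) at *both* ends is at least
``hbond_proxy_angle_min``, where the antecedent is the nearest heavy atom of
the same residue.  Salt bridges pair oppositely charged sidechain sites
within ``salt_bridge_max``; stacking pairs aromatic sidechain sites within
``stacking_centroid_max`` whose CB->site axes are within
``stacking_plane_angle_max`` of parallel (folded to [0, 90] degrees).

Polar atoms are: backbone N and O of ordinary residues (mainchain moiety),
the sidechain site of polar residues, and every N/O atom of a chromophore
residue (sidechain moiety).  Donor/acceptor capability is resolved at the
atom-class level: a mainchain amide N is donor-only and a carbonyl O
acceptor-only, so mainchain-mainchain bonds pair N with O; sidechain sites
(and chromophore polar atoms) carry unresolved hydroxyl/amine hydrogens and
pair with each other or with a carbonyl O, but not with a mainchain N.
Only pairs on different strands, or pairs involving a chromophore residue,
are reported when the inter-strand filter is on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemistry import SIDECHAIN_SITE, sidechain_props
from .errors import StrandgateError, TopologyError
from .structure_core import AtomTable, StructureFrame, StrandTopology, Trajectory

__all__ = [
    "InteractionCriteria",
    "Interaction",
    "OccupancyTable",
    "NetworkDiff",
    "PathwayProfile",
    "detect_interactions",
    "occupancy",
    "find_alternating",
    "diff_networks",
    "pathway_profile",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs; literature-standard defaults (all configurable)."""

    hbond_da_max: float = 3.5            # Angstrom, donor-acceptor
    hbond_angle_min: float = 120.0       # degrees, D-H...A when H present
    hbond_proxy_angle_min: float = 90.0  # degrees, heavy-atom proxy (no H)
    salt_bridge_max: float = 4.0         # Angstrom
    stacking_centroid_max: float = 5.5   # Angstrom
    stacking_plane_angle_max: float = 30.0  # degrees
    persistent_min_occupancy: float = 0.5
    alternating_min_occupancy: float = 0.2

    def __post_init__(self):
        for name in ("hbond_da_max", "salt_bridge_max", "stacking_centroid_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("persistent_min_occupancy", "alternating_min_occupancy"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True, order=True)
class Partner:
    residue_number: int
    group: str      # atom name, e.g. "N", "O", "SC", "OH"
    moiety: str     # "mc" or "sc"


@dataclass(frozen=True)
class Interaction:
    """A canonical contact: same physical contact hashes identically."""

    kind: str  # "hbond" | "salt_bridge" | "stacking"
    partner_a: Partner
    partner_b: Partner
    strand_pair: tuple[str, str]

    @classmethod
    def make(cls, kind: str, p1: Partner, p2: Partner,
             s1: str, s2: str) -> "Interaction":
        if (p2, s2) < (p1, s1):
            p1, p2, s1, s2 = p2, p1, s2, s1
        return cls(kind, p1, p2, (s1, s2))

    @property
    def residues(self) -> tuple[int, int]:
        return (self.partner_a.residue_number, self.partner_b.residue_number)

    def involves(self, residue_number: int, moiety: str | None = None) -> bool:
        for p in (self.partner_a, self.partner_b):
            if p.residue_number == residue_number and (moiety is None or p.moiety == moiety):
                return True
        return False

    def label(self, table: AtomTable | None = None) -> str:
        """Render e.g. "K209(sc)-H217(mc)" when a table gives residue names."""
        def one(p: Partner) -> str:
            name = ""
            if table is not None:
                try:
                    from Bio.Data.IUPACData import protein_letters_3to1
                    name = protein_letters_3to1.get(
                        table.residue_name_of(p.residue_number).capitalize(), "X")
                except (TopologyError, KeyError):
                    name = "X"
            return f"{name}{p.residue_number}({p.moiety})"
        return f"{one(self.partner_a)}-{one(self.partner_b)}[{self.kind}]"


# ---------------------------------------------------------------------------
# candidate-pair tables (cached per atom table + topology)
# ---------------------------------------------------------------------------

@dataclass
class _PolarAtom:
    atom_idx: int
    residue: int
    group: str
    moiety: str
    charge: int
    hb_class: str             # "mcN" | "mcO" | "site"
    same_res_idx: np.ndarray  # indices of other atoms in the same residue


_HB_ALLOWED = {("mcN", "mcO"), ("mcO", "mcN"),
               ("site", "mcO"), ("mcO", "site"),
               ("site", "site")}


@dataclass
class _PairTables:
    hb_pairs: list[tuple[_PolarAtom, _PolarAtom]]
    salt_pairs: list[tuple[_PolarAtom, _PolarAtom]]
    stack_pairs: list[tuple[int, int, int, int, int, int]]  # site_a, cb_a, site_b, cb_b, res_a, res_b
    strand_of: dict[int, str]


def _strand_label(topo: StrandTopology, residue: int) -> str:
    if residue in topo.chromophore_residues:
        return "chromophore"
    return topo.strand_of.get(residue, "")


def _pair_eligible(topo: StrandTopology, res_a: int, res_b: int,
                   inter_strand: bool) -> bool:
    if res_a == res_b:
        return False
    if not inter_strand:
        return True
    if res_a in topo.chromophore_residues or res_b in topo.chromophore_residues:
        return True
    la, lb = topo.strand_of.get(res_a), topo.strand_of.get(res_b)
    return la is not None and lb is not None and la != lb


def _polar_atoms(table: AtomTable, topo: StrandTopology) -> list[_PolarAtom]:
    atoms: list[_PolarAtom] = []
    residue_atoms: dict[int, np.ndarray] = {
        int(r): np.flatnonzero(table.residue_numbers == r)
        for r in table.residue_numbers_unique()
    }
    for i in range(table.n_atoms):
        res = int(table.residue_numbers[i])
        name = str(table.atom_names[i])
        props = sidechain_props(str(table.residue_names[i]))
        is_chromo = res in topo.chromophore_residues
        entry = None
        if is_chromo:
            if table.elements[i] in ("N", "O"):
                entry = (name, "sc", 0, "site")
        elif name == "N":
            entry = (name, "mc", 0, "mcN")
        elif name == "O":
            entry = (name, "mc", 0, "mcO")
        elif name == SIDECHAIN_SITE and props.polar:
            entry = (name, "sc", props.charge, "site")
        if entry is None:
            continue
        others = residue_atoms[res][residue_atoms[res] != i]
        atoms.append(_PolarAtom(i, res, *entry, others))
    return atoms


def _build_pair_tables(table: AtomTable, topo: StrandTopology,
                       inter_strand: bool) -> _PairTables:
    polar = _polar_atoms(table, topo)
    hb, salt = [], []
    for ia in range(len(polar)):
        for ib in range(ia + 1, len(polar)):
            a, b = polar[ia], polar[ib]
            if not _pair_eligible(topo, a.residue, b.residue, inter_strand):
                continue
            if (a.hb_class, b.hb_class) in _HB_ALLOWED:
                hb.append((a, b))
            if a.charge * b.charge < 0:
                salt.append((a, b))

    # stacking candidates: aromatic sidechain sites with a CB axis
    stack = []
    sites: dict[int, tuple[int, int]] = {}
    for res in table.residue_numbers_unique():
        res = int(res)
        if res in topo.chromophore_residues:
            continue
        if not sidechain_props(table.residue_name_of(res)).aromatic:
            continue
        mask = table.residue_mask(res)
        site = np.flatnonzero(mask & (table.atom_names == SIDECHAIN_SITE))
        cb = np.flatnonzero(mask & (table.atom_names == "CB"))
        if len(site) and len(cb):
            sites[res] = (int(site[0]), int(cb[0]))
    residues = sorted(sites)
    for ia in range(len(residues)):
        for ib in range(ia + 1, len(residues)):
            ra, rb = residues[ia], residues[ib]
            if not _pair_eligible(topo, ra, rb, inter_strand):
                continue
            stack.append((*sites[ra], *sites[rb], ra, rb))
    return _PairTables(hb, salt, stack, dict(topo.strand_of))


def _pair_tables(table: AtomTable, topo: StrandTopology,
                 inter_strand: bool) -> _PairTables:
    cache = getattr(table, "_sg_pair_cache", None)
    if cache is None:
        cache = {}
        table._sg_pair_cache = cache
    key = (id(topo), inter_strand)
    if key not in cache:
        cache[key] = _build_pair_tables(table, topo, inter_strand)
    return cache[key]


# ---------------------------------------------------------------------------
# per-frame detection
# ---------------------------------------------------------------------------

def _proxy_angle_ok(coords: np.ndarray, atom: _PolarAtom, other_idx: int,
                    min_angle: float) -> bool:
    if len(atom.same_res_idx) == 0:
        return True
    x = coords[atom.atom_idx]
    d = np.linalg.norm(coords[atom.same_res_idx] - x, axis=1)
    ant = coords[atom.same_res_idx[int(np.argmin(d))]]
    v1 = coords[other_idx] - x
    v2 = ant - x
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return True
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang)) >= min_angle


def detect_interactions(frame: StructureFrame, topo: StrandTopology,
                        criteria: InteractionCriteria = InteractionCriteria(),
                        inter_strand: bool = True) -> frozenset[Interaction]:
    """Detect hydrogen bonds, salt bridges and stackings in one frame."""
    tables = _pair_tables(frame.table, topo, inter_strand)
    coords = frame.coords
    found: set[Interaction] = set()

    if tables.hb_pairs:
        xa = np.array([coords[a.atom_idx] for a, _ in tables.hb_pairs])
        xb = np.array([coords[b.atom_idx] for _, b in tables.hb_pairs])
        dist = np.linalg.norm(xa - xb, axis=1)
        for k in np.flatnonzero(dist <= criteria.hbond_da_max):
            a, b = tables.hb_pairs[int(k)]
            if not _proxy_angle_ok(coords, a, b.atom_idx, criteria.hbond_proxy_angle_min):
                continue
            if not _proxy_angle_ok(coords, b, a.atom_idx, criteria.hbond_proxy_angle_min):
                continue
            found.add(Interaction.make(
                "hbond",
                Partner(a.residue, a.group, a.moiety),
                Partner(b.residue, b.group, b.moiety),
                _strand_label(topo, a.residue), _strand_label(topo, b.residue)))

    if tables.salt_pairs:
        xa = np.array([coords[a.atom_idx] for a, _ in tables.salt_pairs])
        xb = np.array([coords[b.atom_idx] for _, b in tables.salt_pairs])
        dist = np.linalg.norm(xa - xb, axis=1)
        for k in np.flatnonzero(dist <= criteria.salt_bridge_max):
            a, b = tables.salt_pairs[int(k)]
            found.add(Interaction.make(
                "salt_bridge",
                Partner(a.residue, a.group, a.moiety),
                Partner(b.residue, b.group, b.moiety),
                _strand_label(topo, a.residue), _strand_label(topo, b.residue)))

    for site_a, cb_a, site_b, cb_b, res_a, res_b in tables.stack_pairs:
        d = np.linalg.norm(coords[site_a] - coords[site_b])
        if d > criteria.stacking_centroid_max:
            continue
        ax_a = coords[site_a] - coords[cb_a]
        ax_b = coords[site_b] - coords[cb_b]
        na, nb = np.linalg.norm(ax_a), np.linalg.norm(ax_b)
        if na < 1e-9 or nb < 1e-9:
            continue
        cosang = np.clip(abs(ax_a @ ax_b) / (na * nb), -1.0, 1.0)
        angle = np.degrees(np.arccos(cosang))  # folded to [0, 90]
        if angle <= criteria.stacking_plane_angle_max:
            found.add(Interaction.make(
                "stacking",
                Partner(res_a, SIDECHAIN_SITE, "sc"),
                Partner(res_b, SIDECHAIN_SITE, "sc"),
                _strand_label(topo, res_a), _strand_label(topo, res_b)))
    return frozenset(found)


# ---------------------------------------------------------------------------
# occupancy over trajectories
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """Per-interaction presence fractions with frame-range provenance."""

    fractions: dict[Interaction, float]
    n_frames: int
    frame_range: tuple[int, int]
    masks: dict[Interaction, np.ndarray] = field(default_factory=dict)

    def occupancy_of(self, interaction: Interaction) -> float:
        return self.fractions.get(interaction, 0.0)

    def interactions(self) -> list[Interaction]:
        return sorted(self.fractions, key=lambda i: (i.partner_a, i.partner_b, i.kind))

    def to_frame(self):
        import pandas as pd
        rows = [{"interaction": repr(i), "kind": i.kind,
                 "residue_a": i.partner_a.residue_number,
                 "moiety_a": i.partner_a.moiety,
                 "residue_b": i.partner_b.residue_number,
                 "moiety_b": i.partner_b.moiety,
                 "occupancy": f}
                for i, f in self.fractions.items()]
        return pd.DataFrame(rows)


def occupancy(traj: Trajectory, topo: StrandTopology,
              criteria: InteractionCriteria = InteractionCriteria(),
              frame_range: tuple[int, int] | None = None,
              inter_strand: bool = True) -> OccupancyTable:
    """Fraction of frames (within ``frame_range``) each interaction is present."""
    start, stop = frame_range if frame_range is not None else (0, traj.n_frames)
    if not (0 <= start < stop <= traj.n_frames):
        raise StrandgateError(f"empty or out-of-bounds frame range ({start}, {stop})")
    per_frame = [detect_interactions(traj.frame(i), topo, criteria, inter_strand)
                 for i in range(start, stop)]
    all_interactions = set().union(*per_frame) if per_frame else set()
    n = stop - start
    masks = {i: np.array([i in s for s in per_frame]) for i in all_interactions}
    fractions = {i: float(m.sum()) / n for i, m in masks.items()}
    return OccupancyTable(fractions, n, (start, stop), masks)


def find_alternating(table: OccupancyTable,
                     criteria: InteractionCriteria = InteractionCriteria(),
                     max_jaccard: float = 0.2) -> set[tuple[int, Interaction, Interaction]]:
    """Triples (shared residue, partner interaction 1, partner interaction 2)
    where a residue's sidechain alternates between two contacts: both have
    occupancy >= ``alternating_min_occupancy`` but rarely co-occur
    (per-frame Jaccard index <= ``max_jaccard``)."""
    items = [(i, m) for i, m in table.masks.items()
             if table.fractions[i] >= criteria.alternating_min_occupancy]
    out: set[tuple[int, Interaction, Interaction]] = set()
    for ia in range(len(items)):
        for ib in range(ia + 1, len(items)):
            (int_a, mask_a), (int_b, mask_b) = items[ia], items[ib]
            shared = [r for r in int_a.residues if int_b.involves(r, moiety="sc")
                      and int_a.involves(r, moiety="sc")]
            if not shared:
                continue
            union = np.logical_or(mask_a, mask_b).sum()
            inter = np.logical_and(mask_a, mask_b).sum()
            jaccard = inter / union if union else 1.0
            if jaccard <= max_jaccard:
                first, second = sorted(
                    (int_a, int_b), key=lambda i: (i.partner_a, i.partner_b, i.kind))
                for res in shared:
                    out.add((res, first, second))
    return out


@dataclass
class NetworkDiff:
    formed: frozenset[Interaction]
    broken: frozenset[Interaction]
    persistent: frozenset[Interaction]


def diff_networks(table_a: OccupancyTable, table_b: OccupancyTable,
                  threshold: float = 0.5) -> NetworkDiff:
    """Interactions broken (>= threshold in A only), formed (in B only) and
    persistent (>= threshold in both) between two states."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    universe = set(table_a.fractions) | set(table_b.fractions)
    broken, formed, persistent = set(), set(), set()
    for i in universe:
        in_a = table_a.occupancy_of(i) >= threshold
        in_b = table_b.occupancy_of(i) >= threshold
        if in_a and not in_b:
            broken.add(i)
        elif in_b and not in_a:
            formed.add(i)
        elif in_a and in_b:
            persistent.add(i)
    return NetworkDiff(frozenset(formed), frozenset(broken), frozenset(persistent))


# ---------------------------------------------------------------------------
# occupancy along the isomerization coordinate
# ---------------------------------------------------------------------------

@dataclass
class PathwayProfile:
    """Interaction occupancy as a function of the phi_I window center."""

    centers: np.ndarray                      # degrees, ascending
    interactions: list[Interaction]
    matrix: np.ndarray                       # (n_interactions, n_windows)
    break_points: dict[Interaction, float | None]

    def occupancy_of(self, interaction: Interaction) -> np.ndarray:
        return self.matrix[self.interactions.index(interaction)]

    @property
    def interior_centers(self) -> np.ndarray:
        """Window centers excluding the two endpoint windows."""
        return self.centers[1:-1]


def pathway_profile(window_trajs: Sequence[tuple[float, Trajectory]],
                    topo: StrandTopology,
                    criteria: InteractionCriteria = InteractionCriteria(),
                    threshold: float = 0.2) -> PathwayProfile:
    """Occupancy matrix over phi_I windows plus per-interaction break points
    (center of the last window, scanning cis->trans, with occupancy >=
    ``threshold``)."""
    if len(window_trajs) < 2:
        raise StrandgateError("need at least 2 windows")
    centers = np.array([c for c, _ in window_trajs], dtype=float)
    if not np.all(np.diff(centers) > 0):
        raise StrandgateError("window centers must be sorted ascending")
    residue_sets = {frozenset(t.table.residue_numbers_unique().tolist())
                    for _, t in window_trajs}
    if len(residue_sets) != 1:
        raise TopologyError("inconsistent topologies across windows")
    tables = [occupancy(traj, topo, criteria) for _, traj in window_trajs]
    interactions = sorted(set().union(*(t.fractions for t in tables)),
                          key=lambda i: (i.partner_a, i.partner_b, i.kind))
    matrix = np.array([[t.occupancy_of(i) for t in tables] for i in interactions])
    break_points: dict[Interaction, float | None] = {}
    for row, interaction in zip(matrix, interactions):
        above = np.flatnonzero(row >= threshold)
        break_points[interaction] = float(centers[above[-1]]) if len(above) else None
    return PathwayProfile(centers, interactions, matrix, break_points)
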
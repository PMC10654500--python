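"""Synthetic inputs with planted ground truth.

This module stands in for microsecond MD ensembles, umbrella-sampling
windows and wet-lab exchange traces.  It builds a three-strand antiparallel
fragment of a GFP-like barrel (strands "7", "10", "11" on an arc of a
cylinder, canonical GFP residue numbering, dissociating strand 10 flanked
by 7 and 11), with reduced residues: backbone N/CA/C/O plus CB and a single
sidechain interaction-site atom, and a pseudo-chromophore carrying the two
twisting dihedrals phi_P and phi_I.

Interactions are *planted*: atoms of a planted contact are positioned so the
contact satisfies the default geometric criteria exactly, while all
non-planted inter-strand pairs stay outside the cutoffs in noise-free
frames.  A :class:`PlantedDissociation` breaks planted anchors in a given
order, then drifts the dissociating strand away, so event-detection and
anchor-ordering code can be scored against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .chemistry import SIDECHAIN_SITE, sidechain_props
from .errors import FixtureError, StrandgateError
from .hbond_network import Interaction, Partner
from .periodic import periodic_delta, wrap_angle
from .structure_core import (AnnealingSchedule, AtomTable, StrandTopology,
                             Trajectory)

#: kcal/(mol K)
R_KCAL = 1.98720425864083e-3

# --- ideal-geometry constants (Angstrom / degrees) -------------------------
BARREL_RADIUS = 12.0
STRAND_ANGLE_SPACING = 25.0
CA_SPACING = 3.4
CB_OFFSET = 1.5
SITE_OFFSET = 3.0
N_OFFSET = -0.6     # along the chain direction from CA
C_OFFSET = 1.2
O_OFFSET = 2.0
# planted contact distances
BACKBONE_HBOND_DIST = 2.9
SC_HBOND_DIST = 2.85
SALT_BRIDGE_DIST = 3.75  # inside salt cutoff, outside the hbond cutoff
STACKING_DIST = 4.6
SCMC_O_ARM = 1.2         # carbonyl O displaced toward the donor site
CHROMOPHORE_RESIDUE = 66
ASN121_RESIDUE = 121


# ---------------------------------------------------------------------------
# planted-interaction descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneHBond:
    """Mainchain N(donor) to mainchain O(acceptor) hydrogen bond."""
    donor: int
    acceptor: int


@dataclass(frozen=True)
class SidechainContact:
    """Sidechain-sidechain contact; kind in {hbond, salt_bridge, stacking}."""
    res_a: int
    res_b: int
    kind: str


@dataclass(frozen=True)
class SidechainMainchain:
    """Sidechain site (donor) to a mainchain carbonyl O (acceptor)."""
    sc_res: int
    mc_res: int


@dataclass(frozen=True)
class ChromophoreContact:
    """Residue sidechain hydrogen-bonded to a chromophore polar atom."""
    res: int
    chromophore_atom: str = "OH"


@dataclass(frozen=True)
class AlternatingContact:
    """A sidechain alternating between two acceptor residues frame-by-frame."""
    shared: int
    partner_a: int
    partner_b: int
    period: int = 2  # partner_a on even multiples, partner_b otherwise


Planted = BackboneHBond | SidechainContact | SidechainMainchain | ChromophoreContact


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

def _default_residue_names() -> dict[int, str]:
    return {
        146: "ASN", 147: "SER", 148: "HIS", 149: "ASN", 151: "TYR",
        200: "TYR", 202: "SER", 203: "THR", 205: "THR", 209: "LYS",
        214: "LYS", 215: "ARG", 216: "ASP", 217: "HIS", 225: "ASN",
        ASN121_RESIDUE: "ASN",
    }


@dataclass
class BarrelFixtureSpec:
    """Blueprint for the three-strand barrel fragment.

    ``parity_in`` maps each strand label to the residue-number parity
    (0 even / 1 odd) whose sidechains face into the barrel; the default
    encodes odd-in for strand 10 with the neighbor strands phased so that
    contact partners across the sheet face the same way.
    """

    n_residues_per_strand: int = 13
    strand_labels: tuple[str, str, str] = ("7", "10", "11")
    dissociating_strand: str = "10"
    strand_starts: dict[str, int] = field(
        default_factory=lambda: {"7": 144, "10": 197, "11": 213})
    strand_z0: dict[str, float] = field(
        default_factory=lambda: {"7": 34.0, "10": 0.0, "11": 54.4})
    parity_in: dict[str, int] = field(
        default_factory=lambda: {"7": 0, "10": 1, "11": 0})
    residue_names: dict[int, str] = field(default_factory=_default_residue_names)
    planted: tuple[Planted, ...] = ()
    alternating: tuple[AlternatingContact, ...] = ()
    cleavage_site: tuple[int, int] = (209, 213)
    include_asn121: bool = True
    chromophore_phi_I: float = 0.0
    chromophore_phi_P: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dissociating_strand not in self.strand_labels:
            raise FixtureError("dissociating strand not among strand labels")
        present = set(self.all_residues())
        for entry in self.planted:
            for res in _planted_residues(entry):
                if res not in present:
                    raise FixtureError(
                        f"planted interaction {entry} references absent residue {res}")
        for alt in self.alternating:
            for res in (alt.shared, alt.partner_a, alt.partner_b):
                if res not in present:
                    raise FixtureError(f"alternation references absent residue {res}")

    # -- residue bookkeeping ------------------------------------------------

    def strand_residues(self, label: str) -> list[int]:
        start = self.strand_starts[label]
        return list(range(start, start + self.n_residues_per_strand))

    def all_residues(self) -> list[int]:
        out: list[int] = []
        for label in self.strand_labels:
            out.extend(self.strand_residues(label))
        out.append(CHROMOPHORE_RESIDUE)
        if self.include_asn121:
            out.append(ASN121_RESIDUE)
        return out

    def residue_name(self, res: int) -> str:
        if res == CHROMOPHORE_RESIDUE:
            return "CRO"
        return self.residue_names.get(res, "LEU")

    def strand_of_residue(self, res: int) -> str | None:
        for label in self.strand_labels:
            if res in self.strand_residues(label):
                return label
        return None

    def topology(self) -> StrandTopology:
        strand_of = {r: self.strand_of_residue(r) or "helix"
                     for r in self.all_residues()}
        cro = CHROMOPHORE_RESIDUE
        return StrandTopology(
            strand_of=strand_of,
            dissociating_strand=self.dissociating_strand,
            cleavage_site=self.cleavage_site,
            dihedral_specs={
                "phi_I": ((cro, "A1"), (cro, "A2"), (cro, "A3"), (cro, "A4")),
                "phi_P": ((cro, "A0"), (cro, "A1"), (cro, "A2"), (cro, "A3")),
            },
            chromophore_residues=frozenset({cro}),
            strand_labels=self.strand_labels,
        )


def _planted_residues(entry: Planted) -> tuple[int, ...]:
    if isinstance(entry, BackboneHBond):
        return (entry.donor, entry.acceptor)
    if isinstance(entry, SidechainContact):
        return (entry.res_a, entry.res_b)
    if isinstance(entry, SidechainMainchain):
        return (entry.sc_res, entry.mc_res)
    if isinstance(entry, ChromophoreContact):
        return (entry.res,)
    raise TypeError(f"not a planted interaction: {entry}")


def _involves_strand(entry: Planted, spec: BarrelFixtureSpec, label: str) -> bool:
    return any(spec.strand_of_residue(r) == label for r in _planted_residues(entry))


def expected_interaction(entry: Planted, spec: BarrelFixtureSpec) -> Interaction:
    """The canonical :class:`Interaction` the detector reports for a planted
    contact (the generator's ground-truth key for occupancy lookups)."""
    topo = spec.topology()

    def lab(res: int) -> str:
        if res in topo.chromophore_residues:
            return "chromophore"
        return topo.strand_of.get(res, "")

    if isinstance(entry, BackboneHBond):
        return Interaction.make("hbond",
                                Partner(entry.donor, "N", "mc"),
                                Partner(entry.acceptor, "O", "mc"),
                                lab(entry.donor), lab(entry.acceptor))
    if isinstance(entry, SidechainContact):
        return Interaction.make(entry.kind,
                                Partner(entry.res_a, SIDECHAIN_SITE, "sc"),
                                Partner(entry.res_b, SIDECHAIN_SITE, "sc"),
                                lab(entry.res_a), lab(entry.res_b))
    if isinstance(entry, SidechainMainchain):
        return Interaction.make("hbond",
                                Partner(entry.sc_res, SIDECHAIN_SITE, "sc"),
                                Partner(entry.mc_res, "O", "mc"),
                                lab(entry.sc_res), lab(entry.mc_res))
    if isinstance(entry, ChromophoreContact):
        return Interaction.make("hbond",
                                Partner(entry.res, SIDECHAIN_SITE, "sc"),
                                Partner(CHROMOPHORE_RESIDUE, entry.chromophore_atom, "sc"),
                                lab(entry.res), "chromophore")
    raise TypeError(f"not a planted interaction: {entry}")


# ---------------------------------------------------------------------------
# planted dissociation event
# ---------------------------------------------------------------------------

@dataclass
class PlantedDissociation:
    """Ordered anchor losses, a drift onset, and a terminal-solvation frame.

    ``anchor_losses`` lists (planted interaction, last frame present + 1);
    the strand starts drifting along ``drift_vector`` (Angstrom/frame) at
    ``onset_frame``; terminal residues are displaced from
    ``solvation_frame`` on to mimic solvation of the cleaved end.
    """

    anchor_losses: tuple[tuple[Planted, int], ...]
    onset_frame: int
    drift_vector: tuple[float, float, float] = (1.0, 0.0, 0.0)
    solvation_frame: int | None = None

    def __post_init__(self):
        frames = [f for _, f in self.anchor_losses]
        if sorted(frames) != frames:
            raise FixtureError("anchor losses must be ordered by loss frame")
        if any(f > self.onset_frame for f in frames):
            raise FixtureError("anchor losses must not come after the onset")
        if len(frames) > 1 and max(frames[:-1]) >= self.onset_frame:
            raise FixtureError(
                "onset must lie strictly after every anchor loss but the final one")

    @property
    def anchor_loss_order(self) -> tuple[Planted, ...]:
        return tuple(entry for entry, _ in self.anchor_losses)

    def validate_against(self, spec: BarrelFixtureSpec) -> None:
        planted = set(spec.planted)
        for entry, _ in self.anchor_losses:
            if entry not in planted:
                raise FixtureError(f"anchor {entry} is not planted in the fixture")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_MC_ATOMS = ("N", "CA", "C", "O")
_CHROMOPHORE_ATOMS = ("A0", "A1", "A2", "A3", "A4", "OH", "NX")


class _FixtureBuilder:
    """Computes ideal coordinates for one spec; one instance per trajectory."""

    def __init__(self, spec: BarrelFixtureSpec):
        self.spec = spec
        self.angles = self._strand_angles()
        self.atom_order = self._atom_order()
        self.index = {key: i for i, key in enumerate(self.atom_order)}
        self.base = self._base_coords()

    # -- layout -------------------------------------------------------------

    def _strand_angles(self) -> dict[str, float]:
        others = [s for s in self.spec.strand_labels if s != self.spec.dissociating_strand]
        return {others[0]: -STRAND_ANGLE_SPACING,
                self.spec.dissociating_strand: 0.0,
                others[1]: +STRAND_ANGLE_SPACING}

    def _atoms_of(self, res: int) -> tuple[str, ...]:
        if res == CHROMOPHORE_RESIDUE:
            return _CHROMOPHORE_ATOMS
        if not sidechain_props(self.spec.residue_name(res)).has_sidechain:
            return _MC_ATOMS
        return _MC_ATOMS + ("CB", SIDECHAIN_SITE)

    def _atom_order(self) -> list[tuple[int, str]]:
        return [(res, atom) for res in sorted(self.spec.all_residues())
                for atom in self._atoms_of(res)]

    def chain_dir(self, label: str) -> float:
        return 1.0 if label == self.spec.dissociating_strand else -1.0

    def residue_z(self, label: str, res: int) -> float:
        start = self.spec.strand_starts[label]
        return self.spec.strand_z0[label] + self.chain_dir(label) * CA_SPACING * (res - start)

    def radial(self, label: str) -> np.ndarray:
        theta = math.radians(self.angles[label])
        return np.array([math.cos(theta), math.sin(theta), 0.0])

    def faces_in(self, label: str, res: int) -> bool:
        return res % 2 == self.spec.parity_in[label]

    # -- base coordinates ----------------------------------------------------

    def _base_coords(self) -> dict[tuple[int, str], np.ndarray]:
        spec = self.spec
        coords: dict[tuple[int, str], np.ndarray] = {}
        z_hat = np.array([0.0, 0.0, 1.0])
        for label in spec.strand_labels:
            r_hat = self.radial(label)
            direction = self.chain_dir(label)
            for res in spec.strand_residues(label):
                ca = BARREL_RADIUS * r_hat + self.residue_z(label, res) * z_hat
                coords[(res, "CA")] = ca
                coords[(res, "N")] = ca + direction * N_OFFSET * z_hat
                coords[(res, "C")] = ca + direction * C_OFFSET * z_hat
                coords[(res, "O")] = ca + direction * O_OFFSET * z_hat
                if SIDECHAIN_SITE in self._atoms_of(res):
                    sign = -1.0 if self.faces_in(label, res) else 1.0
                    coords[(res, "CB")] = ca + sign * CB_OFFSET * r_hat
                    coords[(res, SIDECHAIN_SITE)] = ca + sign * SITE_OFFSET * r_hat
        coords.update(self._chromophore_coords())
        if spec.include_asn121:
            ca = np.array([-3.0, 2.2, 21.0])
            coords[(ASN121_RESIDUE, "CA")] = ca
            coords[(ASN121_RESIDUE, "N")] = ca - N_OFFSET * z_hat  # chain dir -1
            coords[(ASN121_RESIDUE, "C")] = ca - C_OFFSET * z_hat
            coords[(ASN121_RESIDUE, "O")] = ca - O_OFFSET * z_hat
            away = np.array([-1.0, 0.0, 0.0])
            coords[(ASN121_RESIDUE, "CB")] = ca + CB_OFFSET * away
            coords[(ASN121_RESIDUE, SIDECHAIN_SITE)] = ca + SITE_OFFSET * away
        return coords

    def _chromophore_coords(self) -> dict[tuple[int, str], np.ndarray]:
        spec = self.spec
        a1 = np.array([0.0, -0.4, 19.5])
        a2 = np.array([1.5, -0.4, 19.5])
        a3 = a2 + 1.5 * np.array([math.cos(math.radians(-30.0)),
                                  math.sin(math.radians(-30.0)), 0.0])
        a0 = _place_atom(a3, a2, a1, 1.5, 120.0, spec.chromophore_phi_P)
        a4 = _place_atom(a1, a2, a3, 1.5, 120.0, spec.chromophore_phi_I)
        # hydrogen-bond anchors: the phenolate-like O extends toward the
        # dissociating strand, the imidazolinone-like N sideways; both stay
        # clear of default sidechain sites at every rotation angle
        oh = a4 + np.array([1.4, 0.0, 0.0])
        nx = a1 + np.array([0.0, 1.4, 0.0])
        cro = CHROMOPHORE_RESIDUE
        return {(cro, "A0"): a0, (cro, "A1"): a1, (cro, "A2"): a2,
                (cro, "A3"): a3, (cro, "A4"): a4, (cro, "OH"): oh, (cro, "NX"): nx}

    # -- constraint solving ---------------------------------------------------

    def _solve(self, coords: dict[tuple[int, str], np.ndarray],
               active: Sequence[Planted]) -> None:
        placed: set[tuple[int, str]] = set()

        def put(key: tuple[int, str], pos: np.ndarray) -> None:
            if key in placed:
                raise FixtureError(f"conflicting planted constraints on atom {key}")
            placed.add(key)
            coords[key] = pos

        for entry in active:
            if isinstance(entry, BackboneHBond):
                # keep each atom's own z-offset; close the gap laterally so a
                # residue's planted N and O stay distinct when both directions
                # of a registry pair are planted
                n_pos = coords[(entry.donor, "N")]
                o_pos = coords[(entry.acceptor, "O")]
                dz = o_pos[2] - n_pos[2]
                lat_target_sq = BACKBONE_HBOND_DIST ** 2 - dz ** 2
                if lat_target_sq <= 0:
                    raise FixtureError(
                        f"z offsets too large for backbone bond {entry}")
                gap_vec = o_pos - n_pos
                gap_vec[2] = 0.0
                lat_gap = np.linalg.norm(gap_vec)
                lat_target = math.sqrt(lat_target_sq)
                if lat_gap <= lat_target:
                    raise FixtureError(f"residues too close for backbone bond {entry}")
                u = gap_vec / lat_gap
                arm = (lat_gap - lat_target) / 2.0
                put((entry.donor, "N"), n_pos + arm * u)
                put((entry.acceptor, "O"), o_pos - arm * u)
            elif isinstance(entry, SidechainMainchain):
                cb = coords[(entry.sc_res, "CB")]
                c = coords[(entry.mc_res, "C")]
                u = cb - c
                u /= np.linalg.norm(u)
                put((entry.mc_res, "O"), c + SCMC_O_ARM * u)
                key = (entry.sc_res, SIDECHAIN_SITE)
                if key not in placed:
                    put(key, c + (SCMC_O_ARM + SC_HBOND_DIST) * u)
            elif isinstance(entry, ChromophoreContact):
                anchor = coords[(CHROMOPHORE_RESIDUE, entry.chromophore_atom)]
                cb = coords[(entry.res, "CB")]
                # blend the approach direction away from the chromophore
                # atom's nearest neighbor so the proxy angle at the anchor
                # stays obtuse
                others = [coords[(CHROMOPHORE_RESIDUE, a)]
                          for a in _CHROMOPHORE_ATOMS if a != entry.chromophore_atom]
                ant = min(others, key=lambda p: np.linalg.norm(p - anchor))
                to_cb = cb - anchor
                to_cb /= np.linalg.norm(to_cb)
                ant_dir = ant - anchor
                ant_dir /= np.linalg.norm(ant_dir)
                if to_cb @ ant_dir <= -0.05:
                    u = to_cb  # straight at the residue keeps both ends obtuse
                else:
                    away = anchor - ant
                    away /= np.linalg.norm(away)
                    u = to_cb + away
                    u /= np.linalg.norm(u)
                put((entry.res, SIDECHAIN_SITE), anchor + SC_HBOND_DIST * u)
            elif isinstance(entry, SidechainContact):
                dist = {"hbond": SC_HBOND_DIST, "salt_bridge": SALT_BRIDGE_DIST,
                        "stacking": STACKING_DIST}[entry.kind]
                key_a = (entry.res_a, SIDECHAIN_SITE)
                key_b = (entry.res_b, SIDECHAIN_SITE)
                if key_a in placed and key_b in placed:
                    raise FixtureError(f"both sites already placed for {entry}")
                if key_a in placed or key_b in placed:
                    fixed, free = (key_a, key_b) if key_a in placed else (key_b, key_a)
                    cb_free = coords[(free[0], "CB")]
                    u = cb_free - coords[fixed]
                    norm = np.linalg.norm(u)
                    if norm <= dist:
                        raise FixtureError(f"no room to place partner site for {entry}")
                    put(free, coords[fixed] + dist * (u / norm))
                else:
                    cb_a, cb_b = coords[(entry.res_a, "CB")], coords[(entry.res_b, "CB")]
                    gap = np.linalg.norm(cb_b - cb_a)
                    if gap <= dist:
                        raise FixtureError(f"residues too close for contact {entry}")
                    u = (cb_b - cb_a) / gap
                    arm = (gap - dist) / 2.0
                    put(key_a, cb_a + arm * u)
                    put(key_b, cb_b - arm * u)
            else:
                raise TypeError(f"not a planted interaction: {entry}")

    # -- frame assembly -------------------------------------------------------

    def frame_coords(self, frame_index: int,
                     event: PlantedDissociation | None) -> np.ndarray:
        spec = self.spec
        coords = {k: v.copy() for k, v in self.base.items()}
        diss = spec.dissociating_strand
        post_onset = event is not None and frame_index >= event.onset_frame

        if (event is not None and event.solvation_frame is not None
                and frame_index >= event.solvation_frame):
            cleave_res = next((r for r in spec.cleavage_site
                               if spec.strand_of_residue(r) == diss), None)
            if cleave_res is not None:
                disp = 3.0 * self.radial(diss) + np.array([0.0, 0.0, 1.5])
                for res in spec.strand_residues(diss):
                    if abs(res - cleave_res) < 3:
                        for atom in self._atoms_of(res):
                            coords[(res, atom)] = coords[(res, atom)] + disp

        lost = set()
        if event is not None:
            lost = {entry for entry, loss in event.anchor_losses
                    if frame_index >= loss}
        active: list[Planted] = []
        for entry in spec.planted:
            if entry in lost:
                continue
            if post_onset and _involves_strand(entry, spec, diss):
                continue
            active.append(entry)
        if not post_onset:
            for alt in spec.alternating:
                partner = (alt.partner_a
                           if (frame_index // 1) % (2 * alt.period) < alt.period
                           else alt.partner_b)
                active.append(SidechainContact(alt.shared, partner, "hbond"))
        self._solve(coords, active)

        if post_onset:
            shift = (frame_index - event.onset_frame + 1) * np.asarray(
                event.drift_vector, dtype=float)
            for res in spec.strand_residues(diss):
                for atom in self._atoms_of(res):
                    coords[(res, atom)] = coords[(res, atom)] + shift

        return np.array([coords[key] for key in self.atom_order])

    def atom_table(self) -> AtomTable:
        spec = self.spec
        names, elements, res_nums, res_names, chains = [], [], [], [], []
        for res, atom in self.atom_order:
            names.append(atom)
            if atom.startswith("A") and res == CHROMOPHORE_RESIDUE:
                elements.append("C")
            elif atom == "OH":
                elements.append("O")
            elif atom in ("N", "NX"):
                elements.append("N")
            elif atom == "O":
                elements.append("O")
            else:
                elements.append("C")
            res_nums.append(res)
            res_names.append(spec.residue_name(res))
            chains.append("A")
        return AtomTable(names, elements, res_nums, res_names, chains)


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def generate_barrel_trajectory(spec: BarrelFixtureSpec, n_frames: int,
                               thermal_noise: float = 0.0,
                               event: PlantedDissociation | None = None,
                               schedule: AnnealingSchedule | None = None,
                               ) -> tuple[Trajectory, StrandTopology]:
    """Build an ideal-geometry trajectory with planted interactions.

    Noise-free frames satisfy every planted contact exactly; with an event,
    anchors break in the planted order and the dissociating strand drifts
    away after the onset.  Identical spec + seed give identical output.
    """
    if n_frames < 1:
        raise StrandgateError("n_frames must be >= 1")
    if thermal_noise < 0:
        raise StrandgateError("thermal_noise must be >= 0")
    if event is not None:
        event.validate_against(spec)
    builder = _FixtureBuilder(spec)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for i in range(n_frames):
        xyz = builder.frame_coords(i, event)
        if thermal_noise > 0:
            xyz = xyz + rng.normal(0.0, thermal_noise, xyz.shape)
        else:
            rng.normal(0.0, 1.0, xyz.shape)  # keep the stream aligned
        frames.append(xyz)
    table = builder.atom_table()
    traj = Trajectory(table, np.stack(frames), schedule)
    return traj, spec.topology()


# ---------------------------------------------------------------------------
# preset fixtures encoding the reported interaction networks
# ---------------------------------------------------------------------------

def fig3_cis_spec(seed: int = 0) -> BarrelFixtureSpec:
    """Cis-complex network: mainchain registry, Tyr200-Tyr151 stacking,
    Ser202 alternating with Asn149/Asn225, the Lys209-Asp216 salt-bridge
    anchor, and chromophore contacts of Thr203, Thr205 and His148.  The
    Lys209 anchoring is carried by the salt bridge in this reduced fixture."""
    planted = (
        # mainchain registry, strand 10 <-> 11
        BackboneHBond(205, 221), BackboneHBond(221, 205),
        BackboneHBond(207, 219), BackboneHBond(219, 207),
        # mainchain registry, strand 10 <-> 7 (sparser)
        BackboneHBond(200, 151), BackboneHBond(151, 200),
        BackboneHBond(148, 203),
        # Lys209 anchor
        SidechainContact(209, 216, "salt_bridge"),
        # Tyr200 stacking
        SidechainContact(200, 151, "stacking"),
        # chromophore contacts
        ChromophoreContact(203, "OH"),
        ChromophoreContact(205, "OH"),
        ChromophoreContact(148, "NX"),
    )
    alternating = (AlternatingContact(202, 149, 225),)
    return BarrelFixtureSpec(planted=planted, alternating=alternating,
                             chromophore_phi_I=0.0, seed=seed)


def fig3_trans_spec(seed: int = 0) -> BarrelFixtureSpec:
    """Trans complex after heating: strand-10 sidechain interactions reduced
    to only Tyr200 and Ser202; chromophore rotated to trans."""
    planted = (
        BackboneHBond(205, 221), BackboneHBond(221, 205),
        BackboneHBond(207, 219), BackboneHBond(219, 207),
        BackboneHBond(200, 151), BackboneHBond(151, 200),
        SidechainContact(200, 151, "stacking"),
    )
    alternating = (AlternatingContact(202, 149, 225),)
    return BarrelFixtureSpec(planted=planted, alternating=alternating,
                             chromophore_phi_I=180.0, seed=seed)


def annealing_trans_spec(seed: int = 0) -> BarrelFixtureSpec:
    """Trans complex entering simulated annealing: the Fig. 3c network plus
    the near-cleavage anchors (Lys214, Arg215, His217 sidechains onto the
    strand-10 mainchain, and the Lys209 salt bridge) that break during
    heating.  The (219,207) backbone bond is dropped so Arg215 can anchor
    onto the Thr...207 carbonyl."""
    planted = (
        BackboneHBond(205, 221), BackboneHBond(221, 205),
        BackboneHBond(207, 219),
        BackboneHBond(200, 151), BackboneHBond(151, 200),
        SidechainContact(200, 151, "stacking"),
        SidechainMainchain(214, 209),
        SidechainMainchain(215, 207),
        SidechainMainchain(217, 206),
        SidechainContact(209, 216, "salt_bridge"),
    )
    alternating = (AlternatingContact(202, 149, 225),)
    return BarrelFixtureSpec(planted=planted, alternating=alternating,
                             chromophore_phi_I=180.0, seed=seed)


def default_dissociation_event(onset_frame: int = 48,
                               solvation_frame: int | None = 36,
                               drift: float = 1.0) -> PlantedDissociation:
    """The default planted event over :func:`annealing_trans_spec`: the
    strand-11 sidechains near the cleavage site separate first, the Lys209
    anchor last, then the strand drifts radially outward."""
    return PlantedDissociation(
        anchor_losses=(
            (SidechainMainchain(214, 209), 10),
            (SidechainMainchain(215, 207), 18),
            (SidechainMainchain(217, 206), 26),
            (SidechainContact(209, 216, "salt_bridge"), 44),
        ),
        onset_frame=onset_frame,
        drift_vector=(drift, 0.0, 0.0),
        solvation_frame=solvation_frame,
    )


def default_annealing_schedule(n_frames: int = 100) -> AnnealingSchedule:
    """Three-stage temperature ramp ending at 600 K."""
    a, b = min(20, n_frames), min(40, n_frames)
    segments = [(0, a, 300.0)]
    if b > a:
        segments.append((a, b, 450.0))
    if n_frames > b:
        segments.append((b, n_frames, 600.0))
    return AnnealingSchedule(tuple(segments))


# ---------------------------------------------------------------------------
# isomerization-pathway windows
# ---------------------------------------------------------------------------

def default_contact_schedule(center_deg: float) -> tuple[ChromophoreContact, ...]:
    """Which chromophore contacts exist at a given phi_I window center:
    Thr203 only in the cis endpoint, Thr205/His148 until the chromophore has
    rotated ~45 degrees, Asn121 briefly mid-path."""
    out: list[ChromophoreContact] = []
    if center_deg <= 5.0:
        out.append(ChromophoreContact(203, "OH"))
    if center_deg <= 45.0:
        out.append(ChromophoreContact(205, "OH"))
        out.append(ChromophoreContact(148, "NX"))
    if 55.0 <= center_deg <= 125.0:
        out.append(ChromophoreContact(ASN121_RESIDUE, "NX"))
    return tuple(out)


def generate_isomerization_windows(
    centers: Sequence[float],
    n_frames: int = 6,
    thermal_noise: float = 0.0,
    contact_schedule: Callable[[float], tuple[ChromophoreContact, ...]]
        = default_contact_schedule,
    seed: int = 0,
) -> list[tuple[float, Trajectory]]:
    """Umbrella-window trajectories along phi_I with scheduled chromophore
    contacts, for pathway-occupancy analysis."""
    base = fig3_cis_spec(seed)
    keep = tuple(e for e in base.planted if not isinstance(e, ChromophoreContact))
    windows = []
    for w, center in enumerate(centers):
        spec = replace(base, planted=keep + tuple(contact_schedule(center)),
                       chromophore_phi_I=float(center), seed=seed + 1000 + w)
        traj, _ = generate_barrel_trajectory(spec, n_frames, thermal_noise)
        windows.append((float(center), traj))
    return windows


# ---------------------------------------------------------------------------
# umbrella sampling (exact inverse-CDF draws from the biased density)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """Periodic potential V(phi) in kcal/mol on (-180, 180], plus temperature.

    ``cosine_terms`` is a tuple of (amplitude, multiplicity, phase_deg):
    V = sum_i A_i * (1 - cos(n_i * (phi - phase_i))) / 2, which is periodic
    by construction.  ``sin_squared(h)`` gives h * sin^2(phi).
    """

    cosine_terms: tuple[tuple[float, int, float], ...]
    temperature: float = 300.0

    def __call__(self, phi_deg) -> np.ndarray:
        phi = np.radians(np.asarray(phi_deg, dtype=float))
        v = np.zeros_like(phi)
        for amp, mult, phase in self.cosine_terms:
            v = v + amp * (1.0 - np.cos(mult * (phi - math.radians(phase)))) / 2.0
        return v

    @property
    def kT(self) -> float:
        return R_KCAL * self.temperature

    @classmethod
    def zero(cls, temperature: float = 300.0) -> "PotentialSpec":
        return cls(cosine_terms=(), temperature=temperature)

    @classmethod
    def sin_squared(cls, height: float, temperature: float = 300.0) -> "PotentialSpec":
        # h sin^2(phi) = h (1 - cos(2 phi)) / 2
        return cls(cosine_terms=((height, 2, 0.0),), temperature=temperature)


#: default umbrella force constant, kcal/(mol deg^2); bias sd ~ sqrt(kT/k)
#: ~ 5.5 deg at 300 K, about half the default 10-degree window spacing
DEFAULT_K_BIAS = 0.02


def generate_umbrella_samples(potential: PotentialSpec,
                              centers: Sequence[float],
                              k_bias: float = DEFAULT_K_BIAS,
                              n_per_window: int = 5000,
                              seed: int = 0):
    """Exact i.i.d. draws from exp(-[V + (k/2) dphi^2] / kT) per window,
    via inverse-CDF sampling on a 0.1-degree grid (dphi = minimal periodic
    image).  Returns a list of :class:`~strandgate.umbrella_pmf.UmbrellaWindow`."""
    from .umbrella_pmf import UmbrellaWindow

    if len(centers) == 0:
        raise StrandgateError("need at least one umbrella window")
    if k_bias <= 0:
        raise StrandgateError("k_bias must be positive")
    if n_per_window < 100:
        raise StrandgateError("n_per_window must be >= 100")
    grid_step = 0.1
    edges = np.arange(-180.0, 180.0 + grid_step / 2, grid_step)
    mid = (edges[:-1] + edges[1:]) / 2.0
    v_grid = potential(mid)
    windows = []
    for w, center in enumerate(centers):
        bias = 0.5 * k_bias * periodic_delta(mid, center) ** 2
        energy = v_grid + bias
        logp = -(energy - energy.min()) / potential.kT
        p = np.exp(logp)
        p /= p.sum()
        cdf = np.cumsum(p)
        rng = np.random.default_rng([seed, w])
        u = rng.random(n_per_window)
        idx = np.searchsorted(cdf, u, side="left")
        lo = np.where(idx > 0, cdf[idx - 1], 0.0)
        frac = (u - lo) / np.maximum(cdf[idx] - lo, 1e-300)
        samples = edges[idx] + frac * grid_step
        windows.append(UmbrellaWindow(center=float(center), k_bias=float(k_bias),
                                      samples=wrap_angle(samples),
                                      temperature=potential.temperature))
    return windows


# ---------------------------------------------------------------------------
# exchange traces
# ---------------------------------------------------------------------------

def generate_exchange_trace(k: float, amplitude: float, offset: float,
                            times: Sequence[float], noise_sd: float = 0.0,
                            seed: int = 0, light_on: bool = True,
                            variant: str = "", power_mw: float = 26.0):
    """Pseudo-first-order trace: offset + amplitude (1 - e^{-k t}) + noise."""
    from .kinetics import ExchangeTrace

    t = np.asarray(times, dtype=float)
    if k < 0:
        raise StrandgateError("rate must be >= 0")
    if t.ndim != 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise StrandgateError("times must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    signal = offset + amplitude * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, t.shape)
    return ExchangeTrace(times=t, signal=signal, light_on=light_on,
                         variant=variant, power_mw=power_mw)


# ---------------------------------------------------------------------------
# CSV writers (external interfaces)
# ---------------------------------------------------------------------------

def write_umbrella_csv(windows, directory) -> list[str]:
    """One CSV per window: columns window_center_deg, k_bias, phi_deg."""
    import pandas as pd
    from pathlib import Path

    paths = []
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(windows):
        df = pd.DataFrame({
            "window_center_deg": np.full(len(w.samples), w.center),
            "k_bias": np.full(len(w.samples), w.k_bias),
            "phi_deg": w.samples,
        })
        path = directory / f"window_{i:03d}.csv"
        df.to_csv(path, index=False)
        paths.append(str(path))
    return paths


def write_trace_csv(trace, path) -> None:
    import pandas as pd

    pd.DataFrame({"t_min": trace.times, "signal": trace.signal,
                  "light_on": np.full(len(trace.times), trace.light_on)}
                 ).to_csv(path, index=False)
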
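"""Disorder and dissociation analysis of temperature-ramped trajectories.

Dissociation is operationalised through the fraction of native inter-strand
contacts Q: a residue pair (across strands) is a native contact when its
minimum heavy-atom distance in the reference frame is below ``cutoff``; it
is retained in a later frame while that distance stays below
``retention_factor * cutoff``.  An event onset is the first frame where Q
stays below ``q_threshold`` for ``persistence`` consecutive frames.

Anchor losses are ordered by the end of each sidechain interaction's last
presence run, after closing gaps shorter than ``smoothing`` frames (a
broken anchor stays broken; a thermal flicker does not)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import StrandgateError
from .hbond_network import (Interaction, InteractionCriteria, detect_interactions)
from .structure_core import (StructureFrame, StrandTopology, Trajectory,
                             relative_sasa)

__all__ = [
    "NativeContactSet",
    "DissociationEvent",
    "native_contact_fraction",
    "detect_dissociation",
    "anchor_loss_order",
    "terminal_solvation",
    "register_shift_scan",
]


@dataclass
class NativeContactSet:
    reference_frame: int
    contacts: list[tuple[int, int]]       # residue pairs across strands
    q: np.ndarray                          # per-frame fraction retained


@dataclass
class DissociationEvent:
    onset_frame: int
    onset_temperature: float | None
    anchor_losses: list[tuple[Interaction, int]]
    terminal_solvation_frame: int | None = None


def _strand_residue_atoms(traj: Trajectory, topo: StrandTopology):
    """Residue -> atom index array, for residues on the three strands."""
    table = traj.table
    residues = sorted(r for r, s in topo.strand_of.items()
                      if s in topo.strand_labels)
    return {r: np.flatnonzero(table.residue_numbers == r) for r in residues}


def _min_distances(coords: np.ndarray, pairs, atom_idx) -> np.ndarray:
    dmat = cdist(coords, coords)
    return np.array([dmat[np.ix_(atom_idx[a], atom_idx[b])].min()
                     for a, b in pairs])


def native_contact_fraction(traj: Trajectory, reference: StructureFrame,
                            topo: StrandTopology, cutoff: float = 5.5,
                            retention_factor: float = 1.2) -> NativeContactSet:
    """Per-frame fraction of reference inter-strand residue contacts retained."""
    atom_idx = _strand_residue_atoms(traj, topo)
    residues = sorted(atom_idx)
    all_pairs = [(a, b) for i, a in enumerate(residues) for b in residues[i + 1:]
                 if topo.strand_of[a] != topo.strand_of[b]]
    ref_dist = _min_distances(reference.coords, all_pairs, atom_idx)
    contacts = [p for p, d in zip(all_pairs, ref_dist) if d <= cutoff]
    diss = set(topo.residues_of(topo.dissociating_strand))
    if not any(a in diss or b in diss for a, b in contacts):
        raise StrandgateError("no native contacts involve the dissociating strand")
    retain = retention_factor * cutoff
    q = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        d = _min_distances(traj.coords[i], contacts, atom_idx)
        q[i] = float((d <= retain).mean())
    return NativeContactSet(reference.frame_index, contacts, q)


def _first_sustained(mask: np.ndarray, persistence: int) -> int | None:
    """First index of a run of >= persistence consecutive True values."""
    run = 0
    for i, flag in enumerate(mask):
        run = run + 1 if flag else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def detect_dissociation(traj: Trajectory, topo: StrandTopology,
                        q_threshold: float = 0.2, persistence: int = 10,
                        cutoff: float = 5.5, retention_factor: float = 1.2,
                        criteria: InteractionCriteria | None = None,
                        smoothing: int = 5) -> DissociationEvent | None:
    """Q-based event detection; ``None`` when the complex stays intact.

    When ``criteria`` is given, the returned event also carries the ordered
    anchor-loss table from :func:`anchor_loss_order` (terminal solvation is
    computed separately; it needs per-frame SASA)."""
    reference = traj.frame(0)
    q = native_contact_fraction(traj, reference, topo, cutoff, retention_factor).q
    onset = _first_sustained(q < q_threshold, persistence)
    if onset is None:
        return None
    temperature = (traj.schedule.temperature_at(onset)
                   if traj.schedule is not None else None)
    anchors: list[tuple[Interaction, int]] = []
    if criteria is not None:
        anchors = [(i, f) for i, f in
                   anchor_loss_order(traj, topo, criteria, smoothing)
                   if f <= onset]
    return DissociationEvent(onset, temperature, anchors)


def _close_gaps(mask: np.ndarray, smoothing: int) -> np.ndarray:
    """Fill False gaps shorter than ``smoothing`` between True runs."""
    out = mask.copy()
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        return out
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a < smoothing + 1:
            out[a:b] = True
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop_exclusive) of True runs."""
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def anchor_loss_order(traj: Trajectory, topo: StrandTopology,
                      criteria: InteractionCriteria = InteractionCriteria(),
                      smoothing: int = 5) -> list[tuple[Interaction, int]]:
    """(interaction, last_present_frame) for every inter-strand sidechain
    interaction of the dissociating strand present at the start, sorted by
    loss time (ties by residue number, then kind)."""
    presence: dict[Interaction, np.ndarray] = {}
    per_frame = [detect_interactions(traj.frame(i), topo, criteria)
                 for i in range(traj.n_frames)]
    diss_residues = set(topo.residues_of(topo.dissociating_strand))
    universe = set().union(*per_frame)
    for interaction in universe:
        if interaction.kind == "hbond" and \
                interaction.partner_a.moiety == "mc" and interaction.partner_b.moiety == "mc":
            continue  # mainchain-mainchain: not a sidechain anchor
        if not any(r in diss_residues for r in interaction.residues):
            continue
        presence[interaction] = np.array([interaction in s for s in per_frame])

    results = []
    for interaction, mask in presence.items():
        if not mask[:max(smoothing, 1)].any():
            continue  # not present within the first smoothing window
        closed = _close_gaps(mask, smoothing)
        runs = [(a, b) for a, b in _runs(closed) if b - a >= smoothing]
        if not runs:
            continue
        results.append((interaction, int(runs[-1][1] - 1)))
    results.sort(key=lambda item: (item[1], min(item[0].residues), item[0].kind))
    return results


def terminal_solvation(traj: Trajectory, topo: StrandTopology,
                       terminal_residues: int = 3, sasa_threshold: float = 0.5,
                       persistence: int = 5, probe_radius: float = 1.4,
                       point_number: int = 240) -> int | None:
    """First frame from which the mean relative SASA of the cleaved-end
    residues of the dissociating strand stays above ``sasa_threshold``."""
    diss = topo.residues_of(topo.dissociating_strand)
    cleave_res = next((r for r in topo.cleavage_site
                       if topo.strand_of.get(r) == topo.dissociating_strand), None)
    if cleave_res is None:
        raise StrandgateError("cleavage site does not touch the dissociating strand")
    terminal = sorted(diss, key=lambda r: abs(r - cleave_res))[:terminal_residues]
    series = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rel = relative_sasa(traj.frame(i), probe_radius, point_number,
                            residues=terminal)
        series[i] = float(np.mean([rel[r] for r in terminal]))
    return _first_sustained(series > sasa_threshold, persistence)


def register_shift_scan(traj: Trajectory, topo: StrandTopology,
                        cutoff: float = 5.5, max_shift: int = 4
                        ) -> dict[str, np.ndarray]:
    """Per-frame integer register offset of the dissociating strand against
    each neighbor strand: the shift (in residues, positive toward increasing
    neighbor numbering) that maximises the number of paired CA atoms within
    ``cutoff``.  The zero shift is defined by the frame-0 pairing."""
    table = traj.table
    diss = topo.residues_of(topo.dissociating_strand)
    if len(diss) < 4:
        raise StrandgateError("dissociating strand too short for a register scan")

    def ca_idx(residues):
        return [table.atom_index(r, "CA") for r in residues]

    out: dict[str, np.ndarray] = {}
    diss_ca = ca_idx(diss)
    for label in topo.neighbor_strands:
        neigh = topo.residues_of(label)
        if len(neigh) < 4:
            raise StrandgateError(f"strand {label} too short for a register scan")
        neigh_ca = ca_idx(neigh)
        ref = traj.coords[0]
        # frame-0 registry: nearest neighbor CA per dissociating residue
        d0 = cdist(ref[diss_ca], ref[neigh_ca])
        base = d0.argmin(axis=1)
        offsets = np.empty(traj.n_frames, dtype=int)
        for f in range(traj.n_frames):
            d = cdist(traj.coords[f][diss_ca], traj.coords[f][neigh_ca])
            best_count, best_shift = -1, 0
            for shift in range(-max_shift, max_shift + 1):
                j = base + shift
                valid = (j >= 0) & (j < len(neigh))
                count = int((d[np.arange(len(diss))[valid], j[valid]] <= cutoff).sum())
                if count > best_count or (count == best_count and abs(shift) < abs(best_shift)):
                    best_count, best_shift = count, shift
            offsets[f] = best_shift
        out[label] = offsets
    return out
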
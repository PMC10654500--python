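"""Interaction detection against a brute-force oracle, occupancy, diffs."""

import itertools

import numpy as np
import pytest

from strandgate import synthetic_data as sd
from strandgate.chemistry import SIDECHAIN_SITE, sidechain_props
from strandgate.errors import StrandgateError, TopologyError
from strandgate.hbond_network import (Interaction, InteractionCriteria,
                                      Partner, detect_interactions,
                                      diff_networks, find_alternating,
                                      occupancy, pathway_profile)
from strandgate.structure_core import AtomTable, StructureFrame, StrandTopology, Trajectory


# ---------------------------------------------------------------------------
# brute-force oracle: plain loops, no shared code with the implementation
# ---------------------------------------------------------------------------

def _angle(p, x, a):
    v1, v2 = p - x, a - x
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return 180.0
    return float(np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1, 1))))


def oracle_detect(frame, topo, crit):
    table, xyz = frame.table, frame.coords
    n = table.n_atoms

    def residue_atoms(res):
        return [i for i in range(n) if table.residue_numbers[i] == res]

    def antecedent(i):
        others = [j for j in residue_atoms(int(table.residue_numbers[i])) if j != i]
        if not others:
            return None
        return min(others, key=lambda j: np.linalg.norm(xyz[j] - xyz[i]))

    def strand(res):
        if res in topo.chromophore_residues:
            return "chromophore"
        return topo.strand_of.get(res)

    def eligible(ra, rb):
        if ra == rb:
            return False
        if ra in topo.chromophore_residues or rb in topo.chromophore_residues:
            return True
        sa, sb = topo.strand_of.get(ra), topo.strand_of.get(rb)
        return sa is not None and sb is not None and sa != sb

    polar = []  # (atom index, residue, group, moiety, charge, class)
    for i in range(n):
        res = int(table.residue_numbers[i])
        name = str(table.atom_names[i])
        props = sidechain_props(str(table.residue_names[i]))
        if res in topo.chromophore_residues:
            if table.elements[i] in ("N", "O"):
                polar.append((i, res, name, "sc", 0, "site"))
        elif name == "N":
            polar.append((i, res, name, "mc", 0, "mcN"))
        elif name == "O":
            polar.append((i, res, name, "mc", 0, "mcO"))
        elif name == SIDECHAIN_SITE and props.polar:
            polar.append((i, res, name, "sc", props.charge, "site"))

    found = set()
    for (ia, ra, ga, ma, ca, cla), (ib, rb, gb, mb, cb, clb) in \
            itertools.combinations(polar, 2):
        if not eligible(ra, rb):
            continue
        d = float(np.linalg.norm(xyz[ia] - xyz[ib]))
        allowed = {frozenset(("mcN", "mcO")), frozenset(("site", "mcO")),
                   frozenset(("site",))}
        if frozenset((cla, clb)) in allowed and d <= crit.hbond_da_max:
            ok = True
            for i, j in ((ia, ib), (ib, ia)):
                ant = antecedent(i)
                if ant is not None and \
                        _angle(xyz[j], xyz[i], xyz[ant]) < crit.hbond_proxy_angle_min:
                    ok = False
            if ok:
                found.add(Interaction.make("hbond", Partner(ra, ga, ma),
                                           Partner(rb, gb, mb),
                                           strand(ra) or "", strand(rb) or ""))
        if ca * cb < 0 and d <= crit.salt_bridge_max:
            found.add(Interaction.make("salt_bridge", Partner(ra, ga, ma),
                                       Partner(rb, gb, mb),
                                       strand(ra) or "", strand(rb) or ""))

    # stacking
    aromatic = []
    for res in sorted(set(table.residue_numbers.tolist())):
        if res in topo.chromophore_residues:
            continue
        names = [str(table.atom_names[i]) for i in residue_atoms(res)]
        if not sidechain_props(str(
                table.residue_names[residue_atoms(res)[0]])).aromatic:
            continue
        if SIDECHAIN_SITE in names and "CB" in names:
            aromatic.append(res)
    for ra, rb in itertools.combinations(aromatic, 2):
        if not eligible(ra, rb):
            continue
        sa = xyz[[i for i in residue_atoms(ra)
                  if table.atom_names[i] == SIDECHAIN_SITE][0]]
        sb = xyz[[i for i in residue_atoms(rb)
                  if table.atom_names[i] == SIDECHAIN_SITE][0]]
        ba = xyz[[i for i in residue_atoms(ra) if table.atom_names[i] == "CB"][0]]
        bb = xyz[[i for i in residue_atoms(rb) if table.atom_names[i] == "CB"][0]]
        if np.linalg.norm(sa - sb) > crit.stacking_centroid_max:
            continue
        ax_a, ax_b = sa - ba, sb - bb
        cosang = abs(ax_a @ ax_b) / (np.linalg.norm(ax_a) * np.linalg.norm(ax_b))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) \
                <= crit.stacking_plane_angle_max:
            found.add(Interaction.make(
                "stacking", Partner(ra, SIDECHAIN_SITE, "sc"),
                Partner(rb, SIDECHAIN_SITE, "sc"),
                strand(ra) or "", strand(rb) or ""))
    return frozenset(found)


RESNAMES = ["SER", "LYS", "ASP", "TYR", "LEU", "ASN", "HIS", "THR", "PHE", "GLY"]


def random_frame(rng, n_residues=10, box=16.0):
    names, elements, res_nums, res_names, chains = [], [], [], [], []
    strand_of = {}
    labels = ["7", "10", "11"]
    for r in range(1, n_residues + 1):
        resname = RESNAMES[int(rng.integers(len(RESNAMES)))]
        strand_of[r] = labels[r % 3]
        atoms = ["N", "CA", "C", "O"]
        if sidechain_props(resname).has_sidechain:
            atoms += ["CB", SIDECHAIN_SITE]
        for a in atoms:
            names.append(a)
            elements.append({"N": "N", "O": "O"}.get(a, "C"))
            res_nums.append(r)
            res_names.append(resname)
            chains.append("A")
    # a chromophore-like residue with two polar atoms
    for a, el in [("A1", "C"), ("A2", "C"), ("OH", "O"), ("NX", "N")]:
        names.append(a)
        elements.append(el)
        res_nums.append(99)
        res_names.append("CRO")
        chains.append("A")
    strand_of[99] = "helix"
    table = AtomTable(names, elements, res_nums, res_names, chains)
    coords = rng.uniform(0, box, (table.n_atoms, 3))
    topo = StrandTopology(strand_of, "10", (1, 2),
                          chromophore_residues=frozenset({99}))
    return StructureFrame(table, coords), topo


class TestDetectInteractions:
    def test_close_pair_inside_cutoffs_is_hbond(self, criteria):
        table = AtomTable(["CB", SIDECHAIN_SITE, "CB", SIDECHAIN_SITE],
                          ["C", "O", "C", "O"], [1, 1, 2, 2],
                          ["SER", "SER", "THR", "THR"], ["A"] * 4)
        coords = np.array([[-1.5, 0, 0], [0, 0, 0], [4.4, 0, 0], [2.9, 0, 0]])
        topo = StrandTopology({1: "10", 2: "7"}, "10", (1, 2))
        found = detect_interactions(StructureFrame(table, coords), topo, criteria)
        assert len(found) == 1 and next(iter(found)).kind == "hbond"

    def test_distant_pair_absent(self, criteria):
        table = AtomTable(["CB", SIDECHAIN_SITE, "CB", SIDECHAIN_SITE],
                          ["C", "O", "C", "O"], [1, 1, 2, 2],
                          ["SER", "SER", "THR", "THR"], ["A"] * 4)
        coords = np.array([[-1.5, 0, 0], [0, 0, 0], [7.5, 0, 0], [6.0, 0, 0]])
        topo = StrandTopology({1: "10", 2: "7"}, "10", (1, 2))
        assert not detect_interactions(StructureFrame(table, coords), topo, criteria)

    def test_matches_brute_force_on_random_frames(self, criteria):
        """Exact set equality with an all-pairs enumeration oracle."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            frame, topo = random_frame(rng)
            assert detect_interactions(frame, topo, criteria) == \
                oracle_detect(frame, topo, criteria)

    def test_canonical_identity_stable_under_atom_permutation(self, criteria,
                                                              cis_fixture):
        _, traj, topo = cis_fixture
        frame = traj.frame(0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(frame.table.n_atoms)
        t = frame.table
        table = AtomTable(t.atom_names[perm], t.elements[perm],
                          t.residue_numbers[perm], t.residue_names[perm],
                          t.chain_ids[perm])
        shuffled = StructureFrame(table, frame.coords[perm])
        assert detect_interactions(shuffled, topo, criteria) == \
            detect_interactions(frame, topo, criteria)

    def test_occupancy_non_increasing_when_criteria_tightened(self, cis_fixture):
        _, traj, topo = cis_fixture
        loose = occupancy(traj, topo, InteractionCriteria())
        tight = occupancy(traj, topo, InteractionCriteria(
            hbond_da_max=3.0, salt_bridge_max=3.6, stacking_centroid_max=4.7))
        for interaction, frac in tight.fractions.items():
            assert frac <= loose.occupancy_of(interaction) + 1e-12


class TestOccupancy:
    def test_noise_free_fixture_planted_at_one(self, cis_fixture, criteria):
        spec, traj, topo = cis_fixture
        table = occupancy(traj, topo, criteria)
        for entry in spec.planted:
            assert table.occupancy_of(
                sd.expected_interaction(entry, spec)) == 1.0

    def test_alternating_interaction_at_half(self, cis_fixture, criteria):
        spec, traj, topo = cis_fixture
        table = occupancy(traj, topo, criteria)  # 8 frames, period 2
        alt = spec.alternating[0]
        for partner in (alt.partner_a, alt.partner_b):
            i = sd.expected_interaction(
                sd.SidechainContact(alt.shared, partner, "hbond"), spec)
            assert table.occupancy_of(i) == 0.5

    def test_matches_per_frame_recount(self, annealing_fixture, criteria):
        _, _, traj, topo = annealing_fixture
        sub = Trajectory(traj.table, traj.coords[:30])
        table = occupancy(sub, topo, criteria)
        recount = {}
        for i in range(30):
            for interaction in detect_interactions(sub.frame(i), topo, criteria):
                recount[interaction] = recount.get(interaction, 0) + 1
        assert table.fractions == {k: v / 30 for k, v in recount.items()}

    def test_empty_range_rejected(self, cis_fixture, criteria):
        _, traj, topo = cis_fixture
        with pytest.raises(StrandgateError):
            occupancy(traj, topo, criteria, frame_range=(5, 5))


class TestFindAlternating:
    def test_alternating_triple_reported(self, trans_fixture, criteria):
        spec, traj, topo = trans_fixture
        table = occupancy(traj, topo, criteria)
        triples = find_alternating(table, criteria)
        shared = {s for s, _, _ in triples}
        assert shared == {202}

    def test_co_present_interactions_not_reported(self, cis_fixture, criteria):
        """Persistent pairs sharing a residue have Jaccard 1 and never
        qualify as alternating."""
        spec, traj, topo = cis_fixture
        table = occupancy(traj, topo, criteria)
        triples = find_alternating(table, criteria)
        for _, a, b in triples:
            assert table.masks[a].sum() + table.masks[b].sum() <= traj.n_frames

    def test_matches_pair_enumeration(self, trans_fixture, criteria):
        spec, traj, topo = trans_fixture
        table = occupancy(traj, topo, criteria)
        reported = find_alternating(table, criteria)
        # brute force over interaction pairs sharing a sidechain residue
        expected = set()
        items = list(table.masks.items())
        for (ia, ma), (ib, mb) in itertools.combinations(items, 2):
            if table.fractions[ia] < criteria.alternating_min_occupancy or \
                    table.fractions[ib] < criteria.alternating_min_occupancy:
                continue
            shared = [r for r in ia.residues
                      if ia.involves(r, "sc") and ib.involves(r, "sc")]
            union = np.logical_or(ma, mb).sum()
            jac = np.logical_and(ma, mb).sum() / union if union else 1.0
            if shared and jac <= 0.2:
                a, b = sorted((ia, ib),
                              key=lambda i: (i.partner_a, i.partner_b, i.kind))
                for r in shared:
                    expected.add((r, a, b))
        assert reported == expected


class TestDiffNetworks:
    def test_identical_tables_diff_empty(self, cis_fixture, criteria):
        _, traj, topo = cis_fixture
        table = occupancy(traj, topo, criteria)
        diff = diff_networks(table, table)
        assert not diff.formed and not diff.broken
        assert diff.persistent

    def test_antisymmetry(self, cis_fixture, trans_fixture, criteria):
        _, cis_traj, topo = cis_fixture
        _, trans_traj, _ = trans_fixture
        a = occupancy(cis_traj, topo, criteria)
        b = occupancy(trans_traj, topo, criteria)
        ab, ba = diff_networks(a, b), diff_networks(b, a)
        assert ab.formed == ba.broken and ab.broken == ba.formed

    def test_sets_pairwise_disjoint(self, cis_fixture, trans_fixture, criteria):
        _, cis_traj, topo = cis_fixture
        _, trans_traj, _ = trans_fixture
        diff = diff_networks(occupancy(cis_traj, topo, criteria),
                             occupancy(trans_traj, topo, criteria))
        assert not (diff.formed & diff.broken)
        assert not (diff.formed & diff.persistent)
        assert not (diff.broken & diff.persistent)

    def test_cis_to_trans_breaks_strand7_contacts_forms_none(
            self, cis_fixture, trans_fixture, criteria):
        """Isomerization breaks strand-10/strand-7 bonds and forms no new
        hydrogen bond between the two strands."""
        _, cis_traj, topo = cis_fixture
        _, trans_traj, _ = trans_fixture
        diff = diff_networks(occupancy(cis_traj, topo, criteria),
                             occupancy(trans_traj, topo, criteria))
        pair_7_10 = ("10", "7")
        broken_7_10 = {i for i in diff.broken
                       if set(i.strand_pair) == set(pair_7_10)}
        formed_7_10 = {i for i in diff.formed
                       if set(i.strand_pair) == set(pair_7_10) and i.kind == "hbond"}
        assert broken_7_10  # chromophore-era contacts with strand 7 are lost
        assert not formed_7_10


class TestPathwayProfile:
    def test_contacts_vanishing_beyond_60_degrees(self, criteria):
        def schedule(center):
            return ((sd.ChromophoreContact(205, "OH"),)
                    if center <= 60.0 else ())
        windows = sd.generate_isomerization_windows(
            [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0],
            n_frames=2, contact_schedule=schedule)
        topo = sd.fig3_cis_spec().topology()
        profile = pathway_profile(windows, topo, criteria)
        contact = [i for i in profile.interactions
                   if i.involves(205, "sc") and i.involves(66)][0]
        assert profile.break_points[contact] == 60.0

    def test_flat_interactions_constant_across_windows(self, criteria):
        windows = sd.generate_isomerization_windows(
            [0.0, 60.0, 120.0, 180.0], n_frames=2, contact_schedule=lambda c: ())
        topo = sd.fig3_cis_spec().topology()
        profile = pathway_profile(windows, topo, criteria)
        backbone_rows = profile.matrix[[i for i, x in enumerate(profile.interactions)
                                        if x.partner_a.moiety == "mc"
                                        and x.partner_b.moiety == "mc"]]
        assert np.all(backbone_rows == backbone_rows[:, :1])

    def test_asn121_contact_interior_only(self, criteria):
        """The Asn121 analog touches the chromophore only mid-path."""
        windows = sd.generate_isomerization_windows(
            np.arange(0.0, 180.1, 10.0).tolist(), n_frames=2)
        topo = sd.fig3_cis_spec().topology()
        profile = pathway_profile(windows, topo, criteria)
        contact = [i for i in profile.interactions
                   if i.involves(sd.ASN121_RESIDUE, "sc")][0]
        row = profile.occupancy_of(contact)
        assert row[0] == 0.0 and row[-1] == 0.0
        assert row[(profile.centers >= 60) & (profile.centers <= 120)].min() > 0

    def test_window_validation(self, criteria):
        topo = sd.fig3_cis_spec().topology()
        windows = sd.generate_isomerization_windows([0.0, 40.0], n_frames=2)
        with pytest.raises(StrandgateError):
            pathway_profile(windows[:1], topo, criteria)
        with pytest.raises(StrandgateError):
            pathway_profile([windows[1], windows[0]], topo, criteria)
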
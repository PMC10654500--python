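"""Shared fixtures: generated once per session, never stored on disk."""

import numpy as np
import pytest

from strandgate import synthetic_data as sd
from strandgate.hbond_network import InteractionCriteria, occupancy, pathway_profile
from strandgate.annealing_analysis import anchor_loss_order
from strandgate.structure_core import classify_orientation
from strandgate.design_engine import DesignEvidence


@pytest.fixture(scope="session")
def criteria():
    return InteractionCriteria()


@pytest.fixture(scope="session")
def cis_fixture():
    spec = sd.fig3_cis_spec()
    traj, topo = sd.generate_barrel_trajectory(spec, 8, 0.0)
    return spec, traj, topo


@pytest.fixture(scope="session")
def trans_fixture():
    spec = sd.fig3_trans_spec()
    traj, topo = sd.generate_barrel_trajectory(spec, 8, 0.0)
    return spec, traj, topo


@pytest.fixture(scope="session")
def annealing_fixture():
    """Noise-free annealing trajectory with the default planted event."""
    spec = sd.annealing_trans_spec()
    event = sd.default_dissociation_event()
    schedule = sd.default_annealing_schedule(100)
    traj, topo = sd.generate_barrel_trajectory(spec, 100, 0.0, event, schedule)
    return spec, event, traj, topo


@pytest.fixture(scope="session")
def design_evidence(cis_fixture, annealing_fixture, criteria):
    """The worked-example evidence bundle built from the preset fixtures."""
    cis_spec, cis_traj, topo = cis_fixture
    _, event, ann_traj, _ = annealing_fixture
    cis_occ = occupancy(cis_traj, topo, criteria)
    trans_occ = occupancy(ann_traj, topo, criteria,
                          frame_range=(0, event.onset_frame))
    anchors = anchor_loss_order(ann_traj, topo, criteria)
    orientation = classify_orientation(cis_traj.frame(0), topo)
    windows = sd.generate_isomerization_windows(
        np.arange(0.0, 180.1, 10.0).tolist(), n_frames=4)
    pathway = pathway_profile(windows, topo, criteria)
    names = {r: cis_spec.residue_name(r) for r in cis_spec.all_residues()}
    return DesignEvidence(cis_occ, trans_occ, pathway, orientation, anchors,
                          residue_names=names), topo
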
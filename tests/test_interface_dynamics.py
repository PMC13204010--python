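"""Trajectory interface analysis: RMSD series, contact detection and
frequencies, consensus residues, distance series, COM maps, and the
hydrogen-bond/salt-bridge classification."""

import numpy as np
import pandas as pd
import pytest

from senescreen import (ContactParams, backbone_rmsd_series,
                        classify_interactions, com_contact_map,
                        consensus_residues, contact_frequency,
                        pair_distance_series, read_trajectory,
                        residue_contacts)
from senescreen import synthetic_data as synth
from senescreen.errors import ParameterError
from senescreen.geometry import random_rotation
from senescreen.structure import Structure, Trajectory, write_trajectory


def brute_force_contacts(topo, coords, chain_a, chain_b, cutoff,
                         heavy_only=True):
    """O(n^2) all-atom-pairs oracle for one frame."""
    out = set()
    scope = (topo.element != "H") if heavy_only else np.ones(
        topo.n_atoms, dtype=bool)
    ia = np.flatnonzero((topo.chain == chain_a) & scope)
    ib = np.flatnonzero((topo.chain == chain_b) & scope)
    for i in ia:
        for j in ib:
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                out.add((int(topo.resnum[i]), int(topo.resnum[j])))
    return out


def two_atom_structure(dist, names=("CA", "CA"), resnames=("ALA", "ALA"),
                       elements=("C", "C")):
    return Structure(
        np.array(["A", "B"]), np.array([1, 2]), np.array(resnames),
        np.array(names), np.array(elements),
        np.array([[0.0, 0.0, 0.0], [dist, 0.0, 0.0]]))


# ------------------------------------------------------------- RMSD series

def test_static_trajectory_rmsd_zero():
    truth = synth.gen_trajectory(20, [(1, 101, 1.0)], noise_sigma=0.0,
                                 seed=1)
    series = backbone_rmsd_series(truth.trajectory)
    assert np.allclose(series, 0.0, atol=1e-9)


def test_rmsd_series_invariant_under_global_rotation(rng):
    truth = synth.gen_trajectory(10, [(1, 101, 0.5)], noise_sigma=0.2,
                                 seed=2)
    traj = truth.trajectory
    series = backbone_rmsd_series(traj)
    rotated = np.stack([f @ random_rotation(rng).T + rng.normal(size=3) * 9
                        for f in traj.frames])
    series_rot = backbone_rmsd_series(
        Trajectory(traj.topology, rotated, replica="r1x"),
        reference=traj.frame(0))
    assert np.allclose(series, series_rot, atol=1e-6)


def test_jittered_rmsd_matches_bruteforce(rng):
    truth = synth.gen_trajectory(15, [(1, 101, 0.5)], noise_sigma=0.3,
                                 seed=3)
    traj = truth.trajectory
    series = backbone_rmsd_series(traj)
    from senescreen.geometry import kabsch
    from senescreen.structure import sel_backbone
    mask = traj.topology.mask(sel_backbone)
    for f in range(traj.n_frames):
        expected = kabsch(traj.frames[f][mask], traj.frames[0][mask]).rmsd
        assert series[f] == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------- contacts

def test_contact_threshold_semantics():
    params = ContactParams(cutoff=5.0)
    near = two_atom_structure(4.9)
    far = two_atom_structure(5.1)
    assert residue_contacts(near, "A", "B", params) == {(1, 2)}
    assert residue_contacts(far, "A", "B", params) == set()


def test_contacts_match_planted_bound_geometry():
    truth = synth.gen_trajectory(30, [(5, 105, 1.0), (9, 109, 0.0)],
                                 noise_sigma=0.1, seed=4)
    traj = truth.trajectory
    for f in range(traj.n_frames):
        got = residue_contacts(traj, "A", "B", frame_index=f)
        assert got == {(5, 105)}


def test_contacts_equal_bruteforce_oracle_all_scopes():
    truth = synth.gen_trajectory(
        10, [(1, 101, 0.5), (2, 102, 0.8), (3, 103, 0.2)],
        noise_sigma=0.15, seed=5)
    traj = truth.trajectory
    for scope, heavy in (("heavy", True), ("ca", None)):
        params = ContactParams(cutoff=5.0, atom_scope=scope)
        for f in range(traj.n_frames):
            got = residue_contacts(traj, "A", "B", params, frame_index=f)
            if scope == "heavy":
                expected = brute_force_contacts(
                    traj.topology, traj.frames[f], "A", "B", 5.0)
            else:
                ca_only = traj.topology.name == "CA"
                expected = set()
                ia = np.flatnonzero((traj.topology.chain == "A") & ca_only)
                ib = np.flatnonzero((traj.topology.chain == "B") & ca_only)
                for i in ia:
                    for j in ib:
                        if np.linalg.norm(traj.frames[f][i]
                                          - traj.frames[f][j]) <= 5.0:
                            expected.add((int(traj.topology.resnum[i]),
                                          int(traj.topology.resnum[j])))
            assert got == expected


def test_unknown_chain_raises():
    truth = synth.gen_trajectory(2, [(1, 101, 1.0)], seed=6)
    with pytest.raises(LookupError):
        residue_contacts(truth.trajectory, "A", "Z")


# ---------------------------------------------------------------- frequency

def test_contact_frequency_exact_recovery():
    targets = [(10, 110, 0.0), (11, 111, 0.25), (12, 112, 0.5),
               (13, 113, 0.65), (14, 114, 1.0)]
    truth = synth.gen_trajectory(200, targets, noise_sigma=0.1, seed=7)
    table = contact_frequency(truth.trajectory, "A", "B")
    measured = {(a, b): f for a, b, f in
                zip(table["res_a"], table["res_b"], table["frequency"])}
    for (a, b), expected in truth.realized.items():
        if expected == 0.0:
            assert (a, b) not in measured  # never-contacting pairs omitted
        else:
            assert measured[(a, b)] == expected


def test_contact_frequency_invariant_under_frame_permutation(rng):
    truth = synth.gen_trajectory(40, [(1, 101, 0.4), (2, 102, 0.9)],
                                 noise_sigma=0.1, seed=8)
    traj = truth.trajectory
    perm = rng.permutation(traj.n_frames)
    shuffled = Trajectory(traj.topology, traj.frames[perm], replica="r1")
    t1 = contact_frequency(traj, "A", "B").drop(columns="replica")
    t2 = contact_frequency(shuffled, "A", "B").drop(columns="replica")
    pd.testing.assert_frame_equal(t1, t2)


def test_empty_interface_empty_table():
    truth = synth.gen_trajectory(10, [(1, 101, 0.0)], seed=9)
    table = contact_frequency(truth.trajectory, "A", "B")
    assert len(table) == 0


# ---------------------------------------------------------------- consensus

def test_consensus_returns_only_shared_residues():
    shared = [(32, 401, 0.8), (36, 405, 0.8)]
    private = [[(60, 460, 0.9)], [(70, 470, 0.9)], [(80, 480, 0.9)]]
    truths = synth.gen_replica_trajectories(50, shared, private, seed=10)
    tables = [contact_frequency(t.trajectory, "A", "B") for t in truths]
    cons = consensus_residues(tables, freq_min=0.5)
    assert list(cons.residues_a["residue"]) == [32, 36]
    assert list(cons.residues_b["residue"]) == [401, 405]
    assert set(zip(cons.pairs["res_a"], cons.pairs["res_b"])) == \
        {(32, 401), (36, 405)}


def test_consensus_monotone_in_freq_min():
    shared = [(32, 401, 0.8), (36, 405, 0.55)]
    truths = synth.gen_replica_trajectories(100, shared, [[], []], seed=11)
    tables = [contact_frequency(t.trajectory, "A", "B") for t in truths]
    low = set(consensus_residues(tables, 0.3).residues_a["residue"])
    high = set(consensus_residues(tables, 0.7).residues_a["residue"])
    assert high <= low
    assert 36 in low and 36 not in high


def test_consensus_requires_two_replicas_and_empty_replica_kills_it():
    truth = synth.gen_trajectory(10, [(1, 101, 1.0)], seed=12)
    table = contact_frequency(truth.trajectory, "A", "B")
    with pytest.raises(ParameterError):
        consensus_residues([table])
    empty = table.iloc[0:0]
    cons = consensus_residues([table, empty], freq_min=0.0)
    assert len(cons.residues_a) == 0 and len(cons.pairs) == 0


# ----------------------------------------------------------- distance series

def test_pair_distance_constant_and_mode_ordering():
    truth = synth.gen_trajectory(20, [(1, 101, 1.0)], noise_sigma=0.0,
                                 seed=13)
    traj = truth.trajectory
    series = pair_distance_series(traj, [(1, 101)], "A", "B",
                                  mode="min-heavy")
    assert np.allclose(series["distance"], series["distance"].iloc[0])
    assert series["distance"].iloc[0] == pytest.approx(4.0, abs=1e-6)
    com = pair_distance_series(traj, [(1, 101)], "A", "B", mode="com")
    assert (com["distance"].to_numpy()
            >= series["distance"].to_numpy() - 1e-9).all()
    with pytest.raises(LookupError):
        pair_distance_series(traj, [(1, 999)], "A", "B")


def test_distance_series_consistent_with_contacts():
    truth = synth.gen_trajectory(50, [(1, 101, 0.6)], noise_sigma=0.1,
                                 seed=14)
    traj = truth.trajectory
    series = pair_distance_series(traj, [(1, 101)], "A", "B")
    for f in range(traj.n_frames):
        in_contact = (1, 101) in residue_contacts(traj, "A", "B",
                                                  frame_index=f)
        d = float(series.query("frame == @f")["distance"].iloc[0])
        assert in_contact == (d <= 5.0)


# ------------------------------------------------------------------ COM map

def test_com_map_matches_bruteforce_loop():
    truth = synth.gen_trajectory(8, [(1, 101, 0.5), (2, 102, 0.9)],
                                 noise_sigma=0.2, seed=15)
    traj = truth.trajectory
    mat = com_contact_map(traj, "A", "B", (1, 2), (101, 102))
    masses = traj.topology.masses()
    for ra in (1, 2):
        for rb in (101, 102):
            ia = np.flatnonzero((traj.topology.chain == "A")
                                & (traj.topology.resnum == ra))
            ib = np.flatnonzero((traj.topology.chain == "B")
                                & (traj.topology.resnum == rb))
            dists = []
            for f in range(traj.n_frames):
                ca = np.average(traj.frames[f][ia], axis=0,
                                weights=masses[ia])
                cb = np.average(traj.frames[f][ib], axis=0,
                                weights=masses[ib])
                dists.append(np.linalg.norm(ca - cb))
            assert mat.loc[ra, rb] == pytest.approx(np.mean(dists),
                                                    abs=1e-6)
    assert mat.shape == (2, 2)
    with pytest.raises(ParameterError):
        com_contact_map(traj, "A", "B", (900, 901), (101, 102))


def test_com_map_single_atom_residues_equals_atom_distance():
    s = two_atom_structure(7.0)
    mat = com_contact_map(s, "A", "B", (1, 1), (2, 2))
    assert mat.loc[1, 2] == pytest.approx(7.0)


# ----------------------------------------------------------- classification

def _charged_pair_structure(dist):
    """ARG guanidinium nitrogen (chain A) facing an ASP carboxylate
    oxygen (chain B) at the given distance."""
    return Structure(
        np.array(["A", "A", "B", "B"]),
        np.array([1, 1, 2, 2]),
        np.array(["ARG", "ARG", "ASP", "ASP"]),
        np.array(["NH1", "CZ", "OD1", "CG"]),
        np.array(["N", "C", "O", "C"]),
        np.array([[0.0, 0, 0], [1.3, 0, 0],
                  [-dist, 0, 0], [-dist - 1.5, 0, 0]]))


def test_salt_bridge_definition_case():
    s = _charged_pair_structure(3.2)
    traj = Trajectory(s, s.coords[None], replica="r1")
    out = classify_interactions(traj, [(1, 2)], "A", "B")
    assert out["classification"].iloc[0] == "salt_bridge"
    assert out["saltbridge_occupancy"].iloc[0] == 1.0


def test_backbone_hbond_definition_case():
    s = Structure(
        np.array(["A", "B"]), np.array([1, 2]),
        np.array(["ALA", "ALA"]), np.array(["O", "N"]),
        np.array(["O", "N"]),
        np.array([[0.0, 0, 0], [2.9, 0, 0]]))
    traj = Trajectory(s, s.coords[None], replica="r1")
    out = classify_interactions(traj, [(1, 2)], "A", "B")
    assert out["classification"].iloc[0] == "hbond"


def test_carbon_only_contact_is_other():
    s = two_atom_structure(3.0, names=("CB", "CB"), elements=("C", "C"))
    traj = Trajectory(s, s.coords[None], replica="r1")
    out = classify_interactions(traj, [(1, 2)], "A", "B")
    assert out["classification"].iloc[0] == "other"


def test_classification_occupancy_matches_planted_schedule():
    near = _charged_pair_structure(3.2).coords
    far = _charged_pair_structure(9.0).coords
    schedule = np.array([True, False, True, True, False])
    frames = np.stack([near if on else far for on in schedule])
    traj = Trajectory(_charged_pair_structure(3.2), frames, replica="r1")
    out = classify_interactions(traj, [(1, 2)], "A", "B")
    assert out["saltbridge_occupancy"].iloc[0] == pytest.approx(
        schedule.mean())


# -------------------------------------------------------------------- I/O

def test_trajectory_pdb_roundtrip(tmp_path):
    truth = synth.gen_trajectory(5, [(1, 101, 0.6)], noise_sigma=0.1,
                                 seed=16)
    path = tmp_path / "traj.pdb"
    write_trajectory(path, truth.trajectory)
    back = read_trajectory(path, replica="r1")
    assert back.n_frames == 5
    assert np.allclose(back.frames, truth.trajectory.frames, atol=1e-3)
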
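"""Interaction-interface characterization from multi-replica
trajectories.

All analyses operate on a two-chain complex: backbone-RMSD stability
series, inter-chain residue contacts at a distance cutoff (default
5 Å between heavy atoms), contact frequencies per replica, consensus
interface residues across replicas, residue-pair distance series,
residue center-of-mass contact maps, and a geometric hydrogen-bond /
salt-bridge classification of interface pairs.

Per-frame contact detection uses a k-d tree query at the cutoff scale,
so runtime scales with the number of nearby atom pairs rather than with
all pairs; tests validate it against an O(n^2) loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .geometry import kabsch
from .structure import (Structure, Trajectory, check_shared_topology,
                        read_models, sel_backbone)

logger = logging.getLogger(__name__)

ResiduePair = tuple[int, int]

#: Side-chain atoms carrying formal charge, for salt-bridge detection.
BASIC_NITROGENS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
}
HIS_NITROGENS = ("ND1", "NE2")
ACIDIC_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class ContactParams:
    """Distance criteria for interface analysis (all Å)."""

    cutoff: float = 5.0
    atom_scope: str = "heavy"        # heavy | all | ca
    hbond_da_max: float = 3.5
    saltbridge_max: float = 4.0
    his_charged: bool = False        # treat HIS ND1/NE2 as basic

    def __post_init__(self) -> None:
        if min(self.cutoff, self.hbond_da_max, self.saltbridge_max) <= 0:
            raise ParameterError("all distance criteria must be positive")
        if self.atom_scope not in ("heavy", "all", "ca"):
            raise ParameterError(f"unknown atom_scope {self.atom_scope!r}")


def read_trajectory(path: str | Path, replica: str = "r1") -> Trajectory:
    """Read a multi-model PDB as one replica's trajectory (frames in
    model order)."""
    models = read_models(path)
    check_shared_topology(models)
    frames = np.stack([m.coords for m in models])
    return Trajectory(models[0], frames, replica=replica)


def backbone_rmsd_series(traj: Trajectory,
                         reference: Structure | None = None,
                         chains: Sequence[str] | None = None) -> np.ndarray:
    """Per-frame backbone (N, CA, C, O) RMSD to a reference after
    least-squares superposition.

    The reference defaults to frame 0; the selection defaults to every
    chain.
    """
    topo = traj.topology
    mask = topo.mask(sel_backbone)
    if chains is not None:
        mask &= np.isin(topo.chain, list(chains))
    if mask.sum() < 3:
        raise GeometryError("fewer than 3 backbone atoms selected")
    ref_coords = (reference.coords if reference is not None
                  else traj.frames[0])[mask]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        out[i] = kabsch(traj.frames[i][mask], ref_coords).rmsd
    return out


def _scope_mask(topo: Structure, params: ContactParams) -> np.ndarray:
    if params.atom_scope == "heavy":
        return topo.element != "H"
    if params.atom_scope == "ca":
        return topo.name == "CA"
    return np.ones(topo.n_atoms, dtype=bool)


def _chain_atoms(topo: Structure, chain: str,
                 params: ContactParams) -> tuple[np.ndarray, np.ndarray]:
    """(atom indices, residue numbers) of the scoped atoms of a chain."""
    if chain not in topo.chains():
        raise LookupError(f"chain {chain!r} not present in the topology")
    mask = (topo.chain == chain) & _scope_mask(topo, params)
    idx = np.flatnonzero(mask)
    return idx, topo.resnum[idx]


def _frame_pair_distances(coords: np.ndarray,
                          idx_a: np.ndarray, res_a: np.ndarray,
                          idx_b: np.ndarray, res_b: np.ndarray,
                          cutoff: float) -> dict[ResiduePair, float]:
    """Min scoped-atom distance per inter-chain residue pair, restricted
    to pairs with min distance <= cutoff, via a k-d tree query."""
    tree_a = cKDTree(coords[idx_a])
    tree_b = cKDTree(coords[idx_b])
    sparse = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    best: dict[ResiduePair, float] = {}
    for ai, bi, dist in zip(sparse.row, sparse.col, sparse.data):
        key = (int(res_a[ai]), int(res_b[bi]))
        if dist < best.get(key, np.inf):
            best[key] = float(dist)
    return best


def residue_contacts(frame: Structure | Trajectory,
                     chain_a: str, chain_b: str,
                     params: ContactParams | None = None,
                     frame_index: int = 0) -> set[ResiduePair]:
    """Residue pairs (chain A residue, chain B residue) whose scoped
    atoms approach within the cutoff in one frame.

    Only inter-chain pairs are reported.
    """
    params = params or ContactParams()
    if isinstance(frame, Trajectory):
        topo, coords = frame.topology, frame.frames[frame_index]
    else:
        topo, coords = frame, frame.coords
    idx_a, res_a = _chain_atoms(topo, chain_a, params)
    idx_b, res_b = _chain_atoms(topo, chain_b, params)
    return set(_frame_pair_distances(coords, idx_a, res_a, idx_b, res_b,
                                     params.cutoff))


def contact_frequency(traj: Trajectory, chain_a: str, chain_b: str,
                      params: ContactParams | None = None) -> pd.DataFrame:
    """Fraction of frames each inter-chain residue pair is in contact,
    with the mean (over in-contact frames) of the per-frame minimum
    scoped-atom distance.

    Pairs never in contact are omitted.  Columns: replica, res_a, res_b,
    frequency, mean_min_distance.
    """
    params = params or ContactParams()
    if traj.n_frames < 1:
        raise ParameterError("trajectory has no frames")
    idx_a, res_a = _chain_atoms(traj.topology, chain_a, params)
    idx_b, res_b = _chain_atoms(traj.topology, chain_b, params)
    counts: dict[ResiduePair, int] = {}
    dist_sums: dict[ResiduePair, float] = {}
    for f in range(traj.n_frames):
        per_pair = _frame_pair_distances(traj.frames[f], idx_a, res_a,
                                         idx_b, res_b, params.cutoff)
        for pair, dist in per_pair.items():
            counts[pair] = counts.get(pair, 0) + 1
            dist_sums[pair] = dist_sums.get(pair, 0.0) + dist
    rows = [(traj.replica, a, b, counts[(a, b)] / traj.n_frames,
             dist_sums[(a, b)] / counts[(a, b)])
            for (a, b) in sorted(counts)]
    return pd.DataFrame(rows, columns=["replica", "res_a", "res_b",
                                       "frequency", "mean_min_distance"])


@dataclass
class ConsensusInterface:
    """Interface residues and pairs persistent in every replica."""

    residues_a: pd.DataFrame     # residue, then one frequency column per replica
    residues_b: pd.DataFrame
    pairs: pd.DataFrame          # res_a, res_b, per-replica freq, classification


def consensus_residues(tables: Sequence[pd.DataFrame],
                       freq_min: float = 0.5) -> ConsensusInterface:
    """Residues participating in at least one inter-chain pair with
    frequency >= ``freq_min`` in *every* replica.

    ``tables`` is one contact-frequency table per replica (>= 2).  The
    ``pairs`` output lists the residue pairs meeting the threshold in
    every replica, with classification left unset (see
    :func:`classify_interactions`).
    """
    if len(tables) < 2:
        raise ParameterError("consensus needs at least 2 replicas")
    if not 0.0 <= freq_min <= 1.0:
        raise ParameterError("freq_min must be in [0, 1]")
    replicas = [str(t["replica"].iloc[0]) if len(t) else f"r{i+1}"
                for i, t in enumerate(tables)]

    def qualifying(table: pd.DataFrame) -> pd.DataFrame:
        return table[table["frequency"] >= freq_min]

    per_rep = [qualifying(t) for t in tables]
    res_a_sets = [set(t["res_a"]) for t in per_rep]
    res_b_sets = [set(t["res_b"]) for t in per_rep]
    pair_sets = [set(zip(t["res_a"], t["res_b"])) for t in per_rep]
    cons_a = sorted(set.intersection(*res_a_sets)) if res_a_sets else []
    cons_b = sorted(set.intersection(*res_b_sets)) if res_b_sets else []
    cons_pairs = sorted(set.intersection(*pair_sets)) if pair_sets else []

    def residue_table(residues: list[int], side: str) -> pd.DataFrame:
        data: dict[str, list] = {"residue": residues}
        for rep, table in zip(replicas, tables):
            col = []
            for r in residues:
                sub = table[table[side] == r]
                col.append(float(sub["frequency"].max()) if len(sub) else 0.0)
            data[rep] = col
        return pd.DataFrame(data)

    pair_data: dict[str, list] = {
        "res_a": [p[0] for p in cons_pairs],
        "res_b": [p[1] for p in cons_pairs],
    }
    for rep, table in zip(replicas, tables):
        col = []
        for a, b in cons_pairs:
            sub = table[(table["res_a"] == a) & (table["res_b"] == b)]
            col.append(float(sub["frequency"].iloc[0]) if len(sub) else 0.0)
        pair_data[rep] = col
    pair_df = pd.DataFrame(pair_data)
    pair_df["classification"] = pd.array([None] * len(pair_df), dtype=object)
    return ConsensusInterface(residue_table(cons_a, "res_a"),
                              residue_table(cons_b, "res_b"),
                              pair_df)


def _resolve_residue(topo: Structure, chain: str, resnum: int,
                     heavy_only: bool = True) -> np.ndarray:
    mask = (topo.chain == chain) & (topo.resnum == resnum)
    if heavy_only:
        mask &= topo.element != "H"
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise LookupError(f"residue {chain}:{resnum} not found in topology")
    return idx


def pair_distance_series(traj: Trajectory,
                         pairs: Sequence[ResiduePair],
                         chain_a: str, chain_b: str,
                         mode: str = "min-heavy") -> pd.DataFrame:
    """Per-frame distance series for chosen residue pairs.

    ``mode="min-heavy"`` reports the minimum heavy-atom distance;
    ``mode="com"`` the distance between mass-weighted residue centres.
    Columns: frame, res_a, res_b, distance.
    """
    if mode not in ("min-heavy", "com"):
        raise ParameterError(f"unknown mode {mode!r}")
    topo = traj.topology
    rows = []
    for a, b in pairs:
        ia = _resolve_residue(topo, chain_a, a)
        ib = _resolve_residue(topo, chain_b, b)
        if mode == "com":
            ma = topo.masses()[ia]
            mb = topo.masses()[ib]
        for f in range(traj.n_frames):
            ca = traj.frames[f][ia]
            cb = traj.frames[f][ib]
            if mode == "min-heavy":
                d = float(np.min(np.linalg.norm(
                    ca[:, None, :] - cb[None, :, :], axis=-1)))
            else:
                coma = (ca * ma[:, None]).sum(axis=0) / ma.sum()
                comb = (cb * mb[:, None]).sum(axis=0) / mb.sum()
                d = float(np.linalg.norm(coma - comb))
            rows.append((f, a, b, d))
    return pd.DataFrame(rows, columns=["frame", "res_a", "res_b", "distance"])


def com_contact_map(source: Trajectory | Structure,
                    chain_a: str, chain_b: str,
                    range_a: tuple[int, int],
                    range_b: tuple[int, int]) -> pd.DataFrame:
    """Time-averaged distance between mass-weighted residue centres of
    mass, for residues of chain A in ``range_a`` (inclusive) versus chain
    B in ``range_b``.

    For a single structure the map is instantaneous.  Returned as a
    matrix DataFrame indexed by chain-A residue number, columns chain-B
    residue numbers.
    """
    if isinstance(source, Trajectory):
        topo, frames = source.topology, source.frames
    else:
        topo, frames = source, source.coords[None, :, :]
    masses = topo.masses()

    def residues_in(chain: str, lo_hi: tuple[int, int]) -> list[int]:
        lo, hi = lo_hi
        present = sorted(set(topo.resnum[topo.chain == chain].tolist()))
        sel = [r for r in present if lo <= r <= hi]
        if not sel:
            raise ParameterError(
                f"no residues of chain {chain} in [{lo}, {hi}]")
        return sel

    res_a = residues_in(chain_a, range_a)
    res_b = residues_in(chain_b, range_b)

    def com_series(chain: str, residues: list[int]) -> np.ndarray:
        out = np.empty((len(frames), len(residues), 3))
        for j, r in enumerate(residues):
            idx = _resolve_residue(topo, chain, r, heavy_only=False)
            w = masses[idx]
            out[:, j, :] = (frames[:, idx, :] * w[None, :, None]).sum(axis=1) / w.sum()
        return out

    coms_a = com_series(chain_a, res_a)
    coms_b = com_series(chain_b, res_b)
    dists = np.linalg.norm(coms_a[:, :, None, :] - coms_b[:, None, :, :],
                           axis=-1).mean(axis=0)
    return pd.DataFrame(dists, index=pd.Index(res_a, name="res_a"),
                        columns=pd.Index(res_b, name="res_b"))


def _charged_atoms(topo: Structure, idx: np.ndarray,
                   params: ContactParams) -> tuple[np.ndarray, np.ndarray]:
    """(basic nitrogen indices, acidic oxygen indices) within ``idx``."""
    basic, acidic = [], []
    for i in idx:
        resname = str(topo.resname[i])
        name = str(topo.name[i])
        if name in BASIC_NITROGENS.get(resname, ()):
            basic.append(i)
        elif params.his_charged and resname == "HIS" and name in HIS_NITROGENS:
            basic.append(i)
        elif name in ACIDIC_OXYGENS.get(resname, ()):
            acidic.append(i)
    return np.array(basic, dtype=int), np.array(acidic, dtype=int)


def _min_dist(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    if len(ia) == 0 or len(ib) == 0:
        return np.inf
    return float(np.min(np.linalg.norm(
        coords[ia][:, None, :] - coords[ib][None, :, :], axis=-1)))


def classify_interactions(traj: Trajectory,
                          pairs: Sequence[ResiduePair],
                          chain_a: str, chain_b: str,
                          params: ContactParams | None = None) -> pd.DataFrame:
    """Geometric classification of interface residue pairs as
    ``salt_bridge``, ``hbond`` or ``other``, with per-frame occupancies.

    A frame counts as a salt bridge when a side-chain charged-group
    nitrogen (LYS NZ; ARG NH1/NH2/NE; optionally HIS ND1/NE2) sits
    within ``saltbridge_max`` of a carboxylate oxygen (ASP OD1/OD2;
    GLU OE1/OE2); as a hydrogen bond when any N/O donor-acceptor pair
    sits within ``hbond_da_max`` (pure distance criterion when no
    hydrogens are present; a D-H...A angle >= 120 degrees is additionally
    required when they are).  The label is the criterion with the higher
    occupancy, salt bridge taking precedence at equal occupancy.
    """
    params = params or ContactParams()
    topo = traj.topology
    has_h = bool((topo.element == "H").any())
    rows = []
    for a, b in pairs:
        ia = _resolve_residue(topo, chain_a, a, heavy_only=False)
        ib = _resolve_residue(topo, chain_b, b, heavy_only=False)
        no_a = ia[np.isin(topo.element[ia], ["N", "O"])]
        no_b = ib[np.isin(topo.element[ib], ["N", "O"])]
        basic_a, acidic_a = _charged_atoms(topo, ia, params)
        basic_b, acidic_b = _charged_atoms(topo, ib, params)
        n_sb = 0
        n_hb = 0
        for f in range(traj.n_frames):
            coords = traj.frames[f]
            sb = min(_min_dist(coords, basic_a, acidic_b),
                     _min_dist(coords, basic_b, acidic_a)) <= params.saltbridge_max
            if has_h:
                hb = _hbond_with_angle(topo, coords, no_a, no_b,
                                       params.hbond_da_max)
            else:
                hb = _min_dist(coords, no_a, no_b) <= params.hbond_da_max
            n_sb += sb
            n_hb += hb
        occ_sb = n_sb / traj.n_frames
        occ_hb = n_hb / traj.n_frames
        if occ_sb == 0.0 and occ_hb == 0.0:
            label = "other"
        elif occ_sb >= occ_hb:
            label = "salt_bridge"
        else:
            label = "hbond"
        rows.append((a, b, label, occ_sb, occ_hb))
    return pd.DataFrame(rows, columns=["res_a", "res_b", "classification",
                                       "saltbridge_occupancy",
                                       "hbond_occupancy"])


def _hbond_with_angle(topo: Structure, coords: np.ndarray,
                      no_a: np.ndarray, no_b: np.ndarray,
                      da_max: float) -> bool:
    """Donor-acceptor N/O pairs within ``da_max`` and, where the donor
    carries a hydrogen (within 1.2 Å), a D-H...A angle >= 120 degrees."""
    h_idx = np.flatnonzero(topo.element == "H")
    for donors, acceptors in ((no_a, no_b), (no_b, no_a)):
        for d in donors:
            d_h = h_idx[np.linalg.norm(coords[h_idx] - coords[d], axis=1) <= 1.2]
            for acc in acceptors:
                da = float(np.linalg.norm(coords[d] - coords[acc]))
                if da > da_max:
                    continue
                if len(d_h) == 0:
                    return True
                for h in d_h:
                    v1 = coords[d] - coords[h]
                    v2 = coords[acc] - coords[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                               * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 120.0:
                        return True
    return False
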
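"""Docked-pose ensemble post-processing.

Given an ensemble of same-topology rigid-docking poses (receptor chain
fixed, ligand chain repositioned), the stages here reproduce the usual
refinement funnel: pairwise ligand RMSD after receptor superposition,
cutoff clustering of the RMSD matrix, medoid ("centroid") selection in
the most populated cluster, and a coarse Ramachandran screen of the
selected model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, GeometryError, ParameterError
from .geometry import apply_transform, dihedral, kabsch
from .structure import (AtomPredicate, PoseEnsemble, Structure,
                        check_shared_topology, read_models, sel_and,
                        sel_chain, sel_name)

logger = logging.getLogger(__name__)


def read_poses(path: str | Path,
               score_table: str | Path | None = None) -> PoseEnsemble:
    """Read a multi-model PDB as a pose ensemble, optionally joining a
    per-model interface score table (CSV with columns model_id, I_sc)."""
    models = read_models(path)
    check_shared_topology(models)
    scores = None
    if score_table is not None:
        df = pd.read_csv(score_table)
        if not {"model_id", "I_sc"} <= set(df.columns):
            raise FormatError("score table needs columns model_id, I_sc")
        by_model = dict(zip(df["model_id"].astype(int), df["I_sc"].astype(float)))
        scores = {i: by_model[m.model_id] for i, m in enumerate(models)
                  if m.model_id in by_model}
    return PoseEnsemble(models, scores)


def _default_predicates(topology: Structure) -> tuple[AtomPredicate, AtomPredicate]:
    """Receptor-CA alignment / ligand-CA measurement defaults.

    By convention the first chain in the file is the receptor and the
    second the ligand; both predicates are overridable.
    """
    chains = topology.chains()
    if len(chains) < 2:
        raise ParameterError(
            "default selections need a two-chain complex; pass explicit "
            "align_on/measure_on predicates otherwise")
    receptor, ligand = chains[0], chains[1]
    return (sel_and(sel_chain(receptor), sel_name("CA")),
            sel_and(sel_chain(ligand), sel_name("CA")))


@dataclass
class RmsdMatrix:
    """Symmetric pairwise pose-RMSD matrix (Å) with selection metadata."""

    values: np.ndarray
    align_selection: str = "receptor-ca"
    measure_selection: str = "ligand-ca"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.values)
        if self.values.shape != (n, n):
            raise ParameterError("RMSD matrix must be square")

    def __len__(self) -> int:
        return len(self.values)


def pairwise_rmsd(ensemble: PoseEnsemble,
                  align_on: AtomPredicate | None = None,
                  measure_on: AtomPredicate | None = None) -> RmsdMatrix:
    """All-vs-all pose RMSD: pose j is superposed onto pose i over the
    alignment atoms, then RMSD is measured over the measurement atoms.

    Defaults implement the standard ligand-RMSD convention for rigid
    docking ensembles: align on receptor-chain CA, measure on
    ligand-chain CA.
    """
    topo = ensemble.poses[0]
    labels = ("receptor-ca", "ligand-ca")
    if align_on is None or measure_on is None:
        default_align, default_measure = _default_predicates(topo)
        align_on = align_on or default_align
        measure_on = measure_on or default_measure
    else:
        labels = ("custom", "custom")
    align_mask = topo.mask(align_on)
    measure_mask = topo.mask(measure_on)
    if not align_mask.any() or not measure_mask.any():
        raise GeometryError("alignment/measurement selections are empty")

    n = len(ensemble)
    coords = np.stack([p.coords for p in ensemble.poses])
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fit = kabsch(coords[j][align_mask], coords[i][align_mask])
            moved = apply_transform(coords[j][measure_mask], fit)
            diff = moved - coords[i][measure_mask]
            values[i, j] = values[j, i] = float(
                np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return RmsdMatrix(values, labels[0], labels[1])


@dataclass
class ClusterResult:
    """Cluster assignment of poses; ids are numbered by population
    descending (ties broken by smallest member index)."""

    labels: np.ndarray                  # pose -> cluster id
    populations: dict[int, int]
    centroid: dict[int, int] = field(default_factory=dict)  # cluster -> pose

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _medoid(members: np.ndarray, matrix: RmsdMatrix,
            scores: dict[int, float] | None) -> int:
    """Member minimizing mean RMSD to its co-members; ties by best
    (lowest) I_sc, then smallest index."""
    if len(members) == 1:
        return int(members[0])
    sub = matrix.values[np.ix_(members, members)]
    mean_rmsd = sub.sum(axis=1) / (len(members) - 1)
    best = mean_rmsd.min()
    tied = members[np.isclose(mean_rmsd, best, rtol=0.0, atol=1e-12)]
    if scores:
        tied = sorted(tied, key=lambda i: (scores.get(int(i), np.inf), int(i)))
    return int(tied[0])


def cluster_cutoff(matrix: RmsdMatrix, cutoff: float,
                   method: str = "single") -> ClusterResult:
    """Cluster poses at an RMSD cutoff.

    ``method="single"`` (default): connected components of the graph
    whose edges join pose pairs with RMSD <= cutoff — i.e. single-linkage
    agglomerative clustering cut at the threshold.  ``method="qt"``: a
    quality-threshold variant that repeatedly extracts the pose with the
    most cutoff-neighbours together with those neighbours.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if method not in ("single", "qt"):
        raise ParameterError(f"unknown clustering method {method!r}")
    n = len(matrix)
    adj = matrix.values <= cutoff
    np.fill_diagonal(adj, False)

    raw = np.full(n, -1, dtype=int)
    if method == "single":
        _, raw = connected_components(csr_matrix(adj), directed=False)
    else:
        remaining = np.ones(n, dtype=bool)
        next_id = 0
        while remaining.any():
            counts = (adj & remaining).sum(axis=1) * remaining
            seed = int(np.argmax(counts + remaining))  # ties -> smallest index
            group = np.flatnonzero((adj[seed] | (np.arange(n) == seed))
                                   & remaining)
            raw[group] = next_id
            remaining[group] = False
            next_id += 1

    # renumber by population desc, ties by smallest member index
    order = sorted(set(raw.tolist()),
                   key=lambda c: (-(raw == c).sum(),
                                  int(np.flatnonzero(raw == c)[0])))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    populations = {c: int((labels == c).sum()) for c in range(len(order))}
    result = ClusterResult(labels, populations)
    for c in populations:
        result.centroid[c] = _medoid(result.members(c), matrix, None)
    return result


def select_centroid(result: ClusterResult, matrix: RmsdMatrix,
                    scores: dict[int, float] | None = None) -> int:
    """Pose index of the representative model: the medoid of the most
    populated cluster.

    A population tie between clusters is broken in favour of the cluster
    containing the pose with the best (lowest) I_sc, then the cluster
    with the smallest member index; the medoid tie rule is best I_sc
    then smallest index.
    """
    if len(result.populations) == 0:
        raise ParameterError("empty cluster result")
    top_pop = max(result.populations.values())
    candidates = [c for c, p in result.populations.items() if p == top_pop]
    if len(candidates) > 1 and scores:
        def cluster_key(c: int) -> tuple[float, int]:
            members = result.members(c)
            best = min((scores.get(int(i), np.inf) for i in members),
                       default=np.inf)
            return (best, int(members[0]))
        candidates.sort(key=cluster_key)
    else:
        candidates.sort(key=lambda c: int(result.members(c)[0]))
    return _medoid(result.members(candidates[0]), matrix, scores)


# ----------------------------------------------------------- Ramachandran

#: Default coarse classification rectangles (phi_min, phi_max, psi_min,
#: psi_max) in degrees.  Favored covers the helical and sheet basins;
#: allowed adds a 20 degree margin around each favored rectangle.
FAVORED_REGIONS: tuple[tuple[float, float, float, float], ...] = (
    (-180.0, -30.0, -75.0, -5.0),    # helical
    (-180.0, -45.0, 90.0, 180.0),    # sheet
)
ALLOWED_MARGIN = 20.0


def _in_rect(phi: float, psi: float,
             rect: tuple[float, float, float, float],
             margin: float = 0.0) -> bool:
    lo_phi, hi_phi, lo_psi, hi_psi = rect
    lo_phi, hi_phi = max(lo_phi - margin, -180.0), min(hi_phi + margin, 180.0)
    lo_psi, hi_psi = lo_psi - margin, hi_psi + margin
    ok_phi = lo_phi <= phi <= hi_phi
    # psi rectangles may extend past +/-180; test the wrapped angle too
    ok_psi = any(lo_psi <= v <= hi_psi for v in (psi, psi - 360.0, psi + 360.0))
    return ok_phi and ok_psi


def _classify_phi_psi(phi: float, psi: float, resname: str,
                      regions=FAVORED_REGIONS,
                      margin: float = ALLOWED_MARGIN) -> str:
    if any(_in_rect(phi, psi, r) for r in regions):
        return "favored"
    if any(_in_rect(phi, psi, r, margin) for r in regions):
        return "allowed"
    # glycine/proline basins are not modelled; never call them outliers
    if resname in ("GLY", "PRO"):
        return "allowed"
    return "outlier"


def ramachandran(structure: Structure,
                 regions=FAVORED_REGIONS,
                 margin: float = ALLOWED_MARGIN
                 ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Backbone phi/psi per residue with a coarse rectangular
    classification.

    Chain termini (and residues with missing backbone atoms, which are
    logged) are classed ``undefined`` and excluded from the summary
    fractions.
    """
    records = []
    for chain in structure.chains():
        in_chain = structure.chain == chain
        resnums = sorted(set(structure.resnum[in_chain].tolist()))
        atom_pos: dict[tuple[int, str], np.ndarray] = {}
        for i in np.flatnonzero(in_chain):
            atom_pos[(int(structure.resnum[i]), str(structure.name[i]))] = \
                structure.coords[i]
        resname_of = {int(structure.resnum[i]): str(structure.resname[i])
                      for i in np.flatnonzero(in_chain)}
        for idx, resnum in enumerate(resnums):
            phi = psi = np.nan
            cls = "undefined"
            prev_ok = idx > 0 and resnums[idx - 1] == resnum - 1
            next_ok = idx + 1 < len(resnums) and resnums[idx + 1] == resnum + 1
            needed = [(resnum, a) for a in ("N", "CA", "C")]
            have_backbone = all(k in atom_pos for k in needed)
            if not have_backbone:
                logger.warning("chain %s residue %d: missing backbone atom; "
                               "classed undefined", chain, resnum)
            elif prev_ok and next_ok and \
                    (resnum - 1, "C") in atom_pos and (resnum + 1, "N") in atom_pos:
                phi = dihedral(atom_pos[(resnum - 1, "C")],
                               atom_pos[(resnum, "N")],
                               atom_pos[(resnum, "CA")],
                               atom_pos[(resnum, "C")])
                psi = dihedral(atom_pos[(resnum, "N")],
                               atom_pos[(resnum, "CA")],
                               atom_pos[(resnum, "C")],
                               atom_pos[(resnum + 1, "N")])
                cls = _classify_phi_psi(phi, psi, resname_of[resnum],
                                        regions, margin)
            records.append((chain, resnum, resname_of.get(resnum, ""),
                            phi, psi, cls))
    table = pd.DataFrame(records, columns=["chain", "resnum", "resname",
                                           "phi", "psi", "klass"])
    defined = table[table["klass"] != "undefined"]
    n_def = len(defined)
    summary = {
        "favored": float((defined["klass"] == "favored").sum() / n_def) if n_def else np.nan,
        "allowed": float((defined["klass"] == "allowed").sum() / n_def) if n_def else np.nan,
        "outlier": float((defined["klass"] == "outlier").sum() / n_def) if n_def else np.nan,
        "n_defined": n_def,
    }
    return table, summary
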
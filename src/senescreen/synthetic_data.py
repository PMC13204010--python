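"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the *shape* of one experimental input — a Co-IP
hit list crossed with annotation gene sets, a per-stimulus SASP-style
expression table, a docked pose ensemble with clustered structure, a
two-chain trajectory with scheduled interface contacts, and two-channel
microscopy fields with planted foci and controllable colocalization —
and records the truth it planted so downstream recovery is checkable by
independent recounting.

Design notes

* Identifiers are opaque uppercase symbols ``P0001``, ``P0002``, ...
* Chains are poly-alanine-like: N, CA, C, O, CB per residue — enough
  atoms for backbone RMSD, Ramachandran dihedrals, and heavy-atom
  contacts without rotamer modelling.
* Contact scheduling is exact (deterministic on/off frame assignment,
  shuffled by the seed), so recovered frequencies are exact rather than
  statistical; positional noise is a *truncated* Gaussian (clipped at
  3 sigma) so planted bound/unbound geometries can never cross the
  contact cutoff at the default noise scales.
* All randomness flows through one ``numpy`` Generator per call:
  repeated calls with the same seed are bit-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import GenerationError, ParameterError
from .geometry import build_peptide
from .structure import PoseEnsemble, Structure, Trajectory

# ------------------------------------------------------------------ triage


@dataclass
class TriageTruth:
    """Planted ground truth for the gene-set triage stage."""

    universe: list[str]
    sets: dict[str, set[str]]
    planted_candidates: list[str]           # members of >= k sets
    membership_counts: dict[str, int]       # true per-identifier count
    k: int
    planted_responders: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if not set(self.planted_candidates) <= uni:
            raise GenerationError("planted candidates outside the universe")
        if not set(self.planted_responders) <= set(self.planted_candidates):
            raise GenerationError("responders must be planted candidates")
        for ident in self.planted_candidates:
            if self.membership_counts[ident] < self.k:
                raise GenerationError(
                    f"{ident}: planted count below k={self.k}")


def gen_triage(n_universe: int, n_sets: int, k: int, n_planted: int,
               seed: int) -> TriageTruth:
    """Universe of symbols plus ``n_sets`` annotation sets arranged so
    that exactly ``n_planted`` identifiers belong to >= ``k`` sets and
    every other identifier to fewer."""
    if not (n_sets >= k >= 1):
        raise ParameterError(f"need n_sets >= k >= 1 (got {n_sets}, {k})")
    if not 0 <= n_planted <= n_universe:
        raise ParameterError("n_planted must be in [0, n_universe]")
    rng = np.random.default_rng(seed)
    universe = [f"P{i + 1:04d}" for i in range(n_universe)]
    planted = sorted(rng.choice(universe, size=n_planted, replace=False).tolist())
    planted_set = set(planted)
    set_names = [f"DB{i + 1}" for i in range(n_sets)]
    sets: dict[str, set[str]] = {name: set() for name in set_names}
    counts: dict[str, int] = {}
    for ident in universe:
        if ident in planted_set:
            c = int(rng.integers(k, n_sets + 1))
        else:
            c = int(rng.integers(0, k))
        counts[ident] = c
        for s in rng.choice(n_sets, size=c, replace=False):
            sets[set_names[s]].add(ident)
    return TriageTruth(universe, sets, planted, counts, k)


def gen_expression(candidates: Sequence[str], stimuli: Sequence[str],
                   upregulated: Sequence[str], lr_effect: float = 1.0,
                   q_signal: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Per-(protein, stimulus) expression table.

    Upregulated proteins receive ``logRatio >= lr_effect`` and
    ``qValue <= q_signal`` in every stimulus; all others get a log-ratio
    around 0 with ``qValue >= 0.2``, so threshold recovery is exact for
    any filter with ``q_max < 0.2``.
    """
    if not list(stimuli):
        raise ParameterError("need at least one stimulus")
    up = set(upregulated)
    if not up <= set(candidates):
        raise ParameterError("upregulated identifiers must be candidates")
    if lr_effect <= 0:
        raise ParameterError("lr_effect must be positive")
    if not 0 < q_signal < 1:
        raise ParameterError("q_signal must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for protein in candidates:
        for stim in stimuli:
            if protein in up:
                lr = lr_effect + abs(rng.normal(0.0, 0.25))
                q = q_signal * rng.uniform(0.05, 1.0)
            else:
                lr = rng.normal(0.0, 0.3)
                q = rng.uniform(0.2, 1.0)
            rows.append((protein, stim, float(lr), float(q)))
    return pd.DataFrame(rows, columns=["protein", "stimulus",
                                       "logRatio", "qValue"])


@dataclass
class StudyScenario:
    """The standard triage scenario: a 305-symbol hit list crossed with
    six sets, 22 planted multi-set candidates of which 10 respond under
    three senescence stimuli."""

    truth: TriageTruth
    expression: pd.DataFrame
    stimuli: tuple[str, ...]


def gen_study_scenario(seed: int, n_universe: int = 305, n_sets: int = 6,
                       k: int = 3, n_candidates: int = 22,
                       n_responders: int = 10,
                       stimuli: Sequence[str] = ("IR", "RAS", "ATV")
                       ) -> StudyScenario:
    if n_responders > n_candidates:
        raise ParameterError("n_responders cannot exceed n_candidates")
    truth = gen_triage(n_universe, n_sets, k, n_candidates, seed)
    rng = np.random.default_rng(seed + 1)
    responders = sorted(rng.choice(truth.planted_candidates,
                                   size=n_responders, replace=False).tolist())
    truth.planted_responders = responders
    expression = gen_expression(truth.planted_candidates, list(stimuli),
                                responders, lr_effect=1.0, q_signal=0.01,
                                seed=seed + 2)
    return StudyScenario(truth, expression, tuple(stimuli))


# ------------------------------------------------------------------- poses


@dataclass
class PoseTruth:
    """Planted ground truth for pose clustering."""

    ensemble: PoseEnsemble
    labels: np.ndarray                 # pose index -> planted cluster id
    centers: dict[int, np.ndarray]     # cluster -> zero-noise ligand coords
    center_pose: dict[int, int]        # cluster -> index of its zero-noise pose
    intra_max: float                   # max intra-cluster ligand RMSD
    inter_min: float                   # min inter-cluster ligand RMSD


def _ligand_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _lattice_directions(n: int) -> list[np.ndarray]:
    """First ``n`` distinct nonzero-ordered integer lattice points,
    nearest first; any two differ by at least one lattice unit."""
    pts = sorted(itertools.product(range(-2, 3), repeat=3),
                 key=lambda p: (sum(x * x for x in p), p))
    out = [np.array(p, dtype=float) for p in pts[:n]]
    if len(out) < n:
        raise ParameterError(f"too many clusters requested ({n})")
    return out


def gen_poses(n_clusters: int, per_cluster: int | Sequence[int],
              n_residues: int = 20, intra_sigma: float = 0.5,
              inter_sep: float = 15.0, seed: int = 0,
              max_attempts: int = 5) -> PoseTruth:
    """Rigid receptor (chain A) plus a ligand chain (B) displaced to one
    of ``n_clusters`` centers with isotropic coordinate noise.

    Cluster centers sit on an integer lattice scaled by ``inter_sep``,
    so planted inter-cluster ligand RMSD is at least ``inter_sep``.  The
    first pose generated for each cluster is the exact zero-noise
    center.  The generator verifies that the realized maximum
    intra-cluster RMSD stays strictly below the minimum inter-cluster
    RMSD and regenerates (bounded retries) on violation.
    """
    if inter_sep <= 4 * intra_sigma:
        raise ParameterError(
            "separability guard: need inter_sep > 4 * intra_sigma")
    if isinstance(per_cluster, (int, np.integer)):
        sizes = [int(per_cluster)] * n_clusters
    else:
        sizes = [int(s) for s in per_cluster]
        if len(sizes) != n_clusters:
            raise ParameterError("per_cluster list must match n_clusters")
    if min(sizes) < 1:
        raise ParameterError("every cluster needs at least one pose")

    receptor = build_peptide(n_residues, chain="A")
    ligand_template = build_peptide(n_residues, chain="B",
                                    origin=np.array([25.0, 0.0, 0.0]),
                                    start_resnum=n_residues + 1)
    directions = _lattice_directions(n_clusters)
    n_lig = ligand_template.n_atoms

    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + 100_000 * attempt)
        ligand_coords: list[np.ndarray] = []
        labels: list[int] = []
        centers: dict[int, np.ndarray] = {}
        first_of: dict[int, int] = {}
        for c, size in enumerate(sizes):
            center = ligand_template.coords + inter_sep * directions[c]
            centers[c] = center
            for m in range(size):
                noise = (0.0 if m == 0 else
                         rng.normal(0.0, intra_sigma, size=(n_lig, 3)))
                if m == 0:
                    first_of[c] = len(labels)
                ligand_coords.append(center + noise)
                labels.append(c)
        order = rng.permutation(len(labels))
        ligand_coords = [ligand_coords[i] for i in order]
        labels_arr = np.array([labels[i] for i in order])
        center_pose = {c: int(np.flatnonzero(order == first_of[c])[0])
                       for c in centers}

        n = len(labels_arr)
        intra_max, inter_min = 0.0, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                r = _ligand_rmsd(ligand_coords[i], ligand_coords[j])
                if labels_arr[i] == labels_arr[j]:
                    intra_max = max(intra_max, r)
                else:
                    inter_min = min(inter_min, r)
        if n > 1 and np.isfinite(inter_min) and intra_max >= inter_min:
            continue  # regenerate with a fresh stream

        poses = []
        scores: dict[int, float] = {}
        for i in range(n):
            merged = Structure(
                np.concatenate([receptor.chain, ligand_template.chain]),
                np.concatenate([receptor.resnum, ligand_template.resnum]),
                np.concatenate([receptor.resname, ligand_template.resname]),
                np.concatenate([receptor.name, ligand_template.name]),
                np.concatenate([receptor.element, ligand_template.element]),
                np.vstack([receptor.coords, ligand_coords[i]]),
                model_id=i + 1)
            poses.append(merged)
            scores[i] = float(rng.normal(-15.0, 2.0))
        return PoseTruth(PoseEnsemble(poses, scores), labels_arr, centers,
                         center_pose, intra_max,
                         float(inter_min) if np.isfinite(inter_min) else np.nan)
    raise GenerationError(
        "could not plant separable clusters within the retry budget; "
        "lower intra_sigma or raise inter_sep")


# -------------------------------------------------------------- trajectory


@dataclass
class TrajectoryTruth:
    """Planted ground truth for interface-contact analysis."""

    trajectory: Trajectory
    planted_contacts: list[tuple[int, int, float]]   # (res_a, res_b, target)
    realized: dict[tuple[int, int], float]           # exact on-fraction
    schedules: dict[tuple[int, int], np.ndarray]     # bool per frame


def _residue_block(chain: str, resnum: int, site: np.ndarray) -> Structure:
    res = build_peptide(1, chain=chain, start_resnum=resnum)
    return res.with_coords(res.coords - res.coords.mean(axis=0) + site)


def _solve_offset(template: np.ndarray, target: float) -> float:
    """x-offset between two copies of a centred residue template giving
    the requested minimum inter-atom distance (bisection)."""
    def min_dist(d: float) -> float:
        shifted = template + np.array([d, 0.0, 0.0])
        return float(np.min(np.linalg.norm(
            template[:, None, :] - shifted[None, :, :], axis=-1)))
    lo = float(np.ptp(template[:, 0])) + 1e-6
    hi = lo + target + 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gen_trajectory(n_frames: int,
                   planted_contacts: Sequence[tuple[int, int, float]],
                   noise_sigma: float = 0.0, seed: int = 0,
                   replica: str = "r1",
                   bound_distance: float = 4.0,
                   unbound_distance: float = 8.5) -> TrajectoryTruth:
    """Two-chain trajectory whose inter-chain residue pairs toggle
    between a bound geometry (minimum heavy-atom distance =
    ``bound_distance``, below the 5 Å cutoff) and an unbound geometry
    (``unbound_distance``, above cutoff + 2 Å) on an exact schedule
    hitting each pair's target frequency.

    Positional noise is Gaussian truncated at 3 sigma; with the default
    geometries any ``noise_sigma <= 0.2`` cannot flip a frame across the
    5 Å cutoff, keeping frequency recovery exact.  Residue numbers must
    be unique per chain across the planted pairs.
    """
    if n_frames < 1:
        raise ParameterError("need at least one frame")
    for a, b, f in planted_contacts:
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"target frequency {f} outside [0, 1]")
    res_a_list = [p[0] for p in planted_contacts]
    res_b_list = [p[1] for p in planted_contacts]
    if len(set(res_a_list)) != len(res_a_list) or \
            len(set(res_b_list)) != len(res_b_list):
        raise ParameterError(
            "planted residue numbers must be unique per chain")
    if noise_sigma < 0 or 6 * noise_sigma >= unbound_distance - bound_distance:
        raise ParameterError("noise_sigma too large for the planted margins")

    rng = np.random.default_rng(seed)
    template = build_peptide(1).coords
    template = template - template.mean(axis=0)
    d_on = _solve_offset(template, bound_distance)
    d_off = _solve_offset(template, unbound_distance)

    blocks: list[Structure] = []
    b_slice: dict[tuple[int, int], slice] = {}
    sites_a: dict[tuple[int, int], np.ndarray] = {}
    offset = 0
    spacing = 40.0
    for p, (ra, rb, _) in enumerate(planted_contacts):
        site = np.array([0.0, spacing * p, 0.0])
        blk_a = _residue_block("A", ra, site)
        blocks.append(blk_a)
        offset += blk_a.n_atoms
        blk_b = _residue_block("B", rb, site + np.array([d_off, 0.0, 0.0]))
        blocks.append(blk_b)
        b_slice[(ra, rb)] = slice(offset, offset + blk_b.n_atoms)
        sites_a[(ra, rb)] = site
        offset += blk_b.n_atoms
    # one distant spectator residue per chain, never in contact
    far = np.array([0.0, -spacing, 0.0])
    spectator_a = _residue_block("A", max(res_a_list, default=0) + 50, far)
    spectator_b = _residue_block("B", max(res_b_list, default=0) + 50,
                                 far + np.array([3 * spacing, 0.0, 0.0]))
    blocks.extend([spectator_a, spectator_b])

    topo = Structure(
        np.concatenate([b.chain for b in blocks]),
        np.concatenate([b.resnum for b in blocks]),
        np.concatenate([b.resname for b in blocks]),
        np.concatenate([b.name for b in blocks]),
        np.concatenate([b.element for b in blocks]),
        np.vstack([b.coords for b in blocks]))

    schedules: dict[tuple[int, int], np.ndarray] = {}
    realized: dict[tuple[int, int], float] = {}
    for ra, rb, freq in planted_contacts:
        n_on = int(round(freq * n_frames))
        sched = np.zeros(n_frames, dtype=bool)
        sched[rng.permutation(n_frames)[:n_on]] = True
        schedules[(ra, rb)] = sched
        realized[(ra, rb)] = n_on / n_frames

    base = topo.coords
    frames = np.empty((n_frames, topo.n_atoms, 3))
    shift = d_on - d_off
    for f in range(n_frames):
        coords = base.copy()
        for (ra, rb, _freq) in planted_contacts:
            if schedules[(ra, rb)][f]:
                coords[b_slice[(ra, rb)], 0] += shift
        if noise_sigma > 0:
            noise = rng.normal(0.0, noise_sigma, size=coords.shape)
            coords += np.clip(noise, -3 * noise_sigma, 3 * noise_sigma)
        frames[f] = coords
    traj = Trajectory(topo, frames, replica=replica)
    return TrajectoryTruth(traj, list(planted_contacts), realized, schedules)


def gen_replica_trajectories(n_frames: int,
                             shared_pairs: Sequence[tuple[int, int, float]],
                             private_pairs: Sequence[Sequence[tuple[int, int, float]]],
                             noise_sigma: float = 0.0,
                             seed: int = 0) -> list[TrajectoryTruth]:
    """One trajectory per replica: every replica carries the shared
    planted pairs plus its own private decoy pairs."""
    out = []
    for i, private in enumerate(private_pairs):
        out.append(gen_trajectory(
            n_frames, list(shared_pairs) + list(private),
            noise_sigma=noise_sigma, seed=seed + 1000 * i,
            replica=f"r{i + 1}"))
    return out


# ------------------------------------------------------------------ images


@dataclass
class ImageTruth:
    """Planted ground truth for the imaging readouts."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    nuclei_mask: np.ndarray
    planted_foci: pd.DataFrame      # x, y, cell, area (at half-max), peak
    planted_coloc: float
    half_max_threshold: float

    def __post_init__(self) -> None:
        h, w = self.channel_a.shape
        for _, row in self.planted_foci.iterrows():
            if not (0 <= row["y"] < h and 0 <= row["x"] < w):
                raise GenerationError("planted focus outside the image")
            if int(row["cell"]) not in np.unique(self.nuclei_mask):
                raise GenerationError("planted focus references a missing cell")


def _render_spot(shape: tuple[int, int], cy: float, cx: float,
                 sigma: float, amplitude: float,
                 radius: int = 12) -> tuple[np.ndarray, int]:
    """Render one Gaussian spot into a fresh image; return the image and
    the spot's pixel area at the half-maximum level."""
    img = np.zeros(shape)
    r0, r1 = max(0, int(cy) - radius), min(shape[0], int(cy) + radius + 1)
    c0, c1 = max(0, int(cx) - radius), min(shape[1], int(cx) + radius + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    patch = amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                               / (2 * sigma ** 2))
    img[r0:r1, c0:c1] = patch
    area = int(np.count_nonzero(patch >= amplitude / 2))
    return img, area


def gen_images(shape: tuple[int, int] = (512, 512),
               foci_per_cell: Sequence[int] = (5, 5, 5),
               coloc: float = 1.0, noise_sigma: float = 0.0,
               seed: int = 0, cell_radius: int = 24,
               spot_sigma: float = 2.0, spot_amplitude: float = 1000.0,
               min_spot_separation: float = 12.0,
               max_tries: int = 5000) -> ImageTruth:
    """Two-channel field with labelled nuclei and planted foci.

    Nuclei are non-overlapping labelled disks (one per entry of
    ``foci_per_cell``); foci are Gaussian spots planted inside their
    nucleus with a minimum mutual separation, rendered into channel A.
    Channel B shares a ``coloc`` fraction of channel A's structure plus
    an independent blob field scaled by ``1 - coloc``; Gaussian read
    noise (clipped at zero intensity) is added to both when
    ``noise_sigma > 0``.  At ``coloc=1`` and zero noise the channels are
    identical, so Pearson r is exactly 1.
    """
    if not 0.0 <= coloc <= 1.0:
        raise ParameterError("coloc must be in [0, 1]")
    n_cells = len(foci_per_cell)
    if n_cells < 1:
        raise ParameterError("need at least one cell")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = cell_radius + 4

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n_cells} non-overlapping nuclei in "
                f"{shape} within {max_tries} tries")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all(np.hypot(cy - oy, cx - ox) > 2 * cell_radius + 6
               for oy, ox in centers):
            centers.append((cy, cx))

    nuclei = np.zeros(shape, dtype=np.uint16)
    yy, xx = np.mgrid[0:h, 0:w]
    for lbl, (cy, cx) in enumerate(centers, start=1):
        nuclei[(yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius ** 2] = lbl

    channel_a = np.zeros(shape)
    foci_rows = []
    placed: list[tuple[float, float]] = []
    for lbl, (count, (cy, cx)) in enumerate(zip(foci_per_cell, centers),
                                            start=1):
        for _ in range(int(count)):
            for attempt in range(max_tries):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, cell_radius - 6)
                fy, fx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                if all(np.hypot(fy - oy, fx - ox) >= min_spot_separation
                       for oy, ox in placed):
                    break
            else:
                raise GenerationError(
                    "could not place separated foci; reduce counts or "
                    "separation")
            placed.append((fy, fx))
            spot, area = _render_spot(shape, fy, fx, spot_sigma,
                                      spot_amplitude)
            channel_a += spot
            foci_rows.append((float(fx), float(fy), lbl, area,
                              float(spot_amplitude)))

    # independent structure for the non-colocalized part of channel B
    independent = np.zeros(shape)
    for _ in range(3 * n_cells):
        by = rng.uniform(margin, h - margin)
        bx = rng.uniform(margin, w - margin)
        blob, _ = _render_spot(shape, by, bx, 6.0, 300.0, radius=24)
        independent += blob

    channel_b = coloc * channel_a + (1.0 - coloc) * independent
    if noise_sigma > 0:
        channel_a = np.clip(
            channel_a + rng.normal(0, noise_sigma, shape), 0, None)
        channel_b = np.clip(
            channel_b + rng.normal(0, noise_sigma, shape), 0, None)

    foci = pd.DataFrame(foci_rows, columns=["x", "y", "cell", "area", "peak"])
    return ImageTruth(channel_a, channel_b, nuclei, foci, coloc,
                      spot_amplitude / 2)


# ----------------------------------------------------------------- writers


def write_gene_list(path: str | Path, identifiers: Sequence[str]) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in identifiers))


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]],
              provenance: Mapping[str, str] | None = None) -> None:
    provenance = provenance or {}
    with open(path, "w") as out:
        for name, members in sets.items():
            desc = provenance.get(name, "synthetic")
            out.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_expression_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False,
                 columns=["protein", "stimulus", "logRatio", "qValue"])


def write_image_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write an intensity image as 16-bit TIFF (clipped and rounded)."""
    data = np.clip(np.round(np.asarray(image)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint16))
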
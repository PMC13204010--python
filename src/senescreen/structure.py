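"""Molecular structures, pose ensembles, trajectories, and PDB I/O.

A :class:`Structure` stores one conformation as parallel numpy arrays
(one entry per atom).  Multi-model PDB files — the exchange format for
both docked pose ensembles and MD trajectories here — are read and
written with a fixed-width PDB v3.3 dialect:

* only ``ATOM``/``HETATM``, ``MODEL``/``ENDMDL``, ``TER`` and ``END``
  records are interpreted;
* altloc indicators other than blank or ``'A'`` are dropped with a
  warning;
* insertion codes are rejected with a :class:`~senescreen.errors.FormatError`
  (the synthetic and modelled structures handled here never carry them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Atomic masses (u) for mass-weighted centres of mass.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}
DEFAULT_MASS = 12.011

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Structure:
    """One conformation: ordered atom records with coordinates in Å."""

    chain: np.ndarray      # (n,) str
    resnum: np.ndarray     # (n,) int
    resname: np.ndarray    # (n,) str
    name: np.ndarray       # (n,) str, atom names
    element: np.ndarray    # (n,) str
    coords: np.ndarray     # (n, 3) float
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError("coords must be an (n, 3) array")
        if not np.isfinite(self.coords).all():
            raise ParameterError("coordinates must be finite")
        for attr in ("chain", "resnum", "resname", "name", "element"):
            setattr(self, attr, np.asarray(getattr(self, attr)))

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """(chain, residue number, atom name) identity of every atom, in order."""
        return list(zip(self.chain.tolist(),
                        self.resnum.tolist(),
                        self.name.tolist()))

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain.tolist():
            seen.setdefault(c, None)
        return list(seen)

    def mask(self, predicate: "AtomPredicate") -> np.ndarray:
        m = np.asarray(predicate(self), dtype=bool)
        if m.shape != (self.n_atoms,):
            raise ParameterError("atom predicate must return one flag per atom")
        return m

    def subset(self, predicate: "AtomPredicate") -> "Structure":
        m = self.mask(predicate)
        return Structure(self.chain[m], self.resnum[m], self.resname[m],
                         self.name[m], self.element[m], self.coords[m],
                         model_id=self.model_id)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        return Structure(self.chain, self.resnum, self.resname, self.name,
                         self.element, np.asarray(coords, dtype=float),
                         model_id=self.model_id if model_id is None else model_id)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS.get(e, DEFAULT_MASS) for e in self.element])


AtomPredicate = Callable[[Structure], np.ndarray]


# ---------------------------------------------------------------- selections

def sel_all(s: Structure) -> np.ndarray:
    return np.ones(s.n_atoms, dtype=bool)


def sel_chain(*chains: str) -> AtomPredicate:
    def pred(s: Structure) -> np.ndarray:
        return np.isin(s.chain, list(chains))
    return pred


def sel_name(*names: str) -> AtomPredicate:
    def pred(s: Structure) -> np.ndarray:
        return np.isin(s.name, list(names))
    return pred


def sel_ca(s: Structure) -> np.ndarray:
    return s.name == "CA"


def sel_backbone(s: Structure) -> np.ndarray:
    return np.isin(s.name, list(BACKBONE_ATOMS))


def sel_heavy(s: Structure) -> np.ndarray:
    return s.element != "H"


def sel_and(*preds: AtomPredicate) -> AtomPredicate:
    def pred(s: Structure) -> np.ndarray:
        m = np.ones(s.n_atoms, dtype=bool)
        for p in preds:
            m &= s.mask(p)
        return m
    return pred


# ------------------------------------------------------------------ ensembles

@dataclass
class PoseEnsemble:
    """Ordered same-topology poses, optionally scored (Rosetta I_sc, lower
    is better)."""

    poses: list[Structure]
    scores: dict[int, float] | None = None  # pose index -> I_sc

    def __post_init__(self) -> None:
        if not self.poses:
            raise ParameterError("ensemble must contain at least one pose")
        ref = self.poses[0].atom_keys()
        for i, pose in enumerate(self.poses[1:], start=1):
            if pose.atom_keys() != ref:
                raise FormatError(
                    f"pose {i + 1} (model {pose.model_id}) does not share "
                    f"the ensemble topology")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class Trajectory:
    """Fixed-topology frames of coordinates for a (typically two-chain)
    complex; tagged with the replica it came from."""

    topology: Structure
    frames: np.ndarray                    # (n_frames, n_atoms, 3)
    replica: str = "r1"
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ParameterError(
                "frames must be (n_frames, n_atoms, 3) matching the topology")
        if not self.replica:
            raise ParameterError("replica id must be non-empty")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i], model_id=i + 1)


# -------------------------------------------------------------------- PDB I/O

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if icode.strip():
        raise FormatError(
            f"insertion codes are not supported (line {lineno}: icode {icode!r})")
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1]
    return name, altloc, resname, chain, resseq, x, y, z, element


def read_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a (multi-model) PDB file, in file order.

    A file without MODEL records yields a single structure.
    """
    path = Path(path)
    models: list[Structure] = []
    rec: dict[str, list] = {k: [] for k in
                            ("chain", "resnum", "resname", "name", "element")}
    xyz: list[list[float]] = []
    model_id = 1
    in_model = False
    dropped_altloc = 0

    def flush(mid: int) -> None:
        if not xyz:
            return
        models.append(Structure(
            np.array(rec["chain"]), np.array(rec["resnum"], dtype=int),
            np.array(rec["resname"]), np.array(rec["name"]),
            np.array(rec["element"]), np.array(xyz, dtype=float),
            model_id=mid))
        for v in rec.values():
            v.clear()
        xyz.clear()

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                flush(model_id)
                try:
                    model_id = int(line[6:].split()[0])
                except (IndexError, ValueError):
                    model_id = len(models) + 1
                in_model = True
            elif record == "ENDMDL":
                flush(model_id)
                in_model = False
            elif record in ("ATOM", "HETATM"):
                (name, altloc, resname, chain, resseq,
                 x, y, z, element) = _parse_atom_line(line, lineno)
                if altloc not in (" ", "A"):
                    dropped_altloc += 1
                    continue
                rec["chain"].append(chain)
                rec["resnum"].append(resseq)
                rec["resname"].append(resname)
                rec["name"].append(name)
                rec["element"].append(element)
                xyz.append([x, y, z])
    flush(model_id if in_model else len(models) + 1)
    if dropped_altloc:
        logger.warning("%s: dropped %d alternate-location atoms",
                       path.name, dropped_altloc)
    if not models:
        raise FormatError(f"{path}: no atom records found")
    return models


def check_shared_topology(models: Sequence[Structure]) -> None:
    """Raise :class:`FormatError` naming the first model whose atoms do not
    match model 1."""
    ref = models[0].atom_keys()
    for m in models[1:]:
        if m.atom_keys() != ref:
            raise FormatError(
                f"model {m.model_id} does not match the topology of model "
                f"{models[0].model_id} "
                f"({m.n_atoms} vs {models[0].n_atoms} atoms or differing records)")


def _format_atom_name(name: str) -> str:
    # PDB v3.3: element-aligned names start in column 14 unless 4 chars wide
    return name.ljust(4) if len(name) == 4 else f" {name:<3s}"


def write_models(path: str | Path,
                 models: Iterable[Structure]) -> None:
    """Write structures as a multi-model PDB (MODEL/ENDMDL blocks, TER
    between chains)."""
    path = Path(path)
    with open(path, "w") as out:
        for idx, s in enumerate(models, start=1):
            out.write(f"MODEL     {idx:4d}\n")
            serial = 0
            prev_chain = None
            for i in range(s.n_atoms):
                if prev_chain is not None and s.chain[i] != prev_chain:
                    out.write("TER\n")
                prev_chain = s.chain[i]
                serial += 1
                x, y, z = s.coords[i]
                out.write(
                    "ATOM  {serial:5d} {name}{alt}{res:>3s} {ch}{num:4d}{ic}"
                    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                    "          {el:>2s}\n".format(
                        serial=serial, name=_format_atom_name(str(s.name[i])),
                        alt=" ", res=str(s.resname[i])[:3],
                        ch=str(s.chain[i])[:1], num=int(s.resnum[i]), ic=" ",
                        x=x, y=y, z=z, occ=1.0, b=0.0,
                        el=str(s.element[i])[:2]))
            out.write("TER\nENDMDL\n")
        out.write("END\n")


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    write_models(path, (traj.frame(i) for i in range(traj.n_frames)))
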
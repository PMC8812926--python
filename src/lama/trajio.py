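"""Trajectory/topology I/O and atom selections.

Coordinates are handled in Å throughout (PDB convention) and times in ps.
Three on-disk formats are supported:

* multi-frame PDB (``MODEL``/``ENDMDL`` records) — the canonical interchange,
  read and written through :mod:`biotite.structure.io.pdb`;
* XYZ — a minimal text format (atom count, comment, ``name x y z`` lines);
* a chunked binary coordinate archive (extension ``.bca``) — the fast path
  for desk-scale ensembles, a small struct header followed by raw frames.

A :class:`Topology` carries per-atom records plus named selection groups
(e.g. ``ligand_heavy``, ``headgroup_oxygens``) and marker pairs such as the
Cα residues flanking a transmembrane gap.  Selections use a mini-grammar::

    group ligand_heavy
    resid 161 and name CA
    not (group ligand_heavy or name CA)
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import FormatError, SelectionError, ValidationError

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "select",
    "read_topology",
    "read_ensemble",
    "write_trajectory",
    "write_ensemble",
]

_BCA_MAGIC = b"LBCA"
_BCA_DTYPES = {0: np.float32, 1: np.float64}
_BCA_CODES = {np.dtype(np.float32): 0, np.dtype(np.float64): 1}


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom records plus named selection groups.

    Parameters
    ----------
    names, resnames, chains
        Per-atom atom name, residue name and chain identifier.
    resids
        Per-atom residue number (follows the input file verbatim; no
        renumbering).
    groups
        Named selections as sorted integer atom-index arrays, e.g.
        ``{"ligand_heavy": [12, 13], "headgroup_oxygens": [14]}``.
    markers
        Named residue-number pairs used for gap measurements, e.g.
        ``{"gate": (161, 195)}``.
    """

    names: list[str]
    resnames: list[str]
    resids: list[int]
    chains: list[str]
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    markers: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.resnames) == len(self.resids) == len(self.chains) == n):
            raise ValidationError("per-atom record arrays must share a length")
        # a residue number must identify a single residue within its chain
        seen: dict[tuple[str, int], str] = {}
        for rn, ri, ch in zip(self.resnames, self.resids, self.chains):
            key = (ch, int(ri))
            if key in seen and seen[key] != rn:
                raise ValidationError(
                    f"residue number {ri} in chain {ch!r} maps to both "
                    f"{seen[key]!r} and {rn!r}"
                )
            seen[key] = rn
        clean = {}
        for gname, idx in self.groups.items():
            arr = np.asarray(idx, dtype=np.intp)
            if arr.size == 0:
                raise ValidationError(f"selection group {gname!r} is empty")
            if arr.min() < 0 or arr.max() >= n:
                raise ValidationError(f"group {gname!r} has out-of-range atom indices")
            clean[gname] = np.unique(arr)
        self.groups = clean

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(self, expression: str) -> np.ndarray:
        return select(self, expression)


# ---------------------------------------------------------------------------
# Ensemble container
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames for many independent trajectories.

    ``coords`` is a list of ``(n_frames, n_atoms, 3)`` float arrays in Å, one
    per trajectory; all trajectories share atom count and ordering.
    ``frame_interval_ps`` is the uniform time between successive frames.
    """

    coords: list[np.ndarray]
    frame_interval_ps: float = 10.0
    ids: list[str] | None = None
    topology: Topology | None = None

    def __post_init__(self) -> None:
        if not self.coords:
            raise ValidationError("ensemble must contain at least one trajectory")
        self.coords = [np.asarray(c, dtype=float) for c in self.coords]
        n_atoms = self.coords[0].shape[1] if self.coords[0].ndim == 3 else None
        for i, c in enumerate(self.coords):
            if c.ndim != 3 or c.shape[2] != 3:
                raise ValidationError(
                    f"trajectory {i}: expected shape (n_frames, n_atoms, 3), got {c.shape}"
                )
            if c.shape[1] != n_atoms:
                raise ValidationError(
                    f"trajectory {i}: atom count {c.shape[1]} != {n_atoms}"
                )
            if not np.all(np.isfinite(c)):
                raise ValidationError(f"trajectory {i}: non-finite coordinates")
        if self.frame_interval_ps <= 0:
            raise ValidationError("frame_interval_ps must be > 0")
        if self.ids is None:
            self.ids = [f"traj{i:04d}" for i in range(len(self.coords))]
        if len(self.ids) != len(self.coords):
            raise ValidationError("one id per trajectory required")
        if self.topology is not None and self.topology.n_atoms != n_atoms:
            raise ValidationError(
                f"topology has {self.topology.n_atoms} atoms, frames have {n_atoms}"
            )

    @property
    def n_trajectories(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return self.coords[0].shape[1]

    @property
    def n_frames_total(self) -> int:
        return sum(c.shape[0] for c in self.coords)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All frames stacked, with (trajectory index, frame index) bookkeeping."""
        xyz = np.concatenate(self.coords, axis=0)
        traj_idx = np.concatenate(
            [np.full(c.shape[0], i, dtype=np.intp) for i, c in enumerate(self.coords)]
        )
        frame_idx = np.concatenate(
            [np.arange(c.shape[0], dtype=np.intp) for c in self.coords]
        )
        return xyz, traj_idx, frame_idx


# ---------------------------------------------------------------------------
# Selection mini-grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][\w']*|-?\d+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            if expression[pos:].strip() == "":
                break
            raise SelectionError(
                f"unknown token at position {pos}: {expression[pos:pos + 10]!r}"
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser producing a boolean atom mask."""

    def __init__(self, topology: Topology, tokens: list[tuple[str, int]]):
        self.top = topology
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def take(self) -> tuple[str, int]:
        if self.i >= len(self.tokens):
            raise SelectionError("unexpected end of expression")
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.i != len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise SelectionError(f"unexpected token {tok!r} at position {pos}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok, pos = self.take()
        if tok == "not":
            return ~self.factor()
        if tok == "(":
            mask = self.expr()
            tok2, pos2 = self.take()
            if tok2 != ")":
                raise SelectionError(f"expected ')' at position {pos2}")
            return mask
        if tok == "group":
            gname, gpos = self.take()
            if gname not in self.top.groups:
                raise SelectionError(f"unknown group {gname!r} at position {gpos}")
            mask = np.zeros(self.top.n_atoms, dtype=bool)
            mask[self.top.groups[gname]] = True
            return mask
        if tok == "resid":
            val, vpos = self.take()
            try:
                rid = int(val)
            except ValueError:
                raise SelectionError(f"resid expects an integer at position {vpos}")
            return np.array([r == rid for r in self.top.resids])
        if tok == "name":
            val, _ = self.take()
            return np.array([nm == val for nm in self.top.names])
        raise SelectionError(f"unknown token {tok!r} at position {pos}")


def select(topology: Topology, expression: str) -> np.ndarray:
    """Resolve a selection expression to a sorted atom-index array.

    An expression resolving to no atoms raises :class:`SelectionError`
    (not an empty list) to catch typos early.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(topology, tokens).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return idx.astype(np.intp)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _topology_to_atom_array(topology: Topology, coord: np.ndarray):
    import biotite.structure as struc

    atoms = struc.AtomArray(topology.n_atoms)
    atoms.coord = np.asarray(coord, dtype=np.float32)
    atoms.atom_name = np.array(topology.names, dtype="U6")
    atoms.res_name = np.array(topology.resnames, dtype="U5")
    atoms.res_id = np.array(topology.resids, dtype=int)
    atoms.chain_id = np.array(topology.chains, dtype="U4")
    atoms.element = np.array(
        [re.sub(r"\d", "", nm)[:1] or "C" for nm in topology.names], dtype="U2"
    )
    return atoms


def _write_pdb(coords: np.ndarray, topology: Topology, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    stack = struc.stack(
        [_topology_to_atom_array(topology, frame) for frame in coords]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _read_pdb(path: Path) -> tuple[np.ndarray, Topology]:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:  # biotite reports the offending line
        raise FormatError(f"{path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    top = Topology(
        names=list(stack.atom_name),
        resnames=list(stack.res_name),
        resids=[int(r) for r in stack.res_id],
        chains=list(stack.chain_id),
    )
    return coords, top


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _write_xyz(coords: np.ndarray, topology: Topology | None, path: Path) -> None:
    n_frames, n_atoms = coords.shape[:2]
    names = topology.names if topology is not None else ["X"] * n_atoms
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n_atoms}\nframe {f}\n")
            for a in range(n_atoms):
                x, y, z = coords[f, a]
                fh.write(f"{names[a]:<4s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def _read_xyz(path: Path) -> tuple[np.ndarray, Topology]:
    frames: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: expected atom count at line {i + 1}")
        if i + 1 + n_atoms >= len(lines) + 1:
            raise FormatError(f"{path}: truncated frame starting at line {i + 1}")
        frame = np.empty((n_atoms, 3))
        first = not frames
        for a in range(n_atoms):
            lineno = i + 2 + a
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: unparseable record at line {lineno + 1}")
            if first:
                names.append(parts[0])
            try:
                frame[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FormatError(f"{path}: unparseable record at line {lineno + 1}")
        frames.append(frame)
        i += 2 + n_atoms
    if not frames:
        raise FormatError(f"{path}: no frames found")
    arr = np.stack(frames)
    top = Topology(
        names=names,
        resnames=["UNK"] * len(names),
        resids=list(range(1, len(names) + 1)),
        chains=["A"] * len(names),
    )
    return arr, top


# ---------------------------------------------------------------------------
# Binary coordinate archive (.bca)
# ---------------------------------------------------------------------------

def _write_bca(coords: np.ndarray, path: Path, dtype=np.float64) -> None:
    arr = np.ascontiguousarray(coords, dtype=dtype)
    n_frames, n_atoms = arr.shape[:2]
    with open(path, "wb") as fh:
        fh.write(_BCA_MAGIC)
        fh.write(struct.pack("<HHQQ", 1, _BCA_CODES[arr.dtype], n_frames, n_atoms))
        arr.tofile(fh)


def _read_bca(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _BCA_MAGIC:
            raise FormatError(f"{path}: not a binary coordinate archive")
        version, dcode, n_frames, n_atoms = struct.unpack("<HHQQ", fh.read(20))
        if version != 1 or dcode not in _BCA_DTYPES:
            raise FormatError(f"{path}: unsupported archive version/dtype")
        data = np.fromfile(fh, dtype=_BCA_DTYPES[dcode])
    expected = n_frames * n_atoms * 3
    if data.size != expected:
        raise FormatError(
            f"{path}: expected {expected} coordinate values, found {data.size}"
        )
    return data.reshape(n_frames, n_atoms, 3).astype(float)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_topology(path: str | Path) -> Topology:
    """Read a topology from the first frame of a PDB or XYZ file."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".pdb":
        return _read_pdb(path)[1]
    if ext == ".xyz":
        return _read_xyz(path)[1]
    raise FormatError(f"cannot derive a topology from {ext!r} files")


def _read_any(path: Path, topology: Topology | None) -> tuple[np.ndarray, Topology | None]:
    ext = path.suffix.lower()
    if ext == ".pdb":
        coords, top = _read_pdb(path)
    elif ext == ".xyz":
        coords, top = _read_xyz(path)
    elif ext == ".bca":
        coords, top = _read_bca(path), topology
    else:
        raise FormatError(f"{path}: unrecognised trajectory extension {ext!r}")
    return coords, top


def read_ensemble(
    paths: Sequence[str | Path],
    topology: Topology | str | Path | None = None,
    frame_interval_ps: float = 10.0,
) -> TrajectoryEnsemble:
    """Read one trajectory per file into a :class:`TrajectoryEnsemble`.

    Formats (PDB / XYZ / ``.bca``) are auto-detected by extension and may be
    mixed across files but not within one.  Atom ordering is validated
    against the topology; a mismatch names the file and both counts.
    """
    if topology is not None and not isinstance(topology, Topology):
        topology = read_topology(topology)
    coords, ids = [], []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FormatError(f"{p}: file not found")
        arr, file_top = _read_any(p, topology)
        if topology is None and file_top is not None:
            topology = file_top
        if topology is not None and arr.shape[1] != topology.n_atoms:
            raise FormatError(
                f"{p}: atom-count mismatch (expected {topology.n_atoms}, "
                f"found {arr.shape[1]})"
            )
        coords.append(arr)
        ids.append(p.stem)
    return TrajectoryEnsemble(
        coords=coords,
        frame_interval_ps=frame_interval_ps,
        ids=ids,
        topology=topology,
    )


def write_trajectory(
    coords: np.ndarray,
    path: str | Path,
    topology: Topology | None = None,
) -> None:
    """Write one trajectory; format chosen by extension (.pdb/.xyz/.bca)."""
    path = Path(path)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    ext = path.suffix.lower()
    if ext == ".pdb":
        if topology is None:
            raise ValidationError("PDB output requires a topology")
        _write_pdb(coords, topology, path)
    elif ext == ".xyz":
        _write_xyz(coords, topology, path)
    elif ext == ".bca":
        _write_bca(coords, path)
    else:
        raise FormatError(f"unrecognised trajectory extension {ext!r}")


def write_ensemble(
    ensemble: TrajectoryEnsemble, outdir: str | Path, fmt: str = "pdb"
) -> list[Path]:
    """Write every trajectory of the ensemble to ``outdir`` as ``<id>.<fmt>``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj_id, coords in zip(ensemble.ids, ensemble.coords):
        p = outdir / f"{traj_id}.{fmt}"
        write_trajectory(coords, p, ensemble.topology)
        paths.append(p)
    return paths
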
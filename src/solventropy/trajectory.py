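"""Trajectory containers and I/O.

Two on-disk representations are supported:

* an internal, lossless container: a ``.npy`` array of float64 coordinates
  with a JSON metadata sidecar (``<path>.meta.json``) carrying box edge,
  stride, seed, replicate id and the generating simulation spec;
* read-only support for the CHARMM/NAMD DCD dialect (Fortran-record binary,
  ``CORD`` magic, both endiannesses), restricted to cubic / no-unit-cell
  variants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Optional

import numpy as np

__all__ = ["Frame", "Trajectory", "write_trajectory", "read_trajectory", "read_dcd", "thin_frames"]

_DCD_MAGIC = b"CORD"


@dataclass(frozen=True)
class Frame:
    """One snapshot of solvent coordinates (Å) in a cubic periodic box."""

    coordinates: np.ndarray  # (N, 3)
    box_edge: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coordinates must be (N, 3), got {c.shape}")
        object.__setattr__(self, "coordinates", c)


@dataclass
class Trajectory:
    """Ordered frames of solvent coordinates sharing one cubic box.

    ``coordinates`` has shape (F, N, 3).  ``stride`` records the sweep (or
    frame-saving) interval used when generating/thinning; ``seed`` and
    ``replicate_id`` carry provenance.  ``spec`` is an optional reference to
    the generating :class:`~solventropy.engine.SimulationSpec`.
    """

    coordinates: np.ndarray
    box_edge: float
    stride: int = 1
    seed: Optional[int] = None
    replicate_id: int = 0
    spec: Any = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"coordinates must be (F, N, 3), got {c.shape}")
        if c.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.box_edge <= 0:
            raise ValueError(f"box_edge must be positive, got {self.box_edge}")
        self.coordinates = c

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.box_edge)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self[i]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Serialize a trajectory losslessly: .npy coordinates + JSON sidecar."""
    path = Path(path)
    if traj.n_frames < 1:
        raise ValueError("refusing to write an empty trajectory")
    meta: dict[str, Any] = {
        "format_version": 1,
        "box_edge": traj.box_edge,
        "stride": traj.stride,
        "seed": traj.seed,
        "replicate_id": traj.replicate_id,
    }
    if traj.spec is not None and hasattr(traj.spec, "to_dict"):
        meta["spec"] = traj.spec.to_dict()
    with open(path, "wb") as fh:
        np.save(fh, traj.coordinates)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; bit-stable round trip."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    version = meta.get("format_version")
    if version != 1:
        raise ValueError(f"unsupported trajectory format version {version!r}")
    with open(path, "rb") as fh:
        coords = np.load(fh)
    spec = None
    if "spec" in meta:
        from .engine import SimulationSpec

        spec = SimulationSpec.from_dict(meta["spec"])
    return Trajectory(
        coordinates=coords,
        box_edge=float(meta["box_edge"]),
        stride=int(meta["stride"]),
        seed=meta.get("seed"),
        replicate_id=int(meta.get("replicate_id", 0)),
        spec=spec,
    )


def _read_record(fh, order: str) -> bytes:
    head = fh.read(4)
    if len(head) < 4:
        raise EOFError("truncated record marker")
    (nbytes,) = np.frombuffer(head, dtype=np.dtype(np.int32).newbyteorder(order))
    if nbytes < 0 or nbytes > 1 << 30:
        raise ValueError(f"implausible Fortran record length {nbytes}")
    payload = fh.read(int(nbytes))
    if len(payload) < nbytes:
        raise EOFError("truncated record payload")
    tail = fh.read(4)
    if len(tail) < 4:
        raise EOFError("truncated record trailer")
    (nbytes2,) = np.frombuffer(tail, dtype=np.dtype(np.int32).newbyteorder(order))
    if nbytes2 != nbytes:
        raise ValueError("mismatched Fortran record markers")
    return payload


def read_dcd(path: str | Path, box_edge: Optional[float] = None) -> Trajectory:
    """Read a CHARMM/NAMD-dialect DCD file.

    Endianness is auto-detected from the header record length.  When the
    CHARMM unit-cell flag is set, the per-frame cell record overrides
    ``box_edge`` (cells must be cubic); otherwise ``box_edge`` is required.
    Coordinates are wrapped into the primary cell [0, L).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise ValueError(f"{path}: not a DCD file (too short)")
        order = "<"
        (n,) = np.frombuffer(head, dtype=np.dtype(np.int32).newbyteorder("<"))
        if n != 84:
            (n,) = np.frombuffer(head, dtype=np.dtype(np.int32).newbyteorder(">"))
            if n != 84:
                raise ValueError(f"{path}: bad DCD header record length {n}")
            order = ">"
        fh.seek(0)
        header = _read_record(fh, order)
        if header[:4] != _DCD_MAGIC:
            raise ValueError(f"{path}: bad magic {header[:4]!r}, expected {_DCD_MAGIC!r}")
        icntrl = np.frombuffer(header[4:], dtype=np.dtype(np.int32).newbyteorder(order))
        nset = int(icntrl[0])
        has_cell = bool(icntrl[10])
        _read_record(fh, order)  # title block, ignored
        natoms_rec = _read_record(fh, order)
        (natoms,) = np.frombuffer(natoms_rec, dtype=np.dtype(np.int32).newbyteorder(order))
        natoms = int(natoms)

        f32 = np.dtype(np.float32).newbyteorder(order)
        f64 = np.dtype(np.float64).newbyteorder(order)
        frames = []
        cell_edge: Optional[float] = None
        while True:
            try:
                if has_cell:
                    cell = np.frombuffer(_read_record(fh, order), dtype=f64)
                    a, b, c = float(cell[0]), float(cell[2]), float(cell[5])
                    if not (np.isclose(a, b, rtol=1e-6) and np.isclose(a, c, rtol=1e-6)):
                        raise ValueError(f"{path}: only cubic unit cells are supported")
                    cell_edge = a
                x = np.frombuffer(_read_record(fh, order), dtype=f32)
                y = np.frombuffer(_read_record(fh, order), dtype=f32)
                z = np.frombuffer(_read_record(fh, order), dtype=f32)
            except EOFError:
                break
            if len(x) != natoms or len(y) != natoms or len(z) != natoms:
                raise ValueError(f"{path}: frame coordinate record has wrong length")
            frames.append(np.column_stack([x, y, z]).astype(np.float64))

    if not frames:
        raise ValueError(f"{path}: no frames")
    if nset and nset != len(frames):
        warnings.warn(
            f"{path}: header NSET={nset} but {len(frames)} frames read; using actual count",
            stacklevel=2,
        )
    edge = cell_edge if cell_edge is not None else box_edge
    if edge is None:
        raise ValueError("box_edge required: file carries no unit-cell records")
    coords = np.stack(frames)
    coords -= edge * np.floor(coords / edge)
    return Trajectory(coordinates=coords, box_edge=float(edge))


def thin_frames(traj: Trajectory, every: int, offset: int = 0) -> Trajectory:
    """Keep frames offset, offset+every, ...; stride metadata is multiplied."""
    if every < 1:
        raise ValueError(f"every must be >= 1, got {every}")
    if not 0 <= offset < every:
        raise ValueError(f"offset must satisfy 0 <= offset < every, got {offset}")
    coords = traj.coordinates[offset::every]
    if coords.shape[0] == 0:
        raise ValueError("thinning produced an empty trajectory")
    return Trajectory(
        coordinates=coords.copy(),
        box_edge=traj.box_edge,
        stride=traj.stride * every,
        seed=traj.seed,
        replicate_id=traj.replicate_id,
        spec=traj.spec,
    )
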
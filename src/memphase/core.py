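"""Core data model for coarse-grained membrane snapshots.

A membrane frame holds the particle (bead) coordinates of one time point of a
coarse-grained bilayer simulation, together with per-bead species and bead-name
labels, the rectangular periodic box, and (once assigned) a per-molecule
leaflet tag.  Coordinates are stored in nanometres and are wrapped into
``[0, L)`` on every axis, which is what the contact and gridding layers assume.

File I/O speaks the GROMOS-87 fixed-column coordinate format (``.gro``):
a title line, an atom count, one fixed-width line per atom, and a box line.
Multi-frame input is a plain concatenation of such records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "BeadRecord",
    "Box",
    "MembraneFrame",
    "Trajectory",
    "CompositionSpec",
    "GroParseError",
    "UnsupportedBoxError",
    "SpeciesNotFoundError",
    "DEFAULT_SPECIES_MAP",
    "read_gro",
    "read_gro_frames",
    "read_trajectory",
    "write_gro",
    "write_gro_frames",
    "minimum_image_distance",
    "minimum_image_displacement",
    "assign_leaflets",
    "select_beads",
]


class GroParseError(ValueError):
    """Raised when a coordinate file violates the GROMOS-87 layout."""


class UnsupportedBoxError(ValueError):
    """Raised for non-rectangular (triclinic) periodic boxes."""


class SpeciesNotFoundError(KeyError):
    """Raised when a selection names a species absent from the frame."""


#: Residue-name -> species mapping applied on read.  MARTINI topologies name
#: dilinoleyl-PC "DIPC"/"DUPC"; the canonical labels used throughout this
#: package are DPPC, DLiPC and CHOL.  Users extend this for their solutes.
DEFAULT_SPECIES_MAP: dict[str, str] = {
    "DPPC": "DPPC",
    "DIPC": "DLiPC",
    "DUPC": "DLiPC",
    "DLIPC": "DLiPC",
    "DLIP": "DLiPC",
    "DLiPC": "DLiPC",
    "CHOL": "CHOL",
}


class BeadRecord(NamedTuple):
    """One coarse-grained particle: indices, labels, position (nm)."""

    particle_index: int
    molecule_index: int
    species: str
    bead_name: str
    position: np.ndarray

    def validate(self) -> None:
        if not self.species or not self.bead_name:
            raise ValueError("species and bead_name must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("bead position must be finite")


@dataclass(frozen=True)
class Box:
    """Rectangular (orthorhombic) periodic box with edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ValueError(f"box lengths must be strictly positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def area_xy(self) -> float:
        return float(self.lengths[0] * self.lengths[1])

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into ``[0, L)`` per axis."""
        return np.mod(positions, self.lengths)


@dataclass
class MembraneFrame:
    """One snapshot: bead coordinates plus labels and the periodic box.

    Beads are stored in parallel arrays (positions ``(N, 3)`` in nm, species,
    bead names, molecule indices).  ``molecule_index`` must be contiguous
    per molecule, i.e. all beads of one molecule are adjacent; molecule
    indices start at 0.  ``leaflets`` is a per-molecule array with values in
    ``{"upper", "lower", "none"}`` set by :func:`assign_leaflets`.
    """

    positions: np.ndarray
    species: np.ndarray
    bead_names: np.ndarray
    molecule_index: np.ndarray
    box: Box
    time: float = 0.0
    leaflets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.species = np.asarray(self.species, dtype=str)
        self.bead_names = np.asarray(self.bead_names, dtype=str)
        self.molecule_index = np.asarray(self.molecule_index, dtype=np.intp)
        n = len(self.positions)
        if not (len(self.species) == len(self.bead_names) == len(self.molecule_index) == n):
            raise ValueError("per-bead arrays must share one length")

    # -- structure ---------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if self.n_beads else 0

    def bead(self, i: int) -> BeadRecord:
        return BeadRecord(
            particle_index=i,
            molecule_index=int(self.molecule_index[i]),
            species=str(self.species[i]),
            bead_name=str(self.bead_names[i]),
            position=self.positions[i].copy(),
        )

    def molecule_species(self) -> np.ndarray:
        """Species label per molecule (first bead of each molecule)."""
        first = np.concatenate(([0], np.flatnonzero(np.diff(self.molecule_index)) + 1)) \
            if self.n_beads else np.empty(0, dtype=np.intp)
        out = np.empty(self.n_molecules, dtype=self.species.dtype)
        out[self.molecule_index[first]] = self.species[first]
        return out

    def validate(self) -> None:
        """Check frame invariants: finiteness, labels, molecule contiguity."""
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if np.any(self.species == "") or np.any(self.bead_names == ""):
            raise ValueError("species and bead names must be non-empty")
        if self.n_beads:
            # contiguity: each molecule index appears as exactly one run
            change = np.flatnonzero(np.diff(self.molecule_index)) + 1
            starts = self.molecule_index[np.concatenate(([0], change))]
            if len(np.unique(starts)) != len(starts):
                raise ValueError("molecule_index values must group beads contiguously")
            if self.molecule_index.min() < 0:
                raise ValueError("molecule indices must be non-negative")
        if self.leaflets is not None:
            if len(self.leaflets) != self.n_molecules:
                raise ValueError("leaflets must have one label per molecule")
            has_po4_or_roh = np.zeros(self.n_molecules, dtype=bool)
            lipid = np.isin(self.bead_names, ("PO4", "ROH"))
            has_po4_or_roh[self.molecule_index[lipid]] = True
            bad = has_po4_or_roh & ~np.isin(self.leaflets, ("upper", "lower"))
            if np.any(bad):
                raise ValueError("every phospholipid/cholesterol needs an upper/lower label")

    def copy(self) -> "MembraneFrame":
        return MembraneFrame(
            positions=self.positions.copy(),
            species=self.species.copy(),
            bead_names=self.bead_names.copy(),
            molecule_index=self.molecule_index.copy(),
            box=self.box,
            time=self.time,
            leaflets=None if self.leaflets is None else self.leaflets.copy(),
        )

    def wrapped(self) -> "MembraneFrame":
        out = self.copy()
        out.positions = self.box.wrap(out.positions)
        return out


@dataclass
class Trajectory:
    """Time-ordered frames sharing one particle layout."""

    frames: list[MembraneFrame]
    time_step: float | None = None

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frames:
            ref = self.frames[0]
            for i, fr in enumerate(self.frames[1:], start=1):
                if fr.n_beads != ref.n_beads or not np.array_equal(fr.species, ref.species) \
                        or not np.array_equal(fr.bead_names, ref.bead_names):
                    raise ValueError(f"frame {i} does not share the layout of frame 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[MembraneFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i], time_step=self.time_step)
        return self.frames[i]


@dataclass(frozen=True)
class CompositionSpec:
    """Molecule counts of the ternary mixture plus an optional solute."""

    n_dlipc: int = 540
    n_dppc: int = 828
    n_chol: int = 576
    n_solute: int = 0
    solute_species: str = "OCT"

    def __post_init__(self) -> None:
        for name in ("n_dlipc", "n_dppc", "n_chol", "n_solute"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_lipids == 0:
            raise ValueError("composition needs at least one lipid")

    @property
    def n_lipids(self) -> int:
        return self.n_dlipc + self.n_dppc + self.n_chol

    @property
    def n_phospholipids(self) -> int:
        return self.n_dlipc + self.n_dppc


# ---------------------------------------------------------------------------
# GROMOS-87 coordinate I/O
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def _parse_box_line(line: str, lineno: int) -> Box:
    try:
        fields = [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: malformed box line {line!r}") from exc
    if len(fields) == 3:
        return Box(np.array(fields))
    if len(fields) == 9:
        if any(abs(v) > 0 for v in fields[3:]):
            raise UnsupportedBoxError(
                f"line {lineno}: non-rectangular box with off-diagonal terms {fields[3:]}"
            )
        return Box(np.array(fields[:3]))
    raise GroParseError(f"line {lineno}: box line needs 3 or 9 fields, got {len(fields)}")


def _read_one_frame(lines: Sequence[str], start: int, species_map: dict[str, str]):
    """Parse one title/count/atoms/box record starting at ``lines[start]``."""
    title = lines[start].rstrip("\n")
    try:
        n_atoms = int(lines[start + 1].split()[0])
    except (IndexError, ValueError) as exc:
        raise GroParseError(
            f"line {start + 2}: malformed atom count {lines[start + 1]!r}"
        ) from exc
    box_lineno = start + 2 + n_atoms
    if box_lineno >= len(lines):
        raise GroParseError(
            f"line {start + 2}: declared {n_atoms} atoms but the file ends "
            f"after {len(lines) - start - 2} atom lines"
        )

    positions = np.empty((n_atoms, 3))
    species = np.empty(n_atoms, dtype="U8")
    bead_names = np.empty(n_atoms, dtype="U8")
    resids = np.empty(n_atoms, dtype=np.int64)
    for k in range(n_atoms):
        line = lines[start + 2 + k]
        lineno = start + 3 + k
        if len(line.rstrip("\n")) < 44:
            raise GroParseError(f"line {lineno}: atom line shorter than 44 columns")
        try:
            resids[k] = int(line[0:5])
            positions[k, 0] = float(line[20:28])
            positions[k, 1] = float(line[28:36])
            positions[k, 2] = float(line[36:44])
        except ValueError as exc:
            raise GroParseError(f"line {lineno}: malformed atom line {line!r}") from exc
        resname = line[5:10].strip()
        species[k] = species_map.get(resname, resname)
        bead_names[k] = line[10:15].strip()

    box = _parse_box_line(lines[box_lineno], box_lineno + 1)
    # resids wrap at 100000 in the format; rebuild contiguous molecule indices
    # from runs of identical (resid, resname).
    if n_atoms:
        new_mol = np.ones(n_atoms, dtype=bool)
        new_mol[1:] = (resids[1:] != resids[:-1]) | (species[1:] != species[:-1])
        molecule_index = np.cumsum(new_mol) - 1
    else:
        molecule_index = np.empty(0, dtype=np.intp)

    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else 0.0
    frame = MembraneFrame(
        positions=positions,
        species=species,
        bead_names=bead_names,
        molecule_index=molecule_index,
        box=box,
        time=time,
    )
    return frame.wrapped(), box_lineno + 1


def read_gro_frames(path: str | Path, species_map: dict[str, str] | None = None
                    ) -> Iterator[MembraneFrame]:
    """Yield every frame of a (possibly concatenated) ``.gro`` file."""
    species_map = DEFAULT_SPECIES_MAP if species_map is None else species_map
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip() and all(not l.strip() for l in lines[pos:]):
            break  # trailing blank lines
        frame, pos = _read_one_frame(lines, pos, species_map)
        yield frame


def read_gro(path: str | Path, species_map: dict[str, str] | None = None) -> MembraneFrame:
    """Read the first (usually only) frame of a ``.gro`` coordinate file."""
    try:
        return next(read_gro_frames(path, species_map))
    except StopIteration:
        raise GroParseError(f"{path}: empty coordinate file") from None


def read_trajectory(path: str | Path, species_map: dict[str, str] | None = None,
                    topology: str | Path | None = None,
                    default_time_step: float = 1.0) -> Trajectory:
    """Read a multi-frame trajectory.

    ``.gro`` files are read natively (concatenated frames).  A ``.xtc``
    compressed trajectory is read through MDAnalysis when available and then
    needs ``topology`` (a ``.gro`` file) for the labels.  Frames that carry no
    time stamp are assigned ``default_time_step`` ns spacings.
    """
    path = Path(path)
    if path.suffix.lower() == ".xtc":
        frames = list(_read_xtc(path, topology, species_map))
    else:
        frames = list(read_gro_frames(path, species_map))
    if not frames:
        raise GroParseError(f"{path}: no frames found")
    times = np.array([f.time for f in frames])
    if len(frames) > 1 and np.any(np.diff(times) <= 0):
        for i, fr in enumerate(frames):
            fr.time = i * default_time_step
    return Trajectory(frames, time_step=default_time_step)


def _read_xtc(path: Path, topology, species_map):
    if topology is None:
        raise ValueError("XTC input needs a .gro topology for the labels")
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - depends on install extras
        raise ImportError("reading XTC requires the MDAnalysis extra") from exc
    template = read_gro(topology, species_map)
    u = mda.Universe(str(topology), str(path))
    for ts in u.trajectory:
        fr = template.copy()
        fr.positions = template.box.wrap(ts.positions / 10.0)  # Å -> nm
        fr.box = Box(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
        fr.time = float(ts.time) / 1000.0  # ps -> ns
        yield fr


def write_gro(frame: MembraneFrame, path: str | Path, title: str | None = None) -> None:
    """Write one frame in GROMOS-87 layout (positions rounded to 3 decimals)."""
    with open(path, "w") as fh:
        _write_one_frame(fh, frame, title)


def write_gro_frames(frames: Iterable[MembraneFrame], path: str | Path,
                     title: str | None = None) -> None:
    """Write a concatenated multi-frame ``.gro`` file."""
    with open(path, "w") as fh:
        for frame in frames:
            _write_one_frame(fh, frame, title)


def _write_one_frame(fh, frame: MembraneFrame, title: str | None) -> None:
    head = title if title is not None else "memphase frame"
    fh.write(f"{head} t= {frame.time:.5f}\n")
    fh.write(f"{frame.n_beads:5d}\n")
    for i in range(frame.n_beads):
        resid = (int(frame.molecule_index[i]) + 1) % 100000
        x, y, z = frame.positions[i]
        fh.write(
            f"{resid:5d}{frame.species[i]:<5.5s}{frame.bead_names[i]:>5.5s}"
            f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
        )
    lx, ly, lz = frame.box.lengths
    fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Shortest periodic displacement vector(s) from ``a`` to ``b``."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L = box.lengths
    return d - L * np.round(d / L)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> float | np.ndarray:
    """Euclidean distance between ``a`` and ``b`` minimised over periodic images."""
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# Leaflet assignment and bead selection
# ---------------------------------------------------------------------------

def assign_leaflets(frame: MembraneFrame) -> MembraneFrame:
    """Label each lipid molecule upper/lower by its headgroup height.

    The bilayer midplane is taken as the mean z of all PO4 beads.
    Phospholipids are assigned by their PO4 bead, cholesterol by its ROH
    bead; everything else (solutes) is labelled ``none``.  Returns a new
    frame; the input is untouched.
    """
    po4 = frame.bead_names == "PO4"
    if not np.any(po4):
        raise ValueError("no PO4 beads found: input is not a labelled membrane")
    midplane = float(frame.positions[po4, 2].mean())

    labels = np.full(frame.n_molecules, "none", dtype="U5")
    for marker in ("PO4", "ROH"):
        sel = frame.bead_names == marker
        mols = frame.molecule_index[sel]
        above = frame.positions[sel, 2] >= midplane
        labels[mols] = np.where(above, "upper", "lower")
    out = frame.copy()
    out.leaflets = labels
    return out


ALL = "ALL"


def select_beads(frame: MembraneFrame, species: str | Iterable[str],
                 bead_names: str | Iterable[str] = ALL) -> np.ndarray:
    """Indices of beads matching a species set and a bead-name set.

    ``bead_names=ALL`` matches every bead of the selected species.  Unknown
    species raise :class:`SpeciesNotFoundError` listing the known labels.
    """
    wanted = {species} if isinstance(species, str) else set(species)
    known = set(np.unique(frame.species))
    missing = wanted - known
    if missing:
        raise SpeciesNotFoundError(
            f"unknown species {sorted(missing)}; frame contains {sorted(known)}"
        )
    mask = np.isin(frame.species, sorted(wanted))
    if not (isinstance(bead_names, str) and bead_names == ALL):
        names = {bead_names} if isinstance(bead_names, str) else set(bead_names)
        mask &= np.isin(frame.bead_names, sorted(names))
    return np.flatnonzero(mask)
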
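"""Synthetic striped-membrane generator with known ground truth.

Emulates the geometry of a phase-separated ternary bilayer (DPPC/DLiPC/
cholesterol) whose L_o and L_d domains form stripes along x under periodic
boundaries: lipids sit on jittered per-leaflet lattices inside their stripe,
each built as a simple bead stack (PO4 or ROH headgroup at the leaflet
surface plus chain beads toward the midplane).  Solutes are placed at the
bilayer midplane, uniformly, at the domain interfaces, or inside the L_d
stripe.  The degree of lipid mixing is controlled by a parameter lambda:
``mix_membrane`` randomly permutes the lateral positions of a fraction
lambda of the phospholipids (leaflet-preserving), so lambda = 0 is the fully
striped state and lambda = 1 a uniformly random arrangement whose expected
DLiPC-DPPC contact fraction is the DPPC phospholipid molar fraction.

Every generated configuration carries a :class:`GroundTruth` (per-molecule
phase and leaflet, interface positions) so each analysis stage can be tested
for exact recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import Box, CompositionSpec, MembraneFrame, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_striped_membrane",
    "striped_trajectory",
    "mix_membrane",
    "lattice_mixing_series",
    "MIN_LATTICE_SPACING",
]

#: Minimum lateral site spacing, nm; below this the packing is unphysical.
MIN_LATTICE_SPACING = 0.55

_SOLUTE_MODES = ("uniform_midplane", "interface_band", "ld_partition")

_CHOL_BEADS = 8  # ROH + 7 ring/tail beads


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one synthetic membrane.

    Defaults follow the reference study conditions: 540 DLiPC, 828 DPPC and
    576 cholesterol in a ~20 x 20 nm bilayer (so 50 grid bins give ~0.4 nm
    cells), L_o/L_d thicknesses of 4.2/3.8 nm, 10% of the cholesterol in the
    L_d stripe, and 12 beads per phospholipid (equal for both species, which
    preserves the analytic bead-counting limits).
    """

    composition: CompositionSpec = field(default_factory=CompositionSpec)
    box_xy: tuple[float, float] = (20.0, 20.0)
    box_z: float = 10.0
    mixing_lambda: float = 0.0
    solute_mode: str = "uniform_midplane"
    interface_band_width: float = 1.0
    phase_thickness: Mapping[str, float] = field(
        default_factory=lambda: {"Lo": 4.2, "Ld": 3.8})
    position_jitter: float = 0.05
    chol_ld_fraction: float = 0.1
    beads_per_lipid: int = 12
    interphase_buffer: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_lambda <= 1.0:
            raise ValueError("mixing_lambda must lie in [0, 1]")
        if not 0.0 <= self.chol_ld_fraction <= 1.0:
            raise ValueError("chol_ld_fraction must lie in [0, 1]")
        if self.solute_mode not in _SOLUTE_MODES:
            raise ValueError(f"solute_mode must be one of {_SOLUTE_MODES}")
        if any(t <= 0 for t in self.phase_thickness.values()) \
                or set(self.phase_thickness) != {"Lo", "Ld"}:
            raise ValueError("phase_thickness needs positive Lo and Ld entries")
        if self.position_jitter < 0 or self.interphase_buffer < 0:
            raise ValueError("jitter and buffer must be >= 0")
        if self.beads_per_lipid < 2:
            raise ValueError("beads_per_lipid must be >= 2")
        if self.interface_band_width <= 0:
            raise ValueError("interface_band_width must be > 0")
        if min(self.box_xy) <= 0 or self.box_z <= 0:
            raise ValueError("box dimensions must be positive")


@dataclass
class GroundTruth:
    """Construction-time truth: per-molecule phase/leaflet, interfaces, spec."""

    phase: np.ndarray      # per molecule: "Lo" / "Ld" / "none"
    leaflet: np.ndarray    # per molecule: "upper" / "lower" / "none"
    interface_x: list[float]
    spec: SyntheticSpec

    def to_table(self, path: str | Path) -> None:
        """Serialize as a per-molecule TSV with a '#'-prefixed header."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# interface_x_nm\t{self.interface_x[0]:.6f}\t{self.interface_x[1]:.6f}\n")
            fh.write(f"# box_xy_nm\t{self.spec.box_xy[0]}\t{self.spec.box_xy[1]}\n")
            fh.write(f"# mixing_lambda\t{self.spec.mixing_lambda}\n")
            fh.write(f"# solute_mode\t{self.spec.solute_mode}\n")
            fh.write(f"# seed\t{self.spec.seed}\n")
            fh.write("molecule_index\tphase\tleaflet\n")
            for i, (ph, lf) in enumerate(zip(self.phase, self.leaflet)):
                fh.write(f"{i}\t{ph}\t{lf}\n")


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------

def _grid_dims(w: float, ly: float, n: int) -> tuple[int, int]:
    """Choose an (nx, ny) lattice for n sites in a w x ly stripe.

    Picks the most-square feasible cell; raises if no layout keeps the
    spacing at or above MIN_LATTICE_SPACING.
    """
    best = None
    ny_max = int(math.floor(ly / MIN_LATTICE_SPACING))
    for ny in range(1, max(ny_max, 1) + 1):
        nx = int(math.ceil(n / ny))
        if w / nx < MIN_LATTICE_SPACING:
            continue
        score = abs(w / nx - ly / ny)
        if best is None or score < best[0]:
            best = (score, nx, ny)
    if best is None:
        raise ValueError(
            f"box too small: cannot place {n} molecules in a {w:.2f} x {ly:.2f} nm "
            f"stripe at >= {MIN_LATTICE_SPACING} nm spacing"
        )
    return best[1], best[2]


def _stripe_sites(x0: float, w: float, ly: float, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    nx, ny = _grid_dims(w, ly, n)
    xs = x0 + (np.arange(nx) + 0.5) * (w / nx)
    ys = (np.arange(ny) + 0.5) * (ly / ny)
    sites = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    pick = rng.permutation(len(sites))[:n]
    return sites[pick]


def _split_leaflets(count: int) -> tuple[int, int]:
    return (count + 1) // 2, count // 2


def _molecule_beads(species: str, xy: np.ndarray, z_mid: float, sign: float,
                    thickness: float, beads_per_lipid: int):
    """Bead names and positions of one lipid as a surface-anchored stack."""
    if species == "CHOL":
        nb = _CHOL_BEADS
        names = ["ROH"] + [f"R{k}" for k in range(1, nb)]
    else:
        nb = beads_per_lipid
        names = ["PO4"] + [f"C{k}" for k in range(1, nb)]
    k = np.arange(nb)
    z = z_mid + sign * (thickness / 2.0) * (1.0 - k / nb)
    pos = np.empty((nb, 3))
    pos[:, 0] = xy[0]
    pos[:, 1] = xy[1]
    pos[:, 2] = z
    return names, pos


def _build_lattice(spec: SyntheticSpec, rng: np.random.Generator
                   ) -> tuple[MembraneFrame, GroundTruth]:
    """Unjittered striped membrane plus ground truth."""
    comp = spec.composition
    lx, ly = spec.box_xy
    g = spec.interphase_buffer

    n_chol_ld = int(round(spec.chol_ld_fraction * comp.n_chol))
    n_chol_lo = comp.n_chol - n_chol_ld
    n_ld = comp.n_dlipc + n_chol_ld
    n_lo = comp.n_dppc + n_chol_lo
    usable = lx - 2.0 * g
    if usable <= 0:
        raise ValueError("interphase_buffer leaves no room for the stripes")
    w_ld = usable * n_ld / (n_ld + n_lo)
    w_lo = usable - w_ld
    ld_x0 = g / 2.0
    lo_x0 = ld_x0 + w_ld + g
    interface_x = [0.0, w_ld + g]  # gap centres: periodic boundary and Ld|Lo
    z_mid = spec.box_z / 2.0

    names: list[str] = []
    species: list[str] = []
    mol_index: list[int] = []
    positions: list[np.ndarray] = []
    phase_labels: list[str] = []
    leaflet_labels: list[str] = []
    mol = 0

    stripes = {
        "Ld": (ld_x0, w_ld, {"DLiPC": comp.n_dlipc, "CHOL": n_chol_ld}),
        "Lo": (lo_x0, w_lo, {"DPPC": comp.n_dppc, "CHOL": n_chol_lo}),
    }
    for sign, leaflet in ((1.0, "upper"), (-1.0, "lower")):
        for phase, (x0, w, counts) in stripes.items():
            labels: list[str] = []
            for sp, c in counts.items():
                up, low = _split_leaflets(c)
                labels += [sp] * (up if leaflet == "upper" else low)
            if not labels:
                continue
            rng.shuffle(labels)
            sites = _stripe_sites(x0, w, ly, len(labels), rng)
            t = spec.phase_thickness[phase]
            for sp, xy in zip(labels, sites):
                bead_names, pos = _molecule_beads(
                    sp, xy, z_mid, sign, t, spec.beads_per_lipid)
                names += bead_names
                species += [sp] * len(bead_names)
                mol_index += [mol] * len(bead_names)
                positions.append(pos)
                phase_labels.append(phase)
                leaflet_labels.append(leaflet)
                mol += 1

    # solutes: single-bead particles at midplane depth
    if comp.n_solute:
        sol_xy = _solute_positions(spec, rng, interface_x, ld_x0, w_ld)
        for xy in sol_xy:
            names.append("S1")
            species.append(comp.solute_species)
            mol_index.append(mol)
            positions.append(np.array([[xy[0], xy[1], z_mid]]))
            phase_labels.append("none")
            leaflet_labels.append("none")
            mol += 1

    frame = MembraneFrame(
        positions=np.concatenate(positions, axis=0),
        species=np.array(species),
        bead_names=np.array(names),
        molecule_index=np.array(mol_index),
        box=Box(np.array([lx, ly, spec.box_z])),
        time=0.0,
        leaflets=np.array(leaflet_labels, dtype="U5"),
    )
    truth = GroundTruth(
        phase=np.array(phase_labels, dtype="U4"),
        leaflet=np.array(leaflet_labels, dtype="U5"),
        interface_x=interface_x,
        spec=spec,
    )
    return frame, truth


def _solute_positions(spec: SyntheticSpec, rng: np.random.Generator,
                      interface_x: list[float], ld_x0: float, w_ld: float
                      ) -> np.ndarray:
    n = spec.composition.n_solute
    lx, ly = spec.box_xy
    if spec.solute_mode == "uniform_midplane":
        k = int(math.ceil(math.sqrt(n)))  # densest square grid fitting the count
        xs = (np.arange(k) + 0.5) * (lx / k)
        ys = (np.arange(k) + 0.5) * (ly / k)
        grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
        return grid[:n]
    if spec.solute_mode == "interface_band":
        which = rng.integers(0, 2, size=n)
        x = np.asarray(interface_x)[which] + rng.uniform(
            -spec.interface_band_width / 2.0, spec.interface_band_width / 2.0, size=n)
        y = rng.uniform(0.0, ly, size=n)
        return np.column_stack((np.mod(x, lx), y))
    # ld_partition: interior of the L_d stripe, clear of the interfaces
    margin = min(1.0, w_ld / 4.0)
    x = rng.uniform(ld_x0 + margin, ld_x0 + w_ld - margin, size=n)
    y = rng.uniform(0.0, ly, size=n)
    return np.column_stack((x, y))


def _apply_jitter(frame: MembraneFrame, jitter: float,
                  rng: np.random.Generator) -> MembraneFrame:
    """Rigid Gaussian displacement of each molecule (thermal noise stand-in)."""
    out = frame.copy()
    if jitter > 0:
        offsets = rng.normal(0.0, jitter, size=(frame.n_molecules, 3))
        out.positions = out.positions + offsets[frame.molecule_index]
    out.positions = out.box.wrap(out.positions)
    return out


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_striped_membrane(spec: SyntheticSpec
                              ) -> tuple[MembraneFrame, GroundTruth]:
    """One striped-membrane frame with ground truth; deterministic per seed.

    Builds the lambda = 0 stripe geometry, applies the per-molecule position
    jitter, and, if ``spec.mixing_lambda > 0``, mixes the phospholipids with
    :func:`mix_membrane`.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_build, rng_jitter, rng_mix = (np.random.default_rng(c) for c in ss.spawn(3))
    frame, truth = _build_lattice(spec, rng_build)
    frame = _apply_jitter(frame, spec.position_jitter, rng_jitter)
    if spec.mixing_lambda > 0:
        frame, truth = mix_membrane(frame, truth, spec.mixing_lambda, rng_mix)
    return frame, truth


def striped_trajectory(spec: SyntheticSpec, n_frames: int,
                       time_step_ns: float = 1.0
                       ) -> tuple[Trajectory, GroundTruth]:
    """A stationary trajectory: fixed lattice, fresh thermal jitter per frame."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    rng_build, rng_jitter, rng_mix = (np.random.default_rng(c) for c in ss.spawn(3))
    base, truth = _build_lattice(spec, rng_build)
    if spec.mixing_lambda > 0:
        base, truth = mix_membrane(base, truth, spec.mixing_lambda, rng_mix)
    frames = []
    for i in range(n_frames):
        fr = _apply_jitter(base, spec.position_jitter, rng_jitter)
        fr.time = i * time_step_ns
        frames.append(fr)
    return Trajectory(frames, time_step=time_step_ns), truth


def mix_membrane(frame: MembraneFrame, truth: GroundTruth, lam: float,
                 seed: int | np.random.Generator = 0
                 ) -> tuple[MembraneFrame, GroundTruth]:
    """Randomly permute the lateral positions of a fraction ``lam`` of lipids.

    ``round(lam * n_phospholipids)`` phospholipids are chosen and their
    (x, y) positions permuted among themselves; molecules move rigidly and z
    is untouched, so every lipid keeps its leaflet and its own thickness
    signature.  ``lam = 0`` is the identity; ``lam = 1`` yields a uniformly
    random lateral arrangement of all phospholipids, for which the expected
    DLiPC-DPPC contact fraction is n_DPPC / (n_phospholipids - 1).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = frame.copy()
    if lam == 0.0:
        return out, truth
    mol_species = frame.molecule_species()
    first_bead = np.zeros(frame.n_molecules, dtype=np.intp)
    changes = np.concatenate(([0], np.flatnonzero(np.diff(frame.molecule_index)) + 1))
    first_bead[frame.molecule_index[changes]] = changes
    mol_xy = frame.positions[first_bead, :2]

    delta = np.zeros((frame.n_molecules, 2))
    ids = np.flatnonzero(np.isin(mol_species, ("DPPC", "DLiPC")))
    k = int(round(lam * len(ids)))
    if k >= 2:
        chosen = ids[rng.choice(len(ids), size=k, replace=False)]
        perm = rng.permutation(k)
        delta[chosen] = mol_xy[chosen[perm]] - mol_xy[chosen]
    out.positions[:, :2] = np.mod(
        out.positions[:, :2] + delta[frame.molecule_index], frame.box.lengths[:2])
    return out, truth


# ---------------------------------------------------------------------------
# Two-stage mechanism series
# ---------------------------------------------------------------------------

def _validate_schedule(schedule: Mapping | None) -> dict:
    if schedule is None:
        schedule = {}
    if not isinstance(schedule, Mapping):
        raise ValueError("malformed schedule: expected a mapping")
    kind = schedule.get("kind", "two_stage")
    if kind == "two_stage":
        split = float(schedule.get("stage_split", 0.5))
        lam_final = float(schedule.get("lambda_final", 1.0))
        if not 0.0 < split < 1.0:
            raise ValueError("malformed schedule: stage_split must lie in (0, 1)")
        if not 0.0 <= lam_final <= 1.0:
            raise ValueError("malformed schedule: lambda_final must lie in [0, 1]")
        return {"kind": kind, "stage_split": split, "lambda_final": lam_final}
    if kind == "constant":
        lam = float(schedule.get("lambda", 0.0))
        if not 0.0 <= lam <= 1.0:
            raise ValueError("malformed schedule: lambda must lie in [0, 1]")
        return {"kind": kind, "lambda": lam}
    raise ValueError(f"malformed schedule: unknown kind {kind!r}")


def lattice_mixing_series(spec: SyntheticSpec, n_frames: int,
                          schedule: Mapping | None = None,
                          seed: int | None = None,
                          time_step_ns: float = 1.0
                          ) -> tuple[Trajectory, GroundTruth]:
    """Frame series emulating the linactant mechanism's two stages.

    With the default ``two_stage`` schedule, solutes start homogeneously
    distributed at the midplane and migrate to the domain interfaces during
    the first ``stage_split`` of the frames while the lipids stay fully
    striped; afterwards the lipid mixing parameter ramps linearly to
    ``lambda_final``.  A ``constant`` schedule keeps lambda and the solute
    placement fixed, producing a stationary series.  Deterministic given the
    seed (``spec.seed`` when ``seed`` is None).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    sched = _validate_schedule(schedule)
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_build, rng_target, rng_jitter = (np.random.default_rng(c) for c in ss.spawn(3))
    mix_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    if sched["kind"] == "constant":
        base_spec = replace(spec, mixing_lambda=0.0)
        base, truth = _build_lattice(base_spec, rng_build)
        lam_of = lambda t: sched["lambda"]
        sol_progress = lambda t: 0.0
        targets = None
    else:
        base_spec = replace(spec, mixing_lambda=0.0, solute_mode="uniform_midplane")
        base, truth = _build_lattice(base_spec, rng_build)
        band_spec = replace(spec, solute_mode="interface_band")
        # interface-band destinations for every solute
        w_ld = truth.interface_x[1] - spec.interphase_buffer
        targets = _solute_positions(band_spec, rng_target, truth.interface_x,
                                    spec.interphase_buffer / 2.0, w_ld)
        n_a = max(1, int(round(sched["stage_split"] * n_frames)))
        n_b = n_frames - n_a

        def sol_progress(t: int) -> float:
            return min(1.0, t / max(n_a - 1, 1))

        def lam_of(t: int) -> float:
            if t < n_a or n_b == 0:
                return 0.0
            return sched["lambda_final"] * (t - n_a + 1) / n_b

    sol_mols = np.flatnonzero(truth.phase == "none")
    sol_beads = np.isin(base.molecule_index, sol_mols)
    start_xy = base.positions[sol_beads, :2].copy()
    L_xy = base.box.lengths[:2]

    frames = []
    for t in range(n_frames):
        fr = base.copy()
        if targets is not None:
            d = targets - start_xy
            d -= L_xy * np.round(d / L_xy)  # shortest periodic path
            fr.positions[sol_beads, :2] = np.mod(
                start_xy + sol_progress(t) * d, L_xy)
        fr = _apply_jitter(fr, spec.position_jitter, rng_jitter)
        lam = lam_of(t)
        if lam > 0:
            fr, _ = mix_membrane(fr, truth, lam, np.random.default_rng(mix_seed))
        fr.time = t * time_step_ns
        frames.append(fr)
    return Trajectory(frames, time_step=time_step_ns), truth
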
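"""Planar (XY) gridded views of the membrane.

All landscapes live on a fixed ``bins x bins`` grid (default 50, giving
~0.4 x 0.4 nm cells for a 20 x 20 nm box).  Binning is done in box-fractional
coordinates so that frames with a fluctuating box share one grid; densities
are expressed per mean cell area (beads/nm^2).

Quantities:

* partial density of one species (optionally one bead name set),
* DLiPC density fraction  rho_DLiPC / (rho_DLiPC + rho_DPPC), whose 0.5
  level set defines the L_d/L_o interface,
* normalized solute density (spatial mean 1; >1 marks enrichment),
* thickness (filled by :mod:`memphase.thickness`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import ALL, MembraneFrame, Trajectory, select_beads
from .contacts import tail_window

__all__ = [
    "Landscape",
    "GRID_BINS",
    "resolve_window",
    "partial_density_landscape",
    "dlipc_density_fraction_landscape",
    "normalized_solute_density_landscape",
    "interface_cells",
    "solute_interface_enrichment",
]

GRID_BINS = 50

_QUANTITIES = ("partial_density", "density_fraction", "normalized_density", "thickness")


@dataclass
class Landscape:
    """A 2D gridded membrane quantity.

    ``values`` is indexed ``[ix, iy]`` with x along the first axis; the cell
    spanning fractional coordinates ``[ix/n, (ix+1)/n)`` maps to index ``ix``.
    ``undefined_mask`` marks cells where the quantity has no value (e.g. zero
    reference density for a fraction landscape); values there are NaN.
    """

    values: np.ndarray
    quantity: str
    cell_size: tuple[float, float]
    species: str | None = None
    n_frames: int = 1
    undefined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("landscape values must be a 2D grid")
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"quantity must be one of {_QUANTITIES}")
        if self.undefined_mask is None:
            self.undefined_mask = np.zeros(self.values.shape, dtype=bool)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)
        if self.undefined_mask.shape != self.values.shape:
            raise ValueError("undefined_mask must match the grid shape")

    @property
    def bins(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def defined(self) -> np.ndarray:
        return ~self.undefined_mask

    @property
    def cell_area(self) -> float:
        return self.cell_size[0] * self.cell_size[1]

    def to_text(self, path: str | Path) -> None:
        """Write the grid as a TSV matrix with a YAML metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")
        meta = {
            "quantity": self.quantity,
            "species": None if self.species is None else str(self.species),
            "cell_size_nm": [float(c) for c in self.cell_size],
            "bins": list(self.bins),
            "n_frames": int(self.n_frames),
            "n_undefined_cells": int(self.undefined_mask.sum()),
        }
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=False)
        )


def resolve_window(traj: Trajectory, window=None, duration: float | None = 500.0,
                   fraction: float = 0.1) -> np.ndarray:
    """Turn a window specification into frame indices.

    ``None`` selects the default landscape window: the final 0.5 µs (500 ns)
    when the trajectory spans more, else the final 10% of frames.  A slice or
    an index sequence is used as-is.
    """
    if window is None:
        return tail_window(traj.times, duration, fraction)
    if isinstance(window, slice):
        return np.arange(len(traj))[window]
    idx = np.asarray(window, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("window selects no frames")
    return idx


def _bin_counts(frame: MembraneFrame, sel: np.ndarray, bins: int) -> np.ndarray:
    frac = np.mod(frame.positions[sel, :2] / frame.box.lengths[:2], 1.0)
    counts, _, _ = np.histogram2d(frac[:, 0], frac[:, 1], bins=bins,
                                  range=[[0, 1], [0, 1]])
    return counts


def _accumulate(traj: Trajectory, idx: np.ndarray, sel_fn, bins: int,
                leaflet: str | None):
    counts = np.zeros((bins, bins))
    area = 0.0
    for i in idx:
        frame = traj[int(i)]
        sel = sel_fn(frame)
        if leaflet is not None:
            if frame.leaflets is None:
                raise ValueError("leaflet-resolved landscape needs assign_leaflets first")
            sel = sel[frame.leaflets[frame.molecule_index[sel]] == leaflet]
        counts += _bin_counts(frame, sel, bins)
        area += frame.box.area_xy
    mean_cell_area = area / len(idx) / (bins * bins)
    return counts, mean_cell_area


def partial_density_landscape(traj: Trajectory, species: str,
                              bead_names=ALL, window=None, bins: int = GRID_BINS,
                              leaflet: str | None = None) -> Landscape:
    """Time-averaged planar number density of one species (beads/nm^2).

    Selected beads are binned by their wrapped (x, y) in box-fractional
    coordinates; the per-cell count is averaged over the window frames and
    divided by the mean cell area.  The grid sum times the mean cell area
    therefore equals the mean selected-bead count per frame exactly.
    """
    idx = resolve_window(traj, window)
    counts, cell_area = _accumulate(
        traj, idx, lambda fr: select_beads(fr, species, bead_names), bins, leaflet
    )
    dx_dy = np.sqrt(cell_area)  # cells are square for a square box
    frame0 = traj[int(idx[0])]
    dx = frame0.box.lengths[0] / bins
    dy = frame0.box.lengths[1] / bins
    return Landscape(
        values=counts / (len(idx) * cell_area),
        quantity="partial_density",
        cell_size=(float(dx), float(dy)),
        species=species,
        n_frames=len(idx),
    )


def dlipc_density_fraction_landscape(traj: Trajectory, window=None,
                                     bins: int = GRID_BINS,
                                     leaflet: str | None = None) -> Landscape:
    """Per-cell DLiPC density over total phospholipid (PC) density.

    Ranges from 0 (pure DPPC cell) to 1 (pure DLiPC cell); cells with zero
    phospholipid density are undefined.  The 0.5 level set locates the
    L_d/L_o interfaces.
    """
    dlipc = partial_density_landscape(traj, "DLiPC", ALL, window, bins, leaflet)
    dppc = partial_density_landscape(traj, "DPPC", ALL, window, bins, leaflet)
    total = dlipc.values + dppc.values
    undefined = total == 0
    values = np.full(total.shape, np.nan)
    np.divide(dlipc.values, total, out=values, where=~undefined)
    return Landscape(
        values=values,
        quantity="density_fraction",
        cell_size=dlipc.cell_size,
        species="DLiPC",
        n_frames=dlipc.n_frames,
        undefined_mask=undefined,
    )


def normalized_solute_density_landscape(traj: Trajectory, solute: str,
                                        window=None, bins: int = GRID_BINS,
                                        leaflet: str | None = None) -> Landscape:
    """Solute density normalised by its spatial mean (grid mean = 1).

    Values above 1 mark enrichment, below 1 depletion; the normalisation is
    scale-free so landscapes from different solute counts are comparable.
    """
    dens = partial_density_landscape(traj, solute, ALL, window, bins, leaflet)
    mean = dens.values.mean()
    if mean == 0:
        raise ValueError(f"no {solute} density anywhere on the grid")
    return Landscape(
        values=dens.values / mean,
        quantity="normalized_density",
        cell_size=dens.cell_size,
        species=solute,
        n_frames=dens.n_frames,
    )


def interface_cells(fraction: Landscape, level: float = 0.5) -> np.ndarray:
    """Cells where the density fraction crosses ``level`` against a neighbour.

    A defined cell is marked when the sign of (value - level) differs from
    (or is zero against) that of any of its 4 periodic neighbours.  On a
    two-stripe membrane this yields two connected interface bands.
    """
    if fraction.quantity != "density_fraction":
        raise ValueError("interface_cells expects a density_fraction landscape")
    defined = fraction.defined
    if not np.any(defined):
        raise ValueError("all cells are undefined")
    delta = fraction.values - level
    marked = np.zeros(fraction.values.shape, dtype=bool)
    for axis in (0, 1):
        for shift in (1, -1):
            nb_delta = np.roll(delta, shift, axis=axis)
            nb_defined = np.roll(defined, shift, axis=axis)
            crossing = defined & nb_defined & (delta * nb_delta <= 0)
            marked |= crossing
    return marked


def _dilate_periodic(mask: np.ndarray, iterations: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(iterations):
        grown = out.copy()
        for axis in (0, 1):
            for shift in (1, -1):
                grown |= np.roll(out, shift, axis=axis)
        out = grown
    return out


def solute_interface_enrichment(solute_landscape: Landscape, interface: np.ndarray,
                                band_width: int = 1) -> float:
    """Mean solute density near the interface over the mean away from it.

    The band is the interface mask dilated ``band_width`` cells (4-neighbour,
    periodic).  Ratios substantially above 1 indicate interfacial
    (linactant-like) localisation.
    """
    interface = np.asarray(interface, dtype=bool)
    if interface.shape != solute_landscape.values.shape:
        raise ValueError("interface mask and landscape shapes differ")
    band = _dilate_periodic(interface, band_width)
    outside = ~band
    if not band.any():
        raise ValueError("interface band is empty")
    if not outside.any():
        raise ValueError("interface band covers the whole grid")
    return float(solute_landscape.values[band].mean()
                 / solute_landscape.values[outside].mean())
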
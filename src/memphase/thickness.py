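"""Grid-based bilayer thickness and per-phase thickness estimation.

Local thickness is the distance between the mean z of the PO4 beads of the
two leaflets inside each grid cell, time-averaged over the analysis window.
The characteristic thickness of each phase is the *most frequent* local
thickness: the centre of the maximal bin of a fixed-width histogram of the
cell values belonging to that phase.  Phases are attributed per cell from
the DLiPC density-fraction landscape (fraction >= 0.5 -> L_d, < 0.5 -> L_o).
The L_o - L_d difference is the hydrophobic thickness mismatch that couples
to domain stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Trajectory
from .landscapes import GRID_BINS, Landscape, resolve_window

__all__ = [
    "ThicknessResult",
    "thickness_landscape",
    "phase_masks",
    "most_frequent_thickness",
    "phase_thickness",
    "thickness_mismatch",
    "analyze_thickness",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 0.02  # nm

MIN_CELLS_PER_PHASE = 10


@dataclass
class ThicknessResult:
    """Thickness landscape, per-phase modes, mismatch and histogram."""

    landscape: Landscape
    phase_thickness: dict[str, float]
    mismatch: float | None
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges nm, counts)

    def write(self, directory: str | Path, stem: str = "thickness") -> None:
        directory = Path(directory)
        self.landscape.to_text(directory / f"{stem}.tsv")
        edges, counts = self.histogram
        centers = 0.5 * (edges[:-1] + edges[1:])
        np.savetxt(directory / f"{stem}_histogram.tsv",
                   np.column_stack((centers, counts)),
                   delimiter="\t", fmt="%.6g", header="bin_center_nm\tcount")


def thickness_landscape(traj: Trajectory, window=None, bins: int = GRID_BINS) -> Landscape:
    """Per-cell leaflet-to-leaflet PO4 distance (nm), window-averaged.

    Frames must carry leaflet labels (run :func:`memphase.core.assign_leaflets`
    first).  A cell is defined if at least one window frame has PO4 beads of
    both leaflets in it; frames missing either leaflet in a cell do not
    contribute to that cell's average.
    """
    idx = resolve_window(traj, window)
    acc = np.zeros((bins, bins))
    n_obs = np.zeros((bins, bins), dtype=np.intp)
    for i in idx:
        frame = traj[int(i)]
        if frame.leaflets is None:
            raise ValueError("frames carry no leaflet labels; run assign_leaflets first")
        po4 = np.flatnonzero(frame.bead_names == "PO4")
        mol_leaflet = frame.leaflets[frame.molecule_index[po4]]
        frac = np.mod(frame.positions[po4, :2] / frame.box.lengths[:2], 1.0)
        cell_x = np.minimum((frac[:, 0] * bins).astype(np.intp), bins - 1)
        cell_y = np.minimum((frac[:, 1] * bins).astype(np.intp), bins - 1)
        z = frame.positions[po4, 2]
        sums = {}
        counts = {}
        for leaf in ("upper", "lower"):
            m = mol_leaflet == leaf
            s = np.zeros((bins, bins))
            c = np.zeros((bins, bins))
            np.add.at(s, (cell_x[m], cell_y[m]), z[m])
            np.add.at(c, (cell_x[m], cell_y[m]), 1.0)
            sums[leaf], counts[leaf] = s, c
        both = (counts["upper"] > 0) & (counts["lower"] > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            local = sums["upper"] / counts["upper"] - sums["lower"] / counts["lower"]
        acc[both] += local[both]
        n_obs[both] += 1
    undefined = n_obs == 0
    values = np.full((bins, bins), np.nan)
    values[~undefined] = acc[~undefined] / n_obs[~undefined]
    frame0 = traj[int(idx[0])]
    return Landscape(
        values=values,
        quantity="thickness",
        cell_size=(float(frame0.box.lengths[0] / bins), float(frame0.box.lengths[1] / bins)),
        species=None,
        n_frames=len(idx),
        undefined_mask=undefined,
    )


def phase_masks(fraction: Landscape, level: float = 0.5) -> dict[str, np.ndarray]:
    """Attribute grid cells to phases from the DLiPC density fraction.

    Cells with fraction >= ``level`` are L_d (DLiPC-rich), below are L_o;
    undefined cells belong to neither.
    """
    if fraction.quantity != "density_fraction":
        raise ValueError("phase_masks expects a density_fraction landscape")
    defined = fraction.defined
    return {
        "Ld": defined & (fraction.values >= level),
        "Lo": defined & (fraction.values < level),
    }


def most_frequent_thickness(values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
                            ) -> float:
    """Centre of the maximal fixed-width histogram bin; ties go thicker.

    Bin edges are anchored at integer multiples of ``bin_width`` so the
    estimate does not depend on the sample range.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("no defined thickness values")
    lo = math.floor(x.min() / bin_width) * bin_width
    hi = math.ceil(x.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    best = len(counts) - 1 - int(np.argmax(counts[::-1]))  # last maximal bin
    return float(0.5 * (edges[best] + edges[best + 1]))


def phase_thickness(thickness: Landscape, fraction: Landscape | None = None,
                    bin_width: float = DEFAULT_BIN_WIDTH) -> dict[str, float]:
    """Most-frequent local thickness per phase (or whole membrane).

    With a density-fraction landscape the grid is partitioned into L_d/L_o
    cells and one mode is returned per phase; without one (single-phase
    membranes) a single whole-membrane mode is returned under the key
    ``"all"``.
    """
    if thickness.quantity != "thickness":
        raise ValueError("phase_thickness expects a thickness landscape")
    if fraction is None:
        return {"all": most_frequent_thickness(thickness.values[thickness.defined],
                                               bin_width)}
    masks = phase_masks(fraction)
    out = {}
    for phase, mask in masks.items():
        cells = thickness.values[mask & thickness.defined]
        if len(cells) == 0:
            raise ValueError(f"phase {phase} has no defined thickness cells")
        if len(cells) < MIN_CELLS_PER_PHASE:
            raise ValueError(
                f"phase {phase} has only {len(cells)} defined cells "
                f"(need >= {MIN_CELLS_PER_PHASE})"
            )
        out[phase] = most_frequent_thickness(cells, bin_width)
    return out


def thickness_mismatch(lo: float, ld: float) -> float:
    """Signed L_o - L_d thickness difference (nm)."""
    return lo - ld


def analyze_thickness(traj: Trajectory, fraction: Landscape | None = None,
                      window=None, bins: int = GRID_BINS,
                      bin_width: float = DEFAULT_BIN_WIDTH) -> ThicknessResult:
    """Full thickness analysis: landscape, per-phase modes, mismatch, histogram."""
    land = thickness_landscape(traj, window=window, bins=bins)
    per_phase = phase_thickness(land, fraction, bin_width=bin_width)
    mismatch = None
    if "Lo" in per_phase and "Ld" in per_phase:
        mismatch = thickness_mismatch(per_phase["Lo"], per_phase["Ld"])
    cells = land.values[land.defined]
    lo_edge = math.floor(cells.min() / bin_width) * bin_width
    n_bins = max(1, int(math.ceil((cells.max() - lo_edge) / bin_width)))
    counts, edges = np.histogram(cells, bins=n_bins,
                                 range=(lo_edge, lo_edge + n_bins * bin_width))
    return ThicknessResult(
        landscape=land,
        phase_thickness=per_phase,
        mismatch=mismatch,
        histogram=(edges, counts),
    )
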
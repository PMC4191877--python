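"""Contact counting and contact-fraction statistics.

Three statistics quantify lateral organisation of the ternary
DPPC/DLiPC/cholesterol bilayer:

``dlipc_dppc`` (f_mix)
    Fraction of DLiPC contacts made with DPPC among all DLiPC-phospholipid
    contacts, counted between PO4 headgroup beads within 1.1 nm.  It tends to
    0 at complete phase separation and to the DPPC molar fraction among
    phospholipids (828/1368 ~ 0.61 for the reference composition) at ideal
    mixing.

``solute_dlipc``
    Fraction of solute-phospholipid bead contacts made with DLiPC, counted
    over all beads of the solute and the lipids within 0.8 nm.  0.39
    (= 540/1368) at ideal mixing; ~0.5 for an interface-resident (linactant)
    solute; -> 1 for a solute dissolved in the DLiPC-rich L_d phase.

``chol_dlipc``
    Same fraction for cholesterol, counted between the ROH bead and the
    phospholipid PO4 beads within 1.1 nm.

Counting conventions (see the per-function docs): cross-species contacts are
counted once per molecule pair; same-species DLiPC-DLiPC contacts once per
*ordered* (molecule, neighbour) pair.  This is the convention under which the
ideal-mixing limit of f_mix equals the DPPC molar fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import ALL, MembraneFrame, Trajectory, select_beads

__all__ = [
    "ContactFractionResult",
    "UndefinedStatisticError",
    "count_contacts",
    "dlipc_dppc_contact_fraction",
    "solute_dlipc_contact_fraction",
    "chol_dlipc_contact_fraction",
    "contact_fraction_series",
    "block_average_error",
    "tail_window",
    "summarize_series",
    "DEFAULT_LIPID_CUTOFF",
    "DEFAULT_SOLUTE_CUTOFF",
]

DEFAULT_LIPID_CUTOFF = 1.1  # nm, PO4-PO4 and ROH-PO4
DEFAULT_SOLUTE_CUTOFF = 0.8  # nm, all beads

_COUNTING_MODES = ("bead_pairs", "unordered_pairs", "ordered_from_a")


class UndefinedStatisticError(ValueError):
    """Raised when a contact fraction has a zero denominator."""


@dataclass
class ContactFractionResult:
    """A contact-fraction value with its raw counts and cutoff."""

    statistic_name: str
    value: float
    error: float
    cutoff: float
    counts: dict[str, int] = field(default_factory=dict)
    n_frames: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"contact fraction {self.value} outside [0, 1]")
        if self.error < 0:
            raise ValueError("error must be >= 0")


def _contact_pairs(frame: MembraneFrame, sel_a: np.ndarray, sel_b: np.ndarray,
                   cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """All (i in a, j in b) bead pairs within ``cutoff`` on different molecules."""
    box = frame.box.lengths
    pos = np.mod(frame.positions, box)
    # cKDTree with boxsize rejects points at exactly L after mod rounding
    pos[pos >= box] = 0.0
    tree_a = cKDTree(pos[sel_a], boxsize=box)
    tree_b = cKDTree(pos[sel_b], boxsize=box)
    neigh = tree_a.query_ball_tree(tree_b, cutoff)
    counts = np.fromiter((len(n) for n in neigh), dtype=np.intp, count=len(neigh))
    ia = np.repeat(sel_a, counts)
    jb = sel_b[np.concatenate([np.asarray(n, dtype=np.intp) for n in neigh])] \
        if counts.sum() else np.empty(0, dtype=np.intp)
    keep = frame.molecule_index[ia] != frame.molecule_index[jb]
    return ia[keep], jb[keep]


def count_contacts(frame: MembraneFrame, sel_a: Sequence[int], sel_b: Sequence[int],
                   cutoff: float, counting: str = "bead_pairs") -> int:
    """Count contacts between two bead selections under the minimum image.

    A contact is a bead pair (i in ``sel_a``, j in ``sel_b``) on *different*
    molecules whose minimum-image distance is at most ``cutoff`` (inclusive).

    counting modes
        ``bead_pairs``      each qualifying unordered bead pair counts once.
        ``unordered_pairs`` each unordered molecule pair with at least one
                            qualifying bead pair counts once.
        ``ordered_from_a``  for each molecule contributing to ``sel_a``, each
                            neighbouring molecule of ``sel_b`` counts once per
                            ordered (a-molecule, b-molecule) pair.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if counting not in _COUNTING_MODES:
        raise ValueError(f"counting must be one of {_COUNTING_MODES}")
    sel_a = np.asarray(sel_a, dtype=np.intp)
    sel_b = np.asarray(sel_b, dtype=np.intp)
    if len(sel_a) == 0 or len(sel_b) == 0:
        return 0
    ia, jb = _contact_pairs(frame, sel_a, sel_b, cutoff)
    if len(ia) == 0:
        return 0
    overlap = len(np.intersect1d(sel_a, sel_b)) > 0
    if counting == "bead_pairs":
        if not overlap:
            return int(len(ia))
        pairs = np.stack((np.minimum(ia, jb), np.maximum(ia, jb)), axis=1)
        return int(len(np.unique(pairs, axis=0)))
    ma = frame.molecule_index[ia]
    mb = frame.molecule_index[jb]
    if counting == "ordered_from_a":
        pairs = np.stack((ma, mb), axis=1)
    else:  # unordered_pairs
        pairs = np.stack((np.minimum(ma, mb), np.maximum(ma, mb)), axis=1)
    return int(len(np.unique(pairs, axis=0)))


def _fraction(name: str, c_num: int, c_other: int, cutoff: float,
              labels: tuple[str, str]) -> ContactFractionResult:
    denom = c_num + c_other
    if denom == 0:
        raise UndefinedStatisticError(
            f"{name}: zero contacts within {cutoff} nm, statistic undefined"
        )
    return ContactFractionResult(
        statistic_name=name,
        value=c_num / denom,
        error=0.0,
        cutoff=cutoff,
        counts={labels[0]: c_num, labels[1]: c_other},
    )


def dlipc_dppc_contact_fraction(frame: MembraneFrame,
                                cutoff: float = DEFAULT_LIPID_CUTOFF
                                ) -> ContactFractionResult:
    """Lipid-mixing contact fraction f_mix on one frame.

    f_mix = c(DLiPC, DPPC) / [c(DLiPC, DPPC) + c(DLiPC, DLiPC)] with contacts
    between PO4 beads within ``cutoff``.  Cross-species contacts are unordered
    molecule pairs; same-species DLiPC-DLiPC contacts are ordered from each
    DLiPC (each unordered pair contributes twice), so that at ideal mixing the
    expectation equals the DPPC molar fraction among phospholipids.
    """
    po4_dlipc = select_beads(frame, "DLiPC", "PO4")
    po4_dppc = select_beads(frame, "DPPC", "PO4")
    if len(po4_dlipc) == 0:
        raise ValueError("frame contains no DLiPC PO4 beads")
    c_cross = count_contacts(frame, po4_dlipc, po4_dppc, cutoff, "unordered_pairs")
    c_same = count_contacts(frame, po4_dlipc, po4_dlipc, cutoff, "ordered_from_a")
    return _fraction("dlipc_dppc", c_cross, c_same, cutoff,
                     ("DLiPC-DPPC", "DLiPC-DLiPC"))


def solute_dlipc_contact_fraction(frame: MembraneFrame, solute: str,
                                  cutoff: float = DEFAULT_SOLUTE_CUTOFF
                                  ) -> ContactFractionResult:
    """Solute partitioning fraction: c(sol, DLiPC) / c(sol, DLiPC or DPPC).

    Counted over *all* beads of the solute and of both phospholipids within
    ``cutoff`` (bead-pair counting).
    """
    sol = select_beads(frame, solute, ALL)
    dlipc = select_beads(frame, "DLiPC", ALL)
    dppc = select_beads(frame, "DPPC", ALL)
    c_dlipc = count_contacts(frame, sol, dlipc, cutoff, "bead_pairs")
    c_dppc = count_contacts(frame, sol, dppc, cutoff, "bead_pairs")
    return _fraction("solute_dlipc", c_dlipc, c_dppc, cutoff,
                     (f"{solute}-DLiPC", f"{solute}-DPPC"))


def chol_dlipc_contact_fraction(frame: MembraneFrame,
                                cutoff: float = DEFAULT_LIPID_CUTOFF
                                ) -> ContactFractionResult:
    """Cholesterol partitioning fraction via ROH-PO4 bead contacts."""
    roh = select_beads(frame, "CHOL", "ROH")
    dlipc = select_beads(frame, "DLiPC", "PO4")
    dppc = select_beads(frame, "DPPC", "PO4")
    c_dlipc = count_contacts(frame, roh, dlipc, cutoff, "bead_pairs")
    c_dppc = count_contacts(frame, roh, dppc, cutoff, "bead_pairs")
    return _fraction("chol_dlipc", c_dlipc, c_dppc, cutoff,
                     ("CHOL-DLiPC", "CHOL-DPPC"))


_STATISTICS: dict[str, Callable[..., ContactFractionResult]] = {
    "dlipc_dppc": dlipc_dppc_contact_fraction,
    "solute_dlipc": solute_dlipc_contact_fraction,
    "chol_dlipc": chol_dlipc_contact_fraction,
}


def contact_fraction_series(traj: Trajectory, statistic: str, **params
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame contact-fraction time series ``(times ns, values)``.

    Frames on which the statistic is undefined (zero denominator) carry NaN.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    func = _STATISTICS[statistic]
    values = np.empty(len(traj))
    for i, frame in enumerate(traj):
        try:
            values[i] = func(frame, **params).value
        except UndefinedStatisticError:
            values[i] = np.nan
    return traj.times, values


# ---------------------------------------------------------------------------
# Block averaging
# ---------------------------------------------------------------------------

def block_average_error(series: Sequence[float], tail_fraction: float = 0.5
                        ) -> tuple[float, float]:
    """Mean and block-averaged standard error over the tail of a series.

    The error is estimated by block averaging: starting from blocks of one
    sample, the block length is doubled while at least 4 blocks remain, and
    the reported error is the maximum block standard error of the mean over
    that progression (the plateau of the block-error curve for a correlated
    series).  For i.i.d. data this reduces to the ordinary standard error.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    n_tail = max(int(math.ceil(tail_fraction * len(x))), 0)
    x = x[len(x) - n_tail:]
    if len(x) < 4:
        raise ValueError(
            f"averaging window holds {len(x)} points; block averaging needs >= 4"
        )
    mean = float(x.mean())
    error = 0.0
    block = 1
    while len(x) // block >= 4:
        n_blocks = len(x) // block
        tail = x[len(x) - n_blocks * block:]
        block_means = tail.reshape(n_blocks, block).mean(axis=1)
        se = float(block_means.std(ddof=1) / math.sqrt(n_blocks))
        error = max(error, se)
        block *= 2
    return mean, error


def tail_window(times: np.ndarray, duration: float | None, fraction: float) -> np.ndarray:
    """Indices of the averaging window at the end of a time series.

    Uses the final ``duration`` ns when the series spans more than that,
    otherwise the final ``fraction`` of frames.
    """
    times = np.asarray(times, dtype=float)
    n = len(times)
    if n == 0:
        raise ValueError("empty time series")
    span = times[-1] - times[0]
    if duration is not None and span > duration:
        return np.flatnonzero(times >= times[-1] - duration)
    k = max(1, int(round(fraction * n)))
    return np.arange(n - k, n)


def summarize_series(times: np.ndarray, values: np.ndarray,
                     duration: float | None = 5000.0,
                     fraction: float = 0.5) -> tuple[float, float]:
    """Windowed mean and block error of a contact-fraction series.

    The default window is the final 5 µs (5000 ns) when the series is long
    enough, else the final half of the frames.
    """
    idx = tail_window(times, duration, fraction)
    return block_average_error(np.asarray(values)[idx], tail_fraction=1.0)
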
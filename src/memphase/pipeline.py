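"""End-to-end analysis pipeline: trajectory in, report and landscapes out.

Ties the stages together the way the study's analysis layer does: per-frame
contact-fraction series with block-averaged errors over the contact window
(last 5 µs or final half of the frames), density/fraction/solute landscapes
and the thickness analysis over the landscape window (last 0.5 µs or final
10%), a Table-1-style report row, the mechanism phase-plane series, and the
mixing-vs-molar-fraction curve.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (MembraneFrame, Trajectory, CompositionSpec, assign_leaflets,
                   read_trajectory)
from .contacts import (DEFAULT_LIPID_CUTOFF, DEFAULT_SOLUTE_CUTOFF,
                       UndefinedStatisticError, contact_fraction_series,
                       summarize_series, tail_window)
from .landscapes import (GRID_BINS, dlipc_density_fraction_landscape,
                         normalized_solute_density_landscape,
                         partial_density_landscape)
from .thickness import analyze_thickness
from .synthetic import SyntheticSpec, generate_striped_membrane

__all__ = [
    "AnalysisConfig",
    "ReportRow",
    "PhasePlaneSeries",
    "analyze",
    "molar_ratio",
    "phase_plane",
    "mixing_curve",
]

#: Reference contact fractions drawn on the mechanism phase plane: 0.5 marks a
#: solute resident at the L_o/L_d interface, 0.39 the ideal-mixing value (the
#: DLiPC molar fraction among phospholipids).
INTERFACE_REFERENCE = 0.5
IDEAL_MIXING_REFERENCE = 0.39


@dataclass
class AnalysisConfig:
    """All analysis parameters; mirrors the Methods-level defaults."""

    input_path: str | None = None
    topology: str | None = None
    species_map: dict[str, str] | None = None
    solute: str | None = None
    lipid_cutoff: float = DEFAULT_LIPID_CUTOFF
    solute_cutoff: float = DEFAULT_SOLUTE_CUTOFF
    chol_cutoff: float = DEFAULT_LIPID_CUTOFF
    bins: int = GRID_BINS
    contact_window_ns: float = 5000.0
    contact_window_fraction: float = 0.5
    landscape_window_ns: float = 500.0
    landscape_window_fraction: float = 0.1
    output_dir: str = "memphase_out"
    system_label: str = "system"
    temperature: float = 295.0
    seed: int = 0
    quiet: bool = False

    def __post_init__(self) -> None:
        if min(self.lipid_cutoff, self.solute_cutoff, self.chol_cutoff) <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.bins < 2:
            raise ValueError("need at least 2 grid bins")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def log(self, msg: str) -> None:
        if not self.quiet:
            print(f"[memphase] {msg}")


@dataclass
class ReportRow:
    """One Table-1-style result line."""

    system: str
    solute_species: str | None
    n_solute: int
    molar_ratio: float
    temperature: float
    f_mix: float | None = None
    f_mix_err: float | None = None
    solute_dlipc: float | None = None
    solute_dlipc_err: float | None = None
    chol_dlipc: float | None = None
    chol_dlipc_err: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PhasePlaneSeries:
    """Time-resolved (solute partitioning, lipid mixing) mechanism trace."""

    time: np.ndarray
    solute_dlipc: np.ndarray
    f_mix: np.ndarray
    interface_reference: float = INTERFACE_REFERENCE
    ideal_mixing_reference: float = IDEAL_MIXING_REFERENCE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.time,
            "solute_dlipc": self.solute_dlipc,
            "f_mix": self.f_mix,
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def molar_ratio(n_solute: int, composition: CompositionSpec) -> float:
    """Solute/lipid molar ratio in percent, reported to 2 decimals."""
    if composition.n_lipids <= 0:
        raise ValueError("composition has no lipids")
    return round(100.0 * n_solute / composition.n_lipids, 2)


def _load(config: AnalysisConfig) -> Trajectory:
    if config.input_path is None:
        raise ValueError("config.input_path is not set")
    traj = read_trajectory(config.input_path, species_map=config.species_map,
                           topology=config.topology)
    traj = Trajectory([assign_leaflets(fr) for fr in traj], time_step=traj.time_step)
    return traj


def _detect_solute(traj: Trajectory) -> str | None:
    known = {"DPPC", "DLiPC", "CHOL"}
    other = sorted(set(np.unique(traj[0].species)) - known)
    return str(other[0]) if other else None


def _composition_of(frame: MembraneFrame, solute: str | None) -> CompositionSpec:
    mol_species = frame.molecule_species()
    count = lambda s: int(np.sum(mol_species == s))
    return CompositionSpec(
        n_dlipc=count("DLiPC"), n_dppc=count("DPPC"), n_chol=count("CHOL"),
        n_solute=count(solute) if solute else 0,
        solute_species=solute or "OCT",
    )


def analyze(config: AnalysisConfig, traj: Trajectory | None = None
            ) -> tuple[ReportRow, dict]:
    """Run the full analysis and write every output under ``output_dir``.

    Returns the report row and a dict of the in-memory artefacts
    (landscapes, thickness result, series).  Deterministic for identical
    inputs and configuration.
    """
    t0 = _time.perf_counter()
    if traj is None:
        traj = _load(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    solute = config.solute or _detect_solute(traj)
    comp = _composition_of(traj[0], solute)
    config.log(f"loaded {len(traj)} frames, "
               f"{traj[0].n_beads} beads, solute={solute or 'none'}")

    artefacts: dict = {}
    row = ReportRow(
        system=config.system_label,
        solute_species=solute,
        n_solute=comp.n_solute,
        molar_ratio=molar_ratio(comp.n_solute, comp),
        temperature=config.temperature,
    )

    def _stage(name: str, fn: Callable):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _summ(times, values):
        # short trajectories cannot support block averaging; report the
        # windowed mean with an undefined error instead of failing
        kw = dict(duration=config.contact_window_ns,
                  fraction=config.contact_window_fraction)
        try:
            return summarize_series(times, values, **kw)
        except ValueError:
            idx = tail_window(times, kw["duration"], kw["fraction"])
            return float(np.nanmean(np.asarray(values)[idx])), float("nan")

    def _contacts():
        times, fmix = contact_fraction_series(traj, "dlipc_dppc",
                                              cutoff=config.lipid_cutoff)
        row.f_mix, row.f_mix_err = _summ(times, fmix)
        artefacts["f_mix_series"] = (times, fmix)
        if solute and comp.n_solute:
            times, s = contact_fraction_series(traj, "solute_dlipc", solute=solute,
                                               cutoff=config.solute_cutoff)
            row.solute_dlipc, row.solute_dlipc_err = _summ(times, s)
            artefacts["solute_series"] = (times, s)
        if comp.n_chol:
            times, c = contact_fraction_series(traj, "chol_dlipc",
                                               cutoff=config.chol_cutoff)
            row.chol_dlipc, row.chol_dlipc_err = _summ(times, c)

    _stage("contacts", _contacts)
    config.log(f"contacts done (window {config.contact_window_ns} ns / "
               f"{config.contact_window_fraction:.0%})")

    def _landscapes():
        window = None  # default: last 0.5 us or 10%
        fraction = dlipc_density_fraction_landscape(traj, window, config.bins)
        fraction.to_text(out / "dlipc_fraction.tsv")
        artefacts["fraction"] = fraction
        for sp in ("DLiPC", "DPPC"):
            land = partial_density_landscape(traj, sp, window=window, bins=config.bins)
            land.to_text(out / f"density_{sp}.tsv")
            artefacts[f"density_{sp}"] = land
        if solute and comp.n_solute:
            sol = normalized_solute_density_landscape(traj, solute, window, config.bins)
            sol.to_text(out / f"density_{solute}_normalized.tsv")
            artefacts["solute_density"] = sol

    _stage("landscapes", _landscapes)
    config.log("landscapes done")

    def _thickness():
        try:
            result = analyze_thickness(traj, artefacts["fraction"], bins=config.bins)
        except ValueError:
            # single-phase membrane: fall back to the whole-membrane mode
            result = analyze_thickness(traj, None, bins=config.bins)
        result.write(out)
        artefacts["thickness"] = result

    _stage("thickness", _thickness)
    config.log("thickness done")

    row.write(out / "report.tsv")
    config.log(f"report written to {out / 'report.tsv'} "
               f"({_time.perf_counter() - t0:.1f} s)")
    return row, artefacts


def phase_plane(traj: Trajectory, solute: str,
                config: AnalysisConfig | None = None) -> PhasePlaneSeries:
    """Per-frame (solute-DLiPC, DLiPC-DPPC) paired series for the mechanism plot."""
    config = config or AnalysisConfig()
    times, fmix = contact_fraction_series(traj, "dlipc_dppc",
                                          cutoff=config.lipid_cutoff)
    _, sol = contact_fraction_series(traj, "solute_dlipc", solute=solute,
                                     cutoff=config.solute_cutoff)
    return PhasePlaneSeries(time=times, solute_dlipc=sol, f_mix=fmix)


def mixing_curve(n_solutes: Sequence[int],
                 response: Callable[[float], float],
                 base_spec: SyntheticSpec | None = None,
                 seeds_per_point: int = 5,
                 n_frames: int = 4) -> pd.DataFrame:
    """Lipid mixing as a function of solute molar fraction on generator input.

    For each solute count, the mixing parameter is set to
    ``response(molar_fraction)`` (a user-supplied surrogate for the
    solute-driven mixing response), ``seeds_per_point`` independent membranes
    are generated, and the mean f_mix with its standard error over seeds is
    reported.  Duplicate molar fractions and single-point inputs are errors.
    """
    if len(n_solutes) < 2:
        raise ValueError("mixing_curve needs at least 2 points")
    base_spec = base_spec or SyntheticSpec()
    from .contacts import dlipc_dppc_contact_fraction

    rows = []
    seen = set()
    for n_sol in n_solutes:
        comp = replace(base_spec.composition, n_solute=int(n_sol))
        mfrac = molar_ratio(int(n_sol), comp) / 100.0
        if mfrac in seen:
            raise ValueError(f"duplicate molar fraction {mfrac}")
        seen.add(mfrac)
        lam = float(np.clip(response(mfrac), 0.0, 1.0))
        values = []
        for s in range(seeds_per_point):
            spec = replace(base_spec, composition=comp, mixing_lambda=lam,
                           seed=base_spec.seed + 1000 * s + int(n_sol))
            frame, _ = generate_striped_membrane(spec)
            values.append(dlipc_dppc_contact_fraction(frame).value)
        values = np.asarray(values)
        rows.append({
            "n_solute": int(n_sol),
            "molar_fraction": mfrac,
            "mixing_lambda": lam,
            "f_mix": float(values.mean()),
            "f_mix_err": float(values.std(ddof=1) / np.sqrt(len(values)))
            if len(values) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
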
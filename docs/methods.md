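# Methods

This note records the models, conventions and numerical choices behind
`memphase`, and what the synthetic generator does and does not emulate.

## Contact fractions

A contact is a bead pair on different molecules whose minimum-image
Euclidean distance is at most the cutoff (inclusive; the boundary is a
measure-zero choice fixed for reproducibility). Distances are 3D: for
headgroup-bead statistics the two leaflets are ~4 nm apart, so a 1.1 nm
cutoff cannot produce cross-leaflet contacts and 3D counting coincides with
lateral counting.

Three statistics are implemented, with cutoffs and bead selections:

| statistic      | selection           | cutoff | counting |
|----------------|---------------------|--------|----------|
| `dlipc_dppc` (f_mix) | PO4 beads only | 1.1 nm | cross: unordered molecule pairs; same-species: ordered from each DLiPC |
| `solute_dlipc` | all beads of solute and phospholipids | 0.8 nm | bead pairs |
| `chol_dlipc`   | ROH vs. PO4         | 1.1 nm | bead pairs |

The asymmetric convention for f_mix deserves a note. Writing
`f_mix = c_x / (c_x + c_s)` with cross-species contacts `c_x` counted once
per DLiPC-DPPC molecule pair and same-species contacts `c_s` counted once
per *ordered* (DLiPC, DLiPC-neighbour) pair — i.e. twice per unordered
pair — makes the ideal-mixing expectation exactly the DPPC molar fraction
among phospholipids, `n_DPPC / (n_PL − 1)` ≈ 828/1368 ≈ 0.61 for the
reference composition. Counting same-species pairs once would inflate the
ideal-mixing value to ≈ 0.75, contradicting the molar-fraction limit; the
ordered convention is equivalent to asking, per DLiPC molecule, what
fraction of its phospholipid neighbours are DPPC, and then pooling counts.

Bead-pair counting for the solute and cholesterol fractions preserves the
analogous limit (the DLiPC molar fraction 540/1368 ≈ 0.39) *provided both
phospholipids contribute equal bead counts per molecule*, which holds in
the coarse-grained representation emulated here (12 beads each).

Per-frame statistics are averaged over a tail window — the final 5 µs when
the trajectory is long enough, else the final half of the frames — and the
error is estimated by block averaging: block length doubles from 1 while at
least 4 blocks remain, and the reported error is the maximum block standard
error over that progression (the plateau of the block-error curve). On
i.i.d. noise this reduces to the ordinary standard error; on unit-variance
AR(1) noise with φ = 0.9 it recovers the effective-sample-size closed form
√((1+φ)/(1−φ))/√n within a factor ~1.2 (tests assert a factor 1.5). The
maximum-over-progression rule biases mildly upward, which is the
conservative direction for an error bar.

## Landscapes

All planar fields live on a fixed 50×50 grid. Binning uses box-fractional
coordinates so frames with a fluctuating box share one grid; densities are
normalised by the time-mean cell area (≈ 0.4 × 0.4 nm² for a 20 × 20 nm
box). This makes the conservation identity exact: grid sum × mean cell
area = mean selected-bead count per frame.

The DLiPC density fraction is ρ_DLiPC / (ρ_DLiPC + ρ_DPPC) per cell,
undefined where no phospholipid density was observed. Interfaces are cells
whose fraction crosses the 0.5 level against any 4-neighbour (periodic).
The normalized solute density divides the solute partial density by its
spatial mean over all cells, so the landscape averages to exactly 1 and
enrichment reads directly as values > 1; the interface-enrichment ratio
compares the mean inside a band (interface mask dilated by a configurable
number of cells) against the mean outside. Landscapes default to whole-
bilayer counting; a leaflet flag restricts to one leaflet after leaflet
assignment. The default landscape window is the final 0.5 µs, or the final
10% of frames for short series.

## Thickness

Local thickness is the difference of the mean z of upper- and lower-leaflet
PO4 beads per cell, averaged over the window frames in which both leaflets
sampled the cell; cells never sampled by both leaflets stay undefined
rather than extrapolated. Leaflets are assigned per frame from a single
global midplane (the mean PO4 z), which is sufficient for flat striped
membranes; no flip-flop tracking is attempted.

The per-phase thickness is the *most frequent* local thickness: cells are
attributed to L_d (DLiPC fraction ≥ 0.5) or L_o (< 0.5), a histogram with
0.02 nm bins anchored at integer multiples of the bin width is built from
the raw per-cell values (no smoothing), and the centre of the maximal bin
is returned, ties broken toward the thicker bin. 0.02 nm resolves the
 ~0.2 nm mismatch changes of interest. The mismatch is the signed
L_o − L_d difference. Mode estimation needs a concentrated histogram: with
0.05 nm placement jitter a single frame spreads cell values over ~7 bins,
so thickness analyses here use ≥ 10-frame windows (per-frame thermal
jitter averages down by √n), mirroring the windowed averaging the
procedure assumes.

## Synthetic membranes

The generator stands in for microsecond MD output. It emulates geometry and
composition, not energetics:

* 540 DLiPC + 828 DPPC + 576 cholesterol (defaults; configurable) in a
  20 × 20 nm box — ~0.41 nm² per lipid per leaflet, and 50 grid bins give
  the ~0.4 nm cells used throughout.
* Two stripes along x with areas proportional to their molecule counts;
  DPPC plus (1 − `chol_ld_fraction`) of the cholesterol in L_o, DLiPC plus
  the rest (default 10%, emulating the small L_d cholesterol population) in
  L_d. An optional `interphase_buffer` carves a lipid-free gap at each
  interface; with a 1.2 nm buffer the nearest cross-species PO4 pair sits
  ≈ 1.8 nm apart, beyond the 1.1 nm cutoff, realising complete separation
  (f_mix = 0 exactly).
* Lipids are surface-anchored bead stacks on jittered per-leaflet lattices:
  a PO4 (or ROH) bead at the leaflet surface at ± t_phase/2 and the
  remaining beads stacked toward the midplane (12 beads per phospholipid,
  8 per cholesterol). Default phase thicknesses are L_o 4.2 / L_d 3.8 nm.
  Per-molecule rigid Gaussian jitter (σ = 0.05 nm default) stands in for
  thermal noise.
* Solutes are single beads at the midplane: on the densest square grid
  (`uniform_midplane`), uniform within a band around either interface
  (`interface_band`), or uniform in the L_d interior 1 nm clear of the
  interfaces (`ld_partition`, which drives the solute fraction to ≈ 1 as
  for L_d-dissolved aromatics).
* Mixing: `mix_membrane(λ)` randomly permutes the lateral positions of a
  fraction λ of the phospholipids (whole molecules move rigidly; z and
  hence leaflet membership are untouched). λ = 0 is the identity; λ = 1 is
  a uniformly random lateral arrangement whose expected f_mix is
  n_DPPC/(n_PL − 1). The map λ ↦ E[f_mix] is strictly monotone, giving a
  controllable mixing axis.
* `lattice_mixing_series` produces the two-stage mechanism trace: solutes
  first migrate from uniform placement to the interface band (lipids
  frozen), then λ ramps to its final value — reproducing the event order
  in which a linactant first localises at the interface (solute fraction
  → 0.5 at constant f_mix) and only then destabilises the domains (f_mix
  rise while the solute relaxes toward 0.39).

**What passing tests do and do not show.** The generator reproduces the
*geometric* determinants of every statistic — compositions, stripe
topology, interfaces, per-phase thickness, mixing degree — so tests
validate the analysis code and its analytic limits exactly. It does not
reproduce force-field energetics, lipid conformational disorder, undulations,
continuous diffusion, or water; cell-level densities are near-binary
(a grid cell usually holds one bead column), unlike the smoother fields of
real trajectories. Quantities that depend on MD energetics (e.g. the
absolute f_mix ≈ 0.13 of the solute-free reference membrane) are outside
what the generator claims.

One geometric caveat matters for the analytic limits: with unequal phase
thicknesses the thinner DLiPC stack exposes one more bead layer within the
0.8 nm midplane-solute cutoff, biasing the solute fraction to ≈ 0.42 at
ideal mixing. The 0.61/0.39/0.5 reference values treat the two
phospholipids as geometrically interchangeable, so analytic-limit tests use
equal thicknesses (4.0/4.0 nm) — the physically sensible condition for a
fully mixed membrane, which has no phases to differ in thickness —
while thickness-recovery tests keep the 4.2/3.8 nm stripes.

## Defaults at a glance

| parameter | default | unit | rationale |
|---|---|---|---|
| lipid / chol contact cutoff | 1.1 | nm | headgroup-bead contact shell |
| solute contact cutoff | 0.8 | nm | all-bead contact shell |
| grid bins | 50 × 50 | — | ~0.4 nm cells at 20 nm box |
| contact window | last 5 µs, else last 50% | — | long-time average |
| landscape window | last 0.5 µs, else last 10% | — | converged snapshot |
| thickness histogram bin | 0.02 | nm | resolves ~0.2 nm effects |
| box | 20 × 20 × 10 | nm | ~0.41 nm²/lipid per leaflet |
| phase thickness L_o / L_d | 4.2 / 3.8 | nm | ordered phase thicker |
| position jitter σ | 0.05 | nm | lattice thermal noise |
| chol_ld_fraction | 0.1 | — | small L_d cholesterol population |
| minimum lattice spacing | 0.55 | nm | physical packing floor |

## Numerical choices and degenerate inputs

* Coordinates are wrapped into [0, L) on read; boxes must be rectangular
  (triclinic input is rejected, not silently sheared).
* Contact counting uses periodic KD-trees; correctness is pinned to an
  O(N²) 27-image brute-force oracle in the tests.
* Zero-denominator contact fractions raise an undefined-statistic error per
  frame; series mark such frames NaN and windowed summaries skip them. The
  pipeline reports a NaN error (not a failure) when a window is too short
  for block averaging (< 4 frames).
* Interface detection treats a cell exactly at the 0.5 level as crossing;
  a uniform off-level field yields no interface cells.
* Phase-thickness estimation requires ≥ 10 defined cells per phase;
  single-phase membranes use the whole-membrane mode instead.
* Generation fails loudly when the composition cannot be packed at
  ≥ 0.55 nm lattice spacing, rather than producing an overdense membrane.

## Problem sizes used in the test suite

Full-composition membranes (21 024 beads) generate in ~40 ms, so tests run
the real system size throughout: 50 seeds for the ideal-mixing limits,
11 λ-values × 8 seeds for the mixing calibration, 10-frame windows for
thickness recovery, 30-frame series for the mechanism trace, and 100 random
≤ 200-bead frames for oracle equivalence. The whole suite completes in
under a minute on one CPU.

## Known limitations

* Single global midplane per frame: curved or strongly undulating membranes
  would need local midplane estimation.
* The mixing axis is positional permutation, not diffusion: λ is exactly
  interpretable but kinetics along a series are schedule-imposed.
* Mass-ratio bookkeeping is not computed (solute masses are
  representation-dependent); reports carry molar ratios only.
* `unordered_pairs`/`ordered_from_a` counting assumes selections with one
  marker bead per molecule (PO4/ROH), the only case the statistics need.
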
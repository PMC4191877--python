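"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import itertools

import numpy as np

from memphase.core import Box, MembraneFrame

_SHIFTS = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=3)))  # 27 images


def brute_min_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> float:
    """Minimum distance over the 27 explicit neighbour images."""
    a = np.mod(np.asarray(a, float), box.lengths)
    b = np.mod(np.asarray(b, float), box.lengths)
    d = b - a + _SHIFTS * box.lengths
    return float(np.sqrt((d * d).sum(axis=1)).min())


def brute_contact_matrix(frame: MembraneFrame, sel_a, sel_b, cutoff: float) -> np.ndarray:
    """Boolean (len(sel_a), len(sel_b)) adjacency via the 27-image distances."""
    pos = np.mod(frame.positions, frame.box.lengths)
    pa = pos[np.asarray(sel_a)]
    pb = pos[np.asarray(sel_b)]
    d = pb[None, :, :] - pa[:, None, :]  # (na, nb, 3)
    d2 = np.empty((len(pa), len(pb), len(_SHIFTS)))
    for k, s in enumerate(_SHIFTS):
        dd = d + s * frame.box.lengths
        d2[:, :, k] = (dd * dd).sum(axis=2)
    within = d2.min(axis=2) <= cutoff * cutoff
    ma = frame.molecule_index[np.asarray(sel_a)]
    mb = frame.molecule_index[np.asarray(sel_b)]
    within &= ma[:, None] != mb[None, :]
    return within


def brute_count_contacts(frame: MembraneFrame, sel_a, sel_b, cutoff: float,
                         counting: str) -> int:
    """All-pairs O(N^2) contact count in every counting mode."""
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    adj = brute_contact_matrix(frame, sel_a, sel_b, cutoff)
    ia, jb = np.nonzero(adj)
    if counting == "bead_pairs":
        pairs = {frozenset((int(sel_a[i]), int(sel_b[j]))) for i, j in zip(ia, jb)}
        return len(pairs)
    ma = frame.molecule_index[sel_a[ia]]
    mb = frame.molecule_index[sel_b[jb]]
    if counting == "ordered_from_a":
        return len({(int(x), int(y)) for x, y in zip(ma, mb)})
    if counting == "unordered_pairs":
        return len({frozenset((int(x), int(y))) for x, y in zip(ma, mb)})
    raise ValueError(counting)


def random_bead_frame(rng: np.random.Generator, n_beads: int,
                      multi_bead: bool = True) -> MembraneFrame:
    """A random labelled frame for oracle comparisons (<= a few hundred beads)."""
    box = Box(rng.uniform(3.0, 8.0, size=3))
    if multi_bead:
        beads_per_mol = rng.integers(1, 4, size=n_beads)  # over-allocate, trim
        mol_index = np.repeat(np.arange(len(beads_per_mol)), beads_per_mol)[:n_beads]
        mol_index = np.unique(mol_index, return_inverse=True)[1]
    else:
        mol_index = np.arange(n_beads)
    n_mols = mol_index.max() + 1
    mol_species = rng.choice(["DPPC", "DLiPC", "CHOL", "OCT"], size=n_mols)
    species = mol_species[mol_index]
    bead_names = np.array([f"B{i % 3}" for i in range(n_beads)])
    # one PO4/ROH per lipid molecule so selections by marker bead work
    first = np.searchsorted(mol_index, np.arange(n_mols))
    for m in range(n_mols):
        if mol_species[m] in ("DPPC", "DLiPC"):
            bead_names[first[m]] = "PO4"
        elif mol_species[m] == "CHOL":
            bead_names[first[m]] = "ROH"
    return MembraneFrame(
        positions=rng.uniform(0.0, 1.0, size=(n_beads, 3)) * box.lengths,
        species=species,
        bead_names=bead_names,
        molecule_index=mol_index,
        box=box,
    )
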
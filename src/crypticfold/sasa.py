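"""Solvent accessibility and exposure-change analysis.

Per-residue solvent-accessible surface area (SASA) is computed with the
Shrake-Rupley rolling-probe method: test points distributed nearly
uniformly (golden-spiral lattice) on each atom's solvent-expanded sphere
are counted as accessible when they fall outside every neighbouring
expanded sphere.  Relative accessibility is rASA = SASA / SASA_max with
the Tien et al. theoretical per-residue maxima; a residue is *exposed*
when rASA >= 0.25 (inclusive).  Comparing mean per-state rASA profiles
between the native and a partially unfolded ensemble yields the sets of
newly exposed and newly buried residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tables import DEFAULT_VDW_RADIUS, MAX_SASA_TIEN, THREE_TO_ONE, VDW_RADII

EXPOSURE_THRESHOLD = 0.25


class ExposureError(ValueError):
    pass


@dataclass
class StructureFrame:
    """A single conformer as flat atom arrays.

    ``residue_index`` uses the same 1-based numbering as mutation
    strings and rASA profiles; ``residue_type`` holds one-letter codes
    (per residue occurrence, aligned with the unique residue order).
    """

    coords: np.ndarray  # (n_atoms, 3), Å
    radii: np.ndarray  # (n_atoms,), vdW radii, Å
    residue_index: np.ndarray  # (n_atoms,), 1-based
    residue_type: np.ndarray  # per-atom one-letter codes

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_type = np.asarray(self.residue_type)
        if np.any(self.radii <= 0):
            raise ExposureError("van der Waals radii must be positive")

    def residues(self):
        """Unique residue indices (sorted) and their one-letter types."""
        idx, first = np.unique(self.residue_index, return_index=True)
        return idx, self.residue_type[first]


def sphere_points(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere lattice (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley_sasa(
    frame: StructureFrame,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    per_atom: bool = False,
) -> np.ndarray:
    """Per-residue SASA (Å²) by the Shrake-Rupley method.

    Deterministic for a fixed point count.  Exactly coincident atoms are
    computed as-is with a warning (each shadows the other completely).
    """
    if n_sphere_points < 92:
        raise ExposureError("need at least 92 sphere points")
    pts = sphere_points(n_sphere_points)
    coords, radii = frame.coords, frame.radii
    n = coords.shape[0]
    expanded = radii + probe
    tree = cKDTree(coords)
    pairs = tree.query_pairs(2.0 * (expanded.max()), output_type="ndarray")
    if pairs.size and np.any(
        np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1) < 1e-9
    ):
        warnings.warn("exactly overlapping atoms present", stacklevel=2)
    neighbors = [[] for _ in range(n)]
    for a, b in pairs:
        if np.linalg.norm(coords[a] - coords[b]) < expanded[a] + expanded[b]:
            neighbors[a].append(b)
            neighbors[b].append(a)
    atom_area = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        test = coords[i] + ri * pts
        free = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors[i]:
            d = np.linalg.norm(test[free] - coords[j], axis=1)
            keep = d >= expanded[j]
            idx = np.nonzero(free)[0]
            free[idx[~keep]] = False
            if not free.any():
                break
        atom_area[i] = 4.0 * np.pi * ri * ri * free.sum() / n_sphere_points
    if per_atom:
        return atom_area
    res_idx, _ = frame.residues()
    out = np.zeros(res_idx.size)
    pos = {r: i for i, r in enumerate(res_idx)}
    for a in range(n):
        out[pos[frame.residue_index[a]]] += atom_area[a]
    return out


def rasa_profile(
    sasa: np.ndarray,
    sequence,
    max_table: dict | None = None,
    threshold: float = EXPOSURE_THRESHOLD,
):
    """Relative SASA and exposure flags.

    rASA = SASA / SASA_max per residue; exposed iff rASA >= threshold
    (inclusive).  ``sequence`` is a string of one-letter codes (or any
    iterable of them) matching the SASA vector; ``max_table`` overrides
    the bundled Tien theoretical maxima, e.g. for coarse-grained models.
    Values above 1 are tolerated (extended conformations can slightly
    exceed the tripeptide maxima) but flagged above 1.25.
    """
    sasa = np.asarray(sasa, dtype=float)
    seq = list(sequence)
    if len(seq) != sasa.size:
        raise ExposureError("sequence length does not match the SASA vector")
    table = MAX_SASA_TIEN if max_table is None else max_table
    try:
        maxima = np.array([table[aa] for aa in seq], dtype=float)
    except KeyError as exc:
        raise ExposureError(
            f"no SASA_max value for residue {exc}; supply a custom table"
        ) from exc
    rasa = sasa / maxima
    if np.any(rasa > 1.25):
        warnings.warn("rASA above 1.25 encountered", stacklevel=2)
    return rasa, rasa >= threshold


def state_exposure_summary(
    frames: list[StructureFrame],
    sequence,
    max_table: dict | None = None,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    threshold: float = EXPOSURE_THRESHOLD,
):
    """Ensemble summary: mean per-residue rASA and exposed-frame fraction."""
    if not frames:
        raise ExposureError("need at least one frame")
    rasas, flags = [], []
    for fr in frames:
        sasa = shrake_rupley_sasa(fr, probe=probe, n_sphere_points=n_sphere_points)
        r, f = rasa_profile(sasa, sequence, max_table=max_table, threshold=threshold)
        rasas.append(r)
        flags.append(f)
    return np.mean(rasas, axis=0), np.mean(flags, axis=0)


@dataclass
class ExposureChange:
    """Residues whose exposure status differs between two states (1-based)."""

    newly_exposed: set
    newly_buried: set

    def all_changed(self) -> set:
        return self.newly_exposed | self.newly_buried


def exposure_change(
    native: np.ndarray,
    other: np.ndarray,
    threshold: float = EXPOSURE_THRESHOLD,
    residue_index: np.ndarray | None = None,
) -> ExposureChange:
    """Residues crossing the exposure threshold between two rASA profiles.

    newly_exposed: buried in the native profile (rASA < threshold) but
    exposed (>= threshold) in the comparison state; newly_buried is the
    reverse.  ``residue_index`` supplies the 1-based numbering (defaults
    to 1..n).
    """
    native = np.asarray(native, dtype=float)
    other = np.asarray(other, dtype=float)
    if native.shape != other.shape:
        raise ExposureError("profiles differ in length")
    idx = (np.arange(native.size) + 1 if residue_index is None
           else np.asarray(residue_index))
    exp_n = native >= threshold
    exp_o = other >= threshold
    return ExposureChange(
        newly_exposed=set(idx[~exp_n & exp_o].tolist()),
        newly_buried=set(idx[exp_n & ~exp_o].tolist()),
    )


# ---------------------------------------------------------------------------
# PDB interface (biotite-backed)

def frames_from_pdb(path, include_hydrogens: bool = False,
                    radii: dict | None = None) -> list[StructureFrame]:
    """Read single- or multi-model PDB into StructureFrame conformers."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdbf = pdb.PDBFile.read(str(path))
    stack = pdbf.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    rtab = VDW_RADII if radii is None else radii
    frames = []
    for model in stack:
        model = model[model.hetero == False]  # noqa: E712
        if not include_hydrogens:
            model = model[model.element != "H"]
        rad = np.array([rtab.get(e.upper(), DEFAULT_VDW_RADIUS)
                        for e in model.element])
        rtype = np.array([THREE_TO_ONE.get(rn, "X") for rn in model.res_name])
        frames.append(StructureFrame(
            coords=model.coord, radii=rad,
            residue_index=model.res_id, residue_type=rtype,
        ))
    return frames
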
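"""Structural observables over trajectories.

Implements the per-trajectory quantities used to characterise luciferase
conformational behaviour: best-fit RMSD time series, radius of gyration,
per-site RMSF, Shrake–Rupley solvent-accessible surface area, the
dynamical cross-correlation matrix (DCCM), the inter-helix active-pocket
distance, and α-helix content from backbone hydrogen-bond geometry.

Units: Å for distances, Å² for areas, fractions in [0, 1] for helix
content.  All superpositions use the Kabsch algorithm on the selected
atoms (proper rotations only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajio import Trajectory

__all__ = [
    "ObservableSeries",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rmsf",
    "sasa",
    "dccm",
    "pocket_distance",
    "helix_content",
    "BONDI_RADII",
]

#: Bondi van der Waals radii (Å) by element symbol.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Se": 1.90,
}

#: Default active-pocket helix ranges (residue numbers): α1 and α7.
ALPHA1_RESIDUES = range(12, 19)
ALPHA7_RESIDUES = range(109, 120)


@dataclass
class ObservableSeries:
    """A named per-frame observable with units and the selection it used."""

    name: str
    values: np.ndarray
    units: str
    selection: str = "all"

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Superposition

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Optimal weighted superposition of two point sets (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMSD to
    ``reference``.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point-count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 points")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    W = w / w.sum()
    mu_m = W @ mobile
    mu_r = W @ reference
    X = mobile - mu_m
    Y = reference - mu_r
    H = (X * W[:, None]).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    fitted = X @ R.T
    rmsd = float(np.sqrt(np.sum(W[:, None] * (fitted - Y) ** 2)))
    return R, t, rmsd


def _apply_fit(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    """Selection -> atom index array.  None/'all' = all atoms; 'calpha' = Cα;
    an iterable of residue numbers = their Cα atoms; an integer array = atom
    indices verbatim."""
    if selection is None or (isinstance(selection, str) and selection == "all"):
        return np.arange(traj.n_atoms)
    if isinstance(selection, str) and selection == "calpha":
        idx = traj.topology.calpha_indices()
        if idx.size == 0:
            raise ValueError("selection 'calpha' resolves to no atoms")
        return idx
    arr = np.asarray(list(selection) if not isinstance(selection, np.ndarray) else selection)
    if arr.size == 0:
        raise ValueError("empty selection")
    if arr.dtype.kind in "iu" and isinstance(selection, np.ndarray):
        return arr.astype(int)
    # treat as residue numbers
    return traj.topology.calpha_indices(arr.tolist())


# ---------------------------------------------------------------------------
# RMSD / Rg / RMSF

def rmsd_series(traj: Trajectory, reference_frame: int = 0, selection="calpha",
                fit_selection=None) -> ObservableSeries:
    """Per-frame best-fit RMSD (Å) to a reference frame.

    ``fit_selection`` lets the superposition run on a different atom set
    than the measurement — e.g. ligand RMSD measured after aligning on
    binding-site Cα atoms; it defaults to the measurement selection.
    """
    meas = _resolve_selection(traj, selection)
    fit = meas if fit_selection is None else _resolve_selection(traj, fit_selection)
    ref_fit = traj.coords[reference_frame, fit]
    ref_meas = traj.coords[reference_frame, meas]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[f, fit], ref_fit)
        moved = _apply_fit(traj.coords[f, meas], R, t)
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    return ObservableSeries("rmsd", out, "Å", str(selection))


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Radius of gyration sqrt(Σ w_i |r_i − r̄|² / Σ w_i) in Å."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] < 1:
        raise ValueError("need at least one atom")
    w = np.ones(frame.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    com = (w[:, None] * frame).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((frame - com) ** 2, axis=1)).sum() / w.sum()))


def rg_series(traj: Trajectory, selection="all", masses=None) -> ObservableSeries:
    idx = _resolve_selection(traj, selection)
    vals = np.array([radius_of_gyration(traj.coords[f, idx], masses)
                     for f in range(traj.n_frames)])
    return ObservableSeries("rg", vals, "Å", str(selection))


def _superpose_to_mean(coords: np.ndarray, max_iter: int = 10,
                       tol: float = 1e-8) -> np.ndarray:
    """Iteratively superpose frames onto their running mean structure."""
    out = coords.copy()
    ref = out[0]
    for _ in range(max_iter):
        for f in range(out.shape[0]):
            R, t, _ = kabsch_superpose(out[f], ref)
            out[f] = _apply_fit(out[f], R, t)
        new_ref = out.mean(axis=0)
        if np.max(np.abs(new_ref - ref)) < tol:
            break
        ref = new_ref
    return out


def rmsf(traj: Trajectory, selection="calpha", superpose: bool = True) -> np.ndarray:
    """Per-site root-mean-square fluctuation (Å) about the time-mean position.

    With ``superpose=True`` frames are first iteratively aligned to the
    mean structure, removing rigid-body motion.  For an isotropic Gaussian
    ensemble with per-site SD σ the expected RMSF is σ·√3.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    idx = _resolve_selection(traj, selection)
    sub = traj.coords[:, idx]
    if superpose:
        sub = _superpose_to_mean(sub)
    dev = sub - sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(frame: np.ndarray, elements, probe_radius: float = 1.4,
         n_sphere_points: int = 960, radii_override: dict | None = None):
    """Shrake–Rupley solvent-accessible surface area.

    Parameters
    ----------
    frame
        (n_atoms, 3) coordinates in Å.
    elements
        Element symbol per atom; vdW radii resolved from the Bondi set
        with optional per-element overrides.
    probe_radius
        Solvent probe radius in Å (water = 1.4).
    n_sphere_points
        Quadrature points per atom; the estimate improves monotonically
        in expectation as this grows.

    Returns
    -------
    (total, per_atom)
        Total and per-atom accessible areas in Å².
    """
    frame = np.asarray(frame, dtype=float)
    radii_tbl = dict(BONDI_RADII)
    if radii_override:
        radii_tbl.update(radii_override)
    try:
        radii = np.array([radii_tbl[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise KeyError(
            f"no vdW radius for element {exc.args[0]!r}; supply radii_override"
        ) from None
    ext = radii + probe_radius
    pts = _sphere_points(n_sphere_points)
    n = frame.shape[0]
    per_atom = np.zeros(n)
    for i in range(n):
        surf = frame[i] + ext[i] * pts
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((surf - frame[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        per_atom[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# DCCM

def dccm(traj: Trajectory, selection="calpha", superpose: bool = True) -> np.ndarray:
    """Dynamical cross-correlation matrix over the selected sites.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with Δr the deviation
    from the time-mean position, after a single superposition pass onto
    the mean structure.  Entries lie in [−1, 1]; +1 is fully correlated,
    −1 fully anti-correlated motion.  Sites with zero positional variance
    yield NaN rows/columns (absence of motion is not absence of
    correlation) with a warning.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs >= 2 frames")
    idx = _resolve_selection(traj, selection)
    sub = traj.coords[:, idx]
    if superpose:
        sub = _superpose_to_mean(sub, max_iter=1)
    dev = sub - sub.mean(axis=0)  # (frames, sites, 3)
    inner = np.einsum("fid,fjd->ij", dev, dev) / dev.shape[0]
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} site(s) have zero variance; DCCM entries set to NaN"
        )
        var[zero] = np.nan
    denom = np.sqrt(np.outer(var, var))
    C = inner / denom
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    return C


# ---------------------------------------------------------------------------
# Pocket distance

def pocket_distance(traj: Trajectory, group_a=ALPHA1_RESIDUES,
                    group_b=ALPHA7_RESIDUES) -> ObservableSeries:
    """Per-frame distance between Cα centroids of two residue groups (Å).

    Defaults measure the luciferase active-pocket gap between helix α1
    (residues 12–18) and helix α7 (residues 109–119).
    """
    ia = _resolve_selection(traj, group_a)
    ib = _resolve_selection(traj, group_b)
    ca = traj.coords[:, ia].mean(axis=1)
    cb = traj.coords[:, ib].mean(axis=1)
    vals = np.linalg.norm(ca - cb, axis=1)
    return ObservableSeries("pocket_distance", vals, "Å",
                            f"{list(group_a)}|{list(group_b)}")


# ---------------------------------------------------------------------------
# Helix content (hydrogen-bond based)

_HB_FACTOR = 0.084 * 332.0  # kcal/mol·Å for the electrostatic H-bond model
_HB_CUTOFF = -0.5  # kcal/mol


def _hbond_energy(c, o, n, h) -> float:
    """Electrostatic backbone H-bond energy (kcal/mol) between an acceptor
    C=O and a donor N-H, per the classic DSSP dipole model."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return 0.0
    return _HB_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def helix_content(traj: Trajectory, residue_range) -> tuple[dict, np.ndarray]:
    """α-helix probability per residue and helix fraction per frame.

    A residue is assigned α-helical in a frame when it participates in an
    i→i+4 backbone hydrogen bond — as the acceptor (its C=O bonded to the
    N-H of residue i+4) or the donor (its N-H bonded to the C=O of residue
    i−4) — with dipole-model energy below −0.5 kcal/mol.  The amide
    hydrogen is reconstructed 1 Å from N along the preceding residue's
    O→C direction.  Residues missing backbone atoms are excluded with a
    warning.

    Returns ``(per_residue_probability, per_frame_fraction)``.
    """
    residues = list(residue_range)
    topo = traj.topology
    # full residue ladder present in the topology (needed for i±4 partners)
    all_res = sorted({a.residue_number for a in topo.atoms})
    backbone: dict[int, dict[str, int]] = {}
    for r in all_res:
        idxs = {}
        for name in ("N", "CA", "C", "O"):
            k = topo.atom_index(r, name)
            if k is not None:
                idxs[name] = k
        backbone[r] = idxs
    usable = {r for r, d in backbone.items() if len(d) == 4}
    skipped = [r for r in residues if r not in usable]
    if skipped:
        warnings.warn(f"residues missing backbone atoms excluded: {skipped}")
    kept = [r for r in residues if r in usable]
    if not kept:
        raise ValueError("no residues in range have complete backbones")

    nf = traj.n_frames
    helical = {r: np.zeros(nf, dtype=bool) for r in kept}
    for f in range(nf):
        xyz = traj.coords[f]

        def hpos(r):
            # H approximated 1.0 Å from N along previous residue's O->C axis
            if r - 1 not in usable:
                return None
            c_prev = xyz[backbone[r - 1]["C"]]
            o_prev = xyz[backbone[r - 1]["O"]]
            n = xyz[backbone[r]["N"]]
            d = c_prev - o_prev
            return n + d / np.linalg.norm(d)

        def hbond(i, j):
            """acceptor residue i (C=O), donor residue j (N-H)."""
            if i not in usable or j not in usable:
                return False
            h = hpos(j)
            if h is None:
                return False
            e = _hbond_energy(xyz[backbone[i]["C"]], xyz[backbone[i]["O"]],
                              xyz[backbone[j]["N"]], h)
            return e < _HB_CUTOFF

        for r in kept:
            if hbond(r, r + 4) or hbond(r - 4, r):
                helical[r][f] = True

    prob = {r: float(helical[r].mean()) for r in kept}
    frac = np.mean(np.column_stack([helical[r] for r in kept]), axis=1)
    return prob, frac
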
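"""Synthetic trajectory and energy-table generators with known ground truth.

Real luciferase MD trajectories are hundreds of nanoseconds of all-atom
dynamics; none of the downstream statistics (RMSF, DCCM, Markov models,
flux networks, MM/PBSA summaries) care where the frames came from.  This
module produces inputs whose generating process is known exactly, so every
analysis stage can be tested against analytic or simulated ground truth:

* discrete jump trajectories from a prescribed row-stochastic matrix,
* overdamped Langevin paths on single/double-well potentials,
* Gaussian positional ensembles around a reference structure with
  prescribed per-site standard deviations and site-site correlations,
* per-frame energy-component tables with prescribed means and SDs.

All randomness flows from an explicit integer seed per call; no global RNG
state is touched.  Identical arguments give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory

__all__ = [
    "GeneratorConfig",
    "WellSpec",
    "sample_markov_chain",
    "langevin_double_well",
    "gaussian_ensemble",
    "synth_energy_table",
    "ENERGY_COMPONENTS",
]

#: Component keys accepted by :func:`synth_energy_table` (kcal/mol).
ENERGY_COMPONENTS = ("dE_vdw", "dE_ele", "dG_solv", "dE_int", "dG_pb", "dG_np")


@dataclass(frozen=True)
class GeneratorConfig:
    """Common knobs shared by all generators.

    Parameters
    ----------
    seed
        RNG seed; same seed + same parameters -> bit-identical output.
    n_frames
        Number of frames to generate (>= 1).
    frame_spacing_ns
        Time between saved frames in nanoseconds.  Defaults to 0.1 ns,
        the saving interval of the trajectories these generators emulate.
    """

    seed: int
    n_frames: int = 4500
    frame_spacing_ns: float = 0.1

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_spacing_ns <= 0:
            raise ValueError("frame_spacing_ns must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class WellSpec:
    """Multi-well 1-D/2-D potential for overdamped Langevin dynamics.

    The potential is a sum of quadratic wells joined by a polynomial
    barrier; for the canonical symmetric double well the form is
    ``U(x) = h * (x^2 - 1)^2`` with minima at the two centers and barrier
    height ``h`` (in kT) at the midpoint.

    Parameters
    ----------
    centers
        Well centers (dimensionless coordinates).  One entry per well.
    barrier_height
        Barrier height separating adjacent wells, in units of kT (>= 0).
    diffusion_coeff
        Diffusion coefficient D (> 0), dimensionless units per step unit.
    temperature_factor
        kT scale; enters the noise amplitude sqrt(2 D dt).
    """

    centers: tuple[float, ...] = (-1.0, 1.0)
    barrier_height: float = 3.0
    diffusion_coeff: float = 1.0
    temperature_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.centers) < 1:
            raise ValueError("at least one well center required")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        if self.diffusion_coeff <= 0:
            raise ValueError("diffusion_coeff must be positive")
        if self.temperature_factor <= 0:
            raise ValueError("temperature_factor must be positive")


def _validate_stochastic(T: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < 0):
        row = int(np.argwhere(T < 0)[0, 0])
        raise ValueError(f"transition matrix row {row} has negative entries")
    rowsums = T.sum(axis=1)
    bad = np.where(np.abs(rowsums - 1.0) > max(atol, 1e-12 * T.shape[0]))[0]
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {rowsums[bad[0]]!r}, not 1"
        )
    return T


def sample_markov_chain(
    T: np.ndarray, n_steps: int, initial_state: int = 0, seed: int = 0
) -> np.ndarray:
    """Sample a discrete jump trajectory from a row-stochastic matrix.

    Returns an integer label sequence of length ``n_steps + 1`` starting
    at ``initial_state``.  Empirical transition frequencies converge to
    ``T`` at the usual n^-1/2 rate.

    Raises
    ------
    ValueError
        If ``T`` is not square row-stochastic (the offending row is
        named) or ``initial_state`` is out of range.
    """
    T = _validate_stochastic(T)
    n = T.shape[0]
    if not 0 <= initial_state < n:
        raise ValueError(f"initial_state {initial_state} outside [0, {n})")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling against precomputed per-row cumulative sums
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_steps)
    traj = np.empty(n_steps + 1, dtype=np.int64)
    traj[0] = initial_state
    s = initial_state
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        traj[t + 1] = s
    return traj


def _well_force(x: np.ndarray, spec: WellSpec) -> np.ndarray:
    """-dU/dx for the well potential, applied per dimension."""
    c = np.asarray(spec.centers, dtype=float)
    if c.size == 1:
        # single harmonic well, stiffness = barrier_height (0 -> free diffusion)
        return -2.0 * spec.barrier_height * (x - c[0])
    # double well: U = h * ((x - m)/a)^2 - 1)^2 scaled to minima at centers
    m = 0.5 * (c.min() + c.max())
    a = 0.5 * (c.max() - c.min())
    h = spec.barrier_height
    u = (x - m) / a
    return -4.0 * h * u * (u * u - 1.0) / a


def langevin_double_well(spec: WellSpec, cfg: GeneratorConfig, n_dim: int = 1,
                         x0: float | None = None, dt: float = 0.01) -> np.ndarray:
    """Overdamped Langevin (Euler–Maruyama) path on a multi-well potential.

    dx = beta * D * F(x) dt + sqrt(2 D dt) dW, with beta = 1/kT and F the
    negative potential gradient.  Returns an array of shape
    ``(n_frames, n_dim)``; each dimension experiences the same potential.

    The first frame is the initial condition (``x0`` or the first well
    center), so a run of ``n_frames`` frames takes ``n_frames - 1`` steps.
    """
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    rng = cfg.rng()
    D = spec.diffusion_coeff
    beta = 1.0 / spec.temperature_factor
    start = spec.centers[0] if x0 is None else x0
    x = np.full(n_dim, float(start))
    out = np.empty((cfg.n_frames, n_dim))
    out[0] = x
    amp = np.sqrt(2.0 * D * dt)
    for t in range(1, cfg.n_frames):
        x = x + beta * D * _well_force(x, spec) * dt + amp * rng.standard_normal(n_dim)
        out[t] = x
    return out


def gaussian_ensemble(
    reference: Trajectory | np.ndarray,
    site_sd: np.ndarray,
    correlation: np.ndarray | None = None,
    cfg: GeneratorConfig | None = None,
) -> Trajectory:
    """Gaussian positional ensemble around a reference structure.

    Each frame is ``reference + displacement`` where displacements are
    zero-mean Gaussians, isotropic per site with standard deviation
    ``site_sd[i]`` per Cartesian component, and with prescribed site-site
    correlation ``correlation[i, j]`` (identical in x, y, z; the three
    components are independent).  This makes RMSF and DCCM ground truth
    analytic: RMSF_i = site_sd[i] * sqrt(3) and DCCM_ij = correlation[i, j]
    whenever site_sd[i], site_sd[j] > 0.

    Parameters
    ----------
    reference
        A single-frame :class:`~luciflux.trajio.Trajectory`, or a plain
        ``(n_sites, 3)`` coordinate array.
    site_sd
        Per-site displacement SD in Angstrom, length n_sites, >= 0.
    correlation
        Symmetric PSD matrix with unit diagonal; identity if omitted.
        A non-PSD matrix is rejected outright — no nearest-PSD repair is
        attempted.
    cfg
        Frame count, spacing and seed.
    """
    if cfg is None:
        raise ValueError("a GeneratorConfig is required")
    if isinstance(reference, Trajectory):
        ref_xyz = reference.coords[0]
        topo = reference.topology
    else:
        ref_xyz = np.asarray(reference, dtype=float)
        topo = Topology.point_sites(ref_xyz.shape[0])
    n_sites = ref_xyz.shape[0]
    sd = np.asarray(site_sd, dtype=float)
    if sd.shape != (n_sites,):
        raise ValueError(f"site_sd must have shape ({n_sites},), got {sd.shape}")
    if np.any(sd < 0):
        raise ValueError("site_sd entries must be >= 0")
    if correlation is None:
        corr = np.eye(n_sites)
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (n_sites, n_sites):
            raise ValueError("correlation must be site x site")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.abs(corr).max() > 1 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
    cov = corr * np.outer(sd, sd)
    # symmetric matrix square root; reject non-PSD input instead of repairing
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            "correlation matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g}); nearest-PSD repair is NOT applied — "
            "supply a valid correlation matrix"
        )
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = cfg.rng()
    # independent x/y/z with identical cross-site structure
    z = rng.standard_normal((cfg.n_frames, 3, n_sites))
    disp = z @ L.T  # (frames, 3, sites)
    coords = ref_xyz[None] + np.transpose(disp, (0, 2, 1))
    return Trajectory(topology=topo, coords=coords, frame_spacing_ns=cfg.frame_spacing_ns)


_COMPONENT_ALIASES = {
    "∆E_vdW": "dE_vdw", "∆E_vdw": "dE_vdw", "dE_vdW": "dE_vdw",
    "∆E_ele": "dE_ele",
    "∆G_solv": "dG_solv", "∆G_sol": "dG_solv", "dG_sol": "dG_solv",
    "∆E_int": "dE_int",
    "∆G_pb": "dG_pb",
    "∆G_np": "dG_np",
}


def canonical_component(key: str) -> str:
    """Map a component label (unicode or ASCII alias) to its canonical key."""
    k = _COMPONENT_ALIASES.get(key, key)
    if k not in ENERGY_COMPONENTS:
        raise KeyError(
            f"unknown energy component {key!r}; expected one of {ENERGY_COMPONENTS}"
        )
    return k


def synth_energy_table(
    component_means: dict[str, float],
    component_sds: dict[str, float],
    cfg: GeneratorConfig,
) -> pd.DataFrame:
    """Per-frame energy-component table of independent Gaussian draws.

    Keys may use unicode labels (∆E_vdW, ...) or ASCII aliases (dE_vdw, ...).
    Returns a DataFrame with one row per frame and canonical ASCII column
    names, values in kcal/mol.
    """
    means = {canonical_component(k): float(v) for k, v in component_means.items()}
    sds = {canonical_component(k): float(v) for k, v in component_sds.items()}
    if set(means) != set(sds):
        raise ValueError("component_means and component_sds must share a key set")
    for k, v in sds.items():
        if v < 0:
            raise ValueError(f"SD for {k} must be >= 0")
    rng = cfg.rng()
    cols = [c for c in ENERGY_COMPONENTS if c in means]
    data = {
        c: means[c] + sds[c] * rng.standard_normal(cfg.n_frames) for c in cols
    }
    return pd.DataFrame(data)
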
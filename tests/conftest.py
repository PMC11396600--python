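"""Shared fixtures: ideal peptide-backbone builder and tiny PDB fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from luciflux.trajio import Atom, Topology, Trajectory


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates: bond C-D, angle B-C-D,
    dihedral A-B-C-D (natural extension reference frame)."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(chi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta), r * np.sin(theta) * np.cos(chi),
                  r * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi: float, psi: float, n_res: int,
                   res_name: str = "ALA") -> Trajectory:
    """Single-frame poly-peptide backbone (N, CA, C, O) at uniform φ/ψ.

    Standard geometry: N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, C=O
    1.231 Å; ω fixed at 180°.
    """
    N = [np.zeros(3)]
    CA = [np.array([1.458, 0.0, 0.0])]
    ang = np.deg2rad(111.2)
    C = [CA[0] + 1.525 * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    O: list[np.ndarray] = []
    for i in range(n_res - 1):
        n_next = nerf_place(N[i], CA[i], C[i], 1.329, 116.2, psi)
        ca_next = nerf_place(CA[i], C[i], n_next, 1.458, 121.7, 180.0)
        c_next = nerf_place(C[i], n_next, ca_next, 1.525, 111.2, phi)
        O.append(nerf_place(N[i], CA[i], C[i], 1.231, 120.5, psi + 180.0))
        N.append(n_next)
        CA.append(ca_next)
        C.append(c_next)
    O.append(nerf_place(N[-1], CA[-1], C[-1], 1.231, 120.5, 180.0))
    atoms, coords = [], []
    for i in range(n_res):
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            atoms.append(Atom(name, name[0], i + 1, res_name, "A"))
            coords.append(pos)
    return Trajectory(Topology(atoms), np.array(coords)[None])


@pytest.fixture
def ideal_helix() -> Trajectory:
    return build_backbone(-57.0, -47.0, 12)


@pytest.fixture
def ideal_strand() -> Trajectory:
    return build_backbone(-135.0, 135.0, 12)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.597   7.227  -4.880  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       0.100   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.900   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def random_reversible_model(n: int, rng: np.random.Generator):
    """Random reversible Markov model: T = S / rowsum for symmetric S > 0."""
    from luciflux.msm import MarkovModel, _sorted_eigenvalues

    S = rng.uniform(0.05, 1.0, size=(n, n))
    S = 0.5 * (S + S.T)
    rows = S.sum(axis=1)
    T = S / rows[:, None]
    pi = rows / rows.sum()
    return MarkovModel(
        T=T, lag_steps=1, lag_ns=0.1, counts=np.zeros((n, n), dtype=np.int64),
        stationary=pi, eigenvalues=_sorted_eigenvalues(T),
        active_set=np.arange(n), reversible=True,
    )
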
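"""Minimal implicit-solvent Langevin dynamics of a disulfide-bonded cystine.

A synthetic stand-in for an external MD engine: a four-site model of the
cystine disulfide core (CB-SG-SG'-CB', the CB sites treated as united CH2
groups) with Amber-ff14SB-type bonded parameters, integrated with the BAOAB
Langevin scheme at 300 K. The flat, featureless solvent of the model plays
the role of an implicit-solvent bath through the friction/noise terms.

The purpose is to produce a physically sensible per-frame S-S distance
distribution; its mean tracks the force-field equilibrium length
(r0 = 2.038 A, observed all-atom simulations report ~2.1 A) and its variance
reflects the S-S stiffness. Only bonded terms are modelled — this is a
fixture generator, not an MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL_PER_MOL_K
from .structure import StructureFrame

# Amber-style bonded parameters (kcal/mol, Angstrom, radians).
# E_bond = K (r - r0)^2, E_angle = K (theta - theta0)^2,
# E_dihedral = sum PK (1 + cos(n*phi - gamma)).
SS_BOND = (166.0, 2.038)  # S-S
CS_BOND = (227.0, 1.810)  # CT-S
CSS_ANGLE = (68.0, math.radians(103.70))  # CT-S-S
SS_DIHEDRAL = ((3.5, 2, 0.0), (0.6, 3, 0.0))  # X-S-S-X

MASSES = np.array([14.027, 32.06, 32.06, 14.027])  # CB (united CH2), SG
ATOM_NAMES = ["CB", "SG", "SG", "CB"]
ELEMENTS = ["C", "S", "S", "C"]

# acceleration [A/ps^2] = 418.4 * force[kcal/mol/A] / mass[amu]
# (1 kcal = 4184 J exactly; Avogadro's number cancels against the molar mass)
ACC_CONV = 418.4


def _bond_terms() -> list[tuple[int, int, float, float]]:
    return [
        (0, 1, *CS_BOND),
        (1, 2, *SS_BOND),
        (2, 3, *CS_BOND),
    ]


def _angle_terms() -> list[tuple[int, int, int, float, float]]:
    return [(0, 1, 2, *CSS_ANGLE), (1, 2, 3, *CSS_ANGLE)]


def potential_energy(x: np.ndarray) -> float:
    """Total bonded energy (kcal/mol) of the four-site cystine model."""
    e = 0.0
    for i, j, k, r0 in _bond_terms():
        r = float(np.linalg.norm(x[j] - x[i]))
        e += k * (r - r0) ** 2
    for i, j, l, k, th0 in _angle_terms():
        u, v = x[i] - x[j], x[l] - x[j]
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        e += k * (math.acos(max(-1.0, min(1.0, c))) - th0) ** 2
    phi = _dihedral(x, 0, 1, 2, 3)
    for pk, n, gamma in SS_DIHEDRAL:
        e += pk * (1.0 + math.cos(n * phi - gamma))
    return e


def _dihedral(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2)))


def forces(x: np.ndarray) -> np.ndarray:
    """Analytic bonded forces (kcal/mol/A); validated against finite
    differences of :func:`potential_energy` in the test suite."""
    f = np.zeros_like(x)

    for i, j, k, r0 in _bond_terms():
        rij = x[j] - x[i]
        r = float(np.linalg.norm(rij))
        dedr = 2.0 * k * (r - r0)
        g = dedr * rij / r
        f[i] += g
        f[j] -= g

    for i, j, l, k, th0 in _angle_terms():
        u, v = x[i] - x[j], x[l] - x[j]
        nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
        uh, vh = u / nu, v / nv
        c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
        s = math.sqrt(max(1.0 - c * c, 1e-12))
        theta = math.acos(c)
        dedth = 2.0 * k * (theta - th0)
        dth_di = (c * uh - vh) / (nu * s)
        dth_dl = (c * vh - uh) / (nv * s)
        f[i] -= dedth * dth_di
        f[l] -= dedth * dth_dl
        f[j] += dedth * (dth_di + dth_dl)

    # Dihedral forces via the standard normal-vector decomposition.
    i, j, k, l = 0, 1, 2, 3
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    phi = _dihedral(x, i, j, k, l)
    dedphi = sum(-pk * n * math.sin(n * phi - gamma) for pk, n, gamma in SS_DIHEDRAL)
    # dphi/dr_i = |b2| n1 / |n1|^2, dphi/dr_l = -|b2| n2 / |n2|^2; middle
    # atoms follow from translation invariance and zero net torque.
    fi = -dedphi * nb2 * n1 / float(np.dot(n1, n1))
    fl = dedphi * nb2 * n2 / float(np.dot(n2, n2))
    t = float(np.dot(b1, b2)) / nb2**2
    s2 = float(np.dot(b3, b2)) / nb2**2
    fj = -fi - t * fi + s2 * fl
    fk = -(fi + fj + fl)
    f[i] += fi
    f[j] += fj
    f[k] += fk
    f[l] += fl
    return f


def initial_coordinates() -> np.ndarray:
    """Near-equilibrium start: bonds and angles at r0/theta0, dihedral ~90 deg."""
    th = math.radians(103.70)
    sg1 = np.array([0.0, 0.0, 0.0])
    sg2 = np.array([SS_BOND[1], 0.0, 0.0])
    cb1 = sg1 + CS_BOND[1] * np.array([math.cos(th), math.sin(th), 0.0])
    cb2 = sg2 + CS_BOND[1] * np.array([-math.cos(th), 0.0, math.sin(th)])
    return np.vstack([cb1, sg1, sg2, cb2])


@dataclass
class CystineMDRun:
    trajectory: list[StructureFrame]
    dt_fs: float
    stride: int
    temperature: float
    n_production_steps: int


def run_cystine_md(
    n_steps: int = 500_000,
    dt_fs: float = 1.0,
    temperature: float = 300.0,
    friction_per_ps: float = 1.0,
    stride: int = 50,
    equilibration_steps: int = 10_000,
    seed: int = 0,
) -> CystineMDRun:
    """Integrate the cystine model with BAOAB Langevin dynamics at T.

    Frames are emitted every ``stride`` production steps as
    :class:`StructureFrame` objects (chain A, residues 1 and 2, atoms CB/SG),
    ready for :func:`cysred.structure.bond_geometry`.
    """
    rng = np.random.default_rng(seed)
    dt = dt_fs * 1e-3  # ps
    kbt = KB_KCAL_PER_MOL_K * temperature
    m = MASSES[:, None]
    c1 = math.exp(-friction_per_ps * dt)
    c2 = np.sqrt(kbt * ACC_CONV / MASSES * (1.0 - c1 * c1))[:, None]

    x = initial_coordinates()
    v = rng.normal(0.0, np.sqrt(kbt * ACC_CONV / MASSES)[:, None], size=x.shape)
    a = forces(x) * ACC_CONV / m

    frames: list[StructureFrame] = []
    total = equilibration_steps + n_steps
    for step in range(total):
        v = v + 0.5 * dt * a
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(size=x.shape)
        x = x + 0.5 * dt * v
        a = forces(x) * ACC_CONV / m
        v = v + 0.5 * dt * a
        prod_step = step - equilibration_steps
        if prod_step >= 0 and prod_step % stride == 0:
            frames.append(
                StructureFrame(
                    elements=list(ELEMENTS),
                    radii=np.array([1.7, 1.8, 1.8, 1.7]),
                    coords=x.copy(),
                    residue_ids=np.array([1, 1, 2, 2]),
                    chain_ids=["A"] * 4,
                    atom_names=list(ATOM_NAMES),
                    frame_index=len(frames),
                )
            )
    return CystineMDRun(
        trajectory=frames,
        dt_fs=dt_fs,
        stride=stride,
        temperature=temperature,
        n_production_steps=n_steps,
    )


def mean_ss_length(run: CystineMDRun) -> tuple[float, float]:
    """Normal-fit (MLE) mean and sigma of the per-frame S-S distance."""
    from .structure import bond_geometry

    geom = bond_geometry(run.trajectory, ("A", 1), ("A", 2))
    return float(geom.distances.mean()), float(geom.distances.std(ddof=0))
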
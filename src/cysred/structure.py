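"""Structural analysis of multi-frame atomic coordinates.

Implements the Shrake-Rupley solvent-accessible surface area (SASA)
calculation from scratch (deterministic golden-spiral test points, so results
are bit-reproducible), per-frame disulfide S-S bond geometry, and effective
bond stiffness kappa_SS = kB*T / sigma^2 from the variance of the bond-length
distribution at temperature T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    BONDI_RADII,
    DEFAULT_PROBE_RADIUS,
    KB_KCAL_PER_MOL_K,
)


class DegenerateGeometryWarning(UserWarning):
    pass


@dataclass
class StructureFrame:
    """One frame of atomic coordinates with per-atom metadata.

    Arrays are index-aligned: ``elements[i]``, ``radii[i]`` (vdW, Angstrom),
    ``residue_ids[i]``, ``chain_ids[i]``, ``atom_names[i]`` and
    ``coords[i]`` (Angstrom) describe atom ``i``.
    """

    elements: list[str]
    radii: np.ndarray
    coords: np.ndarray
    residue_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    chain_ids: list[str] = field(default=None)  # type: ignore[assignment]
    atom_names: list[str] = field(default=None)  # type: ignore[assignment]
    frame_index: int = 0

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.radii = np.asarray(self.radii, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if self.residue_ids is None:
            self.residue_ids = np.zeros(n, dtype=int)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.chain_ids is None:
            self.chain_ids = ["A"] * n
        if self.atom_names is None:
            self.atom_names = [f"{el}{i}" for i, el in enumerate(self.elements)]
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atom_index(self, chain_id: str, residue_id: int, atom_name: str) -> int:
        for i in range(self.n_atoms):
            if (
                self.chain_ids[i] == chain_id
                and self.residue_ids[i] == residue_id
                and self.atom_names[i] == atom_name
            ):
                return i
        raise KeyError(
            f"atom {atom_name!r} of residue {chain_id}:{residue_id} "
            f"not found in frame {self.frame_index}"
        )


@dataclass
class BondGeometry:
    """Per-frame S-S distance and sulfur-orientation angles of one bond.

    ``theta1``/``theta2`` are the CB-SG-SG' angles at each sulfur (degrees):
    the orientation of each half-cystine's thiol relative to the bond axis.
    """

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    distances: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray


@dataclass
class StiffnessEstimate:
    sigma2: float  # Angstrom^2 (MLE variance of the bond length)
    kappa_ss: float  # kcal mol^-1 Angstrom^-2, inf when sigma2 == 0
    mean_length: float
    n_frames: int
    temperature: float
    infinite: bool = False


@dataclass
class SasaProfile:
    """Trajectory mean and sd of per-residue SASA (Angstrom^2)."""

    residues: list[tuple[str, int]]
    mean: np.ndarray
    sd: np.ndarray
    probe_radius: float
    n_sphere_points: int
    n_frames: int


def canonical_pose(coords: np.ndarray) -> np.ndarray:
    """Rigid-transform canonicalization: principal-axes pose of a point set.

    Centers the coordinates and rotates them into the covariance eigenbasis
    (axes ordered by decreasing variance, signs fixed by the third moment
    along each axis, handedness restored by flipping the most
    sign-ambiguous axis). Because the construction is covariant under
    proper rigid motions, quantities computed in this pose — in particular
    the discretized Shrake-Rupley SASA — are exactly invariant under
    translation and rotation of the input for generic structures.
    """
    x = np.asarray(coords, float)
    x = x - x.mean(axis=0)
    if len(x) < 2:
        return x
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    proj = x @ v
    m3 = (proj**3).sum(axis=0)
    scale = max(float(np.abs(proj).max()), 1.0) ** 3 * len(x)
    signs = np.where(m3 < -1e-12 * scale, -1.0, 1.0)
    v = v * signs
    if np.linalg.det(v) < 0:
        flip = int(np.argmin(np.abs(m3)))
        v[:, flip] *= -1.0
    return x @ v


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere via the golden spiral.

    Deterministic (no RNG), so SASA values are bit-reproducible.
    """
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    frame: StructureFrame,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    For each atom, ``n_points`` test points are placed on the sphere of
    radius ``r_vdw + probe``; a point is accessible when it lies outside
    every neighbouring atom's expanded sphere, and the atom's SASA is the
    accessible fraction of its expanded-sphere area. Neighbour candidates are
    restricted to atoms within ``r_i + r_j + 2*probe``.
    """
    if n_points < 12:
        raise ValueError("n_points must be >= 12")
    n = frame.n_atoms
    expanded = frame.radii + probe_radius
    unit = sphere_points(n_points)
    # principal-axes pose: makes the discretized result exactly invariant
    # under rigid motion of the input (occlusion geometry is unchanged)
    coords = canonical_pose(frame.coords)
    tree = cKDTree(coords)
    max_cut = 2.0 * float(expanded.max())
    pairs = tree.query_pairs(max_cut, output_type="ndarray")

    neighbours: list[list[int]] = [[] for _ in range(n)]
    if len(pairs):
        d = np.linalg.norm(
            coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1
        )
        within = d < expanded[pairs[:, 0]] + expanded[pairs[:, 1]]
        if np.any(d == 0.0):
            warnings.warn(
                "coincident atoms with positive radii; both scored normally",
                DegenerateGeometryWarning,
                stacklevel=2,
            )
        for (i, j), ok in zip(pairs, within):
            if ok:
                neighbours[i].append(j)
                neighbours[j].append(i)

    sasa = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        if neighbours[i]:
            nb = np.asarray(neighbours[i])
            diff = pts[:, None, :] - coords[nb][None, :, :]
            dist2 = np.einsum("pnk,pnk->pn", diff, diff)
            buried = np.any(dist2 < (expanded[nb] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = 4.0 * math.pi * expanded[i] ** 2 * frac
    return sasa


def residue_sasa_profile(
    trajectory: list[StructureFrame],
    residues: list[tuple[str, int]],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
    frame_range: tuple[int, int] | None = None,
) -> SasaProfile:
    """Trajectory-averaged SASA of selected residues (all atoms included).

    ``residues`` is a list of ``(chain_id, residue_id)`` pairs;
    ``frame_range`` optionally restricts the analysis window (e.g. to skip
    equilibration frames).
    """
    if not residues:
        raise ValueError("empty residue selection")
    frames = trajectory if frame_range is None else trajectory[slice(*frame_range)]
    if not frames:
        raise ValueError("trajectory contains no frames in the requested range")

    per_frame = np.empty((len(frames), len(residues)))
    for fi, frame in enumerate(frames):
        atom_sasa = shrake_rupley_sasa(frame, probe_radius, n_points)
        for ri, (chain, res) in enumerate(residues):
            mask = np.array(
                [
                    frame.chain_ids[a] == chain and frame.residue_ids[a] == res
                    for a in range(frame.n_atoms)
                ]
            )
            if not mask.any():
                raise KeyError(f"residue {chain}:{res} not found in frame {fi}")
            per_frame[fi, ri] = atom_sasa[mask].sum()
    return SasaProfile(
        residues=list(residues),
        mean=per_frame.mean(axis=0),
        sd=per_frame.std(axis=0),
        probe_radius=probe_radius,
        n_sphere_points=n_points,
        n_frames=len(frames),
    )


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b (degrees) of the triple a-b-c."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def bond_geometry(
    trajectory: list[StructureFrame],
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    sg_name: str = "SG",
    cb_name: str = "CB",
) -> BondGeometry:
    """S-S distance and CB-SG-SG' orientation angles, per frame."""
    dists, th1, th2 = [], [], []
    for frame in trajectory:
        sg_a = frame.coords[frame.atom_index(*residue_a, sg_name)]
        sg_b = frame.coords[frame.atom_index(*residue_b, sg_name)]
        cb_a = frame.coords[frame.atom_index(*residue_a, cb_name)]
        cb_b = frame.coords[frame.atom_index(*residue_b, cb_name)]
        dists.append(float(np.linalg.norm(sg_a - sg_b)))
        th1.append(_angle_deg(cb_a, sg_a, sg_b))
        th2.append(_angle_deg(cb_b, sg_b, sg_a))
    return BondGeometry(
        residue_a=residue_a,
        residue_b=residue_b,
        distances=np.asarray(dists),
        theta1=np.asarray(th1),
        theta2=np.asarray(th2),
    )


def estimate_stiffness(
    distances: np.ndarray,
    temperature: float = 300.0,
    kbt: float | None = None,
    min_frames: int = 30,
) -> StiffnessEstimate:
    """Effective harmonic stiffness kappa_SS = kB*T / sigma^2 of a bond.

    The normal fit is realised as maximum-likelihood mean/variance (the
    n-denominator variance), which for normal data is identical to fitting
    the distribution and avoids a histogram binning choice. ``kbt`` may be
    given explicitly (in any energy unit) to obtain kappa in matching units;
    by default kB*T in kcal/mol is used.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {d.size}")
    if kbt is None:
        kbt = KB_KCAL_PER_MOL_K * temperature
    sigma2 = float(d.var(ddof=0))
    mean = float(d.mean())
    if sigma2 == 0.0:
        return StiffnessEstimate(
            sigma2=0.0,
            kappa_ss=math.inf,
            mean_length=mean,
            n_frames=d.size,
            temperature=temperature,
            infinite=True,
        )
    return StiffnessEstimate(
        sigma2=sigma2,
        kappa_ss=kbt / sigma2,
        mean_length=mean,
        n_frames=d.size,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O (multi-model PDB and XYZ)
# ---------------------------------------------------------------------------


def _radius_for(element: str) -> float:
    try:
        return BONDI_RADII[element.capitalize()]
    except KeyError:
        raise ValueError(f"no van der Waals radius tabulated for {element!r}")


def write_trajectory_pdb(frames: list[StructureFrame], path: str | Path) -> None:
    """Write frames as a multi-model PDB file."""
    with open(path, "w") as fh:
        for mi, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.coords[i]
                fh.write(
                    "ATOM  {serial:5d} {name:<4s} {res:<3s} {chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=i + 1,
                        name=frame.atom_names[i][:4],
                        res="CYX",
                        chain=frame.chain_ids[i][:1],
                        resid=int(frame.residue_ids[i]),
                        x=x,
                        y=y,
                        z=z,
                        occ=1.0,
                        b=0.0,
                        el=frame.elements[i][:2].upper(),
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory_pdb(path: str | Path) -> list[StructureFrame]:
    """Read a (multi-model) PDB file into StructureFrames; Bondi radii by element."""
    frames: list[StructureFrame] = []
    cur: list[tuple] | None = None

    def flush(atoms: list[tuple], index: int) -> None:
        if not atoms:
            return
        els = [a[0] for a in atoms]
        frames.append(
            StructureFrame(
                elements=els,
                radii=np.array([_radius_for(e) for e in els]),
                coords=np.array([a[1] for a in atoms]),
                residue_ids=np.array([a[2] for a in atoms]),
                chain_ids=[a[3] for a in atoms],
                atom_names=[a[4] for a in atoms],
                frame_index=index,
            )
        )

    with open(path) as fh:
        cur = []
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                cur = []
            elif rec in ("ATOM  ", "HETATM"):
                element = line[76:78].strip() or line[12:16].strip()[0]
                cur.append(
                    (
                        element,
                        (float(line[30:38]), float(line[38:46]), float(line[46:54])),
                        int(line[22:26]),
                        line[21].strip() or "A",
                        line[12:16].strip(),
                    )
                )
            elif rec.startswith(("ENDMDL", "END")):
                flush(cur, len(frames))
                cur = []
        flush(cur, len(frames))
    if not frames:
        raise ValueError(f"no atoms found in {path}")
    return frames


def read_trajectory_xyz(path: str | Path) -> list[StructureFrame]:
    """Read a multi-frame XYZ file (element x y z per line)."""
    frames: list[StructureFrame] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        els, xyz = [], []
        for row in block:
            parts = row.split()
            els.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        frames.append(
            StructureFrame(
                elements=els,
                radii=np.array([_radius_for(e) for e in els]),
                coords=np.array(xyz),
                frame_index=len(frames),
            )
        )
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames
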
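"""Synthetic ground-truth inputs for every pipeline stage.

Three generators:

* a differential-alkylation peak-area table over a DTT exposure time course,
  with known per-cysteine reduction rate constants (forward model
  ``F(tau) = 1 - (1 - F0) * exp(-k * tau)``),
* harmonic S-S bond-length series with known stiffness
  (``sigma^2 = kB*T / kappa``),
* toy atomic structures whose solvent-accessible surface area is known
  analytically (single spheres, dimers, a fully buried core).

All randomness flows through one explicit seed; with the seed fixed the
outputs are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_PROBE_RADIUS, KB_KCAL_PER_MOL_K
from .structure import StructureFrame
from .topology import (
    CAM,
    NEM,
    MabDefinition,
    Peptide,
    build_disulfide_map,
    digest_tryptic,
    mz_of,
    peptide_monoisotopic_mass,
)

PEAK_TABLE_COLUMNS = [
    "mab",
    "cysteine_id",
    "bond_class",
    "timepoint_min",
    "replicate",
    "species_label",
    "charge",
    "isotope_index",
    "rt_peak_index",
    "area",
    "mass_error_ppm",
    "idotp",
    "mz",
]

#: Charge states monitored per peptide and their nominal intensity split.
CHARGE_STATES = (2, 3)
CHARGE_WEIGHTS = (0.6, 0.4)
#: Diastereomer split of NEM-containing species over two retention-time peaks.
DIASTEREOMER_SPLIT = (0.6, 0.4)


@dataclass
class TimeCourseDesign:
    """DTT partial-reduction time-course layout (times in minutes)."""

    timepoints: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 15.0, 30.0, 60.0)
    dtt_mm: float = 1.0
    replicates: int = 1

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        if not tp or tp[0] != 0.0:
            raise ValueError("timepoints must start at 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(t < 0 for t in tp):
            raise ValueError("timepoints must be non-negative")
        self.timepoints = tp


@dataclass
class NoiseModel:
    """Observation noise: multiplicative lognormal area error plus QC metadata.

    Defaults are placeholders (the source study reports neither replicate
    counts nor area CVs) and should be set from config in real use.
    """

    area_cv: float = 0.05
    ppm_jitter_sd: float = 1.5
    idotp_range: tuple[float, float] = (0.92, 1.0)

    def __post_init__(self) -> None:
        if self.area_cv < 0 or self.ppm_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        lo, hi = self.idotp_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("idotp_range must lie inside [0, 1]")


#: Stated-world class-level rate constants (1/min) under 1 mM DTT: interchain
#: and hinge cysteines reduce ~1000x faster than intrachain ones.
DEFAULT_CLASS_RATES = {
    "interchain": 1e-2,
    "hinge": 2e-2,
    "SEFL": 1e-4,
    "intrachain": 1e-5,
}
DEFAULT_F0 = 0.01  # baseline free-thiol fraction, below the reported <5%


@dataclass
class TruthTable:
    """Ground-truth (k, F0) per cysteine site, keyed by site label."""

    k: dict[str, float] = field(default_factory=dict)
    f0: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, kk in self.k.items():
            if kk < 0:
                raise ValueError(f"negative rate constant for {cid}")
        for cid, f in self.f0.items():
            if not (0 <= f < 1):
                raise ValueError(f"F0 for {cid} must lie in [0, 1)")

    @classmethod
    def from_classes(
        cls,
        analytes: list["Analyte"],
        class_rates: dict[str, float] | None = None,
        f0: float = DEFAULT_F0,
    ) -> "TruthTable":
        rates = dict(DEFAULT_CLASS_RATES)
        if class_rates:
            rates.update(class_rates)
        k: dict[str, float] = {}
        f0s: dict[str, float] = {}
        for an in analytes:
            for site in an.site_labels:
                k[site] = rates[an.bond_class]
                f0s[site] = f0
        return cls(k=k, f0=f0s)


@dataclass(frozen=True)
class Analyte:
    """One monitored quantity: a quantifiable cysteine peptide.

    ``site_labels`` holds one site (e.g. ``LC:C214``) or, for the hinge
    peptide carrying both hinge cysteines, two.
    """

    cysteine_id: str
    bond_class: str
    site_labels: tuple[str, ...]
    peptide: Peptide
    chain_kind: str  # LC | HC


def enumerate_analytes(mab: MabDefinition) -> list[Analyte]:
    """Quantifiable cysteine analytes of a molecule, one per unique peptide.

    Chain copies are indistinguishable in the mass spectrometer, so sites are
    collapsed to (chain kind, position). Cysteines on peptides below the
    retention-length threshold are omitted (they are 'ND' in a real map), and
    cysteines sharing one peptide (the hinge pair) form a single analyte.
    """
    bond_map = build_disulfide_map(mab)
    class_of: dict[tuple[str, int], str] = {}
    for bond in bond_map:
        for site in bond.sites:
            class_of[(site.chain[:2], site.position)] = site.bond_class

    analytes: list[Analyte] = []
    for kind, seq in (("LC", mab.lc_sequence), ("HC", mab.hc_sequence)):
        positions = sorted({p for (ck, p) in class_of if ck == kind})
        for pep in digest_tryptic(seq):
            cys_here = [p for p in positions if p in pep.cys_positions]
            if not cys_here:
                continue
            if not pep.quantifiable:
                continue
            labels = tuple(f"{kind}:C{p}" for p in cys_here)
            classes = {class_of[(kind, p)] for p in cys_here}
            if len(classes) != 1:
                raise ValueError(
                    f"peptide {pep.sequence} mixes bond classes {classes}"
                )
            analytes.append(
                Analyte(
                    cysteine_id="/".join(labels),
                    bond_class=classes.pop(),
                    site_labels=labels,
                    peptide=pep,
                    chain_kind=kind,
                )
            )
    return analytes


def fraction_reduced(k: float, f0: float, tau: float) -> float:
    """Forward kinetic model: F(tau) = 1 - (1 - F0) exp(-k tau)."""
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    return 1.0 - (1.0 - f0) * math.exp(-k * tau)


def isotope_envelope(mass: float, n_isotopes: int = 3) -> np.ndarray:
    """Relative intensities of the first isotopes, Poisson approximation.

    The mean number of heavy-isotope substitutions grows roughly linearly
    with mass (lambda = 0.0006 * mass for peptides); only the shape matters
    downstream, which sums areas over isotopes anyway.
    """
    lam = 0.0006 * mass
    k = np.arange(n_isotopes)
    weights = np.exp(-lam) * lam**k / np.array([math.factorial(i) for i in k])
    return weights / weights.sum()


def _species_shares(analyte: Analyte, truth: TruthTable, tau: float) -> dict[str, float]:
    """Noise-free intensity share of each alkylation species at time tau."""
    fs = [
        fraction_reduced(truth.k[s], truth.f0.get(s, 0.0), tau)
        for s in analyte.site_labels
    ]
    if len(fs) == 1:
        return {"NEM": fs[0], "CAM": 1.0 - fs[0]}
    f1, f2 = fs
    return {
        "NEM/NEM": f1 * f2,
        "NEM/CAM": f1 * (1.0 - f2),
        "CAM/NEM": (1.0 - f1) * f2,
        "CAM/CAM": (1.0 - f1) * (1.0 - f2),
    }


def _species_mass(analyte: Analyte, species_label: str) -> float:
    adducts = [NEM if part == "NEM" else CAM for part in species_label.split("/")]
    return peptide_monoisotopic_mass(analyte.peptide, adducts)


def simulate_reduction_timecourse(
    mab: MabDefinition,
    truth: TruthTable | None = None,
    design: TimeCourseDesign | None = None,
    noise: NoiseModel | None = None,
    total_intensity: float = 1e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Skyline-style peak-area table for a DTT time course.

    Each analyte's total intensity is split between alkylation species
    according to the forward kinetic model, then spread over two charge
    states x three isotopes (and two diastereomer retention-time peaks for
    NEM-containing species) before multiplicative lognormal noise is applied.
    """
    design = design or TimeCourseDesign()
    noise = noise or NoiseModel()
    analytes = enumerate_analytes(mab)
    if truth is None:
        truth = TruthTable.from_classes(analytes)
    for an in analytes:
        for site in an.site_labels:
            if site not in truth.k:
                raise ValueError(f"no ground-truth rate for {site}")

    rng = np.random.default_rng(seed)
    log_sigma = math.sqrt(math.log(1.0 + noise.area_cv**2))
    rows = []
    for an in analytes:
        masses = {
            sp: _species_mass(an, sp)
            for sp in _species_shares(an, truth, 0.0)
        }
        envelopes = {sp: isotope_envelope(m) for sp, m in masses.items()}
        for rep in range(design.replicates):
            for tau in design.timepoints:
                shares = _species_shares(an, truth, tau)
                for sp, share in shares.items():
                    rt_split = (
                        DIASTEREOMER_SPLIT if "NEM" in sp else (1.0,)
                    )
                    for charge, cw in zip(CHARGE_STATES, CHARGE_WEIGHTS):
                        for iso in range(3):
                            for rt_index, rt_w in enumerate(rt_split):
                                base = (
                                    total_intensity
                                    * share
                                    * cw
                                    * envelopes[sp][iso]
                                    * rt_w
                                )
                                if noise.area_cv > 0:
                                    factor = math.exp(
                                        rng.normal(-0.5 * log_sigma**2, log_sigma)
                                    )
                                else:
                                    factor = 1.0
                                rows.append(
                                    (
                                        mab.name,
                                        an.cysteine_id,
                                        an.bond_class,
                                        tau,
                                        rep,
                                        sp,
                                        charge,
                                        iso,
                                        rt_index,
                                        base * factor,
                                        rng.normal(0.0, noise.ppm_jitter_sd)
                                        if noise.ppm_jitter_sd > 0
                                        else 0.0,
                                        rng.uniform(*noise.idotp_range),
                                        mz_of(masses[sp], charge),
                                    )
                                )
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def write_peak_table(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    """Write the peak table CSV, with optional '#'-prefixed provenance header."""
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns and c != "mz"]
    if missing:
        raise ValueError(f"peak table is missing required column(s): {missing}")
    return df


#: Stated-world trajectory-averaged SASA per bond class (Angstrom^2):
#: interchain cysteines are highly exposed, intrachain ones essentially
#: buried (>1000-fold less accessible), hinge/SEFL in between.
DEFAULT_CLASS_SASA = {
    "interchain": 62.0,
    "hinge": 8.0,
    "SEFL": 0.6,
    "intrachain": 0.06,
}

#: Linear coupling k = SASA_SLOPE * SASA used by the linear-truth generator;
#: chosen so the class SASA values above reproduce DEFAULT_CLASS_RATES.
SASA_SLOPE = 1.6e-4


def synthesize_sasa_truth(
    analytes: list[Analyte],
    class_sasa: dict[str, float] | None = None,
    jitter_sd: float = 0.25,
    seed: int = 0,
) -> dict[str, float]:
    """Per-site ground-truth mean SASA: class level times a lognormal jitter."""
    sasa = dict(DEFAULT_CLASS_SASA)
    if class_sasa:
        sasa.update(class_sasa)
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for an in analytes:
        for site in an.site_labels:
            out[site] = sasa[an.bond_class] * math.exp(rng.normal(0.0, jitter_sd))
    return out


def truth_from_sasa(
    analytes: list[Analyte],
    sasa: dict[str, float],
    slope: float = SASA_SLOPE,
    f0: float = DEFAULT_F0,
    class_overrides: dict[str, float] | None = None,
) -> TruthTable:
    """Linear-truth rate table: k = slope * SASA per site.

    ``class_overrides`` replaces the linear rate for whole classes — by
    default the hinge, whose reduction is faster than its accessibility
    alone predicts (it sits above the SASA-k line).
    """
    overrides = {"hinge": DEFAULT_CLASS_RATES["hinge"]}
    if class_overrides is not None:
        overrides = dict(class_overrides)
    k: dict[str, float] = {}
    f0s: dict[str, float] = {}
    for an in analytes:
        for site in an.site_labels:
            k[site] = overrides.get(an.bond_class, slope * sasa[site])
            f0s[site] = f0
    return TruthTable(k=k, f0=f0s)


# ---------------------------------------------------------------------------
# Harmonic bond series
# ---------------------------------------------------------------------------


def simulate_harmonic_bond_series(
    mean: float = 2.1,
    kappa: float = 200.0,
    temperature: float = 300.0,
    n_frames: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """I.i.d. bond lengths from the Boltzmann distribution of a harmonic bond.

    A bond of stiffness ``kappa`` (kcal/mol/A^2) at temperature T samples
    lengths Normal(mean, sigma^2 = kB*T / kappa). Default mean 2.1 A is the
    equilibrium disulfide S-S length seen in all-atom simulations.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    sigma = math.sqrt(KB_KCAL_PER_MOL_K * temperature / kappa)
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sigma, size=n_frames)


# ---------------------------------------------------------------------------
# Toy structures with analytically known SASA
# ---------------------------------------------------------------------------


@dataclass
class ToyStructure:
    frame: StructureFrame
    expected_atom_sasa: np.ndarray | None  # None when no closed form exists
    probe_radius: float


def _sphere_area(r: float) -> float:
    return 4.0 * math.pi * r * r


def _icosahedron_directions() -> np.ndarray:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for a in (1.0, -1.0):
        for b in (phi, -phi):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_toy_structure(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> ToyStructure:
    """Build a small test structure; analytic kinds return exact SASA.

    Kinds: ``single_sphere``, ``far_dimer``, ``overlapping_dimer``,
    ``random_cluster``, ``buried_core``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "single_sphere":
        r = p.get("radius", 1.9)
        frame = StructureFrame(["S"], np.array([r]), np.zeros((1, 3)))
        expected = np.array([_sphere_area(r + probe_radius)])

    elif kind == "far_dimer":
        r1 = p.get("radius_a", 1.7)
        r2 = p.get("radius_b", 1.52)
        d = p.get(
            "separation", 2.0 * (max(r1, r2) + probe_radius) + 1.0
        )
        if d <= r1 + r2 + 2 * probe_radius:
            raise ValueError("far_dimer separation leaves the spheres occluding")
        frame = StructureFrame(
            ["C", "O"],
            np.array([r1, r2]),
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        )
        expected = np.array(
            [_sphere_area(r1 + probe_radius), _sphere_area(r2 + probe_radius)]
        )

    elif kind == "overlapping_dimer":
        r1 = p.get("radius_a", 1.7)
        r2 = p.get("radius_b", 1.52)
        R1, R2 = r1 + probe_radius, r2 + probe_radius
        d = p.get("separation", 0.75 * (R1 + R2))
        if not (abs(R1 - R2) < d < R1 + R2):
            raise ValueError("overlapping_dimer needs |R1-R2| < d < R1+R2")
        # Spherical-cap geometry: each expanded sphere loses the cap cut off
        # by the radical plane of the intersection circle.
        x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
        x2 = d - x1
        frame = StructureFrame(
            ["C", "O"],
            np.array([r1, r2]),
            np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        )
        expected = np.array(
            [2.0 * math.pi * R1 * (R1 + x1), 2.0 * math.pi * R2 * (R2 + x2)]
        )

    elif kind == "random_cluster":
        n = p.get("n_atoms", 5)
        box = p.get("box", 5.0)
        elements = [["C", "N", "O", "S"][i % 4] for i in range(n)]
        radii = np.array([{"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}[e] for e in elements])
        coords = rng.uniform(0.0, box, size=(n, 3))
        frame = StructureFrame(elements, radii, coords)
        expected = None

    elif kind == "buried_core":
        r = p.get("radius", 1.7)
        R = r + probe_radius
        # 12 icosahedral neighbours at 1.1 R: every surface point of the
        # central expanded sphere lies inside some neighbour's expanded
        # sphere (occlusion cap half-angle 56.6 deg > icosahedron covering
        # radius 37.4 deg), so the central atom's SASA is exactly zero.
        d = p.get("separation", 1.1 * R)
        dirs = _icosahedron_directions()
        coords = np.vstack([np.zeros(3), d * dirs])
        frame = StructureFrame(
            ["C"] * 13,
            np.full(13, r),
            coords,
            residue_ids=np.array([0] + [1] * 12),
        )
        expected = None  # analytic only for the central atom (zero)

    else:
        raise ValueError(f"unknown toy-structure kind {kind!r}")

    return ToyStructure(frame=frame, expected_atom_sasa=expected, probe_radius=probe_radius)
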
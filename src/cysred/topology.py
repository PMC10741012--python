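"""Antibody disulfide topology: chains, cysteine registry, digestion and masses.

An IgG1 molecule carries two light chains (LC) and two heavy chains (HC).
Its cysteines pair into disulfide bonds of four classes:

* ``intrachain`` — within one domain of one chain (12 per molecule),
* ``interchain`` — LC–HC bonds at the end of each light chain (2),
* ``hinge``      — the two HC–HC bonds in the flexible hinge (2),
* ``SEFL``       — the engineered extra CH2 bond of stable
  effector-functionless molecules (2).

Positions use mature linear numbering: 1-based residue numbers of the
processed (signal-peptide-free) chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .constants import (
    CAM_DELTA,
    NEM_DELTA,
    PROTON_MASS,
    RESIDUE_MONOISOTOPIC,
    WATER_MASS,
)

BOND_CLASSES = ("intrachain", "interchain", "hinge", "SEFL")
CHAIN_IDS = ("LC1", "LC2", "HC1", "HC2")

#: Tryptic peptides shorter than this are flagged non-quantifiable: very short
#: hydrophilic peptides are not retained on reversed-phase columns, so their
#: alkylation state cannot be measured ("ND").
MIN_RETAINED_LENGTH = 5


class TopologyError(ValueError):
    """Inconsistent disulfide registry (unpaired or doubly-paired cysteine)."""


class DefinitionError(ValueError):
    """A registry position does not hold a cysteine, or a chain is unknown."""


@dataclass(frozen=True)
class CysteineSite:
    """One cysteine: chain copy, mature-linear position, bond class."""

    chain: str  # LC1 / LC2 / HC1 / HC2
    position: int  # 1-based mature linear numbering
    bond_class: str

    def __post_init__(self) -> None:
        if self.chain not in CHAIN_IDS:
            raise DefinitionError(f"unknown chain {self.chain!r}")
        if self.bond_class not in BOND_CLASSES:
            raise DefinitionError(f"unknown bond class {self.bond_class!r}")
        if self.position < 1:
            raise DefinitionError("position must be >= 1")

    @property
    def label(self) -> str:
        """Human-readable label in the field's convention, e.g. ``LC:C214``."""
        return f"{self.chain[:2]}:C{self.position}"


@dataclass(frozen=True)
class DisulfideBond:
    site_a: CysteineSite
    site_b: CysteineSite

    def __post_init__(self) -> None:
        if self.site_a == self.site_b:
            raise DefinitionError("a disulfide bond needs two distinct cysteines")
        if self.site_a.bond_class != self.site_b.bond_class:
            raise DefinitionError(
                f"bond class mismatch: {self.site_a} vs {self.site_b}"
            )

    @property
    def bond_class(self) -> str:
        return self.site_a.bond_class

    @property
    def sites(self) -> tuple[CysteineSite, CysteineSite]:
        return (self.site_a, self.site_b)


@dataclass
class MabDefinition:
    """A monoclonal IgG1 antibody: sequences plus its cysteine registry.

    ``registry`` is a list of per-cysteine entries
    ``{chain, position, bond_class, partner: {chain, position}}`` — the JSON
    schema accepted from config files. ``build_disulfide_map`` turns it into
    validated :class:`DisulfideBond` objects.
    """

    name: str
    lc_sequence: str
    hc_sequence: str
    light_chain_isotype: str  # kappa | lambda
    registry: list[dict] = field(default_factory=list)

    def chain_sequence(self, chain: str) -> str:
        if chain in ("LC1", "LC2"):
            return self.lc_sequence
        if chain in ("HC1", "HC2"):
            return self.hc_sequence
        raise DefinitionError(f"unknown chain {chain!r}")


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located in its parent chain (1-based inclusive)."""

    sequence: str
    start: int
    end: int
    cys_positions: tuple[int, ...]
    quantifiable: bool

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span does not match sequence length")


@dataclass(frozen=True)
class AdductSpec:
    """A cysteine alkylation adduct and its monoisotopic mass shift."""

    label: str  # NEM | CAM | none
    delta_mass: float


NEM = AdductSpec("NEM", NEM_DELTA)
CAM = AdductSpec("CAM", CAM_DELTA)
NO_ADDUCT = AdductSpec("none", 0.0)


def _site_from_entry(mab: MabDefinition, entry: dict) -> CysteineSite:
    site = CysteineSite(entry["chain"], entry["position"], entry["bond_class"])
    seq = mab.chain_sequence(site.chain)
    if site.position > len(seq):
        raise DefinitionError(
            f"{site.label}: position {site.position} beyond chain length {len(seq)}"
        )
    if seq[site.position - 1] != "C":
        raise DefinitionError(
            f"{site.label}: residue at position {site.position} is "
            f"{seq[site.position - 1]!r}, not C"
        )
    return site


def build_disulfide_map(mab: MabDefinition) -> list[DisulfideBond]:
    """Validate the cysteine registry and pair entries into disulfide bonds.

    Every registered cysteine must appear in exactly one bond, its partner
    entry must point back at it, and both partners must carry the same bond
    class. For a canonical IgG1 (+SEFL) the resulting map counts are
    12 intrachain, 2 interchain, 2 hinge (and 2 SEFL).
    """
    sites: dict[tuple[str, int], CysteineSite] = {}
    partner_of: dict[tuple[str, int], tuple[str, int]] = {}
    for entry in mab.registry:
        site = _site_from_entry(mab, entry)
        key = (site.chain, site.position)
        if key in sites:
            raise TopologyError(f"{site.label} registered twice")
        sites[key] = site
        partner = entry.get("partner")
        if partner is None:
            raise TopologyError(f"{site.label} has no partner (unpaired cysteine)")
        partner_of[key] = (partner["chain"], partner["position"])

    bonds: list[DisulfideBond] = []
    seen: set[tuple[str, int]] = set()
    for key, site in sites.items():
        if key in seen:
            continue
        pkey = partner_of[key]
        if pkey not in sites:
            raise TopologyError(
                f"{site.label}: partner {pkey[0]}:C{pkey[1]} is not registered"
            )
        if partner_of[pkey] != key:
            raise TopologyError(
                f"{site.label}: partner entry does not point back at it"
            )
        if pkey == key:
            raise TopologyError(f"{site.label} is bonded to itself")
        bonds.append(DisulfideBond(site, sites[pkey]))
        seen.add(key)
        seen.add(pkey)
    return bonds


def classify_cysteine(
    site_or_label: CysteineSite | tuple[str, int],
    bond_map: list[DisulfideBond],
) -> str:
    """Return the bond class of the bond containing the given cysteine."""
    if isinstance(site_or_label, CysteineSite):
        key = (site_or_label.chain, site_or_label.position)
    else:
        key = site_or_label
    for bond in bond_map:
        for site in bond.sites:
            if (site.chain, site.position) == key:
                return site.bond_class
    raise KeyError(f"cysteine {key[0]}:C{key[1]} not present in the disulfide map")


def class_counts(bond_map: list[DisulfideBond]) -> dict[str, int]:
    counts = {cls: 0 for cls in BOND_CLASSES}
    for bond in bond_map:
        counts[bond.bond_class] += 1
    return counts


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 0,
    min_retained_length: int = MIN_RETAINED_LENGTH,
) -> list[Peptide]:
    """In-silico tryptic digestion: cleave after K or R except before P.

    With ``missed_cleavages = m`` every peptide spanning up to ``m + 1``
    consecutive fully-cleaved fragments is emitted. Peptides shorter than
    ``min_retained_length`` are flagged ``quantifiable=False`` (too short to
    be retained on a reversed-phase column).
    """
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in RESIDUE_MONOISOTOPIC:
            raise ValueError(f"non-standard residue {ch!r}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")

    # Fully-cleaved fragment boundaries (0-based end-exclusive cut points).
    cuts = [0]
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))

    peptides: list[Peptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[i], cuts[j]
            seq = sequence[start:end]
            cys = tuple(
                start + k + 1 for k, ch in enumerate(seq) if ch == "C"
            )
            peptides.append(
                Peptide(
                    sequence=seq,
                    start=start + 1,
                    end=end,
                    cys_positions=cys,
                    quantifiable=len(seq) >= min_retained_length,
                )
            )
    return peptides


def peptide_monoisotopic_mass(
    peptide: Peptide | str, adducts: list[AdductSpec] | None = None
) -> float:
    """Monoisotopic mass of a peptide plus any cysteine adducts (Da).

    Mass is the sum of residue masses plus one water, plus the adduct deltas;
    at most one adduct per cysteine is allowed.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    adducts = adducts or []
    real_adducts = [a for a in adducts if a.label != "none"]
    n_cys = seq.count("C")
    if len(real_adducts) > n_cys:
        raise ValueError(
            f"{len(real_adducts)} adducts for a peptide with {n_cys} cysteine(s)"
        )
    try:
        mass = sum(RESIDUE_MONOISOTOPIC[ch] for ch in seq)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None
    return mass + WATER_MASS + sum(a.delta_mass for a in real_adducts)


def mz_of(mass: float, charge: int) -> float:
    """m/z of a peptide of the given neutral monoisotopic mass."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def read_fasta_chains(path: str | Path) -> dict[str, str]:
    """Read chain sequences from FASTA, keyed by record id (e.g. LC, HC)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_registry(path: str | Path) -> list[dict]:
    """Load a cysteine registry JSON file (list of per-cysteine entries)."""
    with open(path) as fh:
        registry = json.load(fh)
    if not isinstance(registry, list):
        raise DefinitionError("registry JSON must be a list of entries")
    return registry


# ---------------------------------------------------------------------------
# Example molecule
# ---------------------------------------------------------------------------

_FILLER = "ADEFGHILMNQSTVWY"  # no C, K, R, P: cleavage pattern fully controlled

# Mature-linear cysteine positions following the canonical IgG1 layout
# (variable + constant domain pairs; CH2 intrachain pair at placeholder
# positions 264/324, user-overridable).
_LC_CYS = (23, 88, 134, 194, 214)
_HC_CYS = (22, 96, 147, 203, 223, 229, 232, 264, 295, 305, 324, 370, 428)
_LC_LEN = 214
_HC_LEN = 450


def _build_chain(length: int, cys_positions: tuple[int, ...], k_sites: list[int]) -> str:
    seq = [_FILLER[i % len(_FILLER)] for i in range(length)]
    for pos in cys_positions:
        seq[pos - 1] = "C"
    for pos in k_sites:
        if pos - 1 < length and (pos not in cys_positions):
            seq[pos - 1] = "K"
    return "".join(seq)


def _hc_cleavage_sites() -> list[int]:
    sites = []
    for pos in range(12, _HC_LEN, 12):
        if 217 <= pos <= 240:  # hinge region handled explicitly below
            continue
        if pos in _HC_CYS:
            pos += 2  # keep the cysteine, shift the cleavage site
        sites.append(pos)
    # Interchain C223 sits on a deliberately 4-residue peptide (221-224) so it
    # is non-quantifiable, as its conserved real-world counterpart is; the two
    # hinge cysteines C229/C232 share the peptide 225-240.
    sites.extend([220, 224, 240])
    return sorted(sites)


def example_igg1(
    name: str = "mAb1",
    light_chain_isotype: str = "kappa",
    include_sefl: bool = True,
) -> MabDefinition:
    """A synthetic IgG1-like molecule with the canonical disulfide layout.

    Sequences are deterministic synthetic stand-ins (real therapeutic mAb
    sequences are proprietary): cysteines sit at the canonical mature-linear
    positions, and lysines are placed so that every cysteine lands on a
    well-sized tryptic peptide — except the HC interchain cysteine C223,
    whose peptide is 4 residues and therefore non-quantifiable, and the two
    hinge cysteines C229/C232, which share a single peptide.
    """
    lc = _build_chain(_LC_LEN, _LC_CYS, [p for p in range(12, _LC_LEN, 12)])
    hc = _build_chain(_HC_LEN, _HC_CYS, _hc_cleavage_sites())

    def entry(chain: str, pos: int, cls: str, pchain: str, ppos: int) -> dict:
        return {
            "chain": chain,
            "position": pos,
            "bond_class": cls,
            "partner": {"chain": pchain, "position": ppos},
        }

    registry: list[dict] = []
    for lc_chain, hc_chain in (("LC1", "HC1"), ("LC2", "HC2")):
        registry += [
            entry(lc_chain, 23, "intrachain", lc_chain, 88),
            entry(lc_chain, 88, "intrachain", lc_chain, 23),
            entry(lc_chain, 134, "intrachain", lc_chain, 194),
            entry(lc_chain, 194, "intrachain", lc_chain, 134),
            entry(lc_chain, 214, "interchain", hc_chain, 223),
            entry(hc_chain, 223, "interchain", lc_chain, 214),
        ]
        for a, b in ((22, 96), (147, 203), (264, 324), (370, 428)):
            registry += [
                entry(hc_chain, a, "intrachain", hc_chain, b),
                entry(hc_chain, b, "intrachain", hc_chain, a),
            ]
        if include_sefl:
            registry += [
                entry(hc_chain, 295, "SEFL", hc_chain, 305),
                entry(hc_chain, 305, "SEFL", hc_chain, 295),
            ]
    for pos in (229, 232):
        registry += [
            entry("HC1", pos, "hinge", "HC2", pos),
            entry("HC2", pos, "hinge", "HC1", pos),
        ]

    return MabDefinition(
        name=name,
        lc_sequence=lc,
        hc_sequence=hc,
        light_chain_isotype=light_chain_isotype,
        registry=registry,
    )
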
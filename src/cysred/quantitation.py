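"""Peak-area quantitation of differential alkylation.

Turns per-species extracted-ion-chromatogram areas into per-cysteine
NEM-alkylation fractions F(tau): the fraction of a cysteine's population that
carried a free thiol (and was NEM-labelled) at exposure time tau. QC filters
mirror standard peptide-map practice: mass accuracy better than 5 ppm and an
isotopic dot product better than 0.9 per charge state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MAX_PPM = 5.0
DEFAULT_MIN_IDOTP = 0.9
#: Warn when the unlabelled-peptide signal exceeds this share of the total.
UNLABELED_WARN_FRACTION = 0.01


@dataclass
class QcResult:
    kept: pd.DataFrame
    removed: pd.DataFrame  # with a 'qc_reason' column


@dataclass
class AlkylationFraction:
    cysteine_id: str
    timepoint_min: float
    fraction_nem: float | None  # None == 'ND' (no signal at all)
    total_area: float
    n_observations: int
    bond_class: str | None = None
    mab: str | None = None
    replicate: int = 0


def qc_filter(
    observations: pd.DataFrame,
    max_ppm: float = DEFAULT_MAX_PPM,
    min_idotp: float = DEFAULT_MIN_IDOTP,
) -> QcResult:
    """Drop observations failing mass-accuracy or isotope-envelope QC.

    Failures drop the offending charge-state observation only (not the whole
    peptide-timepoint); removals are returned with their reason.
    """
    ppm_bad = observations["mass_error_ppm"].abs() > max_ppm
    idotp_bad = observations["idotp"] < min_idotp
    bad = ppm_bad | idotp_bad
    removed = observations[bad].copy()
    reasons = []
    for p, i in zip(ppm_bad[bad], idotp_bad[bad]):
        r = []
        if p:
            r.append(f"|ppm| > {max_ppm}")
        if i:
            r.append(f"idotp < {min_idotp}")
        reasons.append("; ".join(r))
    removed["qc_reason"] = reasons
    if len(removed):
        logger.info("QC removed %d / %d observations", len(removed), len(observations))
    return QcResult(kept=observations[~bad].copy(), removed=removed)


def total_species_area(observations: pd.DataFrame) -> float:
    """Total area of one species: summed over charge states, isotopes and
    diastereomer retention-time peaks."""
    if len(observations) == 0:
        return 0.0
    labels = observations["species_label"].unique()
    if len(labels) > 1:
        raise ValueError(f"mixed species labels in one summation: {sorted(labels)}")
    return float(observations["area"].sum())


def nem_fraction_single(nem_area: float, cam_area: float) -> float | None:
    """NEM fraction of a single-cysteine peptide: NEM / (NEM + CAM).

    Returns None ('ND') when there is no signal in either channel.
    """
    if nem_area < 0 or cam_area < 0:
        raise ValueError("areas must be non-negative")
    total = nem_area + cam_area
    if total == 0:
        return None
    return nem_area / total


def nem_fraction_hinge(
    area_both_nem: float,
    area_mixed_1: float,
    area_mixed_2: float,
    area_both_cam: float,
) -> float | None:
    """Total hinge NEM level from the four two-cysteine species.

    All three species containing at least one NEM count at full weight in
    the numerator, normalised by the sum of all four peaks. Note this weights
    singly-labelled species upward relative to the per-site expectation
    (see :func:`nem_fraction_hinge_per_site`).
    """
    areas = (area_both_nem, area_mixed_1, area_mixed_2, area_both_cam)
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    total = sum(areas)
    if total == 0:
        return None
    return (area_both_nem + area_mixed_1 + area_mixed_2) / total


def nem_fraction_hinge_per_site(
    area_both_nem: float,
    area_mixed_1: float,
    area_mixed_2: float,
    area_both_cam: float,
) -> float | None:
    """Per-site expected NEM fraction of the hinge pair (sensitivity variant):
    each mixed species contributes one of two sites."""
    areas = (area_both_nem, area_mixed_1, area_mixed_2, area_both_cam)
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    total = sum(areas)
    if total == 0:
        return None
    return (2.0 * area_both_nem + area_mixed_1 + area_mixed_2) / (2.0 * total)


def _is_hinge_table(species: pd.Series) -> bool:
    return species.str.contains("/").any()


def alkylation_fractions(
    peak_table: pd.DataFrame,
    max_ppm: float = DEFAULT_MAX_PPM,
    min_idotp: float = DEFAULT_MIN_IDOTP,
    hinge_per_site: bool = False,
) -> pd.DataFrame:
    """Full quantitation: QC filter, species totals, per-cysteine fractions.

    Returns one row per (mab, cysteine_id, replicate, timepoint) with the
    NEM fraction (NaN for 'ND'), total area and observation count.
    """
    required = {"cysteine_id", "timepoint_min", "species_label", "area",
                "mass_error_ppm", "idotp"}
    missing = required - set(peak_table.columns)
    if missing:
        raise ValueError(f"peak table is missing required column(s): {sorted(missing)}")
    table = peak_table.copy()
    for optional, default in (("mab", ""), ("replicate", 0), ("bond_class", "")):
        if optional not in table.columns:
            table[optional] = default

    kept = qc_filter(table, max_ppm, min_idotp).kept

    unlabeled = kept[kept["species_label"] == "unlabeled"]
    if len(unlabeled):
        share = unlabeled["area"].sum() / max(kept["area"].sum(), 1e-300)
        if share > UNLABELED_WARN_FRACTION:
            logger.warning(
                "unlabeled-peptide signal is %.2f%% of total (> %.0f%%)",
                100 * share, 100 * UNLABELED_WARN_FRACTION,
            )
        kept = kept[kept["species_label"] != "unlabeled"]

    rows = []
    keys = ["mab", "cysteine_id", "bond_class", "replicate", "timepoint_min"]
    for (mab, cid, cls, rep, tau), grp in kept.groupby(keys, sort=True):
        totals = {
            sp: total_species_area(sub)
            for sp, sub in grp.groupby("species_label")
        }
        if _is_hinge_table(grp["species_label"]):
            frac = (nem_fraction_hinge_per_site if hinge_per_site else nem_fraction_hinge)(
                totals.get("NEM/NEM", 0.0),
                totals.get("NEM/CAM", 0.0),
                totals.get("CAM/NEM", 0.0),
                totals.get("CAM/CAM", 0.0),
            )
        else:
            frac = nem_fraction_single(totals.get("NEM", 0.0), totals.get("CAM", 0.0))
        rows.append(
            {
                "mab": mab,
                "cysteine_id": cid,
                "bond_class": cls,
                "replicate": rep,
                "timepoint_min": tau,
                "fraction_nem": math.nan if frac is None else frac,
                "total_area": sum(totals.values()),
                "n_observations": len(grp),
            }
        )
    return pd.DataFrame(rows)


def write_fraction_table(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
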
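"""Solvent accessibility versus reduction rate.

Relates the trajectory-averaged SASA of each cysteine to its fitted
pseudo-first-order reduction rate constant k: Pearson correlation and an
ordinary least-squares line on the raw (SASA, k) values, with hinge
residues excluded by default — hinge disulfides reduce fast despite modest
accessibility (their flexibility adds mechanical stress), so they sit above
the line and depress the correlation when included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SasaRatePair:
    cysteine_id: str
    bond_class: str
    mean_sasa: float  # Angstrom^2
    k: float  # 1/min

    def __post_init__(self) -> None:
        if self.mean_sasa < 0 or self.k < 0:
            raise ValueError("mean_sasa and k must be non-negative")


@dataclass
class CorrelationResult:
    pearson_r: float | None  # None when undefined (zero variance)
    slope: float | None
    intercept: float | None
    n_used: int
    excluded: list[SasaRatePair]
    pearson_r_all: float | None  # sensitivity: including excluded classes
    reason: str | None = None  # why r is undefined, when it is


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def correlate_sasa_rate(
    pairs: list[SasaRatePair],
    exclude_classes: set[str] = frozenset({"hinge"}),
    log_log: bool = False,
) -> CorrelationResult:
    """Pearson r and OLS fit of k against mean SASA.

    Pairs whose bond class is in ``exclude_classes`` are left out of the fit
    but reported, and a correlation including them is also computed for the
    sensitivity comparison. ``log_log`` fits on log10 of both axes instead
    (useful given the ~1000-fold dynamic range, off by default: the relation
    is modelled as linear on raw values).
    """
    excluded = [p for p in pairs if p.bond_class in exclude_classes]
    used = [p for p in pairs if p.bond_class not in exclude_classes]
    if len(used) < 3:
        raise ValueError(f"need >= 3 pairs after exclusion, got {len(used)}")

    def axes(ps: list[SasaRatePair]) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p.mean_sasa for p in ps])
        y = np.array([p.k for p in ps])
        if log_log:
            if np.any(x <= 0) or np.any(y <= 0):
                raise ValueError("log_log requires strictly positive SASA and k")
            x, y = np.log10(x), np.log10(y)
        return x, y

    x, y = axes(used)
    r = _pearson(x, y)
    if r is None:
        zero_axis = "SASA" if np.ptp(x) == 0 else "k"
        return CorrelationResult(
            pearson_r=None,
            slope=None,
            intercept=None,
            n_used=len(used),
            excluded=excluded,
            pearson_r_all=None,
            reason=f"zero variance in {zero_axis}",
        )
    slope, intercept = np.polyfit(x, y, 1)

    r_all = None
    if excluded:
        xa, ya = axes(used + excluded)
        r_all = _pearson(xa, ya)

    return CorrelationResult(
        pearson_r=r,
        slope=float(slope),
        intercept=float(intercept),
        n_used=len(used),
        excluded=excluded,
        pearson_r_all=r_all,
    )
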
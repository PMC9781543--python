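"""Reported quantities: totals, densities, immunoreactivity profiles,
multi-probe averages, shrinkage ratios, and cross-specimen comparisons.

Rounding convention for printed-style percentages is half-up to the nearest
integer (so 35.5 → 36), matching how such tables are conventionally
reported; densities are rounded to a configurable number of decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import HistostereoError
from .synthetic import COMPARTMENTS

__all__ = [
    "IRProfile",
    "SubnucleusReport",
    "ComparisonTable",
    "round_half_up",
    "density",
    "combine_probe_totals",
    "ir_profile",
    "weighted_fraction",
    "mean_fraction",
    "shrinkage_ratio",
    "comparison_table",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (printed-table convention)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class IRProfile:
    """Fractions of counted neurons per immunoreactivity compartment."""

    fractions: dict
    n_counted: int

    def __post_init__(self):
        f = {c: float(self.fractions.get(c, 0.0)) for c in COMPARTMENTS}
        if any(v < 0 for v in f.values()):
            raise HistostereoError("IR fractions must be non-negative")
        if abs(sum(f.values()) - 1.0) > 1e-9:
            raise HistostereoError(f"IR fractions must sum to 1, got {sum(f.values())!r}")
        object.__setattr__(self, "fractions", f)

    def percent(self, compartment: str) -> float:
        """Printed-style integer percentage for one compartment."""
        return round_half_up(100.0 * self.fractions[compartment])

    def as_tuple(self) -> tuple[float, float, float, float]:
        return tuple(self.fractions[c] for c in COMPARTMENTS)


def density(total: float, volume_mm3: float) -> float:
    """Number (or length) density: total per mm³ of reference volume."""
    if volume_mm3 <= 0:
        raise HistostereoError("volume must be positive")
    return total / volume_mm3


def combine_probe_totals(estimates: Sequence[float]) -> tuple[float, float]:
    """Average independent probe estimates of the same population.

    Several markers each count all neurons (immunoreactive or not), so each
    probe run is an independent estimate of the same total; returns
    (arithmetic mean, sample SD).
    """
    vals = np.asarray(list(estimates), dtype=float)
    if vals.size < 2:
        raise HistostereoError("combine_probe_totals requires at least 2 estimates")
    return float(vals.mean()), float(vals.std(ddof=1))


def ir_profile(counted_markers: pd.DataFrame | Sequence[str] | Mapping[str, int]) -> IRProfile:
    """Empirical compartment fractions of counted, labelled cells.

    Accepts a marker table with a ``compartment`` column, a sequence of
    compartment labels, or a mapping compartment → count.
    """
    if isinstance(counted_markers, pd.DataFrame):
        labels = counted_markers["compartment"]
        counts = {c: int((labels == c).sum()) for c in COMPARTMENTS}
    elif isinstance(counted_markers, Mapping):
        counts = {c: int(counted_markers.get(c, 0)) for c in COMPARTMENTS}
    else:
        labels = pd.Series(list(counted_markers))
        counts = {c: int((labels == c).sum()) for c in COMPARTMENTS}
    n = sum(counts.values())
    if n == 0:
        raise HistostereoError("ir_profile requires at least one counted cell")
    return IRProfile(fractions={c: counts[c] / n for c in COMPARTMENTS}, n_counted=n)


def weighted_fraction(
    fractions: Sequence[float], weights: Sequence[float], as_percent: bool = True
) -> float:
    """Population-weighted combined fraction, Σfᵢwᵢ / Σwᵢ.

    Used to pool per-subnucleus immunoreactive fractions into a whole-
    structure figure, weighting each subnucleus by its neuron total.
    Returns a half-up integer percent by default (inputs may be fractions
    or percents; the scale is preserved before rounding).
    """
    f = np.asarray(list(fractions), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if f.shape != w.shape:
        raise HistostereoError("fractions and weights must have equal length")
    if f.size == 0:
        raise HistostereoError("weighted_fraction requires input")
    if (w <= 0).any():
        raise HistostereoError("weights must be positive")
    out = float(np.dot(f, w) / w.sum())
    return round_half_up(out) if as_percent else out


def mean_fraction(fractions: Sequence[float], as_percent: bool = True) -> float:
    """Unweighted mean of per-subnucleus fractions (half-up integer percent)."""
    f = np.asarray(list(fractions), dtype=float)
    if f.size == 0:
        raise HistostereoError("mean_fraction requires input")
    out = float(f.mean())
    return round_half_up(out) if as_percent else out


def shrinkage_ratio(cavalieri_mm3: float, reference_mm3: float) -> float:
    """Processed over in-situ volume, as a half-up integer percent.

    Always reported as Cavalieri / MRI × 100 (<100 means processing shrank
    the tissue), never the inverse.
    """
    if cavalieri_mm3 <= 0 or reference_mm3 <= 0:
        raise HistostereoError("volumes must be positive")
    return round_half_up(100.0 * cavalieri_mm3 / reference_mm3)


@dataclass
class SubnucleusReport:
    """All reported quantities for one subnucleus of one specimen."""

    specimen: str
    region: str
    total: float | None = None
    total_ce: float | None = None
    volume_mm3: float | None = None
    volume_ce: float | None = None
    reference_volume_mm3: float | None = None
    length_m: float | None = None
    length_ce: float | None = None
    ir_profiles: dict = field(default_factory=dict)  # marker -> IRProfile
    processing: str = "DPX"
    notes: list = field(default_factory=list)

    @property
    def density_per_mm3(self) -> float | None:
        if self.total is None or not self.volume_mm3:
            return None
        return density(self.total, self.volume_mm3)

    @property
    def length_density_m_per_mm3(self) -> float | None:
        if self.length_m is None or not self.volume_mm3:
            return None
        return density(self.length_m, self.volume_mm3)

    @property
    def shrinkage_percent(self) -> float | None:
        if not self.volume_mm3 or not self.reference_volume_mm3:
            return None
        return shrinkage_ratio(self.volume_mm3, self.reference_volume_mm3)

    def to_dict(self) -> dict:
        return {
            "specimen": self.specimen,
            "region": self.region,
            "total": self.total,
            "total_ce": self.total_ce,
            "volume_mm3": self.volume_mm3,
            "volume_ce": self.volume_ce,
            "reference_volume_mm3": self.reference_volume_mm3,
            "density_per_mm3": self.density_per_mm3,
            "length_m": self.length_m,
            "length_density_m_per_mm3": self.length_density_m_per_mm3,
            "shrinkage_percent": self.shrinkage_percent,
            "processing": self.processing,
            "ir_profiles": {
                m: {"fractions": p.fractions, "n_counted": p.n_counted}
                for m, p in self.ir_profiles.items()
            },
            "notes": list(self.notes),
        }


@dataclass
class ComparisonTable:
    """Cross-specimen comparison: summary rows plus pairwise total ratios."""

    summary: pd.DataFrame
    total_ratios_percent: pd.DataFrame
    processing_flags: list


def comparison_table(
    reports: Sequence[SubnucleusReport], scaling_notes: Mapping[str, str] | None = None
) -> ComparisonTable:
    """Tabulate totals/volumes/densities and pairwise percent ratios.

    Pairs whose specimens were processed differently (e.g. DPX-mounted
    vibratome sections vs celloidin embedding) are flagged: differential
    shrinkage makes their densities incommensurable.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise HistostereoError("comparison_table requires at least 2 reports")
    labels = [f"{r.specimen}:{r.region}" for r in reports]
    summary = pd.DataFrame(
        {
            "specimen": [r.specimen for r in reports],
            "region": [r.region for r in reports],
            "total": [r.total for r in reports],
            "volume_mm3": [r.volume_mm3 for r in reports],
            "density_per_mm3": [r.density_per_mm3 for r in reports],
            "processing": [r.processing for r in reports],
            "note": [scaling_notes.get(lbl, "") if scaling_notes else "" for lbl in labels],
        },
        index=labels,
    )
    n = len(reports)
    ratios = np.full((n, n), np.nan)
    flags = []
    for i, a in enumerate(reports):
        for j, b in enumerate(reports):
            if a.total is not None and b.total not in (None, 0):
                ratios[i, j] = 100.0 * a.total / b.total
            if i < j and a.processing != b.processing:
                flags.append((labels[i], labels[j]))
    return ComparisonTable(
        summary=summary,
        total_ratios_percent=pd.DataFrame(ratios, index=labels, columns=labels),
        processing_flags=flags,
    )
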
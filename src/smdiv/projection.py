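"""Scenario arithmetic projecting GCF and SM counts to the subphylum scale.

The projection chain is B · N · r · m:

    B — BGCs per species (scenario set, default {30, 40, 50}),
    N — number of species projected over (default 85,000 described
        Pezizomycotina species),
    r — GCF:BGC discovery ratio, the fraction of BGCs that are the first
        observed member of their family, carried as an exact count pair
        (4,463/6,972 from 135 Aspergillus genomes; 9,808/28,696 from 721
        Pezizomycotina genomes) — never as a rounded percentage,
    m — effective SMs per BGC (default 1.57).

All intermediates are exact rationals; rounding (half away from zero)
happens only when a display integer is produced, and the SM display value
is always derived from the unrounded GCF value.  Rounding the GCF count
first would shift one of the standard scenario cells by one.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DiscoveryRatio",
    "ProjectionScenario",
    "ProjectionResult",
    "ASPERGILLUS_RATIO",
    "PEZIZOMYCOTINA_RATIO",
    "DEFAULT_B_SET",
    "DEFAULT_N_SPECIES",
    "DEFAULT_SMS_PER_BGC",
    "round_half_away",
    "derived_bgc_count",
    "project",
    "scenario_grid",
    "sm_from_gcf",
]


def _as_fraction(x) -> Fraction:
    # floats go through their shortest decimal repr so 1.57 means 157/100
    return Fraction(str(x)) if isinstance(x, float) else Fraction(x)


def round_half_away(x) -> int:
    """Round half away from zero (3.5 → 4, −3.5 → −4)."""
    f = _as_fraction(x)
    return int(f + Fraction(1, 2)) if f >= 0 else -int(-f + Fraction(1, 2))


@dataclass(frozen=True)
class DiscoveryRatio:
    """GCF:BGC discovery ratio as an exact count pair."""

    n_gcfs: int
    n_bgcs: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.n_gcfs <= self.n_bgcs:
            raise ValueError("require 0 < n_gcfs <= n_bgcs")

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.n_gcfs, self.n_bgcs)

    @property
    def percent(self) -> float:
        return float(self.fraction * 100)


ASPERGILLUS_RATIO = DiscoveryRatio(4463, 6972, "64% (Aspergillus)")
PEZIZOMYCOTINA_RATIO = DiscoveryRatio(9808, 28696, "34% (Pezizomycotina)")
DEFAULT_B_SET: tuple[int, ...] = (30, 40, 50)
DEFAULT_N_SPECIES = 85_000
DEFAULT_SMS_PER_BGC = Fraction("1.57")


@dataclass(frozen=True)
class ProjectionScenario:
    bgcs_per_species: int
    n_species: int
    ratio: DiscoveryRatio
    sms_per_bgc: Fraction = DEFAULT_SMS_PER_BGC

    def __post_init__(self) -> None:
        if self.bgcs_per_species <= 0 or self.n_species <= 0:
            raise ValueError("B and N must be positive")
        object.__setattr__(self, "sms_per_bgc", _as_fraction(self.sms_per_bgc))
        if self.sms_per_bgc <= 0:
            raise ValueError("sms_per_bgc must be positive")


@dataclass(frozen=True)
class ProjectionResult:
    scenario: ProjectionScenario
    total_bgcs: int
    gcfs_exact: Fraction
    sms_exact: Fraction
    gcfs_display: int
    sms_display: int


def derived_bgc_count(n_genomes: int, mean_bgcs: float) -> int:
    """Total BGC count implied by a genome count and a mean per genome."""
    if n_genomes <= 0 or mean_bgcs <= 0:
        raise ValueError("inputs must be positive")
    return round_half_away(Fraction(n_genomes) * _as_fraction(mean_bgcs))


def project(scenario: ProjectionScenario) -> ProjectionResult:
    """Evaluate the B·N·r·m chain in exact arithmetic."""
    B, N = scenario.bgcs_per_species, scenario.n_species
    total_bgcs = B * N
    gcfs = total_bgcs * scenario.ratio.fraction
    sms = gcfs * scenario.sms_per_bgc
    return ProjectionResult(
        scenario=scenario,
        total_bgcs=total_bgcs,
        gcfs_exact=gcfs,
        sms_exact=sms,
        gcfs_display=round_half_away(gcfs),
        sms_display=round_half_away(sms),
    )


def scenario_grid(
    B_set: Sequence[int] = DEFAULT_B_SET,
    N: int = DEFAULT_N_SPECIES,
    ratios: Iterable[DiscoveryRatio] = (ASPERGILLUS_RATIO, PEZIZOMYCOTINA_RATIO),
    m=DEFAULT_SMS_PER_BGC,
) -> list[ProjectionResult]:
    """Cross every BGCs-per-species value with every discovery ratio.

    Results are ordered ratio-major, then by B ascending, mirroring the
    standard low/average/high scenario table.
    """
    B_set, ratios = list(B_set), list(ratios)
    if not B_set or not ratios:
        raise ValueError("B_set and ratios must be non-empty")
    return [project(ProjectionScenario(B, N, r, m)) for r in ratios for B in B_set]


def grid_to_frame(results: list[ProjectionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        s = res.scenario
        rows.append({
            "ratio_label": s.ratio.label,
            "ratio_percent": s.ratio.percent,
            "bgcs_per_species": s.bgcs_per_species,
            "n_species": s.n_species,
            "total_bgcs": res.total_bgcs,
            "gcfs": res.gcfs_display,
            "sms": res.sms_display,
            "gcfs_exact": float(res.gcfs_exact),
            "sms_exact": float(res.sms_exact),
        })
    return pd.DataFrame(rows)


def sm_from_gcf(n_gcfs: int, m=DEFAULT_SMS_PER_BGC) -> int:
    """SM count implied by a GCF count and an effective SMs-per-BGC multiplier."""
    if n_gcfs <= 0:
        raise ValueError("n_gcfs must be positive")
    m = _as_fraction(m)
    if m <= 0:
        raise ValueError("m must be positive")
    return round_half_away(n_gcfs * m)
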
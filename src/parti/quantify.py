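"""Normalized-abundance arithmetic and acylation-yield estimators.

The central quantity is the unitless normalized abundance

    A_norm = (analyte area / standard area) * (V_aliquot + V_spike)/V_aliquot
                                            * (V_aliquot + V_leftover)/V_aliquot

where the analyte area is the summed area of all validated, non-artifact
isomer peaks of one species, the standard is the spiked Leu-Enk peptide,
and the two volume factors correct for (i) dilution of the standard into
the measured aliquot and (ii) the fraction of supernatant never sampled.
With the default bench volumes (20 ul aliquot, 2 ul spike) the first
factor is 22/20.

Two independent percent-acylation estimators are provided (within-sample
area ratio, and free-Ade depletion against a no-substrate control), plus
ionization-efficiency response factors that make abundances comparable
across species, the intact-tRNA area-ratio yield, and simple group
comparisons (Welch t-test / one-way ANOVA) with the usual significance
tiers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "VolumeConfig",
    "SampleMeta",
    "AnormResult",
    "YieldEstimate",
    "ResponseFactor",
    "GroupComparison",
    "a_norm",
    "yield_ratio",
    "yield_vs_control",
    "yield_from_intact_areas",
    "response_factor",
    "corrected_abundance",
    "compare_conditions",
    "significance_tier",
]


@dataclass(frozen=True)
class VolumeConfig:
    """Bench volumes entering the normalization (ul).

    ``aliquot`` is the supernatant volume taken for LC-HRMS; ``spike`` is
    the internal-standard volume added to it.  Defaults are 20 and 2,
    giving the canonical 22/20 dilution factor.
    """

    aliquot: float = 20.0
    spike: float = 2.0

    def __post_init__(self) -> None:
        if self.aliquot <= 0 or self.spike <= 0:
            raise ValueError("volumes must be > 0")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    leftover_volume: float = 0.0
    standard_species: str = "Leu-Enk"

    def __post_init__(self) -> None:
        if self.leftover_volume < 0:
            raise ValueError("leftover_volume must be >= 0")


@dataclass(frozen=True)
class AnormResult:
    species: str
    analyte_area: float
    standard_area: float
    a_norm: float


@dataclass(frozen=True)
class YieldEstimate:
    percent_acylation: float
    strategy: str
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_acylation <= 100.0:
            raise ValueError("percent_acylation must lie in [0, 100]")


@dataclass(frozen=True)
class ResponseFactor:
    species: str
    factor: float  # A_norm units per % acylation

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("response factor must be > 0")


def a_norm(
    analyte_area: float,
    standard_area: float,
    meta: SampleMeta,
    volumes: VolumeConfig = VolumeConfig(),
    species: str = "",
) -> AnormResult:
    """Normalized abundance of one species in one sample.

    Fails hard when the internal standard was not detected — without it
    the sample is unquantifiable.
    """
    if standard_area <= 0:
        raise ValueError(
            f"internal standard area must be > 0 (sample {meta.sample_id!r}); "
            "sample is unquantifiable"
        )
    if analyte_area < 0:
        raise ValueError("analyte_area must be >= 0")
    dilution = (volumes.aliquot + volumes.spike) / volumes.aliquot
    sampling = (volumes.aliquot + meta.leftover_volume) / volumes.aliquot
    value = (analyte_area / standard_area) * dilution * sampling
    return AnormResult(species=species, analyte_area=analyte_area,
                       standard_area=standard_area, a_norm=value)


def yield_ratio(acyl_area: float, ade_area: float) -> YieldEstimate:
    """Percent acylation from the within-sample area ratio:
    100 * acyl / (acyl + free Ade).

    ``ade_area`` must already exclude fragmentation-artifact peaks.
    """
    if acyl_area < 0 or ade_area < 0:
        raise ValueError("areas must be >= 0")
    if acyl_area == 0 and ade_area == 0:
        raise ValueError("both areas are zero; nothing to estimate")
    pct = 100.0 * acyl_area / (acyl_area + ade_area)
    return YieldEstimate(pct, "ratio",
                         {"acyl_area": acyl_area, "ade_area": ade_area})


def yield_vs_control(a_norm_ade_sample: float, a_norm_ade_control: float) -> YieldEstimate:
    """Percent acylation from free-Ade depletion versus a no-substrate
    control: 100 - 100 * (sample / control), clamped to [0, 100]."""
    if a_norm_ade_control <= 0:
        raise ValueError("control free-Ade A_norm must be > 0")
    raw = 100.0 - 100.0 * (a_norm_ade_sample / a_norm_ade_control)
    pct = min(max(raw, 0.0), 100.0)
    if pct != raw:
        warnings.warn(
            f"control-normalized yield {raw:.1f}% outside [0, 100]; clamped",
            stacklevel=2,
        )
    return YieldEstimate(pct, "control_normalized",
                         {"sample": a_norm_ade_sample, "control": a_norm_ade_control,
                          "raw": raw})


def yield_from_intact_areas(acyl_major_ion_area: float,
                            unreacted_major_ion_area: float) -> YieldEstimate:
    """Acylation yield from intact-tRNA LC-MS major-ion areas."""
    if acyl_major_ion_area < 0 or unreacted_major_ion_area < 0:
        raise ValueError("areas must be >= 0")
    total = acyl_major_ion_area + unreacted_major_ion_area
    if total == 0:
        raise ValueError("both areas are zero; nothing to estimate")
    return YieldEstimate(100.0 * acyl_major_ion_area / total, "intact_ratio",
                         {"acyl": acyl_major_ion_area,
                          "unreacted": unreacted_major_ion_area})


def response_factor(result: AnormResult, independent_yield: float) -> ResponseFactor:
    """Ionization-efficiency calibration: A_norm per percent acylation,
    where the yield comes from an independent measurement (intact-tRNA MS)."""
    if independent_yield <= 0:
        raise ValueError("independent yield must be > 0")
    return ResponseFactor(result.species, result.a_norm / independent_yield)


def corrected_abundance(result: AnormResult, factor: ResponseFactor) -> float:
    """A_norm divided by the species' response factor; response-independent."""
    return result.a_norm / factor.factor


def significance_tier(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    test: str                      # "t-test" (Welch) or "anova" or "descriptive"
    statistic: float
    p_value: float
    tier: str
    group_means: dict
    group_sds: dict
    group_ns: dict


def compare_conditions(groups: dict[str, list[float]]) -> GroupComparison:
    """Per-group mean/SD plus a Welch two-tailed t-test (2 groups) or a
    one-way ANOVA (>2 groups) with ns / * / ** / *** tiers."""
    if not groups:
        raise ValueError("no groups provided")
    means = {k: float(np.mean(v)) for k, v in groups.items() if len(v)}
    sds = {k: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
           for k, v in groups.items() if len(v)}
    ns = {k: len(v) for k, v in groups.items()}
    testable = [v for v in groups.values() if len(v) >= 2]
    if len(groups) < 2 or len(testable) < len(groups):
        return GroupComparison("descriptive", math.nan, math.nan, "ns",
                               means, sds, ns)
    if len(groups) == 2:
        g1, g2 = groups.values()
        if np.std(g1) == 0 and np.std(g2) == 0:
            stat, p = (0.0, 1.0) if np.mean(g1) == np.mean(g2) else (math.inf, 0.0)
        else:
            stat, p = stats.ttest_ind(g1, g2, equal_var=False)
        return GroupComparison("t-test", float(stat), float(p),
                               significance_tier(float(p)), means, sds, ns)
    stat, p = stats.f_oneway(*groups.values())
    return GroupComparison("anova", float(stat), float(p),
                           significance_tier(float(p)), means, sds, ns)
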
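"""Seeded generator of synthetic centroided LC-MS runs with ground truth.

Each analyte is injected as one Gaussian chromatographic profile per
isomer peak.  Abundances are expressed on the monoisotopic-ion scale:
the offset-0 isotope line of an analyte integrates (over time) to
``abundance * response_factor * isomer_fraction``, and the M+1..M+3
lines are added in the proportions of the species' predicted envelope.
That convention makes the injected area directly comparable with what a
monoisotopic-peak EIC recovers, so recovery, linearity and yield checks
have an exact target.

Realism knobs: centroid m/z jitter (<= 2 ppm), multiplicative log-normal
intensity jitter, a uniform low-level noise floor of random centroids,
and in-source fragmentation that re-emits a fraction of every acyl
species' signal as free adenosine at the same retention time.

Identical seeds give bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem import (
    AcylAdenosineSpecies,
    MassSpecies,
    compose_species,
    default_registry,
    expected_isomer_count,
    isotope_envelope,
)
from .eic import ISOTOPE_SPACING
from .lcms_io import Run, Spectrum

__all__ = ["Analyte", "SyntheticRunSpec", "GroundTruth", "simulate_run",
           "make_parti_fixture", "SCENARIOS"]

_SQRT2PI = float(np.sqrt(2 * np.pi))
# emit Gaussian tails down to 1e-12 of apex height so traces decay into
# the noise rather than cutting off sharply
_TAIL_SIGMAS = float(np.sqrt(2 * 12 * np.log(10)))


def _default_fractions(n: int) -> tuple[float, ...]:
    """Area split across isomer peaks: 55:45 for 2'/3' pairs, else equal."""
    if n == 1:
        return (1.0,)
    if n == 2:
        return (0.55, 0.45)
    return tuple([1.0 / n] * n)


@dataclass(frozen=True)
class Analyte:
    """One injected species: isomer retention times (min), molar-scale
    abundance, ionization response factor, and Gaussian peak width."""

    species: AcylAdenosineSpecies | MassSpecies
    isomer_rts: tuple[float, ...]
    abundance: float
    response_factor: float = 1.0
    sigma: float = 0.02
    isomer_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.abundance < 0 or self.response_factor <= 0:
            raise ValueError("abundance >= 0 and response_factor > 0 required")
        lo, hi = expected_isomer_count(self.species)
        if not lo <= len(self.isomer_rts) <= hi:
            raise ValueError(
                f"{self.species.name}: {len(self.isomer_rts)} isomer RTs outside "
                f"the expected bounds [{lo}, {hi}]"
            )
        if self.isomer_fractions is not None:
            if len(self.isomer_fractions) != len(self.isomer_rts):
                raise ValueError("isomer_fractions length must match isomer_rts")
            if abs(sum(self.isomer_fractions) - 1.0) > 1e-9:
                raise ValueError("isomer_fractions must sum to 1")

    @property
    def fractions(self) -> tuple[float, ...]:
        return self.isomer_fractions or _default_fractions(len(self.isomer_rts))

    @property
    def isomer_areas(self) -> tuple[float, ...]:
        tot = self.abundance * self.response_factor
        return tuple(tot * f for f in self.fractions)


@dataclass(frozen=True)
class SyntheticRunSpec:
    """Declarative description of one simulated LC-MS run."""

    analytes: tuple[Analyte, ...]
    label: str = "run"
    condition: str = ""
    leftover_volume: float = 0.0
    rt_window: tuple[float, float] = (1.4, 7.0)
    scan_interval: float = 0.01
    mz_range: tuple[float, float] = (100.0, 3000.0)
    fragmentation_fraction: float = 0.0
    baseline: float = 30.0
    intensity_jitter: float = 0.02
    mz_jitter_ppm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragmentation_fraction < 1.0:
            raise ValueError("fragmentation_fraction must be in [0, 1)")
        if self.scan_interval <= 0 or self.rt_window[1] <= self.rt_window[0]:
            raise ValueError("invalid rt window / scan interval")
        lo, hi = self.mz_range
        for a in self.analytes:
            mz = a.species.protonated_mz
            if not (lo <= mz and mz + 3 * ISOTOPE_SPACING <= hi):
                raise ValueError(
                    f"m/z range does not cover the envelope of {a.species.name}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Expected (pre-noise) monoisotopic-line areas for every injected peak."""

    isomer_areas: dict[str, tuple[float, ...]]
    fragment_ade_areas: dict[str, float]

    def total(self, species_name: str) -> float:
        return float(sum(self.isomer_areas.get(species_name, ())))

    @property
    def total_fragment_ade_area(self) -> float:
        return float(sum(self.fragment_ade_areas.values()))


_ADE = compose_species(None, 0)


def simulate_run(spec: SyntheticRunSpec) -> tuple[Run, GroundTruth]:
    """Render a spec into a centroided Run plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.rt_window[0], spec.rt_window[1] + 1e-12,
                      spec.scan_interval)

    # (mz0, envelope-relative-to-M0 abundances) per distinct species
    def _lines(species) -> tuple[float, np.ndarray]:
        env = isotope_envelope(species.composition, n_peaks=4)
        rel = np.array(env.abundances) / env.abundances[0]
        return species.protonated_mz, rel

    ade_mz0, ade_rel = _lines(_ADE)

    emitters = []  # (mz0, rel, rt, sigma, area, frag: bool)
    truth_areas: dict[str, list[float]] = {}
    frag_areas: dict[str, float] = {}
    for a in spec.analytes:
        mz0, rel = _lines(a.species)
        truth_areas.setdefault(a.species.name, [])
        for rt, area in zip(a.isomer_rts, a.isomer_areas):
            truth_areas[a.species.name].append(area)
            emitters.append((mz0, rel, rt, a.sigma, area))
            is_acyl = (isinstance(a.species, AcylAdenosineSpecies)
                       and a.species.acyl_count > 0)
            if is_acyl and spec.fragmentation_fraction > 0:
                f_area = spec.fragmentation_fraction * area
                emitters.append((ade_mz0, ade_rel, rt, a.sigma, f_area))
                frag_areas[a.species.name] = (
                    frag_areas.get(a.species.name, 0.0) + f_area)

    spectra = []
    lo, hi = spec.mz_range
    for t in times:
        mzs: list[float] = []
        ints: list[float] = []
        for mz0, rel, rt, sigma, area in emitters:
            if abs(t - rt) > _TAIL_SIGMAS * sigma:
                continue
            h = area / (sigma * _SQRT2PI) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
            for k in range(rel.size):
                jit_ppm = float(np.clip(rng.normal(0.0, spec.mz_jitter_ppm),
                                        -2.0, 2.0))
                mz = (mz0 + k * ISOTOPE_SPACING) * (1 + jit_ppm * 1e-6)
                inten = h * rel[k] * float(np.exp(
                    rng.normal(0.0, spec.intensity_jitter)))
                mzs.append(mz)
                ints.append(inten)
        # uniform chemical-noise floor: a few random low centroids per scan
        for _ in range(3):
            mzs.append(float(rng.uniform(lo, hi)))
            ints.append(float(rng.uniform(0.0, spec.baseline)))
        mz_arr = np.array(mzs)
        int_arr = np.array(ints)
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        # merge exact m/z collisions so centroids stay strictly increasing
        if mz_arr.size > 1 and np.any(np.diff(mz_arr) == 0):
            uniq, inv = np.unique(mz_arr, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, int_arr)
            mz_arr, int_arr = uniq, summed
        spectra.append(Spectrum(float(t), mz_arr, int_arr))

    run = Run(spectra, label=spec.label, polarity="positive", mz_range=spec.mz_range)
    truth = GroundTruth(
        isomer_areas={k: tuple(v) for k, v in truth_areas.items()},
        fragment_ade_areas=frag_areas,
    )
    return run, truth


# --------------------------------------------------------------------------
# Canned fixtures emulating the assay's characteristic sample types

_STANDARD_AREA = 5.0e5


def _standard(std: MassSpecies) -> Analyte:
    return Analyte(std, isomer_rts=(4.5,), abundance=_STANDARD_AREA)


def make_parti_fixture(scenario: str, seed: int = 0) -> list[SyntheticRunSpec]:
    """Fully parameterized specs for the documented scenarios.

    Scenarios
    ---------
    no_substrate
        Only the Leu-Enk internal standard; the negative control.
    phe_in_vitro
        An in-vitro phenylalanylation digest: free Ade plus the 2'/3'
        Phe-Ade pair at a 74 % acylated fraction, with 5 % in-source
        fragmentation.
    enantiomer_panel
        Three runs with monoacyl hydroxy-acid species at 2.76 : 2.18 :
        0.20 relative abundance (alpha-OH, (R)-beta2, (S)-beta2).
    diacyl
        A two-peak monoacyl species plus a single-peak diacyl species of
        the same monomer.
    metabolism
        Two acyl species of unequal ionization response (1.5x) in one
        run, plus a no-substrate control run.
    fragmentation
        A 40 %-acylated sample with fragmentation_fraction 0.1.
    dilution_series
        Five runs spanning a 100x analyte abundance range at a fixed
        standard.
    """
    monomers, standards = default_registry()
    std = standards["Leu-Enk"]
    mono = lambda name: compose_species(monomers[name], 1)
    di = lambda name: compose_species(monomers[name], 2)
    base = dict(seed=seed)

    if scenario == "no_substrate":
        return [SyntheticRunSpec(analytes=(_standard(std),), label="no_substrate",
                                 condition="no substrate", **base)]

    if scenario == "phe_in_vitro":
        f, tot = 0.74, 2.0e5
        return [SyntheticRunSpec(
            analytes=(
                Analyte(_ADE, (1.6,), (1 - f) * tot),
                Analyte(mono("Phe"), (2.9, 3.1), f * tot),
                _standard(std),
            ),
            label="phe_in_vitro", condition="Phe in vitro",
            fragmentation_fraction=0.05, **base)]

    if scenario == "enantiomer_panel":
        panel = [("OH-BocK", 2.76, (3.3, 3.5)),
                 ("R-b2-OH-BocK", 2.18, (3.4, 3.6)),
                 ("S-b2-OH-BocK", 0.20, (3.4, 3.6))]
        return [SyntheticRunSpec(
            analytes=(Analyte(mono(name), rts, rel * 1.0e5), _standard(std)),
            label=name, condition=f"0.1 mM {name}", seed=seed + i)
            for i, (name, rel, rts) in enumerate(panel)]

    if scenario == "diacyl":
        return [SyntheticRunSpec(
            analytes=(
                Analyte(mono("R-b2-OH-BocK"), (3.4, 3.6), 2.0e5),
                Analyte(di("R-b2-OH-BocK"), (4.2,), 0.3e5),
                _standard(std),
            ),
            label="diacyl", condition="0.1 mM R-b2-OH-BocK", **base)]

    if scenario == "metabolism":
        sample = SyntheticRunSpec(
            analytes=(
                Analyte(mono("N-Me-BocK"), (3.6, 3.8), 0.57e5, response_factor=1.0),
                Analyte(mono("BocK"), (3.0, 3.2), 0.25e5, response_factor=1.5),
                _standard(std),
            ),
            label="NMeBocK_1mM", condition="1 mM N-Me-BocK", **base)
        control = SyntheticRunSpec(
            analytes=(_standard(std),), label="no_substrate",
            condition="no substrate", seed=seed + 1)
        return [sample, control]

    if scenario == "fragmentation":
        f, tot = 0.4, 2.0e5
        return [SyntheticRunSpec(
            analytes=(
                Analyte(_ADE, (1.6,), (1 - f) * tot),
                Analyte(mono("BocK"), (3.0, 3.2), f * tot),
                _standard(std),
            ),
            label="fragmentation", condition="1 mM BocK",
            fragmentation_fraction=0.1, **base)]

    if scenario == "dilution_series":
        scales = (1.0, 3.0, 10.0, 30.0, 100.0)
        return [SyntheticRunSpec(
            analytes=(Analyte(mono("BocK"), (3.0, 3.2), s * 2.0e3), _standard(std)),
            label=f"dilution_{s:g}x", condition=f"{s:g}x", seed=seed + i)
            for i, s in enumerate(scales)]

    raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")


SCENARIOS = frozenset({
    "no_substrate", "phe_in_vitro", "enantiomer_panel", "diacyl",
    "metabolism", "fragmentation", "dilution_series",
})
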
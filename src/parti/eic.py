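"""Extracted ion chromatograms and the peak confirmation workflow.

The procedure mirrors targeted small-molecule HRMS practice: a discovery
EIC is extracted over a wide symmetric 100 ppm window around the expected
exact [M+H]+; candidate chromatographic peaks are detected on that trace;
each candidate is confirmed by requiring the observed apex centroid mass
to agree with theory within 5 ppm *and* the observed isotope envelope
(M+1/M ratio) to agree with the composition's prediction; confirmed peaks
are then re-quantified from a narrow EIC centred on the observed
monoisotopic centroid so that distant interferences caught by the wide
discovery window do not inflate the area.

Free-adenosine traces need one extra rule: acyl-adenosines partially
fragment to adenosine in the source, producing small Ade peaks co-eluting
with the acyl species.  Those are flagged as fragmentation artifacts and
excluded from free-Ade quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .chem import AcylAdenosineSpecies, IsotopeEnvelope, MassSpecies, isotope_envelope
from .lcms_io import Run

__all__ = [
    "EIC",
    "ChromatographicPeak",
    "extract_eic",
    "default_noise_floor",
    "detect_peaks",
    "validate_peak",
    "requantify_peak",
    "flag_fragmentation_artifacts",
]

#: Nominal spacing between adjacent isotopologue lines, Da (13C-12C).
ISOTOPE_SPACING = 1.0033548378


@dataclass
class EIC:
    """Per-scan summed intensity within an m/z window around a target."""

    target_mz: float
    window: tuple[float, float]
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        lo, hi = self.window
        if not (lo <= self.target_mz <= hi):
            raise ValueError("window must contain target_mz")

    @property
    def integral(self) -> float:
        """Trapezoidal integral of the whole trace (intensity * min)."""
        return float(np.trapezoid(self.intensities, self.times))


@dataclass
class ChromatographicPeak:
    """One detected (and possibly validated) chromatographic peak."""

    apex_rt: float
    rt_lo: float
    rt_hi: float
    area: float
    apex_intensity: float
    target_mz: float
    apex_mz_observed: float | None = None
    mass_error_ppm: float | None = None
    envelope_score: float | None = None
    validated: bool = False
    fragmentation_artifact: bool = False

    def __post_init__(self) -> None:
        if not (self.rt_lo <= self.apex_rt <= self.rt_hi):
            raise ValueError("rt bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def overlaps(self, other: "ChromatographicPeak") -> bool:
        return self.rt_lo <= other.rt_hi and other.rt_lo <= self.rt_hi


def _ppm_window(target_mz: float, ppm: float) -> tuple[float, float]:
    return target_mz * (1 - ppm * 1e-6), target_mz * (1 + ppm * 1e-6)


def extract_eic(run: Run, target_mz: float, ppm_window: float = 100.0) -> EIC:
    """Discovery EIC: per spectrum, sum centroid intensities within
    ``target_mz * (1 +/- ppm_window * 1e-6)``; zero where nothing matches."""
    lo_acq, hi_acq = run.mz_range
    if not (lo_acq <= target_mz <= hi_acq):
        raise ValueError(
            f"target m/z {target_mz:.4f} outside acquisition range "
            f"[{lo_acq}, {hi_acq}]"
        )
    lo, hi = _ppm_window(target_mz, ppm_window)
    times = run.retention_times
    intens = np.empty(len(run.spectra))
    for i, s in enumerate(run.spectra):
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        intens[i] = s.intensity[a:b].sum()
    return EIC(target_mz=target_mz, window=(lo, hi), times=times, intensities=intens)


def default_noise_floor(eic: EIC, multiplier: float = 3.0) -> float:
    """3x the median nonzero trace intensity — deterministic and scale-free."""
    nz = eic.intensities[eic.intensities > 0]
    if nz.size == 0:
        return 0.0
    return multiplier * float(np.median(nz))


def _bounds(y: np.ndarray, apex: int, frac: float = 0.01) -> tuple[int, int]:
    """Walk outward from the apex to the nearest flanking valley or the
    first point at or below ``frac`` of the apex intensity."""
    cut = frac * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] <= y[lo] and y[lo] > cut:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi + 1] <= y[hi] and y[hi] > cut:
        hi += 1
    return lo, hi


def detect_peaks(eic: EIC, noise_floor: float | None = None) -> list[ChromatographicPeak]:
    """Local-maximum peak detection with valley/1 %-of-apex boundaries.

    Candidates whose apexes are closer than twice the median scan interval
    are merged (the more intense wins; ties go to the earlier RT).  Areas
    are trapezoidal integrals over the peak bounds.
    """
    y = eic.intensities
    t = eic.times
    if y.size < 5:
        raise ValueError("EIC trace needs at least 5 points")
    if noise_floor is None:
        noise_floor = default_noise_floor(eic)
    if not np.any(y > noise_floor):
        return []
    idx, _ = signal.find_peaks(y, height=max(noise_floor, np.finfo(float).tiny))
    if idx.size == 0:
        return []

    # merge apexes separated by < 2x the median scan interval
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    merged: list[int] = []
    for i in idx:
        if merged and dt > 0 and t[i] - t[merged[-1]] < 2 * dt:
            if y[i] > y[merged[-1]]:        # tie keeps the earlier apex
                merged[-1] = i
        else:
            merged.append(i)

    peaks = []
    for i in merged:
        lo, hi = _bounds(y, i)
        area = float(np.trapezoid(y[lo:hi + 1], t[lo:hi + 1]))
        peaks.append(ChromatographicPeak(
            apex_rt=float(t[i]), rt_lo=float(t[lo]), rt_hi=float(t[hi]),
            area=area, apex_intensity=float(y[i]), target_mz=eic.target_mz,
        ))
    return peaks


def _apex_spectrum_index(run: Run, apex_rt: float) -> int:
    rts = run.retention_times
    i = int(np.argmin(np.abs(rts - apex_rt)))
    if abs(rts[i] - apex_rt) > 10 * max(np.median(np.diff(rts)), 1e-9):
        raise ValueError(f"no spectrum near apex RT {apex_rt:.3f} min")
    return i


def _window_stats(run: Run, spec_idx: int, center: float, ppm: float) -> tuple[float, float]:
    """(intensity-weighted mean m/z, summed intensity) of centroids in window."""
    s = run.spectra[spec_idx]
    lo, hi = _ppm_window(center, ppm)
    a = np.searchsorted(s.mz, lo, side="left")
    b = np.searchsorted(s.mz, hi, side="right")
    inten = s.intensity[a:b]
    total = inten.sum()
    if total <= 0:
        return np.nan, 0.0
    return float(np.average(s.mz[a:b], weights=inten)), float(total)


def envelope_agreement(observed_ratio: float, expected_ratio: float) -> float:
    """Score the observed M+1/M ratio against theory.

    1 at exact agreement, 0 at a two-fold (or worse) deviation in either
    direction, linear in the fold-deviation between.
    """
    if expected_ratio <= 0:
        return 1.0 if observed_ratio <= 0 else 0.0
    if observed_ratio <= 0:
        return 0.0
    fold = max(observed_ratio, expected_ratio) / min(observed_ratio, expected_ratio)
    return float(np.clip(2.0 - fold, 0.0, 1.0))


def validate_peak(
    run: Run,
    peak: ChromatographicPeak,
    species: AcylAdenosineSpecies | MassSpecies,
    envelope: IsotopeEnvelope | None = None,
    ppm_confirm: float = 5.0,
    envelope_threshold: float = 0.5,
    discovery_ppm: float = 100.0,
) -> ChromatographicPeak:
    """Confirm a peak's identity by exact mass (<5 ppm) and isotope envelope.

    The observed apex m/z is the intensity-weighted mean centroid within
    the discovery window at the apex spectrum; the envelope check compares
    the observed M+1/M intensity ratio at the apex with the composition's
    predicted ratio.
    """
    if envelope is None:
        envelope = isotope_envelope(species.composition)
    theo = species.protonated_mz
    i = _apex_spectrum_index(run, peak.apex_rt)
    obs_mz, m0 = _window_stats(run, i, theo, discovery_ppm)
    if m0 <= 0 or np.isnan(obs_mz):
        return replace(peak, apex_mz_observed=None, mass_error_ppm=None,
                       envelope_score=0.0, validated=False)
    err_ppm = (obs_mz - theo) / theo * 1e6
    _, m1 = _window_stats(run, i, theo + ISOTOPE_SPACING, discovery_ppm)
    score = envelope_agreement(m1 / m0, envelope.m1_over_m0)
    ok = abs(err_ppm) < ppm_confirm and score >= envelope_threshold
    return replace(peak, apex_mz_observed=obs_mz, mass_error_ppm=float(err_ppm),
                   envelope_score=score, validated=bool(ok))


def requantify_peak(run: Run, peak: ChromatographicPeak,
                    ppm_requant: float = 25.0) -> ChromatographicPeak:
    """Re-integrate a validated peak over a narrow EIC centred on the
    observed monoisotopic centroid.

    The narrow window excludes interferences admitted by the 100 ppm
    discovery window.  If the narrow trace is empty over the peak bounds,
    the discovery-window area is retained with a warning.
    """
    if not peak.validated or peak.apex_mz_observed is None:
        raise ValueError("requantify_peak requires a validated peak")
    eic = extract_eic(run, peak.apex_mz_observed, ppm_window=ppm_requant)
    sel = (eic.times >= peak.rt_lo) & (eic.times <= peak.rt_hi)
    if sel.sum() < 2 or eic.intensities[sel].sum() <= 0:
        warnings.warn(
            f"narrow re-extraction at {peak.apex_mz_observed:.4f} is empty; "
            "keeping discovery-window area", stacklevel=2,
        )
        return peak
    area = float(np.trapezoid(eic.intensities[sel], eic.times[sel]))
    return replace(peak, area=area)


def flag_fragmentation_artifacts(
    ade_peaks: list[ChromatographicPeak],
    acyl_peaks: list[ChromatographicPeak],
) -> list[ChromatographicPeak]:
    """Flag free-Ade peaks that co-elute with a validated acyl-Ade peak.

    In-source fragmentation of an acyl-adenosine re-emits adenosine at the
    acyl species' retention time; such Ade peaks must not count toward
    free (unacylated) adenosine.
    """
    out = []
    for p in ade_peaks:
        artifact = any(p.overlaps(q) for q in acyl_peaks if q.validated)
        out.append(replace(p, fragmentation_artifact=artifact))
    return out
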
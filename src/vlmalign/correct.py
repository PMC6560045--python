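"""m/z recalibration against a set of virtual lock masses.

Each spectrum is matched to the lock masses (exactly one peak per VLM
window) and its m/z axis is corrected by piecewise linear interpolation
between the matched peaks: on the segment between consecutive matched VLMs
v_i and v_{i+1} with matched peak m/z values mu_i and mu_{i+1}, a peak at mu
maps to a*mu + b with

    a = (v_{i+1} - v_i) / (mu_{i+1} - mu_i),    b = v_i - a * mu_i,

so matched peaks land exactly on their v_i.  Peaks outside the outer matched
VLMs could only be corrected by extrapolation, which is unreliable; they are
trimmed by default.  Intensities are never modified.  The per-spectrum cost
is linear in its peak count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import DetectionParams, Spectrum, SpectraSet
from .detect import VLMSet

__all__ = [
    "MatchResult",
    "CorrectionModel",
    "CorrectionReport",
    "UncorrectableSpectrumError",
    "match_vlm_peaks",
    "correct_spectrum",
    "correct_set",
    "correction_rmse",
    "rmse_between_models",
]


class UncorrectableSpectrumError(ValueError):
    """Raised when fewer than two lock masses can be matched in a spectrum."""


@dataclass(frozen=True)
class MatchResult:
    """Per-spectrum matching of VLMs to peak indices.

    ``alpha[i]`` is the index of the unique peak matched to the i-th VLM, or
    -1 where the window held zero or several admissible peaks (possible only
    for spectra outside the detection set); interpolation bridges over such
    VLMs.
    """

    alpha: np.ndarray
    matched: np.ndarray  # boolean mask over VLMs

    @property
    def n_matched(self) -> int:
        return int(self.matched.sum())


def match_vlm_peaks(
    spectrum: Spectrum,
    vlms: VLMSet,
    intensity_bounds: Optional[Tuple[float, float]] = None,
) -> MatchResult:
    """Find, per VLM, the unique admissible peak inside its window.

    Admissible peaks must carry an intensity inside ``intensity_bounds``
    (defaulting to the bounds the VLMs were detected with): a lock-mass
    anchor is by definition a thresholded peak, and ignoring the bounds would
    let sub-threshold noise make the match ambiguous in unseen spectra.  For
    spectra belonging to the detection set every VLM matches exactly one peak.
    """
    if intensity_bounds is None:
        intensity_bounds = (vlms.params.t_a, vlms.params.t_b)
    t_a, t_b = intensity_bounds
    w = vlms.params.w
    mz = spectrum.mz
    inten = spectrum.intensity
    r = len(vlms)
    alpha = np.full(r, -1, dtype=np.int64)
    for i, v in enumerate(vlms):
        lo, hi = v.mz * (1.0 - w), v.mz * (1.0 + w)
        i0 = int(np.searchsorted(mz, lo, side="left"))
        i1 = int(np.searchsorted(mz, hi, side="right"))
        hits = [j for j in range(i0, i1) if t_a <= inten[j] <= t_b]
        if len(hits) == 1:
            alpha[i] = hits[0]
    matched = alpha >= 0
    # isolated VLM windows are disjoint, so matched indices are automatically
    # strictly increasing; guard anyway against pathological inputs
    a = alpha[matched]
    if a.size > 1 and np.any(np.diff(a) <= 0):
        raise AssertionError("matched peak indices are not strictly increasing")
    return MatchResult(alpha=alpha, matched=matched)


@dataclass(frozen=True)
class CorrectionReport:
    """What happened to one spectrum during correction."""

    spectrum_id: str
    n_vlms: int
    n_matched: int
    n_trimmed: int
    n_uncorrected: int  # peaks outside the corrected span kept un-modified (trim off)
    corrected_span: Tuple[int, int] = (0, -1)  # inclusive original peak-index range


def correct_spectrum(
    spectrum: Spectrum,
    vlms: VLMSet,
    trim: bool = True,
    intensity_bounds: Optional[Tuple[float, float]] = None,
) -> Tuple[Spectrum, CorrectionReport]:
    """Recalibrate one spectrum's m/z axis against ``vlms``.

    Peaks between the first and last matched VLM peak are corrected by
    piecewise linear interpolation; peaks outside that span are removed when
    ``trim`` (the default) or passed through unmodified otherwise.

    Raises
    ------
    UncorrectableSpectrumError
        If fewer than two VLMs match a unique peak.
    """
    match = match_vlm_peaks(spectrum, vlms, intensity_bounds)
    if match.n_matched < 2:
        raise UncorrectableSpectrumError(
            f"spectrum {spectrum.id!r}: only {match.n_matched} of {len(vlms)} "
            "lock masses matched; need at least 2 for interpolation"
        )
    anchors = match.alpha[match.matched]
    v_vals = vlms.mzs[match.matched]
    anchor_mz = spectrum.mz[anchors]
    if np.any(np.diff(anchor_mz) <= 0):
        raise AssertionError("anchor m/z values must be strictly increasing")
    j_first, j_last = int(anchors[0]), int(anchors[-1])

    # explicit slope/intercept per segment: mz' = a*mz + b with
    # a = (v_{i+1}-v_i)/(mu_{i+1}-mu_i), b = v_i - a*mu_i.  This form maps
    # anchors exactly onto v_i and is the identity (bit-exact) when the
    # anchors already sit on the lock masses, making re-correction a no-op.
    slopes = np.diff(v_vals) / np.diff(anchor_mz)
    intercepts = v_vals[:-1] - slopes * anchor_mz[:-1]
    if np.any(slopes <= 0):
        raise AssertionError("non-positive interpolation slope")
    mz = spectrum.mz.copy()
    span = slice(j_first, j_last + 1)
    seg = np.clip(
        np.searchsorted(anchor_mz, spectrum.mz[span], side="right") - 1,
        0,
        slopes.size - 1,
    )
    mz[span] = slopes[seg] * spectrum.mz[span] + intercepts[seg]
    # every slope is positive, so order is preserved on the span

    n = len(spectrum)
    n_outside = j_first + (n - 1 - j_last)
    if trim:
        corrected = Spectrum(
            id=spectrum.id,
            mz=mz[span],
            intensity=spectrum.intensity[span].copy(),
            label=spectrum.label,
        )
        n_trimmed, n_uncorrected = n_outside, 0
    else:
        inten = spectrum.intensity.copy()
        # an uncorrected out-of-span peak can interleave with shifted in-span
        # peaks near the boundary; restore sortedness when that happens
        if n_outside and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        corrected = Spectrum(id=spectrum.id, mz=mz, intensity=inten, label=spectrum.label)
        n_trimmed, n_uncorrected = 0, n_outside
    report = CorrectionReport(
        spectrum_id=spectrum.id,
        n_vlms=len(vlms),
        n_matched=match.n_matched,
        n_trimmed=n_trimmed,
        n_uncorrected=n_uncorrected,
        corrected_span=(j_first, j_last),
    )
    return corrected, report


@dataclass(frozen=True)
class CorrectionModel:
    """A frozen correction transform: the lock masses plus matching policy.

    Freezing the VLM set before any test spectrum is seen is what makes the
    inductive workflow honest; the model object carries everything needed to
    correct unseen spectra of the same nature.
    """

    vlms: VLMSet
    trim: bool = True

    def match(self, spectrum: Spectrum) -> MatchResult:
        return match_vlm_peaks(spectrum, self.vlms)

    def correct(self, spectrum: Spectrum) -> Tuple[Spectrum, CorrectionReport]:
        return correct_spectrum(spectrum, self.vlms, trim=self.trim)


def correct_set(
    spectra: SpectraSet,
    vlms: VLMSet,
    trim: bool = True,
    on_error: str = "raise",
) -> Tuple[SpectraSet, List[CorrectionReport]]:
    """Correct every spectrum of a set; ``on_error`` is 'raise' or 'skip'.

    With 'skip', uncorrectable spectra are dropped from the output and a
    report with ``n_matched`` below 2 records the failure.
    """
    out: List[Spectrum] = []
    reports: List[CorrectionReport] = []
    for s in spectra:
        try:
            corrected, report = correct_spectrum(s, vlms, trim=trim)
        except UncorrectableSpectrumError:
            if on_error == "raise":
                raise
            match = match_vlm_peaks(s, vlms)
            reports.append(
                CorrectionReport(s.id, len(vlms), match.n_matched, 0, len(s), (0, -1))
            )
            continue
        out.append(corrected)
        reports.append(report)
    return SpectraSet(tuple(out)), reports


def correction_rmse(set_a: SpectraSet, set_b: SpectraSet) -> float:
    """RMSE in ppm between two corrections of the same spectra.

    Peaks must be in 1-1 correspondence by (spectrum, peak index); the
    per-peak deviation is ``1e6 * (mz_a - mz_b) / mz_b`` and the result is
    ``sqrt(mean(deviation**2))``.
    """
    if set_a.m != set_b.m:
        raise ValueError("sets hold different numbers of spectra")
    sq_sum = 0.0
    n_peaks = 0
    for sa, sb in zip(set_a, set_b):
        if len(sa) != len(sb):
            raise ValueError(
                f"peak-count mismatch for {sa.id!r}: {len(sa)} vs {len(sb)}"
            )
        d_ppm = 1e6 * (sa.mz - sb.mz) / sb.mz
        sq_sum += float(np.sum(d_ppm**2))
        n_peaks += len(sa)
    if n_peaks == 0:
        raise ValueError("no peaks to compare")
    return math.sqrt(sq_sum / n_peaks)


def rmse_between_models(test: SpectraSet, vlms_a: "VLMSet", vlms_b: "VLMSet") -> float:
    """RMSE in ppm between two correction models applied to the same spectra.

    Each test spectrum is corrected twice with trimming; a trimmed spectrum
    preserves the original peak order, so original indices are recoverable
    from the recorded span and homologous peaks are those whose original
    index falls in the corrected span of *both* models.  The second model is
    the reference scale.  This is the protocol behind correction learning
    curves: ``vlms_b`` is typically the model fitted on the full collection
    (the best available correction) and ``vlms_a`` a model fitted on a
    training subset.
    """
    sq_sum = 0.0
    n_peaks = 0
    for s in test:
        ca, ra = correct_spectrum(s, vlms_a, trim=True)
        cb, rb = correct_spectrum(s, vlms_b, trim=True)
        lo_a, _ = ra.corrected_span
        lo_b, _ = rb.corrected_span
        lo = max(ra.corrected_span[0], rb.corrected_span[0])
        hi = min(ra.corrected_span[1], rb.corrected_span[1])
        if hi < lo:
            continue
        mz_a = ca.mz[lo - lo_a : hi - lo_a + 1]
        mz_b = cb.mz[lo - lo_b : hi - lo_b + 1]
        d_ppm = 1e6 * (mz_a - mz_b) / mz_b
        sq_sum += float(np.sum(d_ppm**2))
        n_peaks += hi - lo + 1
    if n_peaks == 0:
        raise ValueError("no homologous corrected peaks to compare")
    return math.sqrt(sq_sum / n_peaks)
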
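"""Domain types shared by the whole pipeline.

A centroided mass spectrum is a sequence of (m/z, intensity) peaks sorted by
m/z.  All mass tolerances in this package are *relative* (dimensionless
fractions of m/z): the mass measurement uncertainty of time-of-flight
instruments grows linearly with m/z, so a window of half-width ``w`` around a
peak at ``mz`` spans ``[mz*(1-w), mz*(1+w)]``.  User-facing surfaces (CLI,
configs) express tolerances in ppm; 40 ppm corresponds to ``w = 4.0e-5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "Peak",
    "Spectrum",
    "SpectraSet",
    "MzInterval",
    "DetectionParams",
    "ppm_window",
    "ppm_to_fraction",
    "fraction_to_ppm",
]


def ppm_to_fraction(ppm: float) -> float:
    """Convert a tolerance in ppm to a dimensionless fraction (40 ppm -> 4e-5)."""
    return ppm / 1e6


def fraction_to_ppm(w: float) -> float:
    """Convert a dimensionless relative tolerance to ppm."""
    return w * 1e6


class Peak(NamedTuple):
    """One centroided peak, identified by (spectrum_index, peak_index).

    ``spectrum_index`` (sigma) indexes the spectrum inside a :class:`SpectraSet`
    and ``peak_index`` (rho) the peak inside its spectrum; both are 0-based.
    """

    mz: float
    intensity: float
    spectrum_index: int
    peak_index: int


class MzInterval(NamedTuple):
    """Closed m/z interval ``[lo, hi]`` in Th."""

    lo: float
    hi: float

    def contains(self, mz: float) -> bool:
        return self.lo <= mz <= self.hi

    def overlaps(self, other: "MzInterval") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


def ppm_window(mz: float, w: float) -> MzInterval:
    """Relative window of half-width ``w`` centred on ``mz``.

    Returns ``[mz*(1-w), mz*(1+w)]``; the width ``2*w*mz`` grows linearly with
    m/z, matching ToF mass-error behaviour.

    Raises
    ------
    ValueError
        If ``mz`` or ``w`` is not strictly positive.
    """
    if mz <= 0:
        raise ValueError(f"mz must be > 0, got {mz}")
    if w <= 0:
        raise ValueError(f"window half-width must be > 0, got {w}")
    return MzInterval(mz * (1.0 - w), mz * (1.0 + w))


@dataclass(frozen=True)
class Spectrum:
    """One sample's centroided peak list, sorted by m/z.

    Parameters
    ----------
    id : str
        Sample identifier, unique within a :class:`SpectraSet`.
    mz : ndarray
        Peak m/z values in Th, non-decreasing, all > 0.
    intensity : ndarray
        Peak intensities in counts, same length as ``mz``, all >= 0.
    label : str, optional
        Class label for downstream machine learning.
    """

    id: str
    mz: np.ndarray
    intensity: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and mz[0] <= 0:
            raise ValueError(f"spectrum {self.id!r}: non-positive m/z values")
        if mz.size and np.any(np.diff(mz) < 0):
            raise ValueError(
                f"spectrum {self.id!r}: peaks must be sorted by m/z "
                "(use Spectrum.from_arrays(..., sort=True) to sort)"
            )
        if np.any(inten < 0):
            raise ValueError(f"spectrum {self.id!r}: negative intensities")

    @classmethod
    def from_arrays(
        cls,
        id: str,
        mz: Sequence[float],
        intensity: Sequence[float],
        label: Optional[str] = None,
        sort: bool = False,
    ) -> "Spectrum":
        mz = np.asarray(mz, dtype=np.float64)
        intensity = np.asarray(intensity, dtype=np.float64)
        if sort and mz.size:
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
        return cls(id=id, mz=mz, intensity=intensity, label=label)

    def __len__(self) -> int:
        return int(self.mz.size)

    def peaks(self, spectrum_index: int = 0) -> Iterator[Peak]:
        """Iterate peaks as :class:`Peak` records (m/z ascending)."""
        for rho in range(len(self)):
            yield Peak(float(self.mz[rho]), float(self.intensity[rho]), spectrum_index, rho)

    def with_label(self, label: Optional[str]) -> "Spectrum":
        return replace(self, label=label)


@dataclass(frozen=True)
class SpectraSet:
    """A batch of spectra to be processed together."""

    spectra: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "spectra", tuple(self.spectra))
        ids = [s.id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("spectrum ids must be distinct within a SpectraSet")

    @property
    def m(self) -> int:
        """Number of spectra."""
        return len(self.spectra)

    @property
    def n(self) -> int:
        """Total peak count across all spectra."""
        return sum(len(s) for s in self.spectra)

    @property
    def ids(self) -> tuple:
        return tuple(s.id for s in self.spectra)

    def __len__(self) -> int:
        return self.m

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """A new set holding ``spectra[i] for i in indices`` (order preserved)."""
        return SpectraSet(tuple(self.spectra[i] for i in indices))

    def subset_by_id(self, ids: Sequence[str]) -> "SpectraSet":
        by_id = {s.id: s for s in self.spectra}
        return SpectraSet(tuple(by_id[i] for i in ids))

    def peak(self, spectrum_index: int, peak_index: int) -> Peak:
        s = self.spectra[spectrum_index]
        return Peak(
            float(s.mz[peak_index]),
            float(s.intensity[peak_index]),
            spectrum_index,
            peak_index,
        )


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of lock-mass / alignment-point detection.

    ``w`` is the relative window half-width (use :meth:`from_ppm` for ppm
    input).  ``t_a``/``t_b`` bound admissible peak intensities: low-intensity
    peaks have poor mass accuracy (and may be noise), while peaks above the
    detector's linear range also lose accuracy.  ``require_full`` switches
    between lock-mass mode (a group must hold one peak from *every* spectrum)
    and alignment mode (1..m peaks from distinct spectra).
    """

    w: float
    t_a: float = 1000.0
    t_b: float = math.inf
    require_full: bool = True

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")
        if self.t_a < 0:
            raise ValueError(f"t_a must be >= 0, got {self.t_a}")
        if math.isfinite(self.t_b) and self.t_b <= self.t_a:
            raise ValueError("t_b must exceed t_a when bounded")

    @classmethod
    def from_ppm(
        cls,
        w_ppm: float,
        t_a: float = 1000.0,
        t_b: float = math.inf,
        require_full: bool = True,
    ) -> "DetectionParams":
        return cls(w=ppm_to_fraction(w_ppm), t_a=t_a, t_b=t_b, require_full=require_full)

    @property
    def w_ppm(self) -> float:
        return fraction_to_ppm(self.w)

    def window(self, mz: float) -> MzInterval:
        return ppm_window(mz, self.w)

    def passes_intensity(self, intensity: float) -> bool:
        return self.t_a <= intensity <= self.t_b
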
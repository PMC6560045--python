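"""Synthetic centroided spectra with planted ground truth.

Emulates a batch of spectra of samples of the same nature (e.g. pooled
plasma): a common backbone of compounds present in every sample, a pool of
sample-specific compounds, and low-count background noise peaks.  Each
spectrum carries a multiplicative mass drift (ToF mass error grows linearly
with m/z, so recalibration drift acts as a scale factor) and each peak an
independent relative mass jitter.  Intensities are log-normal.  Everything
is reproducible from the seed, and the planted truth (masses, presence
masks, drifts, peak origins) is returned alongside the spectra for scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import MzInterval, Spectrum, SpectraSet

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "RecoveryReport",
    "generate",
    "score_recovery",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults describe a mid-sized single-batch acquisition: 50 spectra
    sharing 100 backbone compounds, 50 further compounds each present in a
    random half of the samples, and 50 sub-threshold noise peaks per
    spectrum over [50, 1000] Th.  Mass behaviour: true masses separated by
    at least 200 ppm, per-spectrum drift uniform in ±10 ppm, per-peak jitter
    uniform in ±5 ppm.  Compound intensities are log-normal with median
    5e4 counts (well above the customary 1000-count detection threshold);
    noise intensities have median 150 counts, i.e. the background that the
    lower intensity threshold exists to exclude.
    """

    m: int = 50
    k_common: int = 100
    k_variable: int = 50
    presence_prob: float = 0.5
    k_noise_per_spectrum: int = 50
    mass_range: MzInterval = MzInterval(50.0, 1000.0)
    min_separation: float = 200e-6
    drift_scale: float = 10e-6
    jitter_scale: float = 5e-6
    jitter_dist: str = "uniform"  # or "gaussian"
    intensity_logmean: float = math.log(5e4)
    intensity_logsd: float = 0.5
    noise_logmean: float = math.log(150.0)
    noise_logsd: float = 0.35
    sub_ta_fraction: float = 0.0  # common compounds forced under t_a somewhere
    sub_ta_threshold: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.k_common < 0 or self.k_variable < 0 or self.k_noise_per_spectrum < 0:
            raise ValueError("counts must be non-negative (m >= 1)")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")
        if self.jitter_dist not in ("uniform", "gaussian"):
            raise ValueError(f"unknown jitter distribution {self.jitter_dist!r}")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted truth backing one generated SpectraSet."""

    true_masses: np.ndarray          # all compounds, common first
    n_common: int
    presence: np.ndarray             # (n_compounds, m) boolean
    drift: np.ndarray                # per-spectrum epsilon_sigma
    peak_origin: Dict[Tuple[int, int], int]  # (sigma, rho) -> compound, -1 = noise

    @property
    def common_masses(self) -> np.ndarray:
        return self.true_masses[: self.n_common]

    @property
    def present_masses(self) -> np.ndarray:
        """Masses of compounds present in at least one spectrum."""
        return self.true_masses[self.presence.any(axis=1)]


def _draw_masses(rng: np.random.Generator, k: int, mass_range: MzInterval, min_sep: float):
    """Draw k masses with pairwise relative separation >= min_sep."""
    lo, hi = mass_range
    masses: List[float] = []
    attempts = 0
    max_attempts = 10000 * max(k, 1)
    while len(masses) < k:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot place {k} masses in [{lo}, {hi}] at separation {min_sep:g}; "
                "reduce k or min_separation"
            )
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - x) > min_sep * min(cand, x) for x in masses):
            masses.append(cand)
    return np.sort(np.asarray(masses))


def generate(config: SyntheticConfig) -> Tuple[SpectraSet, SyntheticGroundTruth]:
    """Generate a SpectraSet plus its ground truth, reproducibly from the seed.

    Observed m/z of a planted compound of mass M in spectrum sigma is
    ``M * (1 + eps_sigma) * (1 + eta)`` with eps_sigma the spectrum's drift
    and eta the per-peak jitter.  Noise peaks are uniform over the mass
    range.  Peaks are sorted per spectrum.
    """
    rng = np.random.default_rng(config.seed)
    k_total = config.k_common + config.k_variable
    masses = _draw_masses(rng, k_total, config.mass_range, config.min_separation)
    # which of the sorted masses form the common backbone
    common_idx = np.sort(rng.choice(k_total, size=config.k_common, replace=False))
    is_common = np.zeros(k_total, dtype=bool)
    is_common[common_idx] = True
    # order compounds common-first for the ground-truth record
    order = np.concatenate([np.flatnonzero(is_common), np.flatnonzero(~is_common)])
    true_masses = masses[order]
    n_common = config.k_common

    presence = np.zeros((k_total, config.m), dtype=bool)
    presence[:n_common, :] = True
    if k_total > n_common:
        presence[n_common:, :] = (
            rng.random((k_total - n_common, config.m)) < config.presence_prob
        )

    drift = rng.uniform(-config.drift_scale, config.drift_scale, size=config.m)

    # optionally force some common compounds under the detection threshold in
    # one random spectrum each (emulating intensity dropouts)
    n_sub = int(round(config.sub_ta_fraction * n_common))
    sub_compounds = rng.choice(n_common, size=n_sub, replace=False) if n_sub else np.empty(0, int)
    sub_spectrum = {int(c): int(rng.integers(config.m)) for c in sub_compounds}

    spectra: List[Spectrum] = []
    peak_origin: Dict[Tuple[int, int], int] = {}
    lo, hi = config.mass_range
    for sigma in range(config.m):
        present = np.flatnonzero(presence[:, sigma])
        k_here = present.size
        if config.jitter_dist == "uniform":
            jitter = rng.uniform(-config.jitter_scale, config.jitter_scale, size=k_here)
        else:
            jitter = rng.normal(0.0, config.jitter_scale, size=k_here)
        mz_compound = true_masses[present] * (1.0 + drift[sigma]) * (1.0 + jitter)
        inten_compound = rng.lognormal(
            config.intensity_logmean, config.intensity_logsd, size=k_here
        )
        for j, comp in enumerate(present):
            if sub_spectrum.get(int(comp)) == sigma:
                inten_compound[j] = rng.uniform(10.0, 0.5 * config.sub_ta_threshold)
        mz_noise = rng.uniform(lo, hi, size=config.k_noise_per_spectrum)
        inten_noise = rng.lognormal(
            config.noise_logmean, config.noise_logsd, size=config.k_noise_per_spectrum
        )
        mz = np.concatenate([mz_compound, mz_noise])
        inten = np.concatenate([inten_compound, inten_noise])
        origin = np.concatenate([present, np.full(config.k_noise_per_spectrum, -1)])
        order_ = np.argsort(mz, kind="stable")
        mz, inten, origin = mz[order_], inten[order_], origin[order_]
        for rho, comp in enumerate(origin):
            peak_origin[(sigma, rho)] = int(comp)
        spectra.append(Spectrum(id=f"sample{sigma:03d}", mz=mz, intensity=inten))

    truth = SyntheticGroundTruth(
        true_masses=true_masses,
        n_common=n_common,
        presence=presence,
        drift=drift,
        peak_origin=peak_origin,
    )
    return SpectraSet(tuple(spectra)), truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well detected m/z points recover the planted masses."""

    recall: float
    precision: float
    n_targets: int
    n_detected: int
    n_matched: int
    ppm_errors: np.ndarray  # signed, one entry per matched detection


def score_recovery(
    detected_mzs: Sequence[float],
    truth: SyntheticGroundTruth,
    tol: float,
    targets: str = "common",
    mass_range: Optional[MzInterval] = None,
) -> RecoveryReport:
    """Match detected points to planted masses within a relative tolerance.

    ``targets`` selects the reference masses: 'common' (backbone compounds,
    the lock-mass ground truth) or 'present' (compounds present in at least
    one spectrum, the alignment ground truth).  ``mass_range`` restricts the
    reference to compounds inside it — useful after correction, which trims
    peaks outside the outermost lock masses and therefore cannot report
    compounds beyond them.  Each detected point matches its nearest target if
    within ``tol`` (relative units); recall counts targets hit at least once,
    precision the fraction of detections that hit.
    """
    if targets == "common":
        ref = truth.common_masses
    elif targets == "present":
        ref = truth.present_masses
    else:
        raise ValueError(f"unknown target selection {targets!r}")
    if mass_range is not None:
        ref = ref[(ref >= mass_range.lo) & (ref <= mass_range.hi)]
    detected = np.sort(np.asarray(detected_mzs, dtype=np.float64))
    hit = np.zeros(ref.size, dtype=bool)
    errors = []
    n_matched = 0
    for d in detected:
        if ref.size == 0:
            break
        j = int(np.argmin(np.abs(ref - d)))
        if abs(ref[j] - d) <= tol * ref[j]:
            hit[j] = True
            n_matched += 1
            errors.append(1e6 * (d - ref[j]) / ref[j])
    recall = float(hit.mean()) if ref.size else 0.0
    precision = n_matched / detected.size if detected.size else 0.0
    return RecoveryReport(
        recall=recall,
        precision=float(precision),
        n_targets=int(ref.size),
        n_detected=int(detected.size),
        n_matched=n_matched,
        ppm_errors=np.asarray(errors, dtype=np.float64),
    )
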
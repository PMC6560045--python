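"""Alignment-point detection and feature-vector representation.

After lock-mass correction, peaks of the same molecule fragment across
spectra cluster inside a window far narrower than the detection window w.
The alignment window theta is chosen from the data: leaving one interior
lock mass v_i out of the correction and correcting its member peaks with the
remaining ones yields a per-VLM deviation theta_i (the smallest window that
would still gather those peaks); theta is the 95th percentile of the
theta_i, or a cross-validatable percentile z in the inductive workflow.

Alignment points are then detected with the same sweep as lock masses, with
the full-coverage constraint dropped (groups of 1..m peaks from distinct
spectra) and no intensity ceiling.  Each point defines one feature column:
the intensity of the corrected peak falling in its window (0 when absent).
A fixed-width binning featurization is provided as the conventional
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DetectionParams, MzInterval, Spectrum, SpectraSet, fraction_to_ppm
from .correct import CorrectionModel, correct_set, match_vlm_peaks
from .detect import VLMSet, detect_vlms, scan_window_sizes, default_window_grid

__all__ = [
    "AlignmentModel",
    "loo_theta",
    "select_theta",
    "detect_alignment_points",
    "represent",
    "represent_set",
    "bin_spectrum",
    "run_pipeline",
    "PipelineResult",
]


def loo_theta(spectra: SpectraSet, vlms: VLMSet) -> np.ndarray:
    """Leave-one-VLM-out deviations for every interior lock mass.

    ``spectra`` must be the *uncorrected* detection set: withholding v_i
    from an already-corrected set is vacuous, since its anchors sit exactly
    on the lock masses and the bridge reproduces them.

    For each v_i with 1 <= i <= r-2 (the outermost lock masses are excluded:
    without a neighbour on each side their members cannot be re-corrected by
    interpolation), all spectra are corrected with v_i withheld and
    theta_i = max over spectra of |corrected member m/z - v_i| / v_i.

    Only the two segments adjacent to v_i change when it is withheld, so
    each theta_i costs O(m): the member of v_i is re-corrected on the bridge
    between the matched peaks of v_{i-1} and v_{i+1}.
    """
    r = len(vlms)
    if r < 3:
        raise ValueError(f"need at least 3 lock masses for theta selection, got {r}")
    v = vlms.mzs
    devs = np.zeros((spectra.m, r - 2), dtype=np.float64)
    for sigma, s in enumerate(spectra):
        match = match_vlm_peaks(s, vlms)
        if not match.matched.all():
            raise ValueError(
                f"spectrum {s.id!r} does not match every lock mass; "
                "theta selection requires the detection set"
            )
        mu = s.mz[match.alpha]
        a = (v[2:] - v[:-2]) / (mu[2:] - mu[:-2])
        corrected_mid = v[:-2] + a * (mu[1:-1] - mu[:-2])
        devs[sigma] = np.abs(corrected_mid - v[1:-1]) / v[1:-1]
    return devs.max(axis=0)


def select_theta(thetas_i: Sequence[float], percentile_z: float = 95.0) -> float:
    """Nearest-rank upper percentile of the leave-one-out deviations.

    Returns the k-th smallest value with k = ceil(z/100 * len): the smallest
    window covering at least z% of the lock masses.  z = 100 returns the
    maximum, a deliberate overestimate kept as an option.
    """
    thetas = np.sort(np.asarray(thetas_i, dtype=np.float64))
    if thetas.size == 0:
        raise ValueError("empty deviation vector")
    if not 0.0 < percentile_z <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile_z}")
    k = math.ceil(percentile_z / 100.0 * thetas.size)
    return float(thetas[k - 1])


def detect_alignment_points(
    corrected: SpectraSet, theta: float, noise_floor: float = 0.0
) -> VLMSet:
    """Isolated alignment points of a corrected set for window ``theta``.

    Runs the lock-mass sweep with the full-coverage constraint dropped and no
    intensity ceiling; ``noise_floor`` plays the role of an optional lower
    intensity threshold for background suppression.  Singleton groups are
    legal output.
    """
    if corrected.m == 0:
        raise ValueError("empty SpectraSet")
    params = DetectionParams(w=theta, t_a=noise_floor, t_b=math.inf, require_full=False)
    return detect_vlms(corrected, params)


@dataclass(frozen=True)
class AlignmentModel:
    """Frozen alignment transform: theta, its provenance, and the points."""

    theta: float
    thetas_i: np.ndarray
    percentile_z: float
    points: VLMSet
    noise_floor: float = 0.0

    @property
    def theta_ppm(self) -> float:
        return fraction_to_ppm(self.theta)

    @property
    def point_mzs(self) -> np.ndarray:
        return self.points.mzs

    @classmethod
    def fit(
        cls,
        raw: SpectraSet,
        corrected: SpectraSet,
        vlms: VLMSet,
        percentile_z: float = 95.0,
        noise_floor: float = 0.0,
    ) -> "AlignmentModel":
        """Fit theta on the raw detection set, points on its corrected form."""
        thetas_i = loo_theta(raw, vlms)
        theta = select_theta(thetas_i, percentile_z)
        points = detect_alignment_points(corrected, theta, noise_floor)
        return cls(
            theta=theta,
            thetas_i=thetas_i,
            percentile_z=percentile_z,
            points=points,
            noise_floor=noise_floor,
        )


def represent(spectrum: Spectrum, model: AlignmentModel) -> np.ndarray:
    """Feature vector of a corrected spectrum under an alignment model.

    For each alignment point, the feature is the intensity of the peak inside
    its window whose m/z is closest to the point (ties to the lower m/z), or
    0 when the window is empty.  An alignment set admits at most one peak per
    spectrum, so a second in-window peak is off-model; taking the closest one
    keeps the representation deterministic.
    """
    theta = model.theta
    mz = spectrum.mz
    features = np.zeros(len(model.points), dtype=np.float64)
    for f, point in enumerate(model.points):
        lo, hi = point.mz * (1.0 - theta), point.mz * (1.0 + theta)
        i0 = int(np.searchsorted(mz, lo, side="left"))
        i1 = int(np.searchsorted(mz, hi, side="right"))
        if i1 > i0:
            local = np.abs(mz[i0:i1] - point.mz)
            features[f] = spectrum.intensity[i0 + int(np.argmin(local))]
    return features


def represent_set(spectra: SpectraSet, model: AlignmentModel) -> pd.DataFrame:
    """Feature matrix (rows = samples, columns = alignment-point m/z)."""
    columns = [round(float(mz), 6) for mz in model.point_mzs]
    rows = {s.id: represent(s, model) for s in spectra}
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def bin_spectrum(
    spectrum: Spectrum,
    bin_width: float,
    mz_range: MzInterval,
    agg: str = "sum",
    relative: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Baseline featurization: aggregate intensities in fixed bins.

    Bins tile ``[lo, hi)`` half-open; a peak exactly on an inner edge falls
    in the bin starting there.  With ``relative`` the bin width is a
    dimensionless fraction and edges form a geometric ladder, matching the
    relative mass-error behaviour; otherwise the width is in Th.  ``agg`` is
    'sum' (default) or 'max'.  Returns (values, bin centers).
    """
    lo, hi = mz_range
    if hi <= lo:
        raise ValueError("empty m/z range")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if relative:
        n_bins = max(1, math.ceil(math.log(hi / lo) / math.log1p(bin_width)))
        edges = lo * (1.0 + bin_width) ** np.arange(n_bins + 1)
    else:
        n_bins = max(1, math.ceil((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
    keep = (spectrum.mz >= lo) & (spectrum.mz < hi)
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    idx = np.clip(np.digitize(mz, edges) - 1, 0, n_bins - 1)
    values = np.zeros(n_bins, dtype=np.float64)
    if agg == "sum":
        np.add.at(values, idx, inten)
    elif agg == "max":
        np.maximum.at(values, idx, inten)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return values, centers


@dataclass(frozen=True)
class PipelineResult:
    """Everything the end-to-end workflow produces."""

    vlms: VLMSet
    correction: CorrectionModel
    alignment: AlignmentModel
    features_train: pd.DataFrame
    features_test: Optional[pd.DataFrame]
    w_ppm: float
    scan_table: Optional[List[Tuple[float, int]]]
    reports: list


def run_pipeline(
    train: SpectraSet,
    test: Optional[SpectraSet] = None,
    params: Optional[DetectionParams] = None,
    mode: str = "transductive",
    percentile_z: float = 95.0,
    noise_floor: float = 0.0,
    trim: bool = True,
    w_grid_ppm: Optional[Sequence[float]] = None,
) -> PipelineResult:
    """End-to-end detect -> correct -> align -> represent workflow.

    ``transductive`` pools train and test spectra through every stage before
    splitting the feature matrix; ``inductive`` fits every model (lock
    masses, correction, theta, alignment points) on the training spectra
    only, freezes them, and then applies matching, correction and
    representation to the test spectra (bridging unmatched lock masses,
    zero-filling empty alignment windows).  In the inductive workflow the
    percentile z is the natural hyperparameter to cross-validate; the
    transductive workflow keeps it at 95.
    """
    if mode not in ("transductive", "inductive"):
        raise ValueError(f"unknown mode {mode!r}")
    if params is None:
        params = DetectionParams.from_ppm(40.0)

    fit_set = train
    if mode == "transductive" and test is not None:
        fit_set = SpectraSet(tuple(train.spectra) + tuple(test.spectra))

    scan_table = None
    if w_grid_ppm is not None:
        best_ppm, scan_table = scan_window_sizes(fit_set, list(w_grid_ppm), params)
        params = DetectionParams(
            w=best_ppm / 1e6, t_a=params.t_a, t_b=params.t_b, require_full=True
        )

    vlms = detect_vlms(fit_set, params)
    correction = CorrectionModel(vlms=vlms, trim=trim)
    corrected_fit, reports = correct_set(fit_set, vlms, trim=trim)
    alignment = AlignmentModel.fit(
        fit_set, corrected_fit, vlms, percentile_z=percentile_z, noise_floor=noise_floor
    )

    if mode == "transductive":
        features_all = represent_set(corrected_fit, alignment)
        train_ids = [i for i in train.ids if i in features_all.index]
        features_train = features_all.loc[train_ids]
        features_test = None
        if test is not None:
            test_ids = [i for i in test.ids if i in features_all.index]
            features_test = features_all.loc[test_ids]
    else:
        features_train = represent_set(corrected_fit, alignment)
        features_test = None
        if test is not None:
            corrected_test, test_reports = correct_set(
                test, vlms, trim=trim, on_error="skip"
            )
            reports = reports + test_reports
            features_test = represent_set(corrected_test, alignment)

    return PipelineResult(
        vlms=vlms,
        correction=correction,
        alignment=alignment,
        features_train=features_train,
        features_test=features_test,
        w_ppm=params.w_ppm,
        scan_table=scan_table,
        reports=reports,
    )
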
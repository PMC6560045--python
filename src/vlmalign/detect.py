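"""Virtual lock-mass detection by a sweep over the pooled peak lists.

A *virtual lock mass* (VLM) for a set of m spectra and relative window
half-width w is an m/z value v such that some peak set P satisfies:

1. P holds exactly one peak from each spectrum;
2. v is the arithmetic mean of the m/z values in P;
3. every peak of P lies in [v(1-w), v(1+w)];
4. no other peak of the set lies in that interval;
5. every peak of P has intensity in [t_a, t_b].

The detector sweeps the pooled, m/z-sorted peak sequence with a min-heap
holding the next unprocessed peak of each spectrum and an *active sequence*
of consecutive peaks currently considered as a candidate group.  Candidate
groups are collected, then any pair of candidates whose windows intersect is
discarded, leaving only *isolated* VLMs.  Total work is O(n log m) for n
pooled peaks.

Relaxed ("alignment") mode drops property (1)'s full-coverage requirement —
groups may hold 1..m peaks from distinct spectra — and applies no intensity
ceiling; it is used to detect alignment points on corrected spectra.

:func:`brute_force_vlms` implements the definition literally in quadratic
time and serves as an independent oracle for the sweep.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import DetectionParams, MzInterval, Peak, SpectraSet, ppm_to_fraction, ppm_window

__all__ = [
    "VLM",
    "VLMSet",
    "ActiveSequence",
    "detect_vlms",
    "brute_force_vlms",
    "remove_overlaps",
    "scan_window_sizes",
    "compare_homologues",
    "HomologueReport",
    "audit_vlms",
    "filter_strict_exclusivity",
    "default_window_grid",
]


@dataclass(frozen=True)
class VLM:
    """One detected lock mass: mean m/z plus its member peaks (one per spectrum)."""

    mz: float
    members: Tuple[Peak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    def member_keys(self, spectrum_ids: Sequence[str]) -> frozenset:
        """Members as (spectrum_id, peak_index) pairs, stable across subsetting."""
        return frozenset((spectrum_ids[p.spectrum_index], p.peak_index) for p in self.members)


@dataclass(frozen=True)
class VLMSet:
    """Isolated VLMs (or alignment points) sorted by m/z, with their provenance."""

    vlms: Tuple[VLM, ...]
    params: DetectionParams
    spectrum_ids: Tuple[str, ...]
    candidates_removed: int = 0
    heap_operations: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vlms", tuple(self.vlms))
        object.__setattr__(self, "spectrum_ids", tuple(self.spectrum_ids))

    @property
    def w(self) -> float:
        return self.params.w

    @property
    def mzs(self) -> np.ndarray:
        return np.array([v.mz for v in self.vlms], dtype=np.float64)

    def window(self, mz: float) -> MzInterval:
        return ppm_window(mz, self.params.w)

    def __len__(self) -> int:
        return len(self.vlms)

    def __iter__(self):
        return iter(self.vlms)

    def __getitem__(self, i: int) -> VLM:
        return self.vlms[i]


class ActiveSequence:
    """Sweep working set: consecutive pooled peaks considered as one candidate.

    Holds a FIFO list ``L`` of peaks from distinct spectra, per-spectrum
    membership flags ``B``, the m/z of the last peak dropped from the front
    (``mu_l``; None before any removal), and the running mean ``mu_A`` of the
    peaks in ``L`` (0 when empty, by convention).
    """

    __slots__ = ("L", "B", "mu_l", "sigma_l", "mu_ll", "w", "_sum")

    def __init__(self, m: int, w: float) -> None:
        self.L: deque = deque()          # entries: (mz, sigma, rho, intensity)
        self.B = bytearray(m)            # membership flags per spectrum
        self.mu_l: Optional[float] = None    # last peak removed from the front
        self.sigma_l: int = -1               # its spectrum
        self.mu_ll: Optional[float] = None   # peak removed before that
        self.w = w
        self._sum = 0.0

    @property
    def mu_A(self) -> float:
        return self._sum / len(self.L) if self.L else 0.0

    def snapshot(self):
        """Freeze the content as a candidate (mean, members).

        The mean of a group of identical m/z values is that value exactly —
        summation round-off must not perturb it, or re-detection on a
        perfectly aligned set would not reproduce the lock masses bit-exact.
        """
        L = self.L
        if L[0][0] == L[-1][0]:
            return L[0][0], tuple(L)
        return self._sum / len(L), tuple(L)

    def _left_addable(self, next_mz: Optional[float]) -> bool:
        """Could the just-removed predecessor peak rejoin the content?

        True when re-adding ``mu_l`` would again yield a group with distinct
        spectra whose window (around the re-centred mean) contains every
        member and excludes the surrounding peaks — in which case the current
        content is not maximal.
        """
        if self.mu_l is None or self.B[self.sigma_l]:
            return False
        k = len(self.L)
        mean = (self._sum + self.mu_l) / (k + 1)
        lo, hi = mean * (1.0 - self.w), mean * (1.0 + self.w)
        if self.mu_l < lo or self.L[-1][0] > hi:
            return False
        if self.mu_ll is not None and lo <= self.mu_ll <= hi:
            return False
        if next_mz is not None and lo <= next_mz <= hi:
            return False
        return True

    def check(self, next_mz: Optional[float], require_full: bool, m: int):
        """Classify the current content: (admissible, valid).

        *Admissible* means the content satisfies the definition's membership
        properties — distinct spectra (a structural invariant), every member
        inside the window around the running mean, and no surrounding peak
        inside that window.  ``next_mz`` is the m/z at the top of the heap
        (None when exhausted): the pooled peak immediately following the
        content; the peak immediately preceding it is ``mu_l``.  Intensity
        bounds need no check here because out-of-bounds peaks are never fed
        to the sweep.

        *Valid* additionally requires one peak per spectrum in full mode,
        and maximality in relaxed mode: re-admitting the predecessor peak
        must not produce another admissible group (maximality towards the
        right is handled by the insertion logic).
        """
        L = self.L
        if not L:
            return False, False
        mu = self._sum / len(L)
        lo, hi = mu * (1.0 - self.w), mu * (1.0 + self.w)
        admissible = not (
            (next_mz is not None and lo <= next_mz <= hi)
            or (self.mu_l is not None and lo <= self.mu_l <= hi)
            or L[0][0] < lo
            or L[-1][0] > hi
        )
        if not admissible:
            return False, False
        if require_full:
            return True, len(L) == m
        return True, not self._left_addable(next_mz)

    def is_valid(self, next_mz: Optional[float], require_full: bool, m: int) -> bool:
        """True iff the current content is a valid candidate group."""
        return self.check(next_mz, require_full, m)[1]

    def try_insert(self, peak: Tuple[float, int, int, float]) -> bool:
        """Append ``peak`` if the content can still become a valid group.

        Fails if the peak's spectrum is already represented, or if the front
        peak and the candidate would not both fit in the window around the
        new mean.  On failure the state is unchanged.
        """
        mz, sigma = peak[0], peak[1]
        if self.B[sigma]:
            return False
        L = self.L
        if L:
            new_sum = self._sum + mz
            mu = new_sum / (len(L) + 1)
            lo, hi = mu * (1.0 - self.w), mu * (1.0 + self.w)
            if L[0][0] < lo or mz > hi:
                return False
            self._sum = new_sum
        else:
            self._sum = mz
        L.append(peak)
        self.B[sigma] = 1
        return True

    def advance_lower_bound(self) -> None:
        """Drop the front peak, remembering its m/z in ``mu_l``."""
        if not self.L:
            raise RuntimeError("advance_lower_bound on empty active sequence")
        mz, sigma = self.L[0][0], self.L[0][1]
        self.L.popleft()
        self.B[sigma] = 0
        self.mu_ll = self.mu_l
        self.mu_l = mz
        self.sigma_l = sigma
        if self.L:
            self._sum -= mz
        else:
            self._sum = 0.0


def _sweep(spectra: SpectraSet, params: DetectionParams):
    """Collect candidate groups (mean, members) plus the heap-operation count."""
    m = spectra.m
    t_a, t_b = params.t_a, params.t_b
    mz_arrays = [s.mz for s in spectra]
    int_arrays = [s.intensity for s in spectra]
    nxt = [0] * m
    heap: List[Tuple[float, int, int, float]] = []
    ops = 0

    def push_next(sigma: int) -> int:
        i = nxt[sigma]
        mzs, ints = mz_arrays[sigma], int_arrays[sigma]
        size = mzs.size
        while i < size and not (t_a <= ints[i] <= t_b):
            i += 1
        if i < size:
            heapq.heappush(heap, (float(mzs[i]), sigma, i, float(ints[i])))
            nxt[sigma] = i + 1
            return 1
        nxt[sigma] = i
        return 0

    for sigma in range(m):
        ops += push_next(sigma)

    A = ActiveSequence(m, params.w)
    candidates: List[Tuple[float, Tuple]] = []
    found = False
    snapshot: Optional[Tuple[float, Tuple]] = None
    require_full = params.require_full

    while heap:
        top = heap[0]
        if A.try_insert(top):
            heapq.heappop(heap)
            ops += 1
            ops += push_next(top[1])
            next_mz = heap[0][0] if heap else None
            admissible, valid = A.check(next_mz, require_full, m)
            if found and admissible and len(snapshot[1]) == len(A.L) - 1:
                # the pending group extended by this one peak is itself
                # admissible, so the pending group was not maximal: drop it
                found = False
                snapshot = None
            if valid:
                if found:
                    # a shorter valid group with the same front whose one-peak
                    # extension was inadmissible: a maximal group in its own
                    # right, to be emitted alongside the longer one (their
                    # windows overlap, so overlap removal arbitrates)
                    candidates.append(snapshot)
                found = True
                snapshot = A.snapshot()
            if not heap:
                # Terminal drain: no further insertion is possible, so every
                # remaining valid suffix is a candidate.
                if found:
                    candidates.append(snapshot)
                    found = False
                while A.L:
                    A.advance_lower_bound()
                    if A.is_valid(None, require_full, m):
                        candidates.append(A.snapshot())
                break
        else:
            if found:
                candidates.append(snapshot)
                found = False
                snapshot = None
            A.advance_lower_bound()
            # re-validate after shrinking: in relaxed mode the shortened
            # content (down to a singleton) may itself be a maximal group
            # that the next insertion would destroy
            if A.is_valid(heap[0][0] if heap else None, require_full, m):
                found = True
                snapshot = A.snapshot()
    return candidates, ops


def remove_overlaps(candidates: Sequence[Tuple[float, Tuple]], w: float):
    """Discard every candidate whose window intersects a neighbour's window.

    Both members of an overlapping pair are dropped (not just one); on a
    sorted sequence checking adjacent neighbours suffices.  Returns the kept
    candidates and the number removed.
    """
    cands = sorted(candidates, key=lambda c: c[0])
    k = len(cands)
    overlapping = [False] * k
    for i in range(k - 1):
        lo_next = cands[i + 1][0] * (1.0 - w)
        hi_this = cands[i][0] * (1.0 + w)
        if hi_this >= lo_next:
            overlapping[i] = True
            overlapping[i + 1] = True
    kept = [c for c, bad in zip(cands, overlapping) if not bad]
    return kept, k - len(kept)


def detect_vlms(spectra: SpectraSet, params: DetectionParams) -> VLMSet:
    """Find all isolated VLMs (or alignment points) of ``spectra`` for ``params``.

    In ``require_full`` mode at least two spectra are required.  Peaks with
    intensity outside ``[t_a, t_b]`` are invisible to the sweep: they can
    neither join a group nor, by default, veto one (see :func:`audit_vlms`
    for the strict re-check).
    """
    if spectra.m == 0:
        raise ValueError("empty SpectraSet")
    if params.require_full and spectra.m < 2:
        raise ValueError("lock-mass detection needs at least 2 spectra")
    candidates, ops = _sweep(spectra, params)
    kept, removed = remove_overlaps(candidates, params.w)
    vlms = tuple(
        VLM(mz=mu, members=tuple(Peak(p[0], p[3], p[1], p[2]) for p in members))
        for mu, members in kept
    )
    return VLMSet(
        vlms=vlms,
        params=params,
        spectrum_ids=spectra.ids,
        candidates_removed=removed,
        heap_operations=ops,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def _pooled_filtered(spectra: SpectraSet, params: DetectionParams):
    """Pooled (mz, sigma, rho, intensity) records passing the intensity bounds,
    sorted by (mz, sigma) to match the sweep's tie-breaking."""
    records = []
    for sigma, s in enumerate(spectra):
        keep = (s.intensity >= params.t_a) & (s.intensity <= params.t_b)
        for rho in np.flatnonzero(keep):
            records.append((float(s.mz[rho]), sigma, int(rho), float(s.intensity[rho])))
    records.sort()
    return records


def brute_force_vlms(spectra: SpectraSet, params: DetectionParams) -> VLMSet:
    """Quadratic-time oracle applying the VLM definition literally.

    Enumerates every contiguous run of the pooled, intensity-filtered peak
    sequence, checks the definition properties directly, keeps maximal valid
    runs, and removes overlapping candidates.  Intended for small instances.
    """
    if spectra.m == 0:
        raise ValueError("empty SpectraSet")
    if params.require_full and spectra.m < 2:
        raise ValueError("lock-mass detection needs at least 2 spectra")
    pool = _pooled_filtered(spectra, params)
    n = len(pool)
    m = spectra.m

    def _admissible(i: int, j: int) -> bool:
        """Run pool[i:j] satisfies distinct spectra, window containment and
        exclusivity (the first three definition properties)."""
        run = pool[i:j]
        if len({p[1] for p in run}) != len(run):
            return False
        v = math.fsum(p[0] for p in run) / len(run)
        lo, hi = v * (1.0 - params.w), v * (1.0 + params.w)
        if run[0][0] < lo or run[-1][0] > hi:
            return False
        if i > 0 and pool[i - 1][0] >= lo:
            return False
        if j < n and pool[j][0] <= hi:
            return False
        return True

    maximal: List[Tuple[int, int]] = []  # half-open [i, j)
    for i in range(n):
        seen = set()
        for j in range(i, min(i + m, n)):
            sigma = pool[j][1]
            if sigma in seen:
                break
            seen.add(sigma)
            if params.require_full and j + 1 - i != m:
                continue
            if not _admissible(i, j + 1):
                continue
            if not params.require_full:
                # maximality: adjoining either neighbouring pooled peak must
                # not yield another admissible group (only adjacent peaks can
                # join, the window being an interval)
                if i > 0 and _admissible(i - 1, j + 1):
                    continue
                if j + 1 < n and _admissible(i, j + 2):
                    continue
            maximal.append((i, j + 1))
    candidates = []
    for i, j in maximal:
        run = pool[i:j]
        if run[0][0] == run[-1][0]:
            v = run[0][0]  # constant group: the mean is that value exactly
        else:
            v = math.fsum(p[0] for p in run) / len(run)
        candidates.append((v, tuple(run)))
    kept, removed = remove_overlaps(candidates, params.w)
    vlms = tuple(
        VLM(mz=mu, members=tuple(Peak(p[0], p[3], p[1], p[2]) for p in members))
        for mu, members in kept
    )
    return VLMSet(
        vlms=vlms,
        params=params,
        spectrum_ids=spectra.ids,
        candidates_removed=removed,
    )


# ---------------------------------------------------------------------------
# Auditing, window scan, homologues


def audit_vlms(vlms: VLMSet, spectra: SpectraSet, strict_exclusivity: bool = False) -> None:
    """Re-check every emitted VLM against the definition; raise on violation.

    By default exclusivity is checked against peaks inside the detection
    intensity bounds, mirroring what the sweep can see.  With
    ``strict_exclusivity`` every peak of the set, sub-threshold ones
    included, is allowed to veto a window.  In relaxed (alignment) mode,
    maximality is re-checked too: no adjacent pooled peak may be addable to
    a group without breaking the membership properties.
    """
    params = vlms.params
    mus = vlms.mzs
    pool = None
    pool_index = {}
    if not params.require_full:
        pool = _pooled_filtered(spectra, params)
        pool_index = {(p[1], p[2]): k for k, p in enumerate(pool)}
    for idx, v in enumerate(vlms):
        sigmas = [p.spectrum_index for p in v.members]
        if len(set(sigmas)) != len(sigmas):
            raise AssertionError(f"VLM {v.mz}: duplicate spectra among members")
        if params.require_full and len(v.members) != spectra.m:
            raise AssertionError(f"VLM {v.mz}: expected one member per spectrum")
        mean = math.fsum(p.mz for p in v.members) / len(v.members)
        if abs(mean - v.mz) > 1e-9 * v.mz:
            raise AssertionError(f"VLM {v.mz}: mean of members is {mean}")
        lo, hi = ppm_window(v.mz, params.w)
        in_window = 0
        for sigma, s in enumerate(spectra):
            i0, i1 = np.searchsorted(s.mz, [lo, hi], side="left")
            while i1 < s.mz.size and s.mz[i1] <= hi:
                i1 += 1
            for rho in range(i0, i1):
                if strict_exclusivity or params.passes_intensity(float(s.intensity[rho])):
                    in_window += 1
        if in_window != len(v.members):
            raise AssertionError(
                f"VLM {v.mz}: window holds {in_window} peaks for {len(v.members)} members"
            )
        for p in v.members:
            if not (lo <= p.mz <= hi):
                raise AssertionError(f"VLM {v.mz}: member {p.mz} outside window")
            if not params.passes_intensity(p.intensity):
                raise AssertionError(f"VLM {v.mz}: member intensity {p.intensity} out of bounds")
        if idx > 0:
            prev_hi = mus[idx - 1] * (1.0 + params.w)
            if prev_hi >= lo:
                raise AssertionError(f"VLMs {mus[idx-1]} and {v.mz}: windows overlap")
        if pool is not None:
            # maximality: the pooled peaks flanking the member run must not be
            # addable (only adjacent peaks can join a window-interval group)
            ks = sorted(pool_index[(p.spectrum_index, p.peak_index)] for p in v.members)
            if ks != list(range(ks[0], ks[-1] + 1)):
                raise AssertionError(f"point {v.mz}: members not contiguous in pooled order")
            member_sigmas = {p.spectrum_index for p in v.members}
            for k_new in (ks[0] - 1, ks[-1] + 1):
                if not 0 <= k_new < len(pool):
                    continue
                cand = pool[k_new]
                if cand[1] in member_sigmas:
                    continue
                group = sorted([p.mz for p in v.members] + [cand[0]])
                mean = math.fsum(group) / len(group)
                g_lo, g_hi = mean * (1.0 - params.w), mean * (1.0 + params.w)
                if group[0] < g_lo or group[-1] > g_hi:
                    continue
                k_prev = min(ks[0], k_new) - 1
                k_next = max(ks[-1], k_new) + 1
                if k_prev >= 0 and pool[k_prev][0] >= g_lo:
                    continue
                if k_next < len(pool) and pool[k_next][0] <= g_hi:
                    continue
                raise AssertionError(
                    f"point {v.mz}: peak at {cand[0]} could be added (not maximal)"
                )


def filter_strict_exclusivity(vlms: VLMSet, spectra: SpectraSet) -> VLMSet:
    """Drop VLMs whose window contains any non-member peak of the set,
    sub-threshold peaks included.

    The sweep only sees thresholded peaks, so by default a background peak
    below ``t_a`` cannot veto a window.  This post-hoc filter applies the
    stricter reading of the exclusivity property, under which it can.
    """
    kept = []
    removed = 0
    for v in vlms:
        lo, hi = ppm_window(v.mz, vlms.params.w)
        in_window = 0
        for s in spectra:
            i0 = int(np.searchsorted(s.mz, lo, side="left"))
            i1 = int(np.searchsorted(s.mz, hi, side="right"))
            in_window += i1 - i0
        if in_window == len(v.members):
            kept.append(v)
        else:
            removed += 1
    return VLMSet(
        vlms=tuple(kept),
        params=vlms.params,
        spectrum_ids=vlms.spectrum_ids,
        candidates_removed=vlms.candidates_removed + removed,
        heap_operations=vlms.heap_operations,
    )


def default_window_grid(lo_ppm: float = 1.0, hi_ppm: float = 200.0, k: int = 20) -> np.ndarray:
    """Geometric grid of window sizes in ppm (a score or so of values suffices
    in practice given the unimodal behaviour of the isolated-VLM count)."""
    return np.geomspace(lo_ppm, hi_ppm, k)


def scan_window_sizes(
    spectra: SpectraSet,
    grid_ppm: Sequence[float],
    params: Optional[DetectionParams] = None,
) -> Tuple[float, List[Tuple[float, int]]]:
    """Run detection over a grid of window sizes; pick the count maximizer.

    Returns ``(best_w_ppm, [(w_ppm, isolated_count), ...])``; ties break
    toward the smallest window.
    """
    grid = [float(g) for g in grid_ppm]
    if not grid or any(g <= 0 for g in grid):
        raise ValueError("window grid must be non-empty and positive")
    if sorted(grid) != grid:
        raise ValueError("window grid must be sorted ascending")
    base = params or DetectionParams.from_ppm(grid[0])
    table = []
    for g in grid:
        p = DetectionParams(
            w=ppm_to_fraction(g), t_a=base.t_a, t_b=base.t_b, require_full=base.require_full
        )
        table.append((g, len(detect_vlms(spectra, p))))
    best = max(table, key=lambda t: (t[1], -t[0]))
    return best[0], table


@dataclass(frozen=True)
class HomologueReport:
    """Matching of VLMs detected on a subset against VLMs of the full set."""

    n_full: int
    n_sub: int
    n_full_with_homologue: int
    pairs: Tuple[Tuple[float, float], ...]  # (full_mz, sub_mz)


def compare_homologues(vlms_sub: VLMSet, vlms_full: VLMSet) -> HomologueReport:
    """Match each full-set VLM to a subset VLM whose member peaks it contains.

    A subset-set VLM v_B is *homologous* to a full-set VLM v_A when the peaks
    forming v_B are a subset of the peaks forming v_A (peaks identified by
    spectrum id and peak index).  Both sets must share the window size.
    """
    if abs(vlms_sub.params.w - vlms_full.params.w) > 1e-15:
        raise ValueError("homologue comparison requires identical window sizes")
    if not set(vlms_sub.spectrum_ids) <= set(vlms_full.spectrum_ids):
        raise ValueError("subset VLMs must come from a subset of the full set's spectra")
    sub_keys = [(v.mz, v.member_keys(vlms_sub.spectrum_ids)) for v in vlms_sub]
    pairs = []
    for v_full in vlms_full:
        full_keys = v_full.member_keys(vlms_full.spectrum_ids)
        for sub_mz, keys in sub_keys:
            if keys and keys <= full_keys:
                pairs.append((v_full.mz, sub_mz))
                break
    return HomologueReport(
        n_full=len(vlms_full),
        n_sub=len(vlms_sub),
        n_full_with_homologue=len(pairs),
        pairs=tuple(pairs),
    )
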
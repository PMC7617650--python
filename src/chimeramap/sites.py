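"""Spatial clustering tests for annotated site pairs on a transcript.

Tests whether two annotated sites (e.g. protein-binding-site clusters)
are connected by more chimeras than expected under the transcript's
background, using a circular-permutation null: both windows are shifted
jointly in fixed steps along the transcript (wrapping at the ends), so
every null placement preserves the pair's linear separation. Observed
per-replicate counts are compared to the pooled permuted counts with a
one-sided t-test, and p-values are Bonferroni-adjusted over the number
of pairs tested.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import ChimeraRecord

__all__ = [
    "SiteCluster",
    "SitePairTest",
    "pair_contact_counts",
    "circular_permutation_test",
    "site_vs_random_interaction_counts",
]

DEFAULT_RADIUS = 50
DEFAULT_STEP = 50


@dataclass(frozen=True)
class SiteCluster:
    """An annotated site: a centre with a +-radius window (default 50 nt)."""

    name: str
    center: int
    radius: int = DEFAULT_RADIUS

    @classmethod
    def from_interval(cls, name: str, start: int, end: int, radius: int = DEFAULT_RADIUS) -> "SiteCluster":
        return cls(name, (start + end) // 2, radius)

    def window(self, length: int | None = None) -> tuple[int, int]:
        """[center - radius, center + radius], clipped to the transcript."""
        lo, hi = self.center - self.radius, self.center + self.radius
        if length is not None:
            if lo < 0 or hi > length:
                import warnings

                warnings.warn(f"site {self.name!r} window clipped to transcript", stacklevel=2)
            lo, hi = max(0, lo), min(length, hi)
        return lo, hi


@dataclass
class SitePairTest:
    """Result of the circular-permutation test for one site pair."""

    pair: tuple[str, str]
    observed: np.ndarray  # per-replicate counts
    permuted: np.ndarray  # shifts x replicates count matrix
    t_statistic: float
    p_value: float
    p_adjusted: float

    @property
    def mean_observed(self) -> float:
        return float(self.observed.mean())

    @property
    def mean_permuted(self) -> float:
        return float(self.permuted.mean())


def _midpoint_arrays(chimeras: Sequence[ChimeraRecord]) -> tuple[np.ndarray, np.ndarray]:
    arms = np.array(
        [(r.arm1[1], r.arm1[2], r.arm2[1], r.arm2[2]) for r in chimeras], dtype=float
    ).reshape(-1, 4)
    return (arms[:, 0] + arms[:, 1] - 1) / 2, (arms[:, 2] + arms[:, 3] - 1) / 2


def _in_shifted_window(mid: np.ndarray, lo: int, hi: int, shift: int, L: int) -> np.ndarray:
    """Membership of midpoints in window [lo, hi) shifted by ``shift`` on
    the circular transcript (windows straddling the origin wrap)."""
    rel = np.mod(mid - shift, L)
    return (rel >= lo) & (rel < hi)


def _pair_count(
    m1: np.ndarray, m2: np.ndarray, wa: tuple[int, int], wb: tuple[int, int], shift: int, L: int
) -> int:
    a1 = _in_shifted_window(m1, wa[0], wa[1], shift, L)
    a2 = _in_shifted_window(m2, wa[0], wa[1], shift, L)
    b1 = _in_shifted_window(m1, wb[0], wb[1], shift, L)
    b2 = _in_shifted_window(m2, wb[0], wb[1], shift, L)
    return int(((a1 & b2) | (a2 & b1)).sum())


def pair_contact_counts(
    chimeras: Sequence[ChimeraRecord],
    site_a: SiteCluster,
    site_b: SiteCluster,
    transcript_length: int,
) -> int:
    """Chimeras with one arm midpoint in each of two disjoint site windows."""
    wa, wb = site_a.window(transcript_length), site_b.window(transcript_length)
    if max(wa[0], wb[0]) < min(wa[1], wb[1]):
        raise ValueError(f"site windows {site_a.name!r} and {site_b.name!r} overlap")
    m1, m2 = _midpoint_arrays(chimeras)
    return _pair_count(m1, m2, wa, wb, 0, transcript_length)


def circular_permutation_test(
    chimeras_per_replicate: Sequence[Sequence[ChimeraRecord]],
    sites: Sequence[SiteCluster],
    transcript_length: int,
    step: int = DEFAULT_STEP,
    pairs: Sequence[tuple[str, str]] | None = None,
    equal_var: bool = False,
    permuted_per_replicate_mean: bool = False,
) -> list[SitePairTest]:
    """Circular-permutation enrichment test for every site pair.

    For each pair, both windows are shifted jointly by k*step
    (k = 1 .. floor(L/step) - 1) with wrap-around; per-shift counts are
    tallied per replicate, and the observed replicate counts are compared
    to the permuted counts (pooled over shifts and replicates by default,
    or reduced to per-replicate means) with a one-sided t-test of
    observed > permuted (Welch by default). Bonferroni multiplicity is
    the number of pairs actually tested.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(chimeras_per_replicate) < 2:
        raise ValueError("the t-test needs at least 2 replicates")
    L = transcript_length
    by_name = {s.name: s for s in sites}
    if pairs is None:
        pairs = [
            (a.name, b.name)
            for a, b in itertools.combinations(sites, 2)
            if max(a.window(L)[0], b.window(L)[0]) >= min(a.window(L)[1], b.window(L)[1])
        ]
    n_shifts = L // step - 1
    if n_shifts < 1:
        raise ValueError(
            f"transcript of {L} nt with step {step} leaves no non-trivial shifts"
        )
    if any(L < 2 * (s.radius + step) for s in by_name.values()):
        raise ValueError("transcript too short for the requested radius and step")

    # doubled integer midpoints relative to every shift (row 0 is the
    # identity shift), so each pair needs only boolean window comparisons
    # per replicate; doubling keeps .5 midpoints exact in int32
    shifts2 = (np.arange(0, n_shifts + 1) * 2 * step).astype(np.int32)[:, None]
    L2 = 2 * L

    def _rel(m: np.ndarray) -> np.ndarray:
        t = (2 * m).astype(np.int32)[None, :] - shifts2
        return np.where(t < 0, t + L2, t)

    rel = [
        (_rel(m1), _rel(m2))
        for m1, m2 in (_midpoint_arrays(reps) for reps in chimeras_per_replicate)
    ]
    results: list[SitePairTest] = []
    for name_a, name_b in pairs:
        wa = by_name[name_a].window(L)
        wb = by_name[name_b].window(L)
        wa2 = (2 * wa[0], 2 * wa[1])
        wb2 = (2 * wb[0], 2 * wb[1])
        counts = np.empty((n_shifts + 1, len(rel)))
        for r, (r1, r2) in enumerate(rel):
            a1 = (r1 >= wa2[0]) & (r1 < wa2[1])
            a2 = (r2 >= wa2[0]) & (r2 < wa2[1])
            b1 = (r1 >= wb2[0]) & (r1 < wb2[1])
            b2 = (r2 >= wb2[0]) & (r2 < wb2[1])
            counts[:, r] = ((a1 & b2) | (a2 & b1)).sum(axis=1)
        observed = counts[0]
        permuted = counts[1:]
        null_sample = permuted.mean(axis=0) if permuted_per_replicate_mean else permuted.ravel()
        t, p = stats.ttest_ind(
            observed, null_sample, equal_var=equal_var, alternative="greater"
        )
        results.append(
            SitePairTest(
                pair=(name_a, name_b),
                observed=observed,
                permuted=permuted,
                t_statistic=float(t),
                p_value=float(p),
                p_adjusted=min(1.0, float(p) * len(pairs)),
            )
        )
    return results


def site_vs_random_interaction_counts(
    chimeras: Sequence[ChimeraRecord],
    sites: Sequence[SiteCluster],
    transcript_length: int,
    total_mapped: int,
    n_random: int = 116,
    frag_len: int = 110,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """Per-site chimera participation vs randomly placed non-site fragments.

    Each site's total chimera participation (chimeras with at least one
    arm midpoint in the site window) is CPM-normalized and compared to
    the mean over ``n_random`` random fragments of ``frag_len`` nt placed
    outside all site windows (defaults 116 fragments of 110 nt).
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    L = transcript_length
    windows = [s.window(L) for s in sites]
    m1, m2 = _midpoint_arrays(chimeras) if chimeras else (np.array([]), np.array([]))

    def participation(lo: int, hi: int) -> float:
        if m1.size == 0:
            return 0.0
        in1 = (m1 >= lo) & (m1 < hi)
        in2 = (m2 >= lo) & (m2 < hi)
        return float((in1 | in2).sum())

    cpm = 1e6 / total_mapped
    per_site = {s.name: participation(*w) * cpm for s, w in zip(sites, windows)}

    valid_starts = [
        s for s in range(0, L - frag_len + 1)
        if all(s + frag_len <= lo or s >= hi for lo, hi in windows)
    ]
    if not valid_starts:
        raise ValueError("transcript too short to place non-site fragments")
    rng = np.random.default_rng(seed)
    starts = rng.choice(valid_starts, size=n_random, replace=True)
    random_mean = float(np.mean([participation(s, s + frag_len) for s in starts])) * cpm
    return per_site, random_mean
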
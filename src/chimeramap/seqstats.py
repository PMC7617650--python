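"""Sequence composition and motif statistics.

G/C content, windowed numeric tracks (for composition or externally
supplied per-base scores), IUPAC motif counting (e.g. the Pumilio
recognition element UGUANAUA), and G/C comparison of chimera arm
populations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ChimeraRecord

__all__ = [
    "PRE_MOTIF",
    "gc_content",
    "windowed_track",
    "count_motif",
    "iupac_regex",
    "arm_gc_comparison",
    "ArmGcResult",
]

PRE_MOTIF = "UGUANAUA"  # Pumilio recognition element consensus

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


def gc_content(sequence: str) -> float:
    """(G + C) / (length - N); NaN (with a warning) for all-N input."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    s = sequence.upper()
    n_n = s.count("N")
    denom = len(s) - n_n
    if denom == 0:
        warnings.warn("all-N sequence: G/C content undefined", stacklevel=2)
        return float("nan")
    return (s.count("G") + s.count("C")) / denom


def windowed_track(
    values: str | Sequence[float],
    window: int = 20,
    sliding: bool = False,
) -> np.ndarray:
    """Per-window means of a numeric track or of per-base G/C indicators.

    Windows tile the input without overlap (the last partial window is
    retained); ``sliding=True`` switches to a 1-step sliding window.
    Strings are converted to a G/C indicator track with N as NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(values, str):
        s = values.upper()
        track = np.array(
            [np.nan if b == "N" else float(b in "GC") for b in s]
        )
    else:
        track = np.asarray(values, dtype=float)
    if track.size == 0:
        return np.array([])
    if sliding:
        out = np.array(
            [np.nanmean(track[i : i + window]) for i in range(len(track) - window + 1)]
        )
        return out
    n_win = -(-len(track) // window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.array(
            [np.nanmean(track[i * window : (i + 1) * window]) for i in range(n_win)]
        )


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC nucleotide pattern into a regex over ACGU."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    try:
        return "".join(_IUPAC[c] for c in pattern.upper())
    except KeyError as err:
        raise ValueError(f"invalid IUPAC symbol {err.args[0]!r} in pattern") from None


def count_motif(sequence: str, pattern: str = PRE_MOTIF) -> int:
    """Count (possibly overlapping) IUPAC-pattern matches; T == U."""
    seq = sequence.upper().replace("T", "U")
    rx = re.compile(f"(?=({iupac_regex(pattern)}))")
    return sum(1 for _ in rx.finditer(seq))


@dataclass
class ArmGcResult:
    """Per-UMI arm G/C values for two arm populations plus their
    two-sided rank-sum comparison and reference baselines."""

    values: pd.DataFrame  # columns: population, gc, umi
    p_value: float
    statistic: float
    baselines: dict[str, float]


def arm_gc_comparison(
    chimeras: Sequence[ChimeraRecord],
    references: Mapping[str, str],
) -> ArmGcResult:
    """Compare G/C content between the two arm populations of a chimera set.

    Arms are grouped by transcript when the chimeras are intermolecular
    (two transcripts present), otherwise by arm position (arm1 vs arm2).
    Duplicate reads sharing a (arms, UMI) key contribute one data point.
    The two populations are compared with a two-sided Wilcoxon rank-sum
    test; per-reference average G/C baselines are reported alongside.
    """
    seen: set[tuple] = set()
    rows: list[tuple[str, float, str]] = []
    tids = {rec.arm1[0] for rec in chimeras} | {rec.arm2[0] for rec in chimeras}
    by_transcript = len(tids) == 2
    for rec in chimeras:
        key = (rec.arm1, rec.arm2, rec.umi)
        if key in seen:
            continue
        seen.add(key)
        for arm_name, (tid, s, e) in (("arm1", rec.arm1), ("arm2", rec.arm2)):
            if tid not in references:
                raise ValueError(f"no reference sequence for transcript {tid!r}")
            ref = references[tid]
            if s < 0 or e > len(ref):
                raise ValueError(f"arm ({s},{e}) outside reference {tid!r}")
            pop = tid if by_transcript else arm_name
            rows.append((pop, gc_content(ref[s:e]), rec.umi))
    df = pd.DataFrame(rows, columns=["population", "gc", "umi"])
    pops = sorted(df["population"].unique())
    if len(pops) == 2:
        a = df.loc[df["population"] == pops[0], "gc"]
        b = df.loc[df["population"] == pops[1], "gc"]
        stat, p = stats.ranksums(a, b)
    else:
        stat, p = float("nan"), float("nan")
    baselines = {tid: gc_content(seq) for tid, seq in references.items()}
    return ArmGcResult(values=df, p_value=float(p), statistic=float(stat), baselines=baselines)
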
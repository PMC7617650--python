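"""Binned symmetric contact maps from intra-transcript chimeras.

The contact map is the Hi-C-style summary of a proximity-ligation
library: a symmetric ``n_bins x n_bins`` matrix where each chimera adds
one unit at the bin pair of its two arm midpoints. Maps support CPM
normalization (chimeric reads per million mapped reads) and replicate
comparison via Pearson correlation of vectorized window counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .io import ChimeraRecord
from .synth import Transcript

__all__ = ["ContactMap", "build_contact_map", "normalize_cpm", "replicate_correlation"]


@dataclass
class ContactMap:
    """Symmetric binned contact matrix for one transcript."""

    transcript_id: str
    bin_size: int
    counts: np.ndarray
    total_mapped: int
    length: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def upper_triangle(self, k: int = 0) -> np.ndarray:
        """Vectorized upper triangle (including the diagonal for k=0)."""
        iu = np.triu_indices(self.n_bins, k=k)
        return self.counts[iu]

    def total_contacts(self) -> float:
        """Sum over the upper triangle including the diagonal — equals the
        number of contributing chimeras for an unnormalized map."""
        return float(np.triu(self.counts).sum())

    def to_dense_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.counts, fmt="%g", delimiter="\t")

    def to_sparse_tsv(self, path: str | Path) -> None:
        iu = np.triu_indices(self.n_bins)
        with open(path, "w") as fh:
            fh.write("bin_i\tbin_j\tcount\n")
            for i, j in zip(*iu):
                c = self.counts[i, j]
                if c != 0:
                    fh.write(f"{i}\t{j}\t{c:g}\n")


def _bin_of(midpoint: float, bin_size: int) -> int:
    return int(midpoint // bin_size)


def build_contact_map(
    chimeras: Iterable[ChimeraRecord],
    transcript: Transcript | tuple[str, int],
    bin_size: int = 10,
    weight: Literal["read", "dup", "umi"] = "read",
    total_mapped: int | None = None,
    spread: bool = False,
) -> ContactMap:
    """Bin intra-transcript chimeras into a symmetric contact matrix.

    Each chimera contributes at the cell of its two arm-midpoint bins
    (and the mirror cell; diagonal cells once). ``weight`` selects the
    unit: one per record ("read"), the duplicate count ("dup"), or one
    per distinct (arms, UMI) key ("umi"). With ``spread=True`` the unit
    is instead distributed over all bin pairs covered by the two arm
    spans (sensitivity-analysis mode; conservation still holds per
    chimera).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if isinstance(transcript, Transcript):
        tid, L = transcript.id, len(transcript)
    else:
        tid, L = transcript
    n_bins = -(-L // bin_size)
    counts = np.zeros((n_bins, n_bins))
    records = list(chimeras)
    if weight == "umi":
        seen: dict[tuple, ChimeraRecord] = {}
        for rec in records:
            seen.setdefault((rec.arm1, rec.arm2, rec.umi), rec)
        records = list(seen.values())
    n_used = 0
    for rec in records:
        if rec.arm1[0] != tid or rec.arm2[0] != tid:
            raise ValueError(f"chimera {rec.read_id!r} is not on transcript {tid!r}")
        for _, s, e in (rec.arm1, rec.arm2):
            if s < 0 or e > L:
                raise ValueError(f"arm ({s},{e}) outside transcript of length {L}")
        w = float(rec.dup_count) if weight == "dup" else 1.0
        m1, m2 = rec.midpoints()
        if spread:
            b1 = range(_bin_of(rec.arm1[1], bin_size), _bin_of(rec.arm1[2] - 1, bin_size) + 1)
            b2 = range(_bin_of(rec.arm2[1], bin_size), _bin_of(rec.arm2[2] - 1, bin_size) + 1)
            cells = sorted({(min(i, j), max(i, j)) for i in b1 for j in b2})
            u = w / len(cells)
            for i, j in cells:
                counts[i, j] += u
                if i != j:
                    counts[j, i] += u
        else:
            i, j = sorted((_bin_of(m1, bin_size), _bin_of(m2, bin_size)))
            counts[i, j] += w
            if i != j:
                counts[j, i] += w
        n_used += 1
    total = total_mapped if total_mapped is not None else max(n_used, 1)
    return ContactMap(transcript_id=tid, bin_size=bin_size, counts=counts, total_mapped=total, length=L)


def normalize_cpm(cmap: ContactMap) -> ContactMap:
    """Chimeric reads per million mapped reads: each cell x 1e6 / total."""
    if cmap.total_mapped <= 0:
        raise ValueError("total_mapped must be positive for CPM normalization")
    return replace(cmap, counts=cmap.counts * 1e6 / cmap.total_mapped)


def replicate_correlation(map_a: ContactMap, map_b: ContactMap) -> tuple[float, float]:
    """Pearson r between two replicate maps over vectorized upper-triangle
    window counts, plus the clustering-ready distance 1 - r.

    Zero-variance maps make r undefined; (nan, nan) is returned with a
    warning.
    """
    if map_a.transcript_id != map_b.transcript_id:
        raise ValueError("maps are for different transcripts")
    if map_a.bin_size != map_b.bin_size or map_a.n_bins != map_b.n_bins:
        raise ValueError("maps have different binning")
    x, y = map_a.upper_triangle(), map_b.upper_triangle()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance contact map: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return r, 1.0 - r
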
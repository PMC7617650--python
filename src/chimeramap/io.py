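"""Read/write standard formats and the read-preprocessing chain.

Covers the desk-side of a proximity-ligation library prep: adapter
trimming, paired-end merging, duplicate collapsing with UMI extraction,
and parsing/writing of tab-delimited chimera ("hyb") tables.

Coordinate convention: everything in memory is 0-based half-open.
The hyb dialect on disk is 1-based inclusive; conversion happens only at
the format boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RawRead",
    "ChimeraRecord",
    "trim_adapters",
    "merge_pairs",
    "dedup_umi",
    "CollapsedRead",
    "read_hyb",
    "write_hyb",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (T/U both complement to A; output uses T)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class RawRead:
    """A sequencing read, optionally with Phred+33 qualities."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class ChimeraRecord:
    """One proximity-ligated read with two mapped arms.

    Arms are ``(transcript_id, start, end)`` with 0-based half-open
    coordinates. Intra-transcript chimeras are stored in canonical order
    (``arm1.start <= arm2.start``) so that contact maps are symmetric by
    construction.
    """

    read_id: str
    arm1: tuple[str, int, int]
    arm2: tuple[str, int, int]
    umi: str = ""
    dup_count: int = 1

    def __post_init__(self) -> None:
        for arm in (self.arm1, self.arm2):
            tid, start, end = arm
            if end <= start:
                raise ValueError(f"empty arm {arm} in read {self.read_id!r}")
        if self.dup_count < 1:
            raise ValueError("dup_count must be >= 1")
        if self.arm1[0] == self.arm2[0] and self.arm1[1] > self.arm2[1]:
            self.arm1, self.arm2 = self.arm2, self.arm1

    @property
    def intra(self) -> bool:
        return self.arm1[0] == self.arm2[0]

    def midpoints(self) -> tuple[float, float]:
        """Arm midpoints in transcript coordinates."""
        return (
            (self.arm1[1] + self.arm1[2] - 1) / 2,
            (self.arm2[1] + self.arm2[2] - 1) / 2,
        )


# ---------------------------------------------------------------------------
# adapter trimming


def _find_adapter(seq: str, adapter: str, max_mismatch_frac: float = 0.1) -> int:
    """Return the position where the adapter starts, or len(seq) if absent.

    A full-length adapter occurrence tolerates ``max_mismatch_frac``
    mismatches; a partial occurrence at the read 3' end (adapter running
    off the read) must be an exact prefix match of >= 3 nt.
    """
    n, m = len(seq), len(adapter)
    max_mm = int(max_mismatch_frac * m)
    for i in range(0, n):
        frag = seq[i : i + m]
        if len(frag) == m:
            mm = sum(a != b for a, b in zip(frag, adapter))
            if mm <= max_mm:
                return i
        else:  # adapter runs off the 3' end: exact, >= 3 nt
            if len(frag) >= 3 and adapter.startswith(frag):
                return i
    return n


def trim_adapters(
    reads: Iterable[RawRead],
    adapter_fwd: str,
    adapter_rev: str | None = None,
    min_len: int = 10,
    max_mismatch_frac: float = 0.1,
) -> list[RawRead]:
    """Remove 3' sequencing adapters and drop reads shorter than ``min_len``.

    ``adapter_fwd`` is searched in every read; ``adapter_rev`` (the mate
    adapter) is searched as well when given, and the earlier hit wins.
    """
    if not adapter_fwd:
        raise ValueError("adapter_fwd must be non-empty")
    adapters = [adapter_fwd.upper()]
    if adapter_rev:
        adapters.append(adapter_rev.upper())
    out: list[RawRead] = []
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        cut = min(_find_adapter(seq, a, max_mismatch_frac) for a in adapters)
        if cut < min_len:
            continue
        if cut == len(read.sequence):
            out.append(read)
        else:
            out.append(
                RawRead(
                    read.id,
                    read.sequence[:cut],
                    read.quality[:cut] if read.quality else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# paired-end merging


def _merge_one(
    s1: str, s2rc: str, min_overlap: int, max_mismatch_frac: float
) -> str | None:
    """Best ungapped 3'-overlap merge of s1 with the reverse-complemented mate."""
    best = None  # (mismatch_frac, -overlap, merged)
    lo, hi = min_overlap, min(len(s1), len(s2rc))
    for o in range(hi, lo - 1, -1):
        tail, head = s1[-o:], s2rc[:o]
        mm = sum(a != b for a, b in zip(tail, head))
        frac = mm / o
        if frac <= max_mismatch_frac:
            cand = (frac, -o, s1 + s2rc[o:])
            if best is None or cand[:2] < best[:2]:
                best = cand
    return None if best is None else best[2]


def merge_pairs(
    r1: Sequence[RawRead],
    r2: Sequence[RawRead],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[RawRead], np.ndarray]:
    """Merge read pairs by their 3' overlap (mate reverse-complemented).

    Returns the merged reads plus a boolean mask of which pairs merged;
    unmergeable pairs are passed through as the forward read, flagged
    ``False`` in the mask.
    """
    if len(r1) != len(r2):
        raise ValueError(f"r1 has {len(r1)} reads but r2 has {len(r2)}")
    out: list[RawRead] = []
    merged = np.zeros(len(r1), dtype=bool)
    for idx, (a, b) in enumerate(zip(r1, r2)):
        s2rc = revcomp(b.sequence.upper().replace("U", "T"))
        m = _merge_one(a.sequence.upper().replace("U", "T"), s2rc, min_overlap, max_mismatch_frac)
        if m is None:
            out.append(a)
        else:
            out.append(RawRead(a.id, m))
            merged[idx] = True
    return out, merged


# ---------------------------------------------------------------------------
# duplicate collapsing + UMI extraction


@dataclass
class CollapsedRead:
    """A deduplicated read: UMI stripped, duplicate tallies attached.

    ``dup_count`` counts occurrences of this exact (sequence, UMI) key;
    ``umi_count`` counts distinct UMIs seen for this sequence overall.
    """

    read_id: str
    sequence: str
    umi: str
    dup_count: int
    umi_count: int


def dedup_umi(reads: Iterable[RawRead], umi_len: int = 6) -> list[CollapsedRead]:
    """Collapse identical reads, extracting the 3'-terminal UMI.

    The UMI is the last ``umi_len`` bases of each read and is removed from
    the sequence. Records are keyed by (sequence, UMI); the sum of
    ``dup_count`` over the output equals the number of input reads.
    """
    counts: dict[tuple[str, str], int] = {}
    first_id: dict[tuple[str, str], str] = {}
    umis_per_seq: dict[str, set[str]] = {}
    n_in = 0
    for read in reads:
        n_in += 1
        if len(read.sequence) <= umi_len:
            raise ValueError(
                f"read {read.id!r} (length {len(read.sequence)}) is not longer "
                f"than the UMI ({umi_len} nt)"
            )
        seq, umi = read.sequence[:-umi_len], read.sequence[-umi_len:]
        key = (seq, umi)
        counts[key] = counts.get(key, 0) + 1
        first_id.setdefault(key, read.id)
        umis_per_seq.setdefault(seq, set()).add(umi)
    out = [
        CollapsedRead(
            read_id=f"{first_id[key]}_DUP:{n}_UMIS:{len(umis_per_seq[key[0]])}",
            sequence=key[0],
            umi=key[1],
            dup_count=n,
            umi_count=len(umis_per_seq[key[0]]),
        )
        for key, n in counts.items()
    ]
    assert sum(r.dup_count for r in out) == n_in
    return out


# ---------------------------------------------------------------------------
# hyb tab-delimited chimera tables
#
# Pinned 15-column dialect: read id, code, read length, then per arm
# (transcript, read start, read end, ref start, ref end, score). File
# coordinates are 1-based inclusive. UMI and duplicate count are encoded
# in the read-id field as id|UMI|dup.


def _format_id(rec: ChimeraRecord) -> str:
    return f"{rec.read_id}|{rec.umi}|{rec.dup_count}"


def _parse_id(token: str) -> tuple[str, str, int]:
    parts = token.split("|")
    if len(parts) == 3:
        return parts[0], parts[1], int(parts[2])
    return token, "", 1


def write_hyb(records: Iterable[ChimeraRecord], path: str | Path) -> None:
    """Write chimera records as a 15-column hyb-style TSV."""
    with open(path, "w") as fh:
        for rec in records:
            l1 = rec.arm1[2] - rec.arm1[1]
            l2 = rec.arm2[2] - rec.arm2[1]
            cols = [
                _format_id(rec),
                ".",
                str(l1 + l2),
                rec.arm1[0],
                "1",
                str(l1),
                str(rec.arm1[1] + 1),
                str(rec.arm1[2]),
                str(l1),
                rec.arm2[0],
                str(l1 + 1),
                str(l1 + l2),
                str(rec.arm2[1] + 1),
                str(rec.arm2[2]),
                str(l2),
            ]
            fh.write("\t".join(cols) + "\n")


def read_hyb(path: str | Path) -> list[ChimeraRecord]:
    """Parse a hyb-style TSV back into :class:`ChimeraRecord` objects."""
    out: list[ChimeraRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise ValueError(
                    f"{path}: line {lineno}: expected 15 tab-delimited columns, "
                    f"got {len(cols)}"
                )
            try:
                read_id, umi, dup = _parse_id(cols[0])
                arm1 = (cols[3], int(cols[6]) - 1, int(cols[7]))
                arm2 = (cols[9], int(cols[12]) - 1, int(cols[13]))
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: {err}") from None
            out.append(
                ChimeraRecord(read_id=read_id, arm1=arm1, arm2=arm2, umi=umi, dup_count=dup)
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ via Biopython


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[RawRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(RawRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
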
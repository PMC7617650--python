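"""Map reads to reference transcripts and call two-arm chimeras.

A deterministic k-mer-seeded, ungapped-extension mapper adequate for
desk-scale references (a transcript or a small transcript set). For each
read the caller finds the highest-scoring pair of non-overlapping arm
hits; reads fully explained by one hit are counted as non-chimeric.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import ChimeraRecord, RawRead

__all__ = ["ArmHit", "CallResult", "call_chimeras", "build_kmer_index"]


@dataclass(frozen=True)
class ArmHit:
    """One ungapped alignment of a read segment to a reference interval."""

    qstart: int
    qend: int
    transcript_id: str
    rstart: int
    rend: int
    score: int  # matches - mismatches

    def __post_init__(self) -> None:
        if self.qend - self.qstart != self.rend - self.rstart:
            raise ValueError("ungapped hit must have equal query/ref spans")

    @property
    def length(self) -> int:
        return self.qend - self.qstart


@dataclass
class CallResult:
    """Chimera calls plus tallies of single-hit and unmapped reads."""

    chimeras: list[ChimeraRecord] = field(default_factory=list)
    n_single: int = 0
    n_unmapped: int = 0

    @property
    def n_chimeric(self) -> int:
        return len(self.chimeras)


def build_kmer_index(
    reference: Mapping[str, str], k: int
) -> dict[str, list[tuple[str, int]]]:
    """Exact k-mer -> [(transcript, position)] lookup over the reference."""
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tid, seq in reference.items():
        s = seq.upper().replace("U", "T")
        for i in range(len(s) - k + 1):
            index[s[i : i + k]].append((tid, i))
    return dict(index)


def _extend(
    read: str, ref: str, q: int, r: int, k: int, max_mismatch_frac: float
) -> tuple[int, int, int, int]:
    """Greedily extend an exact seed in both directions.

    A mismatch is crossed only while the running mismatch fraction stays
    within ``max_mismatch_frac``; trailing mismatches are trimmed so hits
    end on matches. Returns (qstart, qend, rstart, score).
    """
    n, m = len(read), len(ref)
    matches, mismatches = k, 0

    qe, re_ = q + k, r + k  # right extension
    while qe < n and re_ < m:
        if read[qe] == ref[re_]:
            matches += 1
        elif (mismatches + 1) / (matches + mismatches + 1) <= max_mismatch_frac:
            mismatches += 1
        else:
            break
        qe += 1
        re_ += 1
    while qe > q + k and read[qe - 1] != ref[re_ - 1]:
        qe -= 1
        re_ -= 1
        mismatches -= 1

    qs, rs = q, r  # left extension
    while qs > 0 and rs > 0:
        if read[qs - 1] == ref[rs - 1]:
            matches += 1
        elif (mismatches + 1) / (matches + mismatches + 1) <= max_mismatch_frac:
            mismatches += 1
        else:
            break
        qs -= 1
        rs -= 1
    while qs < q and read[qs] != ref[rs]:
        qs += 1
        rs += 1
        mismatches -= 1

    length = qe - qs
    mm = sum(1 for a, b in zip(read[qs:qe], ref[rs : rs + length]) if a != b)
    return qs, qe, rs, length - 2 * mm


def _read_hits(
    read: str,
    reference: Mapping[str, str],
    index: Mapping[str, list[tuple[str, int]]],
    k: int,
    min_arm: int,
    max_mismatch_frac: float,
) -> list[ArmHit]:
    """All maximal seeded hits of one read, one per (transcript, diagonal)."""
    seen: set[tuple[str, int]] = set()
    hits: dict[tuple[str, int, int], ArmHit] = {}
    for q in range(0, len(read) - k + 1):
        for tid, r in index.get(read[q : q + k], ()):
            diag = (tid, r - q)
            if diag in seen:
                continue
            seen.add(diag)
            qs, qe, rs, score = _extend(read, reference[tid], q, r, k, max_mismatch_frac)
            if qe - qs < min_arm:
                continue
            key = (tid, qs, rs)
            prev = hits.get(key)
            if prev is None or score > prev.score:
                hits[key] = ArmHit(qs, qe, tid, rs, rs + (qe - qs), score)
    return list(hits.values())


def _score(read: str, ref: str, qs: int, qe: int, rs: int) -> int:
    mm = sum(1 for a, b in zip(read[qs:qe], ref[rs : rs + qe - qs]) if a != b)
    return (qe - qs) - 2 * mm


def _split_overlap(
    read: str, reference: Mapping[str, str], a: ArmHit, b: ArmHit, min_arm: int
) -> tuple[ArmHit, ArmHit] | None:
    """Resolve two hits that overlap on the read by splitting at the
    junction point maximizing total per-base matches.

    Greedy extension can overreach a ligation junction by chance matches;
    the optimal split restores the exact arm boundaries on error-free
    reads. Returns None if either trimmed arm falls under ``min_arm``.
    """
    o = a.qend - b.qstart
    if o <= 0:
        return a, b
    ref_a, ref_b = reference[a.transcript_id], reference[b.transcript_id]
    off_a, off_b = a.rstart - a.qstart, b.rstart - b.qstart
    lo, hi = b.qstart, a.qend
    ma = [read[p] == ref_a[p + off_a] for p in range(lo, hi)]
    mb = [read[p] == ref_b[p + off_b] for p in range(lo, hi)]
    # split s in [lo, hi]: a keeps [qstart, s), b keeps [s, qend)
    best_s, best_total = lo, -1
    suffix_b = sum(mb)
    prefix_a = 0
    for k, s in enumerate(range(lo, hi + 1)):
        total = prefix_a + suffix_b
        if total > best_total:
            best_total, best_s = total, s
        if k < len(ma):
            prefix_a += ma[k]
            suffix_b -= mb[k]
    s = best_s
    if s - a.qstart < min_arm or b.qend - s < min_arm:
        return None
    a2 = ArmHit(a.qstart, s, a.transcript_id, a.rstart, off_a + s,
                _score(read, ref_a, a.qstart, s, a.rstart))
    b2 = ArmHit(s, b.qend, b.transcript_id, off_b + s, b.rend,
                _score(read, ref_b, s, b.qend, off_b + s))
    return a2, b2


def _best_pair(
    read: str, reference: Mapping[str, str], hits: Sequence[ArmHit], min_arm: int
) -> tuple[ArmHit, ArmHit] | None:
    """Highest-scoring pair of read-disjoint hits (overlaps resolved by
    junction splitting), deterministic tie-break by (total score desc,
    leftmost arm1 ref start, transcript id)."""
    best: tuple[int, int, str, str, ArmHit, ArmHit] | None = None
    ordered = sorted(hits, key=lambda h: (h.qstart, h.transcript_id, h.rstart))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            pair = _split_overlap(read, reference, a, b, min_arm)
            if pair is None:
                continue
            a2, b2 = pair
            key = (-(a2.score + b2.score), a2.rstart, a2.transcript_id, b2.transcript_id)
            if best is None or key < best[:4]:
                best = (*key, a2, b2)
    return None if best is None else (best[4], best[5])


def call_chimeras(
    reads: Iterable[RawRead],
    reference: Mapping[str, str],
    k: int = 12,
    min_arm: int = 15,
    max_mismatch_frac: float = 0.1,
) -> CallResult:
    """Call two-arm chimeras against a reference transcript set.

    A read whose best single hit covers it end to end is non-chimeric; a
    read shorter than ``2 * min_arm`` can never yield a chimera. Arms of
    an intra-transcript chimera are stored in canonical coordinate order.
    """
    if not reference:
        raise ValueError("empty reference")
    if k < 8:
        raise ValueError("k must be >= 8")
    if min_arm < k:
        raise ValueError("min_arm must be >= k")
    ref = {tid: s.upper().replace("U", "T") for tid, s in reference.items()}
    index = build_kmer_index(ref, k)
    result = CallResult()
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        hits = _read_hits(seq, ref, index, k, min_arm, max_mismatch_frac)
        if not hits:
            result.n_unmapped += 1
            continue
        full = [h for h in hits if h.qstart == 0 and h.qend == len(seq)]
        if full:
            result.n_single += 1
            continue
        pair = _best_pair(seq, ref, hits, min_arm) if len(seq) >= 2 * min_arm else None
        if pair is None:
            result.n_single += 1
            continue
        a, b = pair
        result.chimeras.append(
            ChimeraRecord(
                read_id=read.id,
                arm1=(a.transcript_id, a.rstart, a.rend),
                arm2=(b.transcript_id, b.rstart, b.rend),
            )
        )
    return result
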
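"""From chimera evidence to folding constraints and secondary structures.

The chain mirrors a constraint-folding pipeline: the strongest contact
cells of a chimera map become candidate forced pairings; random subsets
of the constraint set (1,000 shuffles by default) are folded and the
pair frequencies across the ensemble give a consensus; per-pair support
is scored as log2 chimeric counts per million mapped reads.

The folding engine is a weighted Nussinov dynamic program (maximum
weighted nested pairing, canonical {AU, GC, GU} pairs, minimum hairpin
loop of 3 nt) with forced-pair bonuses and prohibited-pair exclusions.
It deliberately trades the thermodynamic nearest-neighbour model for an
exactly testable objective; constraint files are exported in CT and
pin-annotated dot-bracket form for use with external energy-based
engines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .contacts import ContactMap
from .io import ChimeraRecord

__all__ = [
    "FoldConstraint",
    "SecondaryStructure",
    "chimera_constraints",
    "shuffle_constraints",
    "fold_constrained",
    "fold_ensemble",
    "resolve_conflicts",
    "basepair_support",
    "design_decoy",
    "pairs_from_dotbracket",
    "dotbracket_from_pairs",
    "write_ct",
    "read_ct",
    "write_constraints",
]

MIN_LOOP = 3
FORCED_BONUS = 1000.0
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class FoldConstraint:
    """A forced or prohibited base pair (i, j), 0-based, i < j."""

    i: int
    j: int
    kind: str = "forced"  # "forced" | "prohibited"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("constraint requires i < j")
        if self.kind == "forced" and self.j - self.i < MIN_LOOP + 1:
            raise ValueError(
                f"forced pair ({self.i},{self.j}) violates the minimum hairpin loop"
            )
        if self.kind not in ("forced", "prohibited"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")


@dataclass
class SecondaryStructure:
    """A nested secondary structure: dot-bracket string plus pair list."""

    dotbracket: str
    pairs: list[tuple[int, int]]
    score: float = 0.0

    def __post_init__(self) -> None:
        expected = dotbracket_from_pairs(self.pairs, len(self.dotbracket))
        if expected != self.dotbracket:
            raise ValueError("dot-bracket string and pair list disagree")

    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)


# ---------------------------------------------------------------------------
# constraint generation


def chimera_constraints(cmap: ContactMap, top_fraction: float = 0.1) -> list[FoldConstraint]:
    """Forced-pair candidates from the strongest contact cells.

    The ``top_fraction`` highest-count nonzero upper-triangle cells are
    converted to one representative pair each (the nucleotide midpoints
    of the two bins), sorted by weight with deterministic (i, j)
    tie-breaks. Cells whose midpoints violate the minimum loop are
    skipped.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    iu = np.triu_indices(cmap.n_bins)
    cells = [
        (int(i), int(j), float(cmap.counts[i, j]))
        for i, j in zip(*iu)
        if cmap.counts[i, j] > 0
    ]
    if not cells:
        return []
    cells.sort(key=lambda c: (-c[2], c[0], c[1]))
    n_take = max(1, int(np.ceil(top_fraction * len(cells))))
    half = cmap.bin_size // 2
    out: list[FoldConstraint] = []
    for i, j, w in cells[:n_take]:
        pi = min(i * cmap.bin_size + half, cmap.length - 1)
        pj = min(j * cmap.bin_size + half, cmap.length - 1)
        if pj - pi >= MIN_LOOP + 1:
            out.append(FoldConstraint(pi, pj, "forced", w))
    return out


def shuffle_constraints(
    constraints: Sequence[FoldConstraint],
    n_shuffles: int = 1000,
    subset_fraction: float = 0.5,
    seed: int = 0,
) -> list[list[FoldConstraint]]:
    """``n_shuffles`` independent weight-proportional subsets (without
    replacement) of ``round(subset_fraction * N)`` constraints each."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not constraints:
        return [[] for _ in range(n_shuffles)]
    rng = np.random.default_rng(seed)
    w = np.array([c.weight for c in constraints], dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    p = w / w.sum()
    m = int(round(subset_fraction * len(constraints)))
    m = max(min(m, len(constraints)), 0)
    out = []
    for _ in range(n_shuffles):
        idx = rng.choice(len(constraints), size=m, replace=False, p=p)
        out.append([constraints[i] for i in sorted(idx)])
    return out


# ---------------------------------------------------------------------------
# Nussinov-style constrained folding


@njit
def _nussinov_dp(weight: np.ndarray) -> np.ndarray:  # pragma: no cover - numba
    n = weight.shape[0]
    M = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            if weight[i, j] > 0.0:
                v = M[i + 1, j - 1] + weight[i, j]
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = M[i, k] + M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M


def _pair_weights(
    seq: str, constraints: Sequence[FoldConstraint]
) -> np.ndarray:
    n = len(seq)
    s = seq.upper().replace("T", "U")
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if (s[i], s[j]) in _CANONICAL:
                w[i, j] = 1.0
    forced_at: dict[int, FoldConstraint] = {}
    for c in constraints:
        if c.j >= n:
            raise ValueError(f"constraint {c} outside sequence of length {n}")
        if c.kind == "prohibited":
            w[c.i, c.j] = 0.0
        else:
            for pos in (c.i, c.j):
                other = forced_at.get(pos)
                if other is not None and other != c:
                    raise ValueError(
                        f"conflicting forced constraints at position {pos}: "
                        f"({other.i},{other.j}) and ({c.i},{c.j})"
                    )
                forced_at[pos] = c
    for c in constraints:
        if c.kind == "forced" and w[c.i, c.j] > 0:
            w[c.i, c.j] += FORCED_BONUS
    return w


def _traceback(M: np.ndarray, weight: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [(0, M.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 1 or M[i, j] == 0:
            continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
        elif M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
        elif weight[i, j] > 0 and M[i, j] == M[i + 1, j - 1] + weight[i, j]:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for k in range(i + 1, j):
                if M[i, j] == M[i, k] + M[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return sorted(pairs)


def fold_constrained(
    sequence: str,
    constraints: Sequence[FoldConstraint] = (),
    max_length: int = 2000,
) -> SecondaryStructure:
    """Maximum weighted nested pairing under forced/prohibited constraints.

    Every canonical pair scores 1; satisfiable forced pairs carry a large
    bonus so any structure containing them dominates; prohibited pairs
    are excluded. The reported score counts base pairs only (bonuses
    subtracted back out).
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    if n > max_length:
        raise ValueError(f"sequence of {n} nt exceeds the configured cap ({max_length})")
    weight = _pair_weights(sequence, constraints)
    if n < MIN_LOOP + 2:
        return SecondaryStructure("." * n, [], 0.0)
    M = _nussinov_dp(weight)
    pairs = _traceback(M, weight)
    score = float(sum(1.0 for _ in pairs))
    return SecondaryStructure(dotbracket_from_pairs(pairs, n), pairs, score)


def fold_ensemble(
    sequence: str,
    constraints: Sequence[FoldConstraint],
    n_shuffles: int = 1000,
    subset_fraction: float = 0.5,
    seed: int = 0,
    max_length: int = 2000,
) -> dict[tuple[int, int], float]:
    """Consensus pair frequencies over folds of shuffled constraint subsets."""
    subsets = shuffle_constraints(constraints, n_shuffles, subset_fraction, seed)
    freq: dict[tuple[int, int], int] = {}
    for subset in subsets:
        usable = resolve_conflicts(subset)
        s = fold_constrained(sequence, usable, max_length)
        for pair in s.pairs:
            freq[pair] = freq.get(pair, 0) + 1
    return {pair: k / n_shuffles for pair, k in sorted(freq.items())}


def resolve_conflicts(constraints: Sequence[FoldConstraint]) -> list[FoldConstraint]:
    """Greedy de-conflict: keep the heavier forced constraint per position
    (ties by coordinates); prohibitions always pass through."""
    taken: dict[int, FoldConstraint] = {}
    out: list[FoldConstraint] = []
    for c in sorted(constraints, key=lambda c: (-c.weight, c.i, c.j)):
        if c.kind == "prohibited":
            out.append(c)
            continue
        if c.i in taken or c.j in taken:
            continue
        taken[c.i] = taken[c.j] = c
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# per-pair chimera support


def basepair_support(
    structure: SecondaryStructure,
    chimeras: Iterable[ChimeraRecord],
    total_mapped: int,
) -> dict[tuple[int, int], float]:
    """log2 CPM of chimeras spanning each base pair of a structure.

    A chimera supports pair (i, j) when i falls inside arm1's interval
    and j inside arm2's (arms are canonically ordered). Pairs with zero
    support are absent from the result rather than reported as -inf.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    counts: dict[tuple[int, int], int] = {}
    records = list(chimeras)
    for i, j in structure.pairs:
        c = 0
        for rec in records:
            if rec.arm1[1] <= i < rec.arm1[2] and rec.arm2[1] <= j < rec.arm2[2]:
                c += 1
        if c > 0:
            counts[(i, j)] = c
    return {
        pair: float(np.log2(c * 1e6 / total_mapped)) for pair, c in counts.items()
    }


# ---------------------------------------------------------------------------
# decoy design


def design_decoy(
    sequence: str,
    sites: Sequence[tuple[int, int]],
    replacement_motif: str,
) -> str:
    """Replace each annotated site substring with a response-element motif.

    The design rule behind engineered decoy RNAs: keep the structural
    scaffold, swap the protein-binding sites for the desired element
    (e.g. PRE -> let-7 MRE ``CUACCUCA``). Sites must be non-overlapping
    and within the sequence.
    """
    if not replacement_motif:
        raise ValueError("replacement motif must be non-empty")
    ordered = sorted(sites)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping sites ({s1},{e1}) and ({s2},{e2})")
    if ordered and (ordered[0][0] < 0 or ordered[-1][1] > len(sequence)):
        raise ValueError("site outside sequence")
    out: list[str] = []
    pos = 0
    for s, e in ordered:
        out.append(sequence[pos:s])
        out.append(replacement_motif)
        pos = e
    out.append(sequence[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# structure interchange: dot-bracket, CT, pair lists


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def dotbracket_from_pairs(pairs: Sequence[tuple[int, int]], length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        if not 0 <= i < j < length:
            raise ValueError(f"pair ({i},{j}) outside structure of length {length}")
        if db[i] != "." or db[j] != ".":
            raise ValueError(f"position reused in pair ({i},{j})")
        db[i], db[j] = "(", ")"
    return "".join(db)


def write_ct(sequence: str, pairs: Sequence[tuple[int, int]], path: str | Path, title: str = "structure") -> None:
    """Connectivity-table (CT) output, 1-based as the format requires."""
    partner = {i: j for i, j in pairs}
    partner.update({j: i for i, j in pairs})
    n = len(sequence)
    with open(path, "w") as fh:
        fh.write(f"{n}\t{title}\n")
        for i in range(n):
            p = partner.get(i, -1) + 1
            fh.write(f"{i + 1}\t{sequence[i]}\t{i}\t{i + 2 if i + 1 < n else 0}\t{p}\t{i + 1}\n")


def read_ct(path: str | Path) -> tuple[str, list[tuple[int, int]]]:
    seq_chars: list[str] = []
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cols = line.split()
            if len(cols) < 6:
                continue
            idx = int(cols[0]) - 1
            seq_chars.append(cols[1])
            p = int(cols[4]) - 1
            if p > idx:
                pairs.append((idx, p))
    return "".join(seq_chars), sorted(pairs)


def write_constraints(constraints: Sequence[FoldConstraint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tkind\tweight\n")
        for c in constraints:
            fh.write(f"{c.i}\t{c.j}\t{c.kind}\t{c.weight:g}\n")
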
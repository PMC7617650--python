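"""Synthetic chimeric-read libraries from a parameterized structure model.

Proximity-ligation experiments (COMRADES and relatives) read out RNA
duplexes as chimeric reads: two ligated fragments ("arms") whose mapped
positions mark a base-paired or spatially proximal pair of regions. The
generator here emulates such libraries for an arbitrary transcript:

* chimeras are a mixture of *structure-driven* events, drawn from a set of
  stems (duplexes between two intervals of the transcript), and a
  *random-ligation background* of two independent uniform arms;
* a matched control library — in the wet protocol the crosslink is
  reversed before ligation — is the same process with the structure signal
  erased (pure background);
* condition-specific unfolding (e.g. stress treatment) is modelled by
  per-stem weight multipliers;
* a separate channel simulates DMS mutational-profiling pileups, where
  unpaired A/C bases mutate at a higher rate than paired ones.

All draws flow through one :class:`numpy.random.Generator` seeded from a
single integer; replicate r uses seed + r so replicates are independent
but individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChimeraRecord, RawRead

__all__ = [
    "Transcript",
    "StemSpec",
    "StructureModel",
    "DmsModel",
    "random_transcript",
    "simulate_chimeras",
    "simulate_replicates",
    "simulate_control",
    "simulate_dms",
    "chimeras_to_reads",
]

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class Transcript:
    """A reference transcript. T and U are equivalent throughout."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("transcript sequence must be non-empty")
        allowed = set("ACGTUN")
        bad = set(self.sequence.upper()) - allowed
        if bad:
            raise ValueError(f"invalid bases in transcript {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def rna(self) -> str:
        return self.sequence.upper().replace("T", "U")

    def dna(self) -> str:
        return self.sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class StemSpec:
    """A duplex between two intervals of the transcript.

    ``strand5`` and ``strand3`` are 0-based half-open intervals with
    ``strand3.start >= strand5.end``; ``weight`` is the stem's relative
    crosslink propensity.
    """

    strand5: tuple[int, int]
    strand3: tuple[int, int]
    weight: float = 1.0

    def __post_init__(self) -> None:
        for iv in (self.strand5, self.strand3):
            if iv[1] <= iv[0]:
                raise ValueError(f"empty stem strand {iv}")
        if self.strand3[0] < self.strand5[1]:
            raise ValueError("strand3 must start at or after strand5 ends")
        if self.weight < 0:
            raise ValueError("stem weight must be non-negative")


@dataclass
class StructureModel:
    """Generative model for a chimeric proximity-ligation library.

    ``background_rate`` is the fraction of chimeras arising from random
    ligation (two independent uniform arms); the remainder are allocated
    to stems proportionally to ``weight`` times the active condition's
    multiplier. ``condition_multipliers`` maps a condition name to one
    non-negative multiplier per stem (region-wise unfolding).
    """

    transcript: Transcript
    stems: list[StemSpec] = field(default_factory=list)
    background_rate: float = 0.2
    arm_length: float = 30.0
    arm_length_sd: float = 5.0
    arm_jitter: int = 10
    condition_multipliers: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        L = len(self.transcript)
        for stem in self.stems:
            if stem.strand3[1] > L:
                raise ValueError(f"stem {stem} extends past transcript end ({L} nt)")
        for name, mults in self.condition_multipliers.items():
            if len(mults) != len(self.stems):
                raise ValueError(
                    f"condition {name!r} has {len(mults)} multipliers for "
                    f"{len(self.stems)} stems"
                )
            if any(m < 0 for m in mults):
                raise ValueError(f"condition {name!r} has negative multipliers")

    def stem_weights(self, condition: str = "none") -> np.ndarray:
        w = np.array([s.weight for s in self.stems], dtype=float)
        if condition != "none":
            if condition not in self.condition_multipliers:
                raise ValueError(f"unknown condition {condition!r}")
            w = w * np.asarray(self.condition_multipliers[condition], dtype=float)
        return w

    def contact_indicator(self, bin_size: int) -> np.ndarray:
        """0/1 matrix marking bins reachable by each stem's arm midpoints.

        Used as the planted-truth map when checking that simulation
        followed by chimera calling and binning recovers the structure.
        """
        L = len(self.transcript)
        n_bins = -(-L // bin_size)
        ind = np.zeros((n_bins, n_bins))
        half = self.arm_jitter + 1  # midpoint drift bound around strand centre
        for stem in self.stems:
            for iv, jv in [(stem.strand5, stem.strand3)]:
                mi = (iv[0] + iv[1] - 1) / 2
                mj = (jv[0] + jv[1] - 1) / 2
                ilo = max(0, int((mi - half) // bin_size))
                ihi = min(n_bins - 1, int((mi + half) // bin_size))
                jlo = max(0, int((mj - half) // bin_size))
                jhi = min(n_bins - 1, int((mj + half) // bin_size))
                ind[ilo : ihi + 1, jlo : jhi + 1] = 1.0
                ind[jlo : jhi + 1, ilo : ihi + 1] = 1.0
        return ind


@dataclass
class DmsModel:
    """Generative model for DMS mutational profiling of one transcript.

    DMS methylates accessible (unpaired) adenines and cytosines; a
    processive RT converts the adducts into mutations. Paired A/C bases
    mutate at ``rate_paired``, unpaired A/C at ``rate_unpaired`` (>= the
    paired rate); G/U positions never mutate in this channel.
    """

    transcript: Transcript
    paired: frozenset[int] = frozenset()
    rate_paired: float = 0.005
    rate_unpaired: float = 0.05
    coverage: int = 5000
    log_rate_sd: float = 0.5
    profile_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rate_paired", "rate_unpaired"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.rate_unpaired < self.rate_paired:
            raise ValueError("rate_unpaired must be >= rate_paired")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        self.paired = frozenset(self.paired)
        L = len(self.transcript)
        if any(p < 0 or p >= L for p in self.paired):
            raise ValueError("paired positions outside transcript")

    def true_rates(self) -> np.ndarray:
        """The model's per-position mutation rates.

        Base rates (paired/unpaired at A/C, zero at G/U/N) are modulated
        by a mean-one lognormal per-position factor (sd ``log_rate_sd``
        in log space) drawn deterministically from ``profile_seed`` — the
        accessibility profile is a fixed property of the model, so
        independent sequencing replicates share it.
        """
        seq = self.transcript.rna()
        L = len(seq)
        ref = np.array(list(seq))
        rates = np.zeros(L)
        ac = np.isin(ref, ["A", "C"])
        paired_mask = np.zeros(L, dtype=bool)
        if self.paired:
            paired_mask[list(self.paired)] = True
        rates[ac & ~paired_mask] = self.rate_unpaired
        rates[ac & paired_mask] = self.rate_paired
        if self.log_rate_sd > 0:
            prof_rng = np.random.default_rng(self.profile_seed)
            jitter = prof_rng.lognormal(
                mean=-self.log_rate_sd**2 / 2, sigma=self.log_rate_sd, size=L
            )
            rates = np.clip(rates * jitter, 0.0, 1.0)
        return rates


# ---------------------------------------------------------------------------


def random_transcript(length: int, gc: float = 0.5, seed: int = 0, id: str = "synthetic") -> Transcript:
    """An i.i.d. random transcript with expected G+C fraction ``gc``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return Transcript(id=id, sequence=seq)


_UMI_BASES = np.array(list("ACGT"))


def _draw_umis(rng: np.random.Generator, n: int, k: int = 6) -> list[str]:
    if n == 0:
        return []
    mat = rng.integers(0, 4, size=(n, k))
    return ["".join(row) for row in _UMI_BASES[mat]]


def _arm_in_interval(
    rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray, lengths: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Place arms of given lengths uniformly inside [lo, hi) intervals.

    Intervals narrower than the arm are handled by clamping the length;
    everything is finally clipped to the transcript.
    """
    lo = np.clip(lo, 0, L)
    hi = np.clip(hi, 0, L)
    width = np.maximum(hi - lo, 1)
    lengths = np.minimum(lengths, width)
    slack = width - lengths
    starts = lo + np.floor(rng.random(len(lo)) * (slack + 1)).astype(int)
    ends = np.minimum(starts + lengths, L)
    starts = np.maximum(starts, 0)
    return starts, ends


def simulate_chimeras(
    model: StructureModel,
    n: int,
    condition: str = "none",
    seed: int = 0,
    read_prefix: str = "chim",
) -> list[ChimeraRecord]:
    """Draw ``n`` chimeric reads from the structure model.

    Each chimera is background (two independent uniform arms) with
    probability ``background_rate``; otherwise a stem is chosen with
    probability proportional to weight x condition multiplier and the two
    arms are placed inside the jitter-extended stem strands. Arm lengths
    are Normal(arm_length, arm_length_sd) clipped to [15, 60] nt.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    L = len(model.transcript)
    tid = model.transcript.id
    rng = np.random.default_rng(seed)
    w = model.stem_weights(condition)
    total_w = w.sum() if len(w) else 0.0
    if model.background_rate == 0.0 and total_w == 0.0:
        raise ValueError("no signal: background_rate is 0 and all stem weights are 0")
    if n == 0:
        return []

    is_bg = rng.random(n) < model.background_rate if total_w > 0 else np.ones(n, bool)
    lengths1 = np.clip(
        np.round(rng.normal(model.arm_length, model.arm_length_sd, n)), 15, 60
    ).astype(int)
    lengths2 = np.clip(
        np.round(rng.normal(model.arm_length, model.arm_length_sd, n)), 15, 60
    ).astype(int)

    lo1 = np.zeros(n, dtype=int)
    hi1 = np.full(n, L, dtype=int)
    lo2 = np.zeros(n, dtype=int)
    hi2 = np.full(n, L, dtype=int)

    n_stem = int((~is_bg).sum())
    if n_stem:
        probs = w / total_w
        stem_idx = rng.choice(len(model.stems), size=n_stem, p=probs)
        j = model.arm_jitter
        s5 = np.array([s.strand5 for s in model.stems], dtype=int)
        s3 = np.array([s.strand3 for s in model.stems], dtype=int)
        lo1[~is_bg] = s5[stem_idx, 0] - j
        hi1[~is_bg] = s5[stem_idx, 1] + j
        lo2[~is_bg] = s3[stem_idx, 0] - j
        hi2[~is_bg] = s3[stem_idx, 1] + j

    st1, en1 = _arm_in_interval(rng, lo1, hi1, lengths1, L)
    st2, en2 = _arm_in_interval(rng, lo2, hi2, lengths2, L)
    umis = _draw_umis(rng, n)

    return [
        ChimeraRecord(
            read_id=f"{read_prefix}{i}",
            arm1=(tid, int(st1[i]), int(en1[i])),
            arm2=(tid, int(st2[i]), int(en2[i])),
            umi=umis[i],
        )
        for i in range(n)
    ]


def simulate_replicates(
    model: StructureModel,
    n: int,
    n_replicates: int,
    condition: str = "none",
    seed: int = 0,
) -> list[list[ChimeraRecord]]:
    """Independent replicate libraries; replicate r uses stream seed + r."""
    return [
        simulate_chimeras(model, n, condition=condition, seed=seed + r, read_prefix=f"rep{r}_")
        for r in range(n_replicates)
    ]


def simulate_control(model: StructureModel, n: int, seed: int = 0) -> list[ChimeraRecord]:
    """The reverse-crosslinked control: the same library with the structure
    signal erased, i.e. pure random-ligation background."""
    ctrl = StructureModel(
        transcript=model.transcript,
        stems=model.stems,
        background_rate=1.0,
        arm_length=model.arm_length,
        arm_length_sd=model.arm_length_sd,
        arm_jitter=model.arm_jitter,
        condition_multipliers=model.condition_multipliers,
    )
    return simulate_chimeras(ctrl, n, seed=seed, read_prefix="ctrl")


def simulate_dms(dms: DmsModel, seed: int = 0) -> pd.DataFrame:
    """Simulate a DMS-MaP pileup: per-position coverage and mutation counts.

    Mutation counts are Binomial(coverage, rate), where the rate is
    ``rate_unpaired`` at unpaired A/C positions, ``rate_paired`` at paired
    A/C positions, and 0 at G/U/N positions.
    """
    rng = np.random.default_rng(seed)
    seq = dms.transcript.rna()
    L = len(seq)
    ref = np.array(list(seq))
    rates = dms.true_rates()
    coverage = np.full(L, dms.coverage)
    mutations = rng.binomial(coverage, rates)
    return pd.DataFrame(
        {"pos": np.arange(L), "ref": ref, "coverage": coverage, "mutations": mutations}
    )


def block_structure_model(
    transcript: Transcript,
    block_edges: list[int],
    background_rate: float = 0.2,
    segment: int = 50,
    arm_jitter: int = 5,
) -> StructureModel:
    """A planted-domain model: contacts uniform within each block.

    ``block_edges`` are interior boundaries (nt); each block is tiled
    into ``segment``-nt pieces and every piece pair becomes an
    equal-weight stem, so structure-driven chimeras fill the block's
    contact square while the background fills the whole map. Useful for
    validating domain-boundary recovery.
    """
    L = len(transcript)
    edges = [0] + sorted(block_edges) + [L]
    stems: list[StemSpec] = []
    for s, e in zip(edges[:-1], edges[1:]):
        starts = list(range(s, e - segment + 1, segment))
        for a in starts:
            for b in starts:
                if b >= a + segment:
                    stems.append(StemSpec((a, a + segment), (b, b + segment), 1.0))
    return StructureModel(
        transcript=transcript,
        stems=stems,
        background_rate=background_rate,
        arm_jitter=arm_jitter,
    )


# ---------------------------------------------------------------------------
# read emission: chimera records -> sequencing reads


def chimeras_to_reads(
    records: list[ChimeraRecord],
    transcript: Transcript,
    seed: int = 0,
    shuffle_arms: bool = True,
    append_umi: bool = False,
    adapter: str = "",
) -> list[RawRead]:
    """Render chimera records as reads: arm1 + arm2 sequence, optionally in
    random ligation order (proximity ligation is orientation-agnostic),
    optionally with the UMI and a fixed adapter appended."""
    rng = np.random.default_rng(seed)
    seq = transcript.dna()
    out = []
    flip = rng.random(len(records)) < 0.5 if shuffle_arms else np.zeros(len(records), bool)
    for i, rec in enumerate(records):
        a1 = seq[rec.arm1[1] : rec.arm1[2]]
        a2 = seq[rec.arm2[1] : rec.arm2[2]]
        body = a2 + a1 if flip[i] else a1 + a2
        if append_umi:
            body += rec.umi
        if adapter:
            body += adapter
        out.append(RawRead(rec.read_id, body))
    return out
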
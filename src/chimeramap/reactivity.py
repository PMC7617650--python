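"""DMS mutational-profiling (DMS-MaP) reactivity analysis.

DMS methylates accessible adenines and cytosines; a processive reverse
transcriptase converts the adducts into mutations, so the per-position
mutation rate of an amplicon reports base accessibility. This module
turns pileup counts into reactivity profiles (A/C positions with
sufficient coverage), tests paired-vs-unpaired rate separation against a
secondary-structure model, and correlates profiles between samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReactivityProfile",
    "mutation_rates",
    "paired_unpaired_test",
    "profile_correlation",
    "combine_pileups",
    "PairedUnpairedResult",
]

DEFAULT_MIN_COV = 1000


@dataclass
class ReactivityProfile:
    """Per-position reactivity: rate = mutations / coverage.

    The analysis mask keeps positions with an A or C reference base and
    coverage >= ``min_cov``; masked-out positions carry no rate.
    """

    table: pd.DataFrame  # pos, ref, coverage, mutations, rate, masked
    min_cov: int

    @property
    def mask(self) -> np.ndarray:
        return self.table["masked"].to_numpy()

    def rates(self) -> pd.Series:
        """Rates at masked-in positions, indexed by position."""
        t = self.table[self.table["masked"]]
        return pd.Series(t["rate"].to_numpy(), index=t["pos"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mutation_rates(
    pileup: pd.DataFrame,
    min_cov: int = DEFAULT_MIN_COV,
) -> ReactivityProfile:
    """Build a reactivity profile from a (pos, ref, coverage, mutations)
    pileup table.

    Any position where mutations exceed coverage is rejected as a
    malformed pileup. The mask admits A/C reference positions (T/U
    treated as U) with coverage at or above ``min_cov``.
    """
    required = {"pos", "ref", "coverage", "mutations"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup table lacks columns: {sorted(missing)}")
    t = pileup.copy()
    t["ref"] = t["ref"].str.upper().str.replace("T", "U")
    if (t["mutations"] > t["coverage"]).any():
        bad = t.loc[t["mutations"] > t["coverage"], "pos"].tolist()
        raise ValueError(f"mutations exceed coverage at positions {bad[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(t["coverage"] > 0, t["mutations"] / t["coverage"], np.nan)
    t["rate"] = rate
    t["masked"] = t["ref"].isin(["A", "C"]) & (t["coverage"] >= min_cov)
    t.loc[~t["masked"], "rate"] = np.nan
    return ReactivityProfile(table=t.reset_index(drop=True), min_cov=min_cov)


@dataclass
class PairedUnpairedResult:
    """Rank-sum comparison of mutation rates at paired vs unpaired A/C."""

    p_two_sided: float
    p_one_sided: float  # unpaired > paired
    median_paired: float
    median_unpaired: float
    n_paired: int
    n_unpaired: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_two_sided)


def paired_unpaired_test(
    profile: ReactivityProfile,
    paired_positions: Iterable[int],
    min_group: int = 3,
) -> PairedUnpairedResult:
    """Wilcoxon rank-sum test of reactivity at paired vs unpaired bases.

    ``paired_positions`` usually comes from
    :meth:`chimeramap.structure.SecondaryStructure.paired_positions`.
    Groups smaller than ``min_group`` masked positions make the test
    undefined (NaN p-values, with a warning).
    """
    paired_set = set(paired_positions)
    rates = profile.rates()
    grp_paired = rates[rates.index.isin(paired_set)]
    grp_unpaired = rates[~rates.index.isin(paired_set)]
    if len(grp_paired) < min_group or len(grp_unpaired) < min_group:
        warnings.warn(
            "fewer than %d masked positions in a group: test undefined" % min_group,
            stacklevel=2,
        )
        return PairedUnpairedResult(
            float("nan"), float("nan"),
            float(grp_paired.median()) if len(grp_paired) else float("nan"),
            float(grp_unpaired.median()) if len(grp_unpaired) else float("nan"),
            len(grp_paired), len(grp_unpaired),
        )
    _, p_two = stats.ranksums(grp_unpaired, grp_paired)
    _, p_one = stats.ranksums(grp_unpaired, grp_paired, alternative="greater")
    return PairedUnpairedResult(
        p_two_sided=float(p_two),
        p_one_sided=float(p_one),
        median_paired=float(grp_paired.median()),
        median_unpaired=float(grp_unpaired.median()),
        n_paired=len(grp_paired),
        n_unpaired=len(grp_unpaired),
    )


def profile_correlation(
    profile_a: ReactivityProfile,
    profile_b: ReactivityProfile,
    min_shared: int = 3,
) -> tuple[float, int]:
    """Spearman rho between two profiles over their shared masked
    positions; returns (rho, n_shared). Undefined (NaN) below
    ``min_shared`` shared positions."""
    ra, rb = profile_a.rates(), profile_b.rates()
    shared = ra.index.intersection(rb.index)
    n = len(shared)
    if n < min_shared:
        warnings.warn("fewer than %d shared masked positions" % min_shared, stacklevel=2)
        return float("nan"), n
    rho = stats.spearmanr(ra.loc[shared], rb.loc[shared]).statistic
    return float(rho), n


def combine_pileups(pileups: list[pd.DataFrame]) -> pd.DataFrame:
    """Coverage-weighted combination of overlapping amplicon pileups.

    Coverages and mutation counts are summed per position, which weights
    each amplicon's rate by its coverage in the overlap.
    """
    merged = pd.concat(pileups, ignore_index=True)
    out = (
        merged.groupby(["pos", "ref"], as_index=False)[["coverage", "mutations"]]
        .sum()
        .sort_values("pos")
        .reset_index(drop=True)
    )
    return out
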
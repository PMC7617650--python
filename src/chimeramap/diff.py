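"""Windowed differential-contact testing and per-gene chimera enrichment.

A self-contained negative-binomial framework in the DESeq2 mould:
median-of-ratios size factors, per-row method-of-moments dispersions
shrunk toward a fitted mean-dispersion trend, and a Wald test on the
log2 fold change with Benjamini-Hochberg adjustment. Counting units are
``bin_size x bin_size`` windows of the contact map (default 10 nt) or
genes (for intermolecular enrichment against reverse-crosslinked
controls, flagged at fold > 1.25 and p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ChimeraRecord
from .synth import Transcript

__all__ = [
    "window_counts",
    "size_factors",
    "nb_test",
    "gene_enrichment",
    "DISPLAY_CAP",
]

DISPLAY_CAP = 2.0  # -log10 padj display scores are clamped to [-2, 2]
ENRICHMENT_FOLD = 1.25
ENRICHMENT_P = 0.05


def window_counts(
    chimeras_per_sample: Mapping[str, Sequence[ChimeraRecord]],
    transcript: Transcript | tuple[str, int],
    bin_size: int = 10,
) -> pd.DataFrame:
    """Per-sample chimera counts in (i <= j) bin-pair windows.

    Rows are indexed by (window_i, window_j); windows with zero counts in
    every sample are dropped. Column order follows the mapping order.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if isinstance(transcript, Transcript):
        tid, L = transcript.id, len(transcript)
    else:
        tid, L = transcript
    n_bins = -(-L // bin_size)
    samples = list(chimeras_per_sample)
    tallies: dict[tuple[int, int], np.ndarray] = {}
    for s_idx, name in enumerate(samples):
        for rec in chimeras_per_sample[name]:
            if rec.arm1[0] != tid or rec.arm2[0] != tid:
                raise ValueError(f"chimera {rec.read_id!r} not on transcript {tid!r}")
            m1, m2 = rec.midpoints()
            i, j = sorted((int(m1 // bin_size), int(m2 // bin_size)))
            if j >= n_bins:
                raise ValueError(f"arm midpoint outside transcript for {rec.read_id!r}")
            row = tallies.setdefault((i, j), np.zeros(len(samples)))
            row[s_idx] += 1
    if not tallies:
        return pd.DataFrame(
            columns=samples,
            index=pd.MultiIndex.from_arrays([[], []], names=["window_i", "window_j"]),
            dtype=float,
        )
    keys = sorted(tallies)
    data = np.vstack([tallies[k] for k in keys])
    idx = pd.MultiIndex.from_tuples(keys, names=["window_i", "window_j"])
    return pd.DataFrame(data, index=idx, columns=samples)


def size_factors(table: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    factor_s = median over all-positive rows of count_{r,s} / geomean_r.
    If no row is positive in every sample the ratio-of-totals fallback is
    used (geometric mean scaled to 1) with a warning.
    """
    counts = table.to_numpy(dtype=float)
    pos = (counts > 0).all(axis=1)
    if pos.any():
        logs = np.log(counts[pos])
        loggeo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - loggeo, axis=0))
    else:
        warnings.warn(
            "no window with positive counts in all samples; "
            "falling back to ratio-of-totals size factors",
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: a sample has zero total")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=table.columns, name="size_factor")


def _fit_dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Parametric mean-dispersion trend alpha(mu) = a0 + a1/mu.

    Fit as a gamma-family GLM (identity link) on rows with a positive
    raw dispersion estimate and non-trivial mean, with one outlier-
    trimming pass — moment estimates at very low means are essentially
    noise and would otherwise dominate a least-squares fit.
    """
    import statsmodels.api as sm

    use = (disp > 0) & (base_mean >= 1.0)
    if use.sum() < 10:
        use = (disp > 0) & (base_mean > 0)
    if use.sum() < 3:
        med = float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01
        return np.full_like(base_mean, max(med, 1e-8))

    def _glm_fit(mask: np.ndarray) -> tuple[float, float] | None:
        X = np.column_stack([np.ones(mask.sum()), 1.0 / base_mean[mask]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(
                    disp[mask], X, family=sm.families.Gamma(sm.families.links.Identity())
                ).fit()
            a0, a1 = fit.params
        except Exception:
            coef, *_ = np.linalg.lstsq(X, disp[mask], rcond=None)
            a0, a1 = coef
        return max(float(a0), 1e-8), max(float(a1), 0.0)

    a0, a1 = _glm_fit(use)
    pred = a0 + a1 / np.maximum(base_mean, 1e-8)
    ratio = disp / np.maximum(pred, 1e-12)
    trimmed = use & (ratio > 1e-4) & (ratio < 15)
    if 3 <= trimmed.sum() < use.sum():
        a0, a1 = _glm_fit(trimmed)
    return a0 + a1 / np.maximum(base_mean, 1e-8)


def nb_test(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    shrink_weight: float = 0.9,
    min_base_mean: float = 0.0,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test per row.

    Counts are modelled as NB with size-factor offsets (median-of-ratios
    by default, or externally supplied ``sf``); group means are estimated
    as normalized-count averages, per-row dispersions by the method of
    moments and shrunk toward the fitted mean-dispersion trend (arithmetic
    interpolation with weight ``shrink_weight`` on the trend — heavy
    shrinkage by default because row-wise moment estimates from a few
    replicates are very noisy). The Wald statistic tests log2FC (group2
    vs group1, groups in sorted label order) against zero; BH adjustment
    runs across retained rows.

    Returns a DataFrame with baseMean, log2FC, foldEnrichment, p, padj
    and the signed display score sign(log2FC) * min(-log10 padj, 2).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = [s for s in table.columns if groups[s] == labels[0]]
    g2 = [s for s in table.columns if groups[s] == labels[1]]
    if not g1 or not g2:
        raise ValueError("each group needs at least one sample")
    if min(len(g1), len(g2)) < 2:
        warnings.warn("a group has a single sample; dispersion is pooled", stacklevel=2)

    table = table.loc[(table.sum(axis=1) > 0)]
    if sf is None:
        sf = size_factors(table)
    else:
        sf = sf.reindex(table.columns)
        if sf.isna().any() or (sf <= 0).any():
            raise ValueError("supplied size factors must be positive for every sample")
    counts = table.to_numpy(dtype=float)
    norm = counts / sf.to_numpy()
    base_mean = norm.mean(axis=1)

    i1 = [table.columns.get_loc(s) for s in g1]
    i2 = [table.columns.get_loc(s) for s in g2]

    # method-of-moments dispersion from within-group variability
    disp_raw = np.zeros(len(table))
    for idx in (i1, i2):
        if len(idx) >= 2:
            m = norm[:, idx].mean(axis=1)
            v = norm[:, idx].var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (v - m) / m**2
            disp_raw += np.where(np.isfinite(a), np.maximum(a, 0.0), 0.0)
    n_grp = sum(1 for idx in (i1, i2) if len(idx) >= 2)
    disp_raw = disp_raw / max(n_grp, 1)
    trend = _fit_dispersion_trend(base_mean, disp_raw)
    disp = (1 - shrink_weight) * disp_raw + shrink_weight * trend

    # group means with offsets: mu_g = sum(counts) / sum(sf), moderated
    # by half a count to keep the log fold change finite
    sf1, sf2 = sf.iloc[i1].sum(), sf.iloc[i2].sum()
    t1 = counts[:, i1].sum(axis=1)
    t2 = counts[:, i2].sum(axis=1)
    mu1 = (t1 + 0.5) / sf1
    mu2 = (t2 + 0.5) / sf2
    log2fc = np.log2(mu2 / mu1)

    # Var(log mu_g) by the delta method on the NB group total
    def _var_log(total: np.ndarray, mu: np.ndarray, idx: list[int]) -> np.ndarray:
        s = sf.to_numpy()[idx]
        var_tot = np.zeros_like(mu)
        for sj in s:
            var_tot += sj * mu * (1 + disp * sj * mu)
        return var_tot / np.maximum((mu * s.sum()) ** 2, 1e-12)

    var = _var_log(t1, mu1, i1) + _var_log(t2, mu2, i2)
    z = np.log(mu2 / mu1) / np.sqrt(np.maximum(var, 1e-12))
    p = 2 * stats.norm.sf(np.abs(z))

    keep = base_mean > min_base_mean
    padj = np.full(len(table), np.nan)
    if keep.any():
        padj[keep] = multipletests(p[keep], method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        score = np.sign(log2fc) * np.minimum(-np.log10(np.maximum(padj, 1e-300)), DISPLAY_CAP)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "foldEnrichment": 2.0**log2fc,
            "p": p,
            "padj": padj,
            "display_score": score,
        },
        index=table.index,
    )


def gene_enrichment(
    crosslinked: pd.DataFrame,
    control: pd.DataFrame,
    fold_threshold: float = ENRICHMENT_FOLD,
    p_threshold: float = ENRICHMENT_P,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene chimera enrichment of crosslinked libraries over
    reverse-crosslinked controls.

    Inputs are gene x sample count tables (shared gene index). A gene is
    flagged ``enriched`` when fold-enrichment (crosslinked / control)
    exceeds ``fold_threshold`` and the NB Wald p is below ``p_threshold``.
    """
    genes = crosslinked.index.union(control.index)
    xl = crosslinked.reindex(genes, fill_value=0).add_prefix("xl_")
    ct = control.reindex(genes, fill_value=0).add_prefix("ctrl_")
    table = pd.concat([ct, xl], axis=1)
    groups = {c: ("a_control" if c.startswith("ctrl_") else "b_crosslinked") for c in table.columns}
    if sf is not None and not all(c in sf.index for c in table.columns):
        sf = pd.Series(
            {**{f"ctrl_{c}": sf[c] for c in control.columns if c in sf},
             **{f"xl_{c}": sf[c] for c in crosslinked.columns if c in sf}}
        )
    res = nb_test(table, groups, sf=sf)
    res["enriched"] = (res["foldEnrichment"] > fold_threshold) & (res["p"] < p_threshold)
    return res
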
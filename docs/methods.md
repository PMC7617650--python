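# Methods

This note documents the models, statistics and numerical choices behind
`chimeramap`, and what the synthetic-data results do and do not show
about real libraries.

## The measurement being modelled

A chimeric proximity-ligation experiment crosslinks base-paired RNA in
cells, fragments it, enriches crosslinked duplexes, and ligates the two
strands of each duplex into one molecule. Sequencing yields chimeric
reads whose two arms map to the interacting regions; a control library
reverses the crosslink before ligation, so its chimeras reflect random
ligation only. The analysis treats one transcript (or a small
transcript set) mapped at high depth; all coordinates are 0-based
half-open internally, converted only at format boundaries (hyb tables
are 1-based inclusive, CT files 1-based).

## Synthetic-library generator

`StructureModel` draws each chimera from a two-component mixture:

- with probability `background_rate`, two independent, uniformly placed
  arms (random ligation);
- otherwise a stem chosen with probability proportional to
  weight × condition multiplier; each arm is placed uniformly so that
  it lies fully inside the stem strand extended by ±`arm_jitter`
  (default 10 nt). This keeps arm midpoints within a bounded band
  around the strand, which is what downstream window statistics see.

Arm lengths are Normal(30, 5) clipped to [15, 60] nt, a stand-in for
RNase III fragmentation producing mappable 20–40-nt arms; the protocol
papers do not report fragmentation statistics, so these are design
choices, not calibrated values. UMIs are uniform random 6-mers. Read
emission concatenates the two arm sequences in random order (proximity
ligation is orientation-agnostic) with optional UMI and adapter
suffixes. One integer seeds everything; replicate r uses seed + r, so
replicates are independent but individually reproducible. The true
crosslinking efficiency of the assay is unknown; `background_rate` and
stem weights are therefore free parameters, and analyses that need a
defined enrichment (e.g. a 10× site pair) construct it arithmetically
from the background expectation.

The control generator is the same model with `background_rate` forced
to 1 — the definition of a reverse-crosslinked library.

`DmsModel` simulates mutational profiling: mutation counts are
Binomial(coverage, rate) with rate `rate_unpaired` at unpaired A/C,
`rate_paired` at paired A/C (defaults 0.05 and 0.005) and 0 at G/U, the
chemistry of DMS as read out by a processive RT. On top of the two base
rates, each position carries a mean-one lognormal factor
(`log_rate_sd` = 0.5) drawn deterministically from `profile_seed`:
real reactivity profiles vary continuously from base to base, and
without this fixed per-position heterogeneity two sequencing replicates
of the same model would have nothing to rank-correlate within a group.

What the generator does not emulate: sequencing errors outside the DMS
channel, PCR amplification bias beyond duplicate counts, intermolecular
chimeras with a full transcriptome, mappability structure, or the
1–2 kb-scale coverage unevenness of real libraries. Tests passing on
synthetic data therefore demonstrate the correctness and calibration of
the algorithms under their stated model, not robustness to every
artefact of real data.

## Chimera calling

Reads are decomposed by exact k-mer seeding (k = 12) into per-diagonal
ungapped extensions that tolerate mismatches while the running mismatch
fraction stays within 10%, trimmed to end on matches. The best pair of
hits on the read is selected by total score with deterministic
tie-breaks (score, then leftmost reference start, then transcript id).
Hits that overlap on the read are split at the junction maximizing
total per-base matches: greedy extension can overreach a ligation
junction through chance matches, and the optimal split restores exact
arm boundaries whenever the junction is sequence-unambiguous. When the
base following arm 1 in the reference happens to equal the first base
of arm 2 (probability ≈ 1/4 per side on random sequence), the junction
is genuinely ambiguous for any aligner; the leftmost optimal split is
chosen, which can shift both arm ends jointly by a few nucleotides.
Midpoint-based statistics are insensitive to this. Reads fully covered
by a single hit are non-chimeric; reads shorter than 2 × `min_arm`
cannot produce a call. Reverse-strand mapping is off by default (sense
transcriptome mapping).

## Contact maps and domains

Each chimera adds one unit at the bin pair of its two arm midpoints
(mirror cell symmetric, diagonal counted once), so the upper-triangle
sum equals the number of contributing chimeras. Midpoint assignment was
chosen over spreading the unit across the arm spans because it
preserves count conservation exactly; a `spread=True` mode exists for
sensitivity analysis. The last partial bin is kept (ceiling division).
Weights: per read, per duplicate count, or per distinct (arms, UMI)
key. CPM normalization multiplies by 10⁶ / `total_mapped`. No
Hi-C-style matrix balancing is applied — the assay is analysed on raw
or CPM counts.

Domain calling follows the three TopDom stages. binSignal at bin i is
the mean of counts[u, d] for u ∈ (i−w, i], d ∈ (i, i+w], truncated at
matrix edges (no padding, to avoid fabricating contacts beyond the
transcript; the last bin is NaN). Candidate boundaries are local minima
of the signal within a ±w window that rise on both sides, leftmost bin
on plateaus. Each candidate is kept only if the cross-boundary diamond
is depleted relative to the flanking within-domain triangles by a
one-sided Mann–Whitney test at p < 0.05. Minimum domain size is 2 bins
(the weaker of two too-close boundaries is dropped). Segments whose
mean signal falls below the 5th percentile of nonzero signals are
tagged `gap`. Every step is rank- or order-based, so the output is
invariant to rescaling the matrix. At the standard settings — 10-nt
bins, w = 30 — the effective window is 300 nt.

## Differential contacts and gene enrichment

Counting units are (i ≤ j) bin-pair windows (default 10 nt) or genes;
all-zero rows are dropped. Size factors are DESeq-style
median-of-ratios over rows positive in every sample, with a flagged
ratio-of-totals fallback. Caveat: when a large fraction of windows
genuinely changes (as in a deliberate unfolding simulation), the
all-positive rows over-represent the changed windows and
median-of-ratios absorbs part of the effect; for equal-depth libraries
pass explicit size factors (`sf=`), the normalization the CPM
convention implies.

The test is a per-row NB Wald test. Group means are moderated ratio
estimates (total + 0.5) / Σ size factors. Per-row dispersions come from
the method of moments within each group (average over groups with ≥ 2
replicates), then are shrunk toward a parametric trend
α(μ) = a₀ + a₁/μ fitted as a gamma-family GLM (identity link) on rows
with positive raw dispersion and mean ≥ 1, with one outlier-trimming
pass — moment estimates at near-zero means are noise and would dominate
a plain least-squares fit. Shrinkage is arithmetic with weight 0.9 on
the trend: with 3–4 replicates the row-wise estimates are so noisy that
heavy shrinkage is needed for calibration, which is verified by
simulation (null fraction of p < 0.05 ≈ 0.05 at mean 100, dispersion
0.1, 4+4 samples; ≥ 90% power on 4-fold windows). The Wald statistic
uses a delta-method variance of log(μ₂/μ₁) against a normal reference;
BH adjustment runs across retained rows. There is no Cook's-distance
filtering or independent filtering; the contract is a calibrated NB
windowed test, not a bit-for-bit reimplementation of any particular
tool. Display scores are sign(log2FC) × min(−log₁₀ padj, 2).

Gene-level enrichment runs the same test on crosslinked-versus-control
gene counts and flags genes with fold-enrichment > 1.25 and p < 0.05.

## Site-pair circular permutation test

For a pair of annotated sites (±50-nt windows by default), the observed
statistic is the number of chimeras with one arm midpoint in each
window, per replicate. The null shifts both windows jointly by k × step
(step 50 nt, k = 1 … ⌊L/step⌋ − 1) with wrap-around at the transcript
ends, preserving the pair's separation exactly — shift 0 reproduces the
observed counts and is excluded from the null. The test is a one-sided
Welch t-test of the observed replicate counts against the permuted
counts pooled over shifts and replicates (a per-replicate-mean pooling
and a pooled-variance t are available as flags; the paper-style
"independent t-tests" leave both unspecified, so the defaults are
documented rather than inferred). Bonferroni multiplicity is the number
of pairs actually tested. Calibration was checked by simulation: under
a uniform background with 3 replicates of 10,000–20,000 chimeras the
raw one-sided test rejects at ≈ 5% (the in-window null mean is ≥ 8
counts there; at much shallower depth the counts become too discrete
for a t-test and the test should not be trusted).

Per-site interaction totals are CPM-normalized counts of chimeras
touching the site window, compared against the mean over 116 random
110-nt fragments placed outside all site windows.

## Constraint folding

The strongest `top_fraction` of nonzero contact cells become candidate
forced pairs between the bin midpoints (deterministic weight-then-
coordinate ordering; pairs violating the 3-nt minimum loop are
skipped). `shuffle_constraints` draws 1,000 weight-proportional subsets
(without replacement) of half the constraints by default; the
subsetting fraction is a free parameter of this pipeline, not a
published value. Each subset is folded and pair frequencies across the
ensemble form the consensus.

The folding engine is a weighted Nussinov dynamic program: maximum
nested pairing over {AU, GC, GU}, minimum hairpin loop 3, prohibited
pairs excluded, satisfiable forced pairs carrying a large bonus so any
structure containing them dominates; the reported score counts base
pairs only. This is a deliberate design choice over thermodynamic
nearest-neighbour folding: the objective is exactly testable against
brute-force enumeration, and the pipeline's shape (constraints →
shuffled ensemble → consensus) is preserved; CT and constraint exports
let users run an external energy-based engine instead. Conflicting
forced constraints (one position in two pairs) are an error in
`fold_constrained`; `resolve_conflicts` applies the greedy
heavier-weight-wins rule that `fold_ensemble` uses internally. The
default length cap is 2,000 nt (the DP is cubic; ~1-s scale at a few
hundred nt, minutes near the cap).

Per-pair support is log₂(CPM) of chimeras whose arm 1 contains i and
arm 2 contains j (canonical arm order); zero-support pairs are omitted
rather than reported as −∞.

Decoy design replaces each annotated site substring with a replacement
element (e.g. `CUACCUCA`), validating that sites are disjoint and in
range — the sequence rule used to convert a Pumilio decoy into a let-7
sponge.

## DMS reactivity

Rates are mismatches/coverage per position; indels are ignored
(amplicon context). "Sufficient coverage" is not a published number, so
the mask defaults to coverage ≥ 1,000 at A/C positions and is recorded
in the output. Paired-versus-unpaired comparisons use the Wilcoxon
rank-sum test (two-sided reported alongside the one-sided
unpaired > paired). Profile comparisons use Spearman correlation on the
intersection of masks, with the shared-position count reported;
fewer than 3 shared positions is undefined, not zero. Overlapping
amplicons are combined by summing coverages and mutation counts, i.e. a
coverage-weighted average rate in the overlap.

## Problem sizes used in the checks

The packaged checks run at desk scale, chosen to make the statistical
assertions sharp while keeping the whole suite in a few minutes:
10,000–50,000 chimeras per library, 2–3 replicates, 1–5-kb transcripts,
1,000 windows per NB calibration table, 1,000 permutation-test trials
for type-I calibration, 200 brute-force folding comparisons at ≤ 12 nt.

## Known limitations

- The NB test's heavy dispersion shrinkage assumes most windows share
  the mean-dispersion trend; strongly row-specific overdispersion will
  be over-shrunk.
- Junction-ambiguous chimeras carry a few-nt coordinate uncertainty
  that no aligner can resolve; arm-end-sensitive analyses should use
  midpoints.
- The t-based permutation test needs non-trivial in-window null counts
  (roughly ≥ 5 per replicate) to be calibrated.
- The Nussinov objective ignores stacking energies; its structures are
  evidence-maximizing, not minimum-free-energy, and should be read as a
  scaffold for the chimera-derived constraints.
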
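# Methods

## Model and assumptions

The package treats a proteome as a point cloud in LD space: one point
(ln *L*, ID) per primary protein. The underlying assumptions are:

1. one protein represents each gene locus (the longest isoform); isoform
   choice has little effect on the density grid because alternative
   isoforms mostly land in the same or adjacent blocks;
2. ln(*L*) and ID are treated as independent axes — their empirical
   correlation in real proteomes is weak (|CC| ≈ 0.1), and the package
   reports Pearson and Spearman coefficients per proteome so users can
   check this on their own data;
3. the block densities, not the raw points, carry the comparative signal.
   Normalization (Σ *X*<sub>ij</sub> = 1) makes proteomes of very
   different sizes directly comparable and bounds all pairwise distances
   by √2.

## Disorder quantities

A residue is disordered when its predictor score is **≥ 0.5** (inclusive;
scores of exactly 0.5 count as disordered). `id_pep` is the per-protein
fraction of disordered residues and drives the ID axis, the %IDP summary
column and the IDP classification (id_pep ≥ 0.5). `id_res` is the
unthresholded mean of raw residue scores over a proteome. For the census
of short/long disordered proteins, a *strict* threshold variant
(ID > 0.5) is also exposed; pipelines record which convention is active
(`id_threshold_convention` in the run config and run log), because both
conventions are in use in the literature and they differ exactly for
proteins whose id_pep is 0.5.

## Partition

The default 10 × 10 partition has ln(*L*) edges 0, 4.6, 4.9, …, 7.0, ∞
(interior step 0.3) and ID edges 0, 0.1, …, 1.0. Bins are half-open
[lo, hi) with the last bin of each axis closed above, so id_pep = 1.0 maps
to bin *N* and every valid protein maps to exactly one block. The
corresponding integer length boundaries follow from the
smallest-integer-≥-e^b mapping: the short-protein cut at ln(*L*) < 4.6 is
*L* < 100, block edges at 4.9 and 7.0 are 135 and 1097, and the display
clamps at 4.3 and 7.3 correspond to *L* < 74 and *L* > 1480. For other
(*M*, *N*) the interior ln edges are equally spaced on [4.6, 7.0] — the
natural generalization of the uniform 0.3 spacing — with open-ended
first/last bins, and ID bins are equal-width on [0, 1]. Coarser nested
grids (e.g. merging adjacent 10 × 10 blocks into 5 × 5) are supported by
constructing an explicit `LDPartition` from merged edges.

Clamping of extreme ln(*L*) values (to 4.3 and 7.3) is a **rendering**
device only, applied when drawing contour maps; binning always uses the
open-ended first and last bins.

## Neighbor joining

Classical Saitou–Nei NJ on the fingerprint distance matrix. Determinism is
fully specified: exact ties in the Q-criterion are broken by the
lexicographically smallest (sorted) label pair, where an internal node is
labelled by the smallest leaf name in its clade; negative branch-length
estimates are clamped to 0 with the deficit moved to the sister branch
(their sum is preserved). The output is an unrooted tree with a
trifurcating root node, serialized as Newick; any rooted rendering is a
display choice. On additive matrices NJ provably recovers the generating
topology, which the tests exercise; on fingerprint-derived matrices the
topology is cross-checked against scikit-bio's independent NJ
implementation.

## Proxy scorer

The built-in scorer maps each residue to a frozen TOP-IDP-style disorder
propensity (shipped as a versioned JSON data file), min-max rescales the
scale to [0, 1] (min = W at −0.884, max = P at 0.987) and smooths with a
centred sliding window (default 21 residues, truncated at the termini;
windows longer than the sequence are clamped to its length). It is
deterministic and self-contained but is **not** an emulation of any
trained predictor — it captures composition-driven disorder tendency only.
Runs record the score source ("proxy" or the score-file path) in the run
log, and real analyses should supply per-residue scores from a dedicated
predictor.

## Synthetic proteome generator

The generator emulates the two marginal regularities of real proteomes:
rank-linear ln(*L*) (equally spaced sorted ln-lengths, i.e. an exponential
length distribution) and rank-linear ID. Defaults for the two presets:

| parameter | eukaryote-like | prokaryote-like |
|---|---|---|
| n_proteins | 1000 | 1000 |
| ln(*L*) range | 3.22–8.52 (L ≈ 25–5000) | 3.40–7.78 (L ≈ 30–2400) |
| target mean ID | 0.41 | 0.16 |
| target ID sd | 0.22 | 0.09 |

The mean IDs are the observed group-level disorder contents of eukaryotic
vs prokaryotic proteomes; the ln(*L*) ranges put the median lengths near
350 and 270 residues respectively. The within-proteome ID spreads are not
a reported quantity; 0.22 and 0.09 were fixed once as realistic spreads
that keep the rank-linear profile `mean ± √3·sd` inside [0, 1].

ID targets are paired with lengths through a random permutation so the two
attributes are unrelated by construction. Disorder truth is planted
directly in the score file: *N*<sub>D</sub> = round(id·*L*) residues at
score 0.9 (one contiguous stretch, mimicking an IDPR) and the rest at 0.1,
so the recovered id_pep equals *N*<sub>D</sub>/*L* exactly and never sits
on the 0.5 threshold boundary. Optional `X` residues and shorter
alternative isoforms are injected at configurable rates with exact
bookkeeping in the truth table.

What the generator does **not** emulate: real amino-acid sequence
evolution or homology, predictor noise (scores are bimodal 0.1/0.9),
length–disorder correlation, and proteome-specific multimodality of the
length distribution. Passing tests therefore show that the pipeline's
arithmetic, binning, distances and tree reconstruction are correct and
that well-separated proteome architectures are recovered as clades; they
do not certify biological conclusions about any real organism.

## Numerical choices and problem sizes

- Densities are exact ratios of integers; normalization error is bounded
  by accumulation only (tested at 1e−12).
- Correlation on degenerate (zero-variance) input returns a distinguished
  "undefined" result instead of NaN.
- Median length is the standard mid-point (mean of the two central order
  statistics for even counts); percentages are displayed to one decimal in
  TSV but kept at full precision internally.
- The cohort clade-recovery experiment uses 8 proteomes × 1000 proteins ×
  100 replicate seeds; metric/normalization property checks use a few
  hundred randomized grids. These sizes give stable rates while keeping a
  full run of the suite and the acceptance script in the minutes range.

## Known limitations

- The proxy scorer's absolute id_pep values are composition-driven and not
  comparable to trained-predictor output; only supply it where
  self-containment matters more than predictive accuracy.
- Fingerprints ignore everything except (ln *L*, ID); proteomes with
  different biology but similar length/disorder architecture are
  indistinguishable by construction.
- NJ produces a single tree without support values; no bootstrap is
  implemented.
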
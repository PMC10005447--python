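# Methods

## Coordinate system and reference proteins

All positions are 1-based inclusive coordinates on the *mature* protein
chain (precursor minus signal peptide), the convention under which the
casein bioactive-peptide literature reports spans such as β-casomorphin-7 =
β-casein 60–66 or the digestion-resistant C-terminal domain 193–209. The
bundled references are the canonical genetic variants of the four major
bovine caseins — β (P02666, A2, mature length 209), α_s1 (P02662, B, 199),
α_s2 (P02663, A, 207) and κ (P02668, A, 169) — with signal peptides of
15/15/15/21 residues removed. Which variants a given identification
database contained is usually unknowable after the fact; we ship one
canonical variant per casein and treat variant enumeration as out of scope.
The fixture-integrity tests assert the classic anchors (YPFPGPI at 60,
YPVEPF at 114, SLVYPFPGPI at 57, RYLGYLE at 90, YFYPEL at 144) so any
accidental edit of the FASTA is caught immediately.

## Peptide-to-protein mapping

Search engines report exact sequences, so mapping is exact substring
location, not scored alignment: every occurrence of the peptide in every
reference, in deterministic order (protein input order, ascending start).
Isoleucine/leucine are isobaric; an `equate_ile_leu` option canonicalises
both to one letter before matching but is off by default, because the
search output has already committed to a residue. A peptide matching k > 1
loci is either expanded into k copies flagged ambiguous (default — profiles
then count it in each matched protein) or dropped (`unique_only`). The
mapping report preserves the accounting identity
`input = unique + ambiguous + unmapped`. Missing intensities are imputed to
1.0 and flagged, so count-only tables flow through the intensity machinery
unchanged. Peptides shorter than 2 residues are rejected at parse time.

## Profiles, sizes, counts

The residue profile is a pure painting operation: each peptide adds its
intensity (or 1) to every position of its span. Two identities pin it
down and are tested: Σ_positions profile = Σ_peptides intensity × length,
and occurrence mode equals intensity mode at unit intensities. Profiles per
(substrate, time) sum over animals; a `mean` aggregation is deliberately
not the default because summation is the simplest reading of
"sum of intensities of all overlapping peptides", and per-row
normalisation is available as a flag (whether published area plots were
normalised per sample is typically unstated, so raw is the default).

Size distributions count *unique sequences* per length bin. Default bins
2–5 / 6–9 / 10–14 / ≥15 follow the spoken categories of duodenal
peptidomics (the 6–9 window is the sweet spot of ion-trap identification;
"longer than 10" is the usual long-peptide cutoff); they are configurable
because published figure binnings are rarely stated numerically.

Count summaries reproduce identification-level bookkeeping: per time point,
the number of distinct sequences seen in ≥1 animal and the number seen in
all n animals ("common"); column totals are *plain sums over time points*,
not deduplicated unions — that is how such tables are printed (e.g. per-time
counts 444 + 369 + … + 434 = 3863) — and a separate `dedup_union_count` is
provided for the union semantics.

## Terminal logos

The logo content is the 20×6 frequency matrix over included peptides;
columns are exactly stochastic. Peptides shorter than 5 residues are
excluded by default (below the identification floor of the MS setups this
targets), and for a length-5 peptide the windows overlap so its middle
residue counts in both N3 and C−3 — the stated convention for this analysis
rather than the more common exclude-short rule. No pseudocounts and no
information-content scaling: the matrix, not a rendered logo, is the
product.

## Multivariate analysis

PCA operates on the samples × residues matrix (all four caseins
concatenated, cell = residue intensity sum). Columns are mean-centred;
unit-variance scaling is off by default because intensity shares one
meaningful scale across residue features (both are flags; zero-variance
columns are dropped with a log entry under scaling). The decomposition is a
thin SVD; `explained_ratio` sums to 1 over returned components, and each
component's sign is fixed by making its largest-magnitude loading positive.
Tests check reconstruction to 1e-8, agreement with a brute-force covariance
eigendecomposition, and agreement with scikit-learn's PCA.

Clustering of samples in peptide space uses peptides present in at least
2 time points within a substrate (the scope of "present in at least two
time points" is ambiguous — within substrate or overall — so both are
implemented, within-substrate being the default). Intensities are
log10(1+x)-transformed by default since MS intensities span decades.
Defaults are Euclidean distance with Ward linkage; the original
heatmap-clustering software's method is typically unstated, so these
robustness-motivated defaults are a reproduction caveat, and
correlation distance (with a defined fallback of distance 1 between
non-identical zero-variance rows, 0 between identical ones) and
average/complete/single linkage are available. Agglomeration is delegated
to scipy; a naive O(n³) agglomeration oracle and a minimum-spanning-tree
cross-check for single linkage guard it in tests. Leaf order is
deterministic (smaller subtree first, ties by smallest leaf index) and the
tree exports to Newick.

## Plasma statistics

Per analyte: balanced two-way fixed-effects ANOVA (substrate × time) with
the standard cell-means sums of squares, verified against statsmodels and
against the decomposition identity SS_total = SS_A + SS_B + SS_AB + SS_E.
Per-time substrate contrasts use t statistics on the pooled MSE with
Bonferroni adjustment; the family is the set of time points tested (9 on
the full sampling grid −15, 5, 20, 45, 60, 120, 180, 240, 360 min,
including the basal draw, since a contrast is computed at every level).
Stars follow the usual 0.05/0.01 convention on adjusted p.

Caveat stated openly: the underlying crossover design (each animal receives
both substrates) is *not* modelled — no animal factor, no repeated-measures
correlation — matching the plain two-way-ANOVA-plus-Bonferroni analysis
this reproduces. Unbalanced designs are rejected rather than approximated;
Type II/III machinery and mixed models are out of scope.

## Synthetic data generator

The generator exists because studies of this kind rarely deposit raw MS
data; it emulates the statistical structure the analysis assumes, not mass
spectra. Digestion model: each protein molecule is cut independently at
bond i with probability proportional to a P1 propensity of the preceding
residue (pepsin-like: F/L 1.0, W/Y 0.9, E 0.5, M 0.3, background 0.05;
bonds flanking proline ×0.02), times any protection factor, rescaled so the
mean cut probability equals the hydrolysis extent (probabilities cap at 1
with the remainder redistributed, so the mean is exact). Fragments of 5–40
residues are observable — the lower edge mimics the five-residue MS
identification floor. Per (animal, time) sample, 20 molecules per protein
are pooled, repeated identifications sum their log-normal intensities
(log10 mean 6, sd 0.4), and the sample is capped at the top 180 (casein) /
150 (hydrolysate) peptides *by intensity*, mirroring data-dependent
acquisition; an intensity-ranked cap is what makes a stable core peptidome
common to all animals, as real tables show.

Study defaults are calibrated once to the magnitudes such experiments
report: casein = extent 0.30 with β-casein 193–209 protected ×0.1
(its documented resistance to gastric digestion), hydrolysate = extent
0.50, 6 animals × 10 post-intake time points (5–150 min). At these
settings one study yields ~440–465 unique casein peptides per time point
(~345–360 hydrolysate), ~24% of casein peptides longer than 10 residues
versus ~10% for the hydrolysate, C-terminal β-casein enrichment in the
casein profiles, and PC1/dendrogram separation of the substrates.
Problem sizes throughout tests (one study of ~23k observations, 100 small
peptidomes, 2000 ANOVA replicates) are chosen to exercise every claim at
desk scale.

What the generator does **not** emulate: chromatographic or ionisation
bias beyond the intensity cap, missed/partial cleavage kinetics over time
(profiles are time-stationary apart from sampling noise, consistent with
the observed near-constancy of duodenal profiles across time), endogenous
(non-milk) peptides, genetic variants or modified residues. Passing
recovery tests therefore shows the *analysis* is correct and sensitive to
planted structure of realistic size — not that real digests obey this
model.

Plasma model: concentration = substrate-specific mean curve + per-animal
offset (SD 3 μmol/L default) + Gaussian noise (SD 6), truncated at zero
with a warning. Default curves emulate faster/higher hydrolysate
amino-acid appearance before 200 min converging by 360 min, plus a null
analyte; dedicated null and planted-shift specs drive the type-I
calibration (rejection rate within [0.040, 0.060] at α = 0.05 over 2000
replicates) and power checks.

## Numerical and degenerate-input choices

Deterministic everything: all randomness flows from a single
`numpy.random.default_rng(seed)` per generator call; mapping order, k-mer
tie-breaks (lexicographic), PCA signs and dendrogram leaf order are all
fixed. Empty inputs: empty observation lists yield empty outputs and
zero reports; an empty logo input raises with advice; an all-cut digestion
sample warns and is flagged rather than silently dropped. Percentages of
empty size-distribution groups are defined as 0. SE of single-record cells
is reported as 0 with an explicit `se_defined=False` flag.

## Known limitations

Exact matching cannot place peptides with substitutions or modifications;
paralog-shared peptides depend on the ambiguity policy chosen; the
clustering defaults are not a faithful port of any particular heatmap
tool's algorithm; the ANOVA ignores the crossover structure; and the
generator's single-residue P1 model is deliberately simpler than a full
position-specific cleavage matrix — sufficient to plant the qualitative
contrasts the analysis must recover, and transparent enough to test.
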
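# Methods

This note documents the models and conventions behind `protniche`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Input handling

Proteomes are protein FASTA; records shorter than `min_length` residues
(default 100, mirroring the common "ORFs under 100 codons" sampling filter)
are dropped after stripping terminal stop characters (`*`). Whether the
original codon filter counted the stop codon is ambiguous; the threshold is
configurable to cover both readings. Ambiguity codes B/Z/X/U are retained
in records but excluded from every composition denominator (usage, GRAVY,
aromaticity, aliphatic index) — excluding them avoids inventing
frequencies for codes that are not residues. Metadata, COG-annotation and
ortholog-hit tables are UTF-8 TSV with headers; categorical metadata
fields are validated against closed vocabularies so that group assignments
are always driven by the table, never inferred from organism names.

## Amino-acid usage

Usage is residue-weighted over the whole filtered proteome (concatenated
counts / total countable residues), the organism-total convention of
codon-usage tools, rather than a mean of per-protein frequencies; for
typical proteomes the two differ little, but the organism total is the
quantity a compositional ordination should see. Columns follow the
alphabetical one-letter order `ACDEFGHIKLMNPQRSTVWY`.

Heat-map standardisation is the per-column z-score with population SD
(ddof = 0, the `scipy.stats.zscore` convention); constant columns map to
zero. Range scaling would also be defensible — the choice is isolated in
`standardize_columns` and configurable by swapping that step.

The GC-unbiased reduction keeps Val, Ser, Thr, His, Gln, Asp, Glu, Cys and
pools the remaining twelve residues into `other`. The eight-residue list
is a hard-coded constant, *not* derived from a codon-GC rule: a naive rule
would also admit Leu, which is conventionally excluded from this set. Row
sums are preserved, so the reduced matrix remains compositional.

Group extreme summaries report each residue's highest and lowest group
mean as percentages rounded to 2 decimals; ties break on lexicographic
group name (first-match `idxmax`/`idxmin` over a sorted index).

## Physico-chemical indices

The net-charge model is Henderson–Hasselbalch over the free termini plus
the ionizable side chains (positive: N-terminus, His, Lys, Arg; negative:
C-terminus, Asp, Glu, Cys, Tyr). The pKa set is the EMBOSS default
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1), stored as a named, swappable `PKaSet`: published pI methods
differ mainly in this table, and no single set is canonical, so all
distribution-level conclusions should be robust to the choice — the test
suite checks pI properties (root quality, monotonicity under charged
appends, acidic/basic ordering) rather than absolute values.

The pI is found by bisection on [0, 14]. The charge function is strictly
decreasing in pH under this model, so the bracket always contains exactly
one root; iteration continues until the interval is below `tol`
(default 0.01 pH) *and* |charge| ≤ 1e-4 (≤ 200 iterations). Unknown
residues are non-ionizable, never an error.

GRAVY uses the Kyte–Doolittle scale and the instability index the
Guruprasad dipeptide weight table, both taken from biopython's published
scale data (`Bio.SeqUtils.ProtParamData`); the computations themselves
(mean over countable residues; `10/L · Σ` over consecutive dipeptides,
skipping dipeptides with non-standard codes) are implemented here. The
aliphatic index uses Ikai's coefficients a = 2.9 (Val) and b = 3.9
(Ile/Leu) on mole fractions.

pI distributions use half-open 0.5-pH bins over [2, 14); out-of-range
values are clamped into the end bins so percentages always total 100.
Group profiles are the per-bin arithmetic mean and sample SD (ddof = 1)
across organisms; a singleton group gets SD 0 with a warning.

## Clustering and correspondence analysis

Complete linkage is implemented directly (O(n³) agglomeration) so the
tie-break is a contract: among equal-height candidate merges, the pair
whose sorted (min-label, min-label) identifier is lexicographically
smallest wins. scipy's implementation is used as an independent oracle in
the tests, not in the pipeline, precisely because it does not guarantee
this tie-break. Complete linkage is monotone, so merge heights are
non-decreasing and the dendrogram is ultrametric; Newick export gives each
child a branch length of (parent merge height − child merge height).
Exact leaf ordering of any published dendrogram is not reproducible and is
out of scope.

CA is classical: with `P = X / grand total`, row masses `r`, column masses
`c`, the standardised residuals `S = D_r^{−1/2}(P − r cᵀ)D_c^{−1/2}` are
decomposed by SVD; principal coordinates are `F = D_r^{−1/2} U Σ` (rows)
and `G = D_c^{−1/2} V Σ` (columns); axis k explains `σ_k²/Σσ²` of the
inertia. Singular values below 1e-12 (relative) are dropped, so a rank-1
(independence) table yields zero axes. Axis signs are arbitrary; every
test and reported correlation is sign-flip tolerant. Rows entering CA are
raw per-organism frequency profiles (row-profile CA), not standardised
values — configurable by standardising upstream.

Axis–covariate association is the Pearson correlation with the two-sided
p-value from the t transform; zero variance on either side is an error
rather than a NaN.

## Directional substitution bias

Ortholog hits pass the filter iff similarity ≥ 40%, length difference
< 20% of the *longer* sequence (the denominator is a choice; the shorter
or mean denominator would admit slightly different sets), and
e-value ≤ 1e-10, all boundaries as stated. Similarity is taken as reported
by the upstream search; it is never recomputed.

Alignment is deterministic Needleman–Wunsch with affine gaps (Gotoh three
matrices), default BLOSUM62 with gap open 10 and extend 0.5; a run of L
gap columns costs `open + (L−1)·extend` (the EMBOSS convention).
Traceback ties prefer diagonal, then a gap in the subject, then a gap in
the query, making results bit-reproducible. Precomputed alignments can be
supplied instead, bypassing this stage entirely.

Counting: every aligned column with two differing standard residues
increments `N[source][target]`; identities land on the diagonal; columns
with a gap or ambiguity code are skipped. For each of the 190 unordered
pairs the *forward* direction is the larger of the two directed counts
(lexicographic orientation on exact ties), the ratio is forward/reverse
(flagged undefined when reverse = 0; such pairs sort after all finite
ratios in the ratio panel), the gain is forward − reverse, and printed
ratios are rounded half-up to 2 decimals.

The chi-square uses a 2×2 table whose rows are
`[N[i][j], other replacements out of i]` and
`[N[j][i], other replacements out of j]`, 1 df, Pearson statistic without
continuity correction; degenerate margins give (0, 1). Two conventions
are defensible for the remainder cells — per-row remainders (default) or
a pooled remainder shared by both rows — and both are implemented behind
the `pooled_remainder` flag. Remainders exclude the diagonal (identities
are not replacements) and the pair partner. Note that the chi-square is
defined *relative to the chosen direction*: transposing the matrix (swap
source and target organisms) leaves pair, forward/reverse counts, ratio
and gain unchanged but conditions the remainders on the other organism's
losses, so the chi-square can differ. Significance is reported as a
numeric tier: 3, 4, 5, 6 for p < 1e-3 … 1e-6 (0 = not significant);
symbol mappings vary between publications, so no symbols are hard-coded.

## Synthetic data

The generator exists so that every pipeline stage can be exercised and
validated without downloading genomes; all outputs are pure functions of
parameters + seed (byte-identical regeneration is tested).

**Proteomes.** Codons are drawn i.i.d. from the 61 sense codons with
weight ∝ `g^GC·(1−g)^AT` for GC target g ∈ [0.25, 0.75], then translated
with the standard genetic code. This is the simplest model that couples
genomic GC to residue composition and reproduces the canonical split
(Pro/Ala/Arg/Gly rising with GC; Phe/Tyr/Lys/Asn/Ile falling). Realised
codon GC lands within ±0.02 of the target for ≥ 10⁴ residues (tested).
Protein lengths are `min + Poisson(mean − min)` clipped at `max`
(defaults 100/300/1500 — a realistic prokaryotic length scale above the
length filter). Optional multipliers on the Asp/Glu or Lys/Arg codons
plant acidic- or basic-shifted proteomes; the study-bundle default of 2.0
produces an exaggerated but unambiguous charge contrast between the two
planted metabolic groups. What the model does **not** emulate: codon
context, amelioration, gene-level compositional heterogeneity, strand
bias, or any phylogenetic correlation between organisms — organisms are
independent draws, so passing tests demonstrate that the *analysis*
responds correctly to planted signals, not that real archaea behave this
way.

**Ortholog pairs.** Substitution-only divergence (no indels) so truth
counts are exact: identity columns carry one uniform residue; substituted
columns carry a directed event (source, target). A `focal_share` fraction
of events (default 0.1) involves the focal pair (i, j), taking direction
i → j with probability m/(m+1); the rest are uniform over the other
directed pairs. This event-level construction makes the forward/reverse
count ratio a consistent estimator of the injected multiplier m — a
residue-weight scheme would bias the ratio away from m. With m = 3 and
10,000 substituted columns the focal pair receives ≈ 750 forward / 250
reverse events, giving a relative standard error of ≈ 7%, comfortably
inside a ±20% recovery band.

**COG universes.** Each group's core (which contains its exclusive set)
is planted in every member; exclusive IDs never occur outside their group;
Poisson noise IDs are sprinkled from the non-exclusive pool. Every
non-exclusive core ID is additionally leaked round-robin into at least one
outside organism — without this, core IDs that no outsider happens to
draw would surface as spurious exclusives, and groups planted with no
exclusive set could not be guaranteed an empty reverse search. The default
spec (69 organisms in groups of 25/26/18, universe 2000, core 488/196/50,
exclusive 22/0/0, noise mean 40) mirrors the scale of the archaeal study
the pipeline is modelled on.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: proteomes of
30–60 proteins × ~250–300 residues, 8–12 organisms per bundle, ortholog
simulations of 20,000 columns, 100 recovery replicates, a 69-organism COG
universe. These sizes were chosen so every stochastic check has
comfortable statistical margin while the whole suite stays fast; all
randomness flows through explicit integer seeds (`numpy.random.default_rng`),
and derived seeds stay below 2³¹.

## Known limitations

- The pI model ignores charged-residue interactions, cysteine bridging and
  post-translational modification; absolute pI values shift with the pKa
  set, which is why conclusions are distributional.
- The alignment engine is quadratic and intended for single protein pairs,
  not genome-scale all-vs-all searches; ortholog discovery itself
  (BLAST-style search, COG assignment) is out of scope and consumed as
  input tables.
- CA on compositional data inherits the usual closure effects; no
  log-ratio transformation is applied, matching the classical workflow
  this package reimplements.
- The chi-square on replacement pairs treats columns as independent
  observations, ignoring within-protein correlation; tiers should be read
  as ranking evidence, not exact error rates.
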
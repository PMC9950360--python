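# Methods

This note documents the models, conventions and numerical choices behind
`haplodistill`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

All coordinates are 1-based inclusive (VCF convention); region strings
are `chrom:start-end`. Alleles are coded 0 = reference, 1 = alternate,
−1 = missing. For PED input without a reference-allele table, the
lexicographically smaller base becomes 0 (logged). Unphased or
half-missing diploid genotypes are set missing on both haplotype columns
of the sample. Indels are retained as biallelic presence/absence markers
and count one difference each. Missing data are handled by pairwise
deletion throughout: a site missing in either member of a pair is
dropped from that pair's comparison, and per-pair compared-site counts
are recorded.

## Linkage disequilibrium and the block

Because haplotypes are phased, two-locus haplotype frequencies are
counted directly (no EM), and r² is the squared correlation of the 0/1
indicator vectors. Blocks are tag-anchored: membership is r² ≥ threshold
(default 0.8) against a single tag variant, which matches how such
blocks are displayed against a tag SNP; all-pairs verification is an
optional strict report, since requiring every within-block pair to pass
would amount to clique-finding. Pairs where either site is monomorphic
after pairwise deletion are reported as undefined, not as r² = 0.

## Clade distillation

Distances are Hamming counts over non-missing shared sites; archaic
heterozygous sites enter pseudo-haplotype vectors as 0.5 (half a
difference). Trees are built by neighbor joining with a deterministic
tie-break (lowest row/column index on equal Q), so results depend only
on input order. NJ is used rather than maximum likelihood because the
tree's only role here is the two-clade split and its bootstrap support,
which NJ recovers consistently on additive and deep-divergence data; the
implementation is cross-checked against scikit-bio's NJ on random
additive matrices in the test suite. Bootstrap support resamples block
variants with replacement and counts replicates whose tree contains an
edge separating clade 1 from everything else.

Clade numbering is frequency-based: clade 1 is the larger (common)
clade. Assignment methods: `nj_root_split` (root on the outgroup's
attachment edge), `kmeans2` (deterministic 2-medoids seeded with the most
distant pair) and `tag_allele` (carrier split at a named variant).
Haplotypes whose distances to the two clade medoids differ by less than
10% of their mean are reported as ambiguous (none arise under the
default simulation, but recombinant-like haplotypes in real data would).

Core haplotypes are per-clade majority alleles with their consensus
fractions; exact 50/50 ties are flagged unresolved and excluded from
concordance scoring. Overall clade-2 frequency is the unweighted mean of
population frequencies (a haplotype-weighted figure is reported
alongside). The ancient trajectory bins samples by age (default 2,000-y
bins over 0–45,000 BP, configurable), averages the clade-2 allele
frequency across the tag SNPs within each bin, and reports empty bins as
missing, never zero.

## Diversity scan

π is the mean pairwise difference count; per-site values divide by the
physical window span (default 1,500 bp — genotype matrices carry no
per-base callability; a callable-length override exists). Watterson's
θ_w = S/a₁ with a₁ = Σ_{i<n} 1/i. Tajima's D uses total S and π (not
per-site) with the standard constants; it is undefined (distinct from
zero) when S = 0, and windows with S < 3 are excluded from ranking
because D is numerically meaningless there. The scan slides a 1.5 kb
window in 100 bp steps; windows are ranked by the sum of their π-rank
and D-rank, ties are flagged, and contiguous top windows merge into one
candidate segment. The null distribution for the peak D conditions on
the observed S (fixed-S coalescent simulation, the classical approach);
a θ-mode null is also available. The empirical p-value uses the add-one
rule p = (1 + #{null ≥ obs}) / (1 + n_null).

## Coalescent generator

Neutral mode is a standard Hudson coalescent: k lineages coalesce at
rate C(k,2) in units of 2N generations; mutations are infinite-sites,
Poisson(θ/2 × total branch length) in θ-mode or exactly S_fixed placed
multinomially on branches in fixed-S mode; positions are unique uniform
integers on [1, L]. Calibration tests verify E[S] = θa₁ (within 2% at
n = 20, θ = 10, 10⁴ replicates), E[π] = θ at n = 2, and mean D within
±0.1 of zero, with msprime as an independent oracle.

Two-clade mode draws the study conditions:

| parameter | default | meaning |
| --- | --- | --- |
| n1, n2 | 135, 65 | clade sample sizes (clade 2 at 32.5%) |
| L | 70,000 bp | locus length |
| T_split | 61,600 gen | clade join (1.54 My at 25 y/gen) |
| T_archaic | 29,160 gen | archaic branch-off (729 ky) |
| T_outgroup | 240,000 gen | outgroup divergence (6 My) |
| N_e | 5,000 | within-clade diploid effective size |
| μ | 1.25 × 10⁻⁸ /site/gen | mutation rate |
| target | central 3 kb, 40% of stem mutations | dense segment for the scan |
| archaic het rate | 0.016 /site | IUPAC het calls in the archaic diploid |

Within-clade genealogies run independently and join deterministically at
T_split (no migration or structured coalescent: the signal of interest
is the deep split itself). Replicates whose within-clade TMRCA exceeds
the stem are rejected and redrawn, with counts surfaced; clade 2 is
additionally conditioned on TMRCA₂ ≤ T_archaic so the archaic lineage
joins the clade-2 stem and is monophyletic with the whole clade. N_e is
the *allele-class* size, not the species-level effective size: a clade
held at intermediate frequency f coalesces internally like a population
of roughly f·N diploids, and a species-level choice would produce crowns
so deep that almost no clade-defining (fixed inter-clade) sites remain —
the opposite of the observed regime, where hundreds of variants travel
as two coherent core haplotypes. There is no intralocus recombination,
matching the empirically suppressed recombination across such blocks.

Because every modern–modern cross-clade path has length exactly
2·T_split and every path to the outgroup exactly 2·T_outgroup, the
outgroup-calibrated dating t = 6 My × d_focal/d_calibration is unbiased
by construction, and its only noise is Poisson mutation counts; the
recovery test (median over 200 seeds within 15% of 1.54 My, at clade
sizes 20 + 10 to keep runtime small) exercises precisely this.

The generator records ground truth: clade labels, clade-defining stem
positions (flagging those younger than T_archaic, which the archaic does
not carry), realised TMRCAs, rejection counts and the target segment.
All randomness flows from one counter-based Philox stream per simulation
seeded with a single integer; identical parameters give bit-identical
output.

What the generator does *not* emulate: genotyping error and missingness
in modern haplotypes, recombination and partial LD decay, population
structure within clades, selection acting during the sampled period, and
the slight pre-crown archaic attachment seen in real data (real archaic
concordance with the clade-2 core is a few percent below 100% because
the archaic lineage branches off marginally before the clade-2 crown;
in the generator the discordant fraction is instead the stem segment
younger than T_archaic, typically 0–15% of clade-defining sites).
Passing tests therefore demonstrate correctness of the inference chain
under a clean deep-split model, not robustness to real-data artefacts.

Downstream layers: expression = intercept + β·dosage + N(0, σ²) floored
at 0, with `beta_for_r2` solving β²Var(g)/(β²Var(g)+σ²) = r² under
Hardy–Weinberg dosage variance 2f(1−f) (defaults σ = 1, intercept 5
FPKM, r² = 0.235 at f = 0.325). Ancient samples draw Binomial(2, f(age))
tag genotypes with configurable missingness (default trajectory: flat
30%, 10 samples per 2,000-y bin, 20% missing calls).

## Archaic concordance and dating

Concordance compares an archaic diploid to a clade's core haplotype on
bases (so it is invariant to REF/ALT orientation). Heterozygous archaic
sites never enter the homozygous match percentage; they are tallied
separately with a one-allele-matches flag, and a secondary any-allele
percentage is available. Dating uses mean cross-group Hamming distance
over all pairs (the simplest estimator consistent with per-locus
sequence scaling); a consensus-to-consensus variant is available.
The expected-block-length formula L = 1/(c·g), with c in crossovers per
bp per generation (1 cM/Mb = 10⁻⁸) and g the haplotype age in
generations, reproduces 2.62 kb for (1.54 My, 25 y, 0.62 cM/Mb) and is
strictly decreasing in both age and recombination rate.

## eQTL

Additive coding only (dosage 0/1/2); the regression is simple OLS with a
two-sided t-test on n − 2 degrees of freedom, so r² equals the squared
Pearson correlation (verified numerically). Samples failing the inner
join on sample id or with an unassigned haplotype are excluded and
reported, never imputed. No multiple-testing correction is applied for
the single-locus, single-gene test; a Benjamini–Hochberg helper is
provided for batch use. Calibration: under β = 0 the type-I error at
α = 0.05 lies in (0.04, 0.06) over 10⁴ replicates, and simulations tuned
to variance explained 0.235 at n = 161 recover that r² within its
sampling interval.

## Pipeline

`run_all` executes LD → distillation → ancient trajectory → scan (with
null) → dating → concordance → block length → eQTL on whatever inputs
the flat key=value config names, skipping absent stages with an explicit
notice and aborting with the stage name on error. The report cites a
hash of the non-path config parameters, and all outputs are
byte-identical across runs with the same config and seed. Problem sizes
in the shipped tests (200-haplotype fixtures, 10⁴ calibration
replicates, 100–500 seed recovery loops, 1,000-replicate nulls) were
chosen so the whole suite runs in about a minute on one CPU while
keeping Monte-Carlo error well inside each test's tolerance.

## Known limitations

Tag-anchored blocks can include variants violating pairwise r² among
themselves (strict mode reports them). The NJ bootstrap measures support
for one bipartition, not whole-tree confidence. Dating assumes a
molecular clock and equal mutation rates on all branches. The scan's
physical-span L slightly underestimates per-site diversity where
callability is incomplete. The generator's rejection conditioning
truncates the within-clade TMRCA distribution; realised TMRCAs are
reported in the truth object so tests can account for it.
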
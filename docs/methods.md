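# Methods

This note documents the models behind `ancientmt`, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Coordinate frame

The reference mitogenome is circular; all in-memory coordinates are
1-based inclusive, and intervals may wrap the origin (position L is
adjacent to position 1). Interval arithmetic is done on the doubled
sequence and reduced modulo L. On disk, interval files use 0-based
half-open coordinates (BED convention); origin-wrapping amplicons keep a
single record whose end runs past L. The conversion happens only in
`io.py`.

## Synthetic data

The generator's job is to make every downstream stage testable against
exact truth, under conditions matching the study system: a ~16.3 kb
circular genome, 130 overlapping primer pairs producing 155–230 bp
products arranged in four multiplex sets, and reads whose error
structure resembles early pyrosequencing of ancient templates. Every
perturbation of every read is recorded in a per-read ledger, which is
the oracle for the test suite.

**Reference genomes** are uniform random sequence with planted
homopolymer runs (`homopolymer_boost` = expected runs of ≥ 6 identical
bases per kb; default 1) and a region annotation mirroring the real
mitogenome architecture: one control region, two rRNAs, 22 tRNAs
interleaved among 13 protein genes, with default class fractions
protein 0.695, rRNA 0.155, tRNA 0.092, control region 0.056 (the
composition of a taurine mitogenome). User-supplied fractions are
honored verbatim even if they cover less of the genome.

**Panels** place insert start points evenly around the circle and draw
each insert long enough to reach `min_overlap` (default 30 bp) into its
successor, within the insert range. Primers (18–25 bp) are exact
reference substrings flanking the insert, the reverse primer stored
reverse-complemented as synthesized. Multiplex set labels are assigned
by a round-robin-preferring backtracking colouring so that no two
overlapping amplicons share a set; infeasible requests (too few
amplicons, or one set with overlaps) raise immediately.

**Depth.** Per-amplicon read counts are lognormal, ceil(exp(N(μ, σ))),
with μ = ln 93 and σ = √(2 ln(463/93)) ≈ 1.79, moment-matched so the
count distribution has median 93 and mean 463 reads — the mean ≫ median
skew of pooled amplicon sequencing in which some products are
re-sequenced. The lognormal's coefficient of variation is ≈ 4.9, so
sample means over a single 130-amplicon panel fluctuate by tens of
percent; distribution-level checks therefore sample ≥ 10⁴ counts
through the same draw the simulator uses. Per-nucleotide depth is the
sum of counts over covering inserts and thus scales with the tiling
multiplicity (≈ 1.5 for default panels).

**Damage** is modelled as strand-symmetric cytosine deamination applied
uniformly along the read: each C on a forward-strand read (each G in
reference orientation on a reverse-strand read) converts with
probability `damage_rate` per base. Only aggregate type I/type II
counts are consumed downstream, so the well-known enrichment of damage
at fragment ends is deliberately not modelled. Because each event is
visible only on reads from the strand carrying the pyrimidine, the
expected mismatch ratio under this model is

    E[type II / type I] ≈ 1 + (3/2) · damage_rate / seq_error_rate.

The defaults `seq_error_rate = 0.01` (a realistic aggregate per-base
pyrosequencing error) and `damage_rate = 0.004` give an expected ratio
of 1.6, the characteristic excess observed in authentic ancient
amplicon data; simulated full-scale runs land within ~10% of it, the
residual spread coming from depth-weighted base-composition
fluctuations. Contaminant reads receive sequencing errors but no
damage.

**Homopolymer indels.** For each maximal run of k ≥ 3 identical bases
in a template, a read acquires a single-base insertion or deletion at
the run's end with probability min(rate·(k − 2), 0.5)
(`homopolymer_indel_base_rate` default 0.03). The direction of the
miscount is drawn once per amplicon-template run context, not per read:
run-length miscalls are a systematic property of the flow signal for a
given context, and this is what allows an artifact at a long run to
reach a consensus majority — with a per-read coin flip the
single-direction support could never exceed 25% and the artifact class
the homopolymer filter exists for would never arise. Short runs have
low per-read rates, so at realistic depth (median ≈ 93) binomial
concentration keeps them out of the consensus and surviving artifacts
sit almost exclusively at runs > 5 — the regime the run-length filter
is built for. At shallow depth (≲ 20) occasional run-4/5 artifacts do
reach the consensus; they are by definition kept by a "> 5" filter and
are the reason weakly covered amplicons get re-pooled rather than
trusted.

**Contamination** draws a configurable fraction of reads from a
contaminant haplotype sliced at the same coordinates (the panel primers
amplify the contaminant too). The contaminant must be at least as long
as the longest amplicon span.

What the generator does not emulate: flowgram-level signal, PCR
chimeras, fragment-length distributions, end-enriched damage curves,
quality scores (FASTQ qualities are constant). Tests passing on this
synthetic data therefore validate the pipeline's logic and statistics,
not its robustness to those real-data phenomena.

## Consensus calling

Reads are assigned by exact or ≤ `primer_mismatches` (default 1)
matching of their terminal prefix against the panel's primers; a read
matching two primers is dropped as ambiguous, and pairwise primer
distinguishability is checked up front. After masking, each insert is
globally aligned to its amplicon's reference window with unit mismatch
cost and affine gaps (open 2, extend 1) via Biopython's
`PairwiseAligner`; no banding is used because windows are ~200 bp.
Equal-length reads with ≥ 90% ungapped identity skip the dynamic
program — at these costs an indel pair would have to explain several
compensating mismatches to beat the ungapped alignment. Reads below
70% alignment identity are excluded as exogenous.

Calling is argmax over {A, C, G, T, deletion} per position; depth below
`min_depth` (default 1) or an exact tie yields N (ties are left to
replication rather than encoded as IUPAC ambiguity). A winning deletion
suppresses the position. An insertion is emitted when its count exceeds
half the local depth — a threshold chosen to make insertion calls
majority-rule like substitutions. Mean/median depth are computed over
all reference positions; mean support over covered positions only.

## Authentication

*Damage typing is against the consensus*, not the mapping reference:
misincorporation is a read-level deviation from the endogenous
sequence. The type II/type I ratio gets a percentile bootstrap over
reads (n = 1000, seeded); the read is the resampling unit because
damage events on one template molecule are not independent.

*The homopolymer filter* removes an indel iff its (single) base equals
the base of a maximal reference run of length > `run_threshold`
(default 5) that the indel lies in or immediately flanks ("flanks"
= within one position of the run ends, since the miscount materializes
at the run boundary). Mixed-base indels and substitutions always pass.

*The overlap screen* computes per-site minor-allele frequency
(second-most-frequent base over ACGT depth, hence ≤ 0.5) at positions
covered by ≥ 2 amplicon inserts, classes sites monomorphic/polymorphic
from an aligned modern panel, and reports the two MAF spectra, the
count of polymorphic sites above `maf_threshold` (default 0.02), and a
per-amplicon stratified MAF for diagnostics. Under zero contamination
the polymorphic and monomorphic flag rates agree with the
sequencing-error null; under admixture the polymorphic class shows MAF
near the contamination fraction at sites where the contaminant differs.

*Replicate comparison* requires both consensuses in the same coordinate
frame and skips positions either replicate called N (uninformative, not
discordant).

*Damage-ambiguity triage*: consensus-vs-reference C→T or G→A
substitutions with support below `support_threshold` (default 0.75) are
flagged for replication, never auto-reverted — the threshold separates
the ~50–60% support typical of damage-inflated calls from near-fixed
genuine variants.

## Comparative statistics

Pairwise diffs left-normalize indels (shift left while the preceding
base equals the last base of the indel allele) so one physical edit has
one canonical coordinate. Sites with N on either side are excluded
pairwise. `percent_distance` counts substitutions only, over the
shorter ungapped length — the convention under which a 73-substitution
pair of ~16.34 kb genomes is 0.45%. Distances to a genome panel count
substitutions by default with an `include_indels` switch. Region
partition reports counts and 2-dp percentages over
{control region, rRNA+tRNA, protein, other}.

An equal-length sequence pair is diffed column-by-column only when its
mismatches are sparse and isolated (no run > 5, no 8 mismatches within
40 bp); anything denser — the signature of compensating indels — goes
through the global aligner.

## QC and dating

The standard curve is an ordinary least-squares fit of Ct on
log₁₀(copies) (scipy `linregress`); efficiency is 10^(−1/slope) − 1
(so slope −3.391 ⇒ 0.97, and the perfect-doubling slope −3.3219 ⇒
1.00). Quantification inverts the fitted line; replicate Cts give a
mean ± sd. Racemization thresholds default to D/L < 0.10 for aspartic
acid, alanine and glutamine — conventional screening values, surfaced
with the caveat that the approach's utility is debated. Radiocarbon
averaging is unweighted by default (two determinations of the same
horizon), with an inverse-variance option.

Clock calibration conserves rate × divergence-time exactly, reflecting
that the substitution count along the calibration branch is the
measured quantity; the three canonical calibrations (1, 2, 5 My) carry
rates 3.3×10⁻⁸, 1.6×10⁻⁸ and 6.6×10⁻⁹ substitutions/site/year.

The ρ estimator is the mean substitution count from an ancestral
haplotype to each sampled sequence; age = ρ/(μL), with the
star-genealogy variance Σcᵢ/n² giving a ±1.96σ interval. On star
genealogies with the true ancestral, the interval shows nominal
coverage. On coalescent genealogies the ancestral must in practice be
inferred from the sample (here: majority consensus), which subtracts
exactly the high-frequency derived sites from every path and produces
the estimator's well-known downward bias; the test suite demonstrates
both behaviours against simulated genealogies with known ages (msprime
as the coalescent oracle). Ne = θ/(2μg) with generation time g = 7
years treats the mitogenome as haploid and maternally inherited; θ is
supplied externally (no demographic inference is performed here).

## Determinism and problem sizes

All randomness flows from integer seeds through NumPy `Generator`
streams split per amplicon, so read sets are reproducible independent
of iteration order; bootstrap and panel construction are seeded
separately. JSON reports sort keys and round floats to 10 significant
digits, making identical configs byte-identical.

The test suite exercises the full chain on 1.5–4 kb genomes with 12–32
amplicons and median depths 10–93 (a few seconds per scenario), plus
distribution-level checks at 2×10⁴ depth draws and 20-replicate
genealogy simulations; the acceptance script and the analysis scripts
run the complete study-scale configuration (16,338 bp, 130 amplicons,
median 93 reads/amplicon, ~40–60k reads) in about a minute. These sizes
were chosen as the smallest at which each statistical claim is
well-powered.

## Known limitations

Quality scores are ignored throughout (no quality-aware calling); the
consensus model has no genotype likelihoods and no probabilistic
damage correction; the overlap screen reports spectra rather than
estimating a contamination mixture fraction; the vendor mapping of the
original study is replaced by per-amplicon global alignment, which
presumes read-to-amplicon assignment by primers is correct; and
phylogenetic inference (tree building, Bayesian dating, skyline
demography) is explicitly out of scope.
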
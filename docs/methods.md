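# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; conversion happens only at
format boundaries (GTF is 1-based inclusive, BED 0-based half-open). A
3'-end read is reduced to its cleavage coordinate: chromEnd−1 for + strand
records, chromStart for − strand records. Gene biotypes use a fixed
five-label vocabulary (protein_coding, antisense, lincRNA,
processed_pseudogene, other); unknown labels map to "other" rather than
being rejected. Transcript introns are the gaps between a transcript's
exons; a transcript 3'UTR is taken from explicit annotation when present
and otherwise derived as the exonic region 3' of the CDS.

## PAC calling

Reads are deduplicated per sample on (chromosome, strand, position, UMI) —
position only when no UMI is present. Internal-priming artifacts, reads
whose 3' end reflects oligo(dT) annealing to genomic A-tracts rather than a
poly(A) tail, are flagged when the 10-nt genomic window immediately
downstream of the cleavage site (read-strand sense) contains ≥7 A or ≥6
consecutive A; windows beyond a chromosome end are padded with non-A. The
rule is configurable and can be disabled. Surviving positions are pooled
across samples and clustered per chromosome/strand by single linkage with
`max_gap` = 24 nt (a gap of exactly 24 joins); clusters with fewer than
`min_reads` = 2 deduplicated reads are dropped. The 24-nt gap follows the
established 3'-end-sequencing clustering convention; both parameters are
exposed. Each cluster's summit is its modal position, ties broken toward
the most upstream position in transcription direction so results are
deterministic and strand-symmetric. PACs are called once on pooled reads
and then counted per sample; assignment uses the half-open cluster extent,
and read totals are conserved between deduplicated input and
assigned + unassigned output.

## PAS merging and isoform sets

Candidate PASs per gene are annotated transcript 3' ends, optional
"assembled" 3' ends supplied as an extra BED (external transcript assembly
is not reimplemented), and PAC summits. A PAC is assigned to a same-strand
gene whose span, extended 5 kb past its 3' end, contains the summit; when
two loci qualify, the gene with the nearest 3' span end wins and the
ambiguity is logged. Candidates within `merge_window` = 25 nt on a gene
collapse into one PAS whose representative position is the PAC summit when
any member is a PAC (highest-count PAC, ties toward the distal one), else
the most distal transcript end; source sets are unioned. Genes with ≥2
merged PASs form an APA isoform set with PPS = m/(n−1); single-PAS genes go
to a skip list.

## Quantification and differential testing

In `transcript_tpm` mode each transcript maps to the PAS nearest its 3' end
(≤ merge window, else excluded and logged) and PAS abundance is the summed
member-transcript TPM; `pac_counts` mode uses per-sample PAC read counts.
Usage is quantified over the PASs *measurable in the chosen mode*: a PAS
with no mapped transcript (or no PAC) contributes no observation, so it is
removed and ranks/PPS are recomputed over the quantifiable sites — the
usage analysis describes observed isoforms, and unquantifiable sites would
otherwise dilute every position score deterministically. Genes left with
fewer than two quantifiable PASs, and genes below `min_expr` = 1 TPM in at
least one sample of both conditions, are dropped.

ψ is the usage-fraction-weighted mean PPS. Differential testing is a
two-sided Welch t-test on per-replicate ψ (gene level) or usage fractions
(PAS level) with BH adjustment; this deliberately simple, calibrated test
stands in for the bespoke estimators of upstream tools, whose internals are
out of scope — downstream consumers only need (effect, adjusted p). Rows
with zero variance in both groups get p = 1 at equal means and an exact
permutation p over replicate labelings otherwise (at 3 vs 3 the 20
labelings bound p below by 0.1, i.e., such genes are never called). ∆ψ and
∆usage columns clipped at ±0.2 are emitted for plotting only; statistics
always use unclipped values.

## Genomic context

Feature overlap intersects a ±10 nt window around each differentially used
PAS (significant at both gene and PAS level) with its own gene's features;
`cds_or_intron_only` marks PASs touching CDS/intron but neither a 3'UTR nor
a noncoding transcript — the class expected to truncate protein output.
Counts per exact feature combination give UpSet-style tallies. An
independent intronic-PAS assessment takes PACs fully inside an intron of
every transcript of their gene and Fisher-tests (site vs other-PAC reads) ×
(control vs mutant) with replicate counts pooled, BH across sites.

Gene density is the mean edge-to-edge distance (0 when spans overlap,
strand-agnostic, same chromosome) to the k = 10 nearest "expressed and
polyadenylated" neighbors, operationalized as genes passing the expression
filter that own at least one PAC. Gene length is the full span. Context is
related to the expression effect β by Spearman correlation (overall and
within coding/noncoding subsets) and to shift classes
(distal/proximal/unchanged) by two-sided Mann–Whitney tests. Fisher
enrichment (e.g., DE classes among shifted genes) computes the two-sided p
by summing hypergeometric point probabilities ≤ that of the observed table;
odds ratios use the Haldane 0.5 correction at zero cells.

## Sequence scans

MicroRNA sites use the standard canonical seed classes — 8mer, 7mer-m8,
7mer-A1 from microRNA nucleotides 2–8 — counted once per (microRNA,
offset); presence/absence (not hit counts) enters the Fisher tests,
matching the "contains at least one site" framing. Foreground regions run
from the most-used proximal PAS (mean usage over both conditions) to the
most distal PAS with significantly increased (distal-shifted genes) or
decreased (proximal-shifted) usage, sense strand; the background is the
3'UTR of the most distal transcript of expressed, non-shifted
protein-coding genes. K-mer enrichment (k = 6, ±50 nt sense-strand windows
around PASs, truncated at chromosome ends) compares differentially used
PASs of shifted genes against unchanged PASs the same way. DNA alphabet
internally; U↔T normalized on input.

## Differential expression stand-in

Gene TPM is the sum of member-transcript TPM. The effect size is
β = ln((mean mutant TPM + c)/(mean control TPM + c)) with pseudocount
c = 0.5, tested by Welch on ln(TPM + c) with BH; classes are up/down at
adjusted p ≤ 0.05. β is antisymmetric under condition swap. This is a
documented stand-in for bootstrap-variance DE models: every consumer here
reads only (β, adjusted p, class). Biotype summaries compare each
biotype's β distribution against all other tested genes (Mann–Whitney, BH
across biotypes).

## Synthetic data generator

The generator defines the reference study conditions; the defaults are not
tuning knobs. 500 genes on two chromosomes, strands 50/50, placed in
25-gene blocks sharing a density stratum (intergenic gap
10^U(2.2, 4.3) nt with small per-gene jitter) so neighbor-distance
statistics have real structure. Each gene has a 200-nt first exon, an
intron of 10^U(2.3, 3.7) nt, and a last exon carrying 1–5 PASs spaced
200–800 nt apart (80% of genes are multi-PAS; one transcript per PAS, so
the transcript→PAS mapping is exact by construction — many-to-one mapping
is exercised by dedicated fixtures instead). Protein-coding genes get a CDS
so derived 3'UTRs exist.

Planted effects: 100 genes receive a usage shift of |∆ψ| = 0.15 applied as
a proximal↔distal mass shift, with an exact 85/15 distal/proximal
composition (a Bernoulli draw would let the realized distal fraction
fluctuate below the 0.8 recovery margin purely by chance); shifted genes
are drawn preferentially from short/dense genes (weights
exp(−z(log-length)−z(log-gap))) so context comparisons have signal.
Expression is log-normal (σ = 1) with β couplings of +0.25 per SD of log
length and log spacing (short/dense down-regulated) plus biotype offsets
(+0.1 coding, −0.2 noncoding classes). Replicates (3 vs 3): per-replicate
expression noise is log-normal with CV 10%; per-replicate usage fractions
jitter the target ψ by Normal(0, σ_ψ = 0.02) (again a proximal↔distal mass
shift) and then draw Dirichlet(concentration × target). The concentration
default is 2000 so residual compositional noise (ψ SD ≈ 0.011) stays below
σ_ψ and the total replicate ψ noise is ≈ σ_ψ; a concentration near 200
would itself contribute ψ noise ≈ 0.035, swamp the stated σ_ψ, and leave
the Welch/BH call underpowered at ∆ψ = 0.15 with 3 replicates — σ_ψ is the
intended binding noise condition. TPM is normalized to 10⁶ per sample.

3'-end reads: per-PAS counts are Poisson(depth × TPM/10⁶) at 100 000 reads
per sample, positions Normal(PAS, σ = 10) rounded, 8-nt random UMIs. 15% of
genes emit an additional unannotated intronic PAS signal at 5% of gene
reads (equal in both conditions by default — a null for the intronic
test). Internal-priming artifacts are emitted at 5% of reads immediately
upstream of planted intergenic A/T decoy tracts, which the artifact filter
should flag. AATAAA is written 21 nt upstream of PASs with probability 0.8
at shifted-gene PASs and 0.05 elsewhere; an 8mer site of the first
synthetic microRNA is planted between the PASs of 50% of shifted vs 5% of
non-shifted multi-PAS genes. All randomness flows from one seed through
per-stage generators, so truth + abundances can be re-simulated cheaply
without materializing the genome, and all outputs are byte-identical under
a fixed seed.

What the generator does *not* emulate: read-level sequences (FASTQ),
fragment-length/GC bias, many-to-one transcript→PAS structure in the
default config, overlapping genes, alternative last exons with distinct
splicing, or correlated replicate structure. Passing tests therefore show
the estimators are correct and calibrated under the stated noise model,
not that real libraries meet that model.

## Numerical and design choices

- Fisher's two-sided p sums hypergeometric probabilities ≤ the observed
  table's (relative tolerance 1e−7 for float ties); it matches the
  independent SciPy implementation to 1e−12 across exhaustive small tables.
- BH adjustment via statsmodels; NaN p-values pass through untested.
- Summit and merge tie-breaks always resolve toward a strand-symmetric,
  deterministic choice; a mirror harness (reverse-complemented genome,
  mirrored coordinates, flipped strands) asserts ψ invariance end to end.
- Result TSVs are written with a fixed float format, so identical inputs
  and seed reproduce byte-identical files.
- Test problem sizes: unit and property tests run on 40–200-gene
  configurations; recovery and calibration checks use the default 500-gene
  conditions with the file-free truth+abundance path, and the read-level
  null calibration uses 150 genes × 20 seeds at 20 000 reads per sample.

## Known limitations

- The end-to-end ∆ψ recovery check asserts per-gene accuracy (|error| ≤
  0.05 for ≥90% of significant genes) rather than a high rank correlation
  with truth: with a single planted effect size the true values are almost
  all tied, which caps any rank correlation well below 1 regardless of
  estimator quality.
- Under a global null, per-family BH false-discovery indicators are
  Bernoulli(≈α); a 20-seed mean can exceed 0.1 with small probability even
  for a perfectly calibrated test.
- The intronic-site Fisher test pools replicates and therefore ignores
  replicate-level overdispersion; it is intended as a descriptive
  cross-check, not a replacement for the replicate-aware usage tests.
- In transcript mode, PAC-only sites (e.g., novel intronic PASs) are
  reported in the merged annotation but not quantified; quantifying them
  requires `pac_counts` mode or assembled transcripts covering them.
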
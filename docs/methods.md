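# Methods

This note documents the models and procedures implemented in `pirnakit`,
the parameters that matter, the numerical choices, and the limits of what
the synthetic validation shows.

## Scope and conventions

All genomic intervals are 0-based half-open; GFF3 input is converted at
the boundary and BED is native. Sequences are uppercase DNA with U
normalized to T on input, so the "1U" signature is tested as
`sequence[0] == 'T'`. FASTQ quality is fixed at Phred+33 (HiSeq-era
encoding); there is no offset autodetection. Collapsed FASTA headers
follow the `>id_xCOUNT` dialect. Positions in all outputs are 1-based
from the 5′ end, matching the "10A" convention.

## Read QC

Filters run in a fixed order — low quality → high N → 5′ adapter →
missing 3′ adapter/insert → poly-X → length — and each removed read is
attributed to the first filter that drops it, which makes the accounting
identity `input = clean + Σ removed` exact. Thresholds:

| filter | rule | default |
|---|---|---|
| low quality | drop iff #(Q ≤ qmax)/len **>** q_frac | qmax 5, q_frac 0.5 |
| N content | drop iff #N/len **>** n_frac | 0.10 |
| 5′ adapter | ≥ 6 nt prefix match, ≤ 1 mismatch, inside the first len(adapter5) bases | — |
| 3′ adapter | leftmost ≥ 6 nt adapter-prefix alignment, ≤ 1 mismatch; no match or empty insert ⇒ drop | — |
| poly-X | drop iff one base ≥ polyx_frac of the trimmed insert | 0.80 |
| length | keep iff min_len ≤ insert ≤ max_len (inclusive) | 24–33 |

Percentage thresholds are strict (>), length bounds inclusive — boundary
semantics follow the printed rules the cascade reproduces. The poly-X
fraction and adapter tolerances are not standardized anywhere; 0.8 / 6 nt /
1 mismatch mirror common small-RNA trimmers and are exposed as
parameters.

## Candidate calling

Tags are placed at every exact occurrence of the tag or its reverse
complement (a reverse-complement hit at `[s, s+L)` is a minus-strand
alignment there). Placement uses repeated substring search per
chromosome; at the genome sizes this package targets (a few Mb) this is
faster to verify and reason about than an index, and it is cross-checked
against an independent regex scan in the tests. Multi-mapping is kept:
`n_loci` counts all placements, proportion statistics weight each
placement `1/n_loci` (conserving tag mass), and cluster membership uses
unweighted presence.

Only structural ncRNAs (miRNA, rRNA, tRNA, snRNA, snoRNA) are *excluded*,
in that fixed cascade order, by ≥ 1 bp strand-agnostic overlap of any
alignment; removal tallies depend on the order but the surviving set does
not (the filter is conjunctive). Overlap with CDS/UTR/intron/lncRNA/repeat
is *annotated* as origin rather than excluded — candidate piRNAs are
expected to derive substantially from intron, CDS and repeat sequence, so
excluding those classes would contradict the downstream origin analysis.
The candidate rule itself is `1U or 10A`, applied after length selection
(24–33 nt), so position 10 always exists.

Region attribution uses the priority CDS > UTR5 > UTR3 > intron > lncRNA >
repeat > intergenic per alignment; a tag's single reported region is its
highest-priority class across loci. Repeat families are classed by the
prefix before `/` into LINE/SINE/LTR (Class I), DNA (Class II), other.

## Pi-cluster scan

Parameters: `window` 5,000 bp, `max_gap` 20,000 bp, `min_distinct` 10.
Each chromosome is tiled into consecutive windows; a window is marked when
it contains at least one candidate 5′ end (either strand; the 5′ end is
`start` on plus, `end−1` on minus). Marked windows whose start-to-start
distance is ≤ `max_gap` are chained, and a chained region is emitted when
it holds ≥ `min_distinct` distinct tag sequences, with bounds tightened to
the outermost member alignment endpoints and read counts split by strand.
An alternative parameterization (20 kb window, 5 kb shift) is one
parameter change away; the two coincide in the dense-cluster limit. A
`require_both_strands` flag implements the stricter dual-strand reading;
the default counts both strands jointly. The scan is verified against a
brute-force enumerate-mark-merge-threshold oracle, including the exact
20 kb gap and exactly-10-distinct boundaries.

## Ping-pong signature

For a plus alignment `p` and minus alignment `m` on one chromosome with
intersecting intervals, the 5′ overlap is `m.end − p.start` (the canonical
geometry: `p` at [100,128)+ and `m` at [90,110)− overlap by 10). Pairs
with overlap 1–30 accumulate weight — the product of the two tags' read
counts by default, or 1 per pair in `unique` mode. The enrichment score is
`z10 = (w10 − mean(w_k≠10)) / sd(w_k≠10)` (sample sd over the 29 other
bins). A perfectly flat histogram scores 0 by symmetry; any other
zero-variance background leaves z10 undefined and sets a flag rather than
fabricating a score. No threshold is hard-coded for "signature present";
z10 is reported and interpretation left to the user (values above ~3 mark
a clear peak in practice). The sweep implementation (binary search over
plus starts per minus alignment) is tested against the all-pairs O(n²)
oracle.

## Differential expression

Expression is reported as TPM over the quantified tags
(`count/libsize × 1e6`; columns sum to 1e6 exactly). The two-phase test
is an in-package negative-binomial exact-style test:

1. **Size factors** — median-of-ratios over tags with all-positive counts,
   rescaled so the median factor is 1 (a pure scale choice; all downstream
   statistics are invariant to it, and an unperturbed sample keeps
   factor 1). The ratios agree with the DESeq2 reference implementation up
   to that global scale, which a test asserts.
2. **Dispersion** — per-tag method-of-moments α from pooled within-group
   variances of normalized counts (`var = μ + αμ²`), smoothed by a
   centered rolling median across tags ordered by mean (window
   `max(25, n/20)` each side), floored at 1e-8. Pooling across tags of
   similar mean is what makes α usable at n = 6 per group.
3. **Test** — under the null of a common mean, the two group sums are
   modelled as NB with moment-matched dispersion
   (`α_sum = α·Σs_j²/ (Σs_j)²`); the two-sided p-value sums the
   probabilities of all splits of the observed total no more likely than
   the observed split, normalized over all splits. In the Poisson limit
   (α→0) this reduces exactly to the conditional binomial split test,
   which a test asserts against a closed-form oracle.
4. **Screen** — `p < 0.05`, fold change > 2 in either direction (strict),
   and the larger group mean raw count > 10 (strict), applied jointly; no
   multiple-testing correction enters the screen (a Benjamini–Hochberg
   column is emitted for users). log2 fold changes use normalized group
   means with a 0.5 pseudocount; "counts > 10" is read as the larger group
   mean because per-sample and total-count readings are both defensible
   and the mean is scale-robust — it is exposed as `count_min`.
   Direction is always reported as `up_in_<phase>` to avoid the ambiguity
   of "up/down-regulated" labels between two phases.

Under a null NB simulation (2,000 tags, 6 vs 6, α = 0.1) the realized
p < 0.05 rate sits near 5–6%, and with a planted |log2FC| = 2 in 20% of
tags the screen reaches sensitivity ≈ 1 with false-discovery proportion
below 1% and mean absolute log2FC error ≈ 0.22 — these are recomputed by
the test suite and `scripts/acceptance.py`, not quoted.

The `2^−ΔΔCt` helper computes ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = mean ΔCt(group) − mean ΔCt(calibrator), and relative expression
`2^−ΔΔCt` (calibrator ≡ 1).

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the study conditions: 2 phases × 6 replicates;
24–33 nt tags with probability peaks at 24 nt (0.20) and 27–29 nt
(0.14/0.15/0.13); `frac_1U = 0.8` (the ">75% start with uracil" regime);
region mix dominated by intron/CDS/repeat (0.30/0.20/0.20) with minor
UTR/lncRNA shares; LINE-dominated TE mix (0.45); ping-pong partner rate
0.5; NB counts with mean 30 per tag per sample and dispersion 0.1; a 20%
DE fraction at log2FC = 2. Where the emulated study reports no value
(e.g. per-filter defect rates, contaminant counts), defaults are set once
at realistic small-RNA magnitudes and documented in the dataclass.

Mechanics worth knowing:

- Clusters are placed in disjoint reserved intervals separated by ≥ 25 kb,
  the minimum that guarantees two planted clusters can never chain under
  the 5 kb/20 kb scan; placement samples free gaps directly (weighted by
  capacity) with a deterministic fallback across chromosomes, so dense
  configurations pack reliably.
- The 1U/10A signature is planted by editing genome bases before the
  genome is finalized, so truth-table sequences align exactly. Non-1U
  primaries receive a 10A rescue, keeping every planted tag a candidate
  and making the realized first-base U fraction an unbiased Bernoulli
  estimate of `frac_1U`. Tags within a cluster may overlap, so a later
  edit can occasionally flip an earlier tag's signature base (≲0.5% of
  tags at default densities); tests allow for this.
- Ping-pong partners are antisense tags whose 5′ end sits exactly 10 nt
  into their primary. Complementarity couples the signatures: a 1U primary
  implies a 10A partner and a 10A-rescued primary implies a 1U partner.
  Consequence: partners dilute the pooled first-base U fraction below
  `frac_1U` (at rate 0.5 and frac_1U 0.8, the pooled expectation is
  ≈ 0.67), so frac_1U recovery is validated on partner-free simulations
  and the pipeline reports the pooled value it actually measures.
- DE fold changes are one-sided: the up-phase keeps the base mean and the
  other phase is scaled by `2^−log2fc`. Large log2fc values therefore
  produce genuinely phase-specific clusters (used to validate the FP/LP
  cluster comparison); a symmetric ±lfc/2 split would leave the "off"
  phase expressed.
- Raw FASTQ emission assembles insert + 3′ adapter + random fill into
  50 bp reads and plants QC defects per read. Every constructed read is
  verified against the package's own QC cascade and re-drawn until its
  realized class matches the intended one; if a tag's own sequence makes
  the intended class unreachable, the realized first-failing class is
  recorded in the truth table instead, so truth is exact either way.
  `random_clean_tags` rejection-samples tag sequences that would
  intrinsically trip a filter (chance 5′-adapter-like prefixes occur in
  ~0.7% of random reads).

What passing tests show: the implementations recover exactly the
structures the generator plants, at the study's design size, and agree
with independent oracles on constructed inputs. What they do not show:
robustness to sequencing error, non-uniform genomic background
(GC/repeat structure of a real 2.6 Gb genome), imperfect annotations,
bowtie-style mismatch alignment, or library-preparation biases — none of
which the generator models. Absolute tag/cluster counts from the emulated
study are functions of its sequencing depth and genome and are not
reproduction targets at this scale.

## Determinism and problem sizes

All randomness flows from a single seed through named substreams
(`default_rng([seed, k])`), so reruns are byte-identical, including TSV
output. The default synthetic scale — 3 × 500 kb chromosomes, 30
clusters, ~1,200 tags, 12 samples — was chosen so a full pipeline run
takes seconds and the complete validation (test suite + acceptance
script) a few minutes, while every statistic still operates in its
intended regime (hundreds of tags per phase, ≥ 10 distinct tags per
cluster, counts in the tens). Thread counts never affect results; the
implementation is single-threaded.

## Known limitations

- Exact matching only; no mismatch-tolerant alignment.
- The NB test conditions on raw group sums, so p-values are only
  approximately invariant to rescaling a single library (fold changes are
  invariant up to size-factor re-estimation).
- `z10` has no attached p-value; it is a descriptive enrichment score.
- The cluster scan is threshold-based, not probabilistic; expression-
  normalized cluster calling is out of scope.
- SAM ingest accepts only pure-match CIGARs with NM = 0; BAM/CRAM are not
  written.
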
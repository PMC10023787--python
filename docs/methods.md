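# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the simulation-based tests do and do not establish.

## Encoding architecture and hybridization model

The trio-pharmacophore library is held together by four anchor strands:
the SL-A strand, two SL-B strands (left and right, bridged through the
displayed linker compound) and the SL-C strand. The declared duplex
specification is

| duplex | length (bp) |
| --- | --- |
| SL-B internal, short + long | 6 + 12 |
| SL-A : SL-B(left) | 33 |
| SL-B(right) : SL-C | 13 |
| SL-A : SL-C | 6 |

`design_anchor_set` realizes these lengths by embedding complementary
segments in otherwise random strands (seeded rejection sampling, bounded
at 500 attempts). A candidate is accepted only when every declared pair
reproduces its length *exactly* under `longest_complementary_run`, the
short internal duplex exists as a separate run, unintended cross-pairs
stay below a 6 bp spoiler threshold, and the three per-channel read flanks
are pairwise ≥ 4 mismatches apart.

Hybridization stability is modeled as *longest contiguous perfect duplex ≥
threshold* (default 10 bp), with no nearest-neighbor thermodynamics. The
assembly evidence this has to reproduce is qualitative — a 6 bp overlap
does not hold two sub-libraries together while 13 bp does — and the
contiguity cutoff reproduces that pattern for every threshold in 7–13 bp
with a single parameter. Secondary structure and cross-hybridization free
energies are out of scope; real anchor sequences can be supplied via FASTA
and validated with the same machinery.

## Codes, indexes and the read layout

Codebooks are built by seeded rejection sampling with a minimum pairwise
Hamming distance (default: length 12, distance ≥ 3; up to ~1000 codes this
accepts nearly every draw). Distance ≥ 3 with a 1-mismatch assignment
budget guarantees unique correction of any single substitution; the
decoder precomputes the 1-error neighborhood of each codebook for O(1)
assignment.

The read layout is `[sample index (8 nt)][constant flank (10 nt)]
[code (12 nt)][tail (10 nt)]`, 0-based half-open coordinates in sequencing
orientation (a flag handles reverse-complemented layouts). The actual
amplicon layout of a given sequencing protocol is a free design choice, so
the package defines this default and records it in the design file; the
constant flank doubles as the channel identifier because each read carries
exactly one sub-library's code. Code and index lengths are config values.

## Binding and selection model

One selection is a single probabilistic capture round. Capture weight:

* target: `W(a,b,c) = β + w_a[a] · w_c[c] · l_b[b]`
* no-target (blank support): `W = β`
* no-ligand (unmodified flanking strands): `W = β + ε_direct · l_b[b]`

with background `β = 1`, direct linker–target contact `ε_direct = 0.1`.
The multiplicative `w_a·w_c·l_b` term encodes avidity between the flanking
fragments modulated by the linker; no quantitative binding model exists
for this chemistry, so the form is a declared choice kept behind the
`BindingModel` interface. Random models draw log-normal weights with
median 1: σ = 1.0 for fragments (diverse libraries span orders of
magnitude in affinity) and σ = 0.5 for linkers (modulators, not primary
binders). Affinity-maturation runs instead fix the flanking weights at a
known-ligand strength (`ligand_weight`, default 2.0) and vary only the
linkers, which is what that experiment does.

Two sampling operations serve two different readouts:

* `simulate_selection` — the *composition* of a fixed-size pool:
  `post ~ Multinomial(N, p ∝ abundance · W)`. Sequencing normalizes totals
  away, so this is the right model for NGS count data. The pre-selection
  pool is itself a multinomial sample so the pre channel carries sampling
  noise.
* `simulate_capture` — *absolute yields*: each input copy is retained
  independently with probability `capture_rate · W` (binomial, default
  rate 0.01). qPCR measures absolute eluted amounts, and the hallmark
  control result — the whole linker sub-library elutes more strongly with
  ligand-bearing flanks than without, and both exceed background — lives
  in the totals, which a fixed-size multinomial cannot express.

Pre-selection abundances default to uniform: every conjugate is purified,
so near-equimolar assembly is the realistic baseline. One round only; the
protocol performs single-round selections.

## Sequencing and qPCR simulation

Reads are strand-wise: each pool member contributes one read per channel
per pool copy (optionally resampled to a target depth), so the three
channels are decoded independently — there is deliberately no code-joining
mechanism, matching the encoding. Errors are substitution-only with
independent per-base probability ε (default 0.005), applied vectorized;
quality is constant Phred 40. Indels, PCR amplification bias and
paired-end layouts are not modeled, which is consistent with the
Hamming-only decoder; if indels mattered in real data the anchored
code-extraction mode (flank search) would mitigate but not eliminate them.
Read names carry the true source id so per-read accuracy is auditable.

qPCR: `Ct = slope · log10(q) + intercept + N(0, noise_sd)` with defaults
slope −3.3219 (100% efficiency), intercept 30, noise 0.2 Ct. Standard
curves are ordinary least squares of Ct on log10(quantity); per-code
curves are supported (code-specific primers can differ in efficiency) with
fallback to a shared curve. Amounts below the calibrated range are flagged
as extrapolated; non-positive simulated amounts are flagged
`below_detection`, never silently NaN. Control-normalized ratios floor the
control at 0.1 × the smallest calibrated standard, and floored codes are
flagged.

## Decoding policy

Index, flank and code matching are all Hamming-nearest-unique within a
mismatch budget (defaults: index 1, flank 1, code 1 when the codebook
distance is ≥ 3). Ties always resolve to an explicit `ambiguous` tally and
near-misses to `no_index`/`no_code`; nothing is dropped silently and
conservation (reads in = assigned + rejected) holds by construction and is
asserted in tests. Decoding is a single streaming pass with constant
memory in the number of reads; gzip input is transparent.

## Enrichment statistics

Folds use the smoothed estimator
`((post_i+α)/(T_post+αM)) / ((pre_i+α)/(T_pre+αM))` with α = 1 by default
for NGS counts (zero pre-counts are expected at realistic depth) and α = 0
for qPCR amounts. With α = 0, a zero pre-count gives an infinite fold,
which is kept, flagged and sorted above all finite folds. Ranking breaks
fold ties by post-count then id so runs are reproducible. The
pre-fraction-weighted mean fold equals 1 at α = 0 (probability-mass
conservation), which serves as an invariant test.

Percentiles in `mw_statistics` use linear interpolation between closest
ranks; for small compound sets (e.g. 45 resynthesis candidates) the upper
percentiles depend on this convention and on which mass column (free base
vs salt) the user supplies. Combined masses are additive with an optional
linkage correction (e.g. 2 × 18 Da water loss); chemically correct
enumeration of fused structures is a non-goal.

## Problem sizes and determinism

Default simulations run at desk scale — 50 × 10 × 50 libraries, pools of
2 × 10⁵–10⁶, one read per pool copy per channel — mirroring the
883 × 30 × 890 architecture whose enumeration stays lazy (the full 23.6 M
member iterator is never materialized). Every stochastic operation takes a
mandatory seed; pipeline stages derive their seeds from the one run seed,
and the manifest records config hash, seed and version so a run is
reproducible byte-for-byte from the manifest alone.

## What the synthetic data does not show

The generator emulates barcode structure, sampling noise, substitution
errors and control selections; it does not emulate PCR bias, indels,
quality-score structure, chimeric reads, synthesis truncations or
target-specific chemistry. Passing the recovery tests therefore shows the
*decoding and statistics* are correct and well-calibrated under the
declared noise model — not that any particular real selection will rank
binders this cleanly. Enrichment significance testing is out of scope
(none is performed in this workflow); folds are descriptive statistics.
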
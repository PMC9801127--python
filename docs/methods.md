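# Methods

## The measurement model

A Watson–Crick-face methylation (m¹A, m¹G) on a tRNA perturbs reverse
transcription in two ways: with some probability the RT writes a
non-templated base into the cDNA at the modified position
(*misincorporation*), and with some probability it terminates there
(*RT stop*). Sequencing the cDNA library therefore converts modification
level into two observables: an elevated per-position mutation rate, and a
deficit of reads covering positions 5′ of the stop (cDNA synthesis primes
on the 3′ adapter and runs 3′→5′ along the tRNA, so a stopped read retains
the tRNA's 3′ side).

The quantity of interest at a monitored position is the mutation rate

    M_rate = Read_Mutant / Read_Total

computed independently in the enzyme-treated and the untreated sample and
background-corrected as `max(0, M_rate(treated) − M_rate(untreated))`.
The subtraction removes sequencing error and any pre-existing RT signal;
clamping at zero reflects that a negative modification level is
meaningless. Because the misincorporation probability of a strong m¹A-type
signature is below 1 (default 0.79 here), M_rate is a *proxy* for the
methylated fraction, linear in it but scaled by the signature strength —
which is why relative comparisons (variant vs. wild type, tRNA vs. tRNA)
are the meaningful readout.

## Two callers, and why both exist

**Alignment-based profiling** handles a pool of distinct references: each
adapter-trimmed read is aligned semi-globally (free end gaps on the
reference) against every reference and assigned to the best score.
Scoring defaults are match +1, mismatch −1, gap −2 (linear), minimum
accepted score 0.6 × read length; ties between references leave the read
unassigned rather than guessed. Mutation events are mismatches plus
deletions; insertions are tallied but excluded from the rate numerator by
default, since the signals of interest are misincorporations (a flag
restores them). The alignment engine is edlib (Myers bit-vector edit
distance); scores under the match/mismatch/gap scheme are re-derived from
the optimal edit path. Candidate references are pre-screened by edit
distance: under the default scoring a reference can only outscore the
closest one if its distance is below 1.5× the minimum, so alignments
outside that band are skipped.

**Exact-sequence counting** handles a single-point variant library, where
alignment is hopeless: every member differs from every other by one base,
so near-ties are the rule, not the exception. Instead, each variant
contributes four full-length query sequences — one per base at the
monitored target position — and a read counts for a query it contains
verbatim. Query sets of distinct variants are provably disjoint (each
query carries the variant's own substitution), so counting is
unambiguous; the ambiguity tally is still reported as a safety check.
Exact matching discards reads with an error anywhere inside the query,
which lowers Read_Total (about 9% at error rate 0.001 over ~90 nt) but
does not bias M_rate, because sequencing errors are position-independent.
A rate is reported only when Read_Total ≥ 100 (configurable); below that
the variant is flagged undefined rather than given a noisy number.

Both callers are run on the same simulated pool in the acceptance script
and agree with r² > 0.99, which is the package's internal
cross-validation of the two routes.

## Thresholds

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 1000 | per-position depth floor; below it a position is missing, and a reference with no surviving position is "not analyzable" |
| `site_threshold` | 0.01 | subtracted rate strictly above ⇒ modified site / substrate call |
| `loss_threshold` | 0.05 | subtracted rate strictly below ⇒ variant lost activity |
| `min_total` | 100 | Read_Total floor for a defined M_rate |

All comparisons are strict inequalities; rates exactly at a threshold fall
on the conservative side (0.01 → not called, 0.05 → retained). The depth
floor applies per position, not per reference, so a poorly reverse
transcribed tRNA yields a partial profile (3′ side present, D-arm
missing) instead of disappearing entirely.

## The simulator

Per read: (1) draw a reference by pool abundance; (2) in treated samples,
decide modification status from the member's modification fraction;
(3) for modified molecules, walk the signature positions in RT order
(3′→5′): stop with `stop_rate` (truncating everything 5′ of the stop) or
misincorporate with `misincorporation_rate`, drawing the written base from
the substitution spectrum (uniform over the three non-templated bases by
default — the true spectrum of m¹A under TGIRT is not modelled);
(4) apply uniform substitution sequencing error (default 0.001/base);
(5) append the 3′ adapter (`CTGTAGGCACCATCAAT`) and emit at constant Q37.
The accompanying truth table records the implied per-position mutation
rate, `p·(1 − e/3) + (1 − p)·e` with `p` the marginal misincorporation
probability and `e` the error rate (the `e/3` term is error reverting a
misincorporated base to the templated one).

What it deliberately does **not** emulate: indel sequencing errors (the
statistic is substitution-based), PCR duplicates, circularization
artifacts, quality-score variation, or a realistic m¹A substitution
spectrum. Passing tests therefore demonstrate that the *estimators* are
correct under the stated generative model, not that the pipeline is
robust to every artifact of real libraries; the alignment stage, however,
is exercised with indels and error rates up to 5% in the unit tests.

Synthetic reference pools (`random_trna_pool`) are random sequences with
tRNA-like length (70–95 nt), a G start, a CCA end, the target base fixed
at the monitored label, and a coarse fixed element layout. They are
labelled synthetic throughout; no real gene sequences ship with the
package.

Reproducibility contract: one integer seed drives all randomness
(`random.Random` for read draws, `numpy` Generator for rate draws), and a
fixed seed yields byte-identical FASTQ. Pipeline stages derive
independent sub-seeds from the master seed by hashing the stage name.

## Library design and cassettes

The variant designer enumerates 3 substitutions per mutable position in a
deterministic order (position index, then A<C<G<U), naming variants
`<wt><label><new>` in the RNA alphabet. The default mutable set is every
position except the monitored target and the three CCA nucleotides — for
an 84-position tRNA that gives the canonical 240-variant library. Which
positions to mutate is always overridable, since real screens exclude
positions for experimental reasons the sequence alone cannot predict.
Position labels are free-form annotation strings (insertion labels such
as `20a`, `45b` are just labels); automatic Sprinzl alignment is out of
scope.

Transcription cassettes are T7 promoter + coding sequence + a constant
38-nt tail whose BsaI module lets digestion terminate the template at the
CCA codon. A 5′ G is prepended when the tRNA does not start with G (T7
initiates on G); `predicted_transcript` returns exactly the RNA that
run-off transcription of the digested template yields, so the cassette
builder is testable without touching an enzyme.

## Kinetics and downstream statistics

Michaelis–Menten parameters are fit by bounded nonlinear least squares on
the untransformed data; no Lineweaver–Burk linearization is used anywhere
(reciprocal transforms inflate low-velocity noise and bias both
parameters). Initialization is Vmax₀ = max(v), Km₀ = the concentration
whose velocity is nearest Vmax₀/2; both parameters are bounded positive,
the problem is rescaled by the initial guess and solved to tight
tolerances (noiseless data refit to better than 4 significant digits).
Non-convergence is a flagged result, not an exception, and a fit whose Km
standard error exceeds half the estimate is flagged non-identifiable —
the typical failure of an all-saturating concentration design. Negative
velocities are clipped to zero with a warning.

Method-agreement plots use ordinary least squares with r² = 1 −
SS_res/SS_tot. Replicate group comparisons use Welch's two-sample t-test
(two-sided): with n = 3 per group and no reason to assume equal
variances, Welch is the defensible default; a permutation test
cross-checks it in the test suite.

## Problem sizes

The acceptance script simulates 20 references × 50,000 reads per sample
(1M reads per sample, two samples) for the caller-agreement check, and
6 concentrations × 3 replicates for each kinetic recovery; the recognition
screen in the test suite runs the full 240-variant library at ~1,200 reads
per variant. These sizes put every binomial standard error well below the
decision thresholds while keeping a full run in tens of seconds on one
core. Duplicate reads are collapsed before alignment and counting — for
low-diversity tRNA pools this reduces the work by one to two orders of
magnitude and is exact, not an approximation.

## Known limitations

- Exact counting requires full-length queries to appear in reads; heavy
  RT stopping between the 5′ end and the target position removes those
  molecules from Read_Total, so stop-rich signatures should be quantified
  with the profiler (windowed queries are a possible extension).
- The profiler's tie rule discards reads equidistant from two references;
  for pools containing near-identical members this deflates depth rather
  than risking misassignment.
- M_rate saturates at the signature's misincorporation probability, not
  at 1; absolute methylation stoichiometry requires an external calibration
  of the signature strength.
- Untreated-sample subtraction assumes the untreated library shares the
  treated library's error structure; batch effects between the two
  libraries are not modelled.
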
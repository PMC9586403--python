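# Methods

## The assay being modelled

A plasmid cassette carries, in order: a loxP site with a mutant right RBE, a
24-bp marker tag B, a wild-type lox2272 site, a stuffer, a second loxP copy
with the *same* mutant RBE, marker tag A, and a second lox2272 site. Cre
excision between the loxP pair removes tag B; excision between the lox2272
pair removes tag A; the two events are mutually exclusive on one molecule
because loxP and lox2272 spacers are incompatible. Sequencing the cassette
after Cre induction therefore reads out, per molecule, both the variant
identity (the 13 bases after the 21-bp loxP anchor = left RBE + spacer) and
the outcome (which tags survive). The per-variant cleavage rate —
loxP excisions as a percentage of all excisions — measures the variant's
residual recognition by Cre in direct competition with a wild-type pair, so
the wild type sits at 50% by symmetry.

Both loxP copies carry the identical variant RBE. This is a structural
assumption of the simulator: it is the only arrangement under which the
variant identity survives all three outcomes (in particular lox2272
excision, which deletes one loxP copy), and hence the only one consistent
with a per-variant three-way tally. Element order was chosen so tag A
survives only loxP excision and tag B only lox2272 excision; only that
decision logic is contractual, not the exact coordinates. The uncleaved
amplicon is 224 bp, so a 2×150 pair covers it fully; excision products are
112 bp.

Spacers are written on the top strand as ATGTATGC (loxP) and AAGTATCC
(lox2272); variant listings elsewhere often print the loxP spacer as its
bottom-strand reading GCATACAT. The wild-type right RBE on the top strand is
TATACGAAGTTAT (the reverse complement of the left RBE ATAACTTCGTATA, since
the two arms are an inverted repeat); all substitution counts in the
packaged reference table verify against it.

## Library design model

Doped synthesis keeps the wild-type base at each of the 13 positions with
probability x/100 and substitutes uniformly among the other three bases
otherwise. Substitution counts are Binomial(13, 1 − x/100). The default
retention rate is x = 84.7% (each alternative base at 5.1%), which puts the
mode at 2 substitutions (P ≈ 0.294) — the yield-maximizing choice for double
mutants. The k-substitution class contains C(13,k)·3^k sequences (39 singles,
702 doubles); coverage is reported as the percentage of a class observed.
Explicit class enumeration is only materialized on request, since class size
grows exponentially; the analyses enumerate k ≤ 2.

## Synthetic data generator

The generator defines the simulated study conditions:

- depth: 2000 molecules per variant (one read pair per molecule);
- outcome draw: Multinomial(n; p_nc, (1−p_nc)·p, (1−p_nc)·(1−p)) with
  non-cleavage probability p_nc = 0.035 (the induced steady state) and
  per-variant loxP share p;
- reads: 2×150, mate 1 from the amplicon 5′ end, mate 2 the reverse
  complement of the 3′ end, constant Phred 37, i.i.d. substitution errors at
  a configurable rate (default 0; indels and chimeras are out of scope);
- marker tags, flanks and stuffer are drawn once per run, rejected if they
  contain a lox anchor or left-RBE substring, and recorded in markers.yaml;
- output is byte-identical for a fixed seed.

Where no measured rate is available, the default truth model assigns
p = 0.5·exp(−0.18·k) with lognormal jitter (σ = 0.15) clipped to
[0.005, 0.60]: 0.5 for the wild type by symmetry, ≈17% at k = 6, spanning
the 0.5%–60% dynamic range the assay resolves. The packaged 50-variant
reference table provides measured rates (17.3%–34.6%) for realistic
simulations. The decay constant and jitter are descriptive conveniences, not
fitted quantities.

What the generator does *not* emulate: PCR amplification bias, quality-score
structure, adapter read-through, chimeric molecules, or library
representation skew. Passing recovery tests therefore demonstrates the
correctness of the classification and estimation logic under multinomial
sampling noise, not robustness to those real-data artifacts.

## Read classification

Matching is exact (0 mismatches) against the 21-bp anchor and the 24-bp
marker tags, on both mates and their reverse complements. Design choices:

- Variant extraction requires all complete anchor hits within a pair to
  agree; discordant duplicates are dropped as extraction failures rather
  than voted, the conservative treatment of a likely sequencing error. Hits
  too close to a read's 3′ end to yield a full 13-mer are ignored.
- The read-count cutoff is strict: a variant is flagged reliable only when
  its pair count exceeds 500; a tie at exactly 500 fails.
- Unclassified pairs (neither marker found) are excluded from both rate
  denominators; only the three informative classes enter rates. Pairs whose
  denominator is empty yield an undefined rate (NaN in the table), never 0.
- Coordinates are 0-based half-open internally; user-facing positions are
  1-based. TSV output rounds rates to 1 decimal; full precision is kept in
  memory.

Raising the substitution error rate strictly inflates extraction failures
(exact-match anchors) — a monotone, visible degradation rather than silent
bias.

## qPCR validation path

Three assays per sample (intact cassette, loxP junction, lox2272 junction)
are each calibrated against their own 7-point 10-fold dilution series
(1e7 → 1 copies/µL) by least squares of Cq on log10 copies; efficiency is
10^(−1/slope) − 1. Replicates are averaged on the copy scale, not the Cq
scale, because the reported rates are ratios of copies. The rate algebra is
identical to the sequencing route and invariant to rescaling all three
assays, so absolute calibration cancels out of the rates. Synthetic Cq
values add Gaussian noise of 0.15 cycles. Concordance between routes is the
squared Pearson correlation of cleavage rates; validation runs use nine
variants spanning the dynamic range plus the wild type, averaged over two
simulated experiments. A Welch two-tailed t-test utility contrasts
non-cleavage rates with induction off (p_nc ≈ 1) versus on.

## Numerical and statistical choices

- All randomness flows through `numpy.random.default_rng` from a single
  integer seed per entry point; seeds and a config digest are stamped into
  every output file.
- Group comparisons use Welch's (unequal-variance) two-tailed t-test;
  adjacent substitution classes with fewer than two members are skipped.
- Goodness-of-fit of sampled libraries pools expected cells below 5 before
  the chi-square test.
- Estimates tables sort by ascending cleavage rate with a stable sort, NaN
  rates last.

## Problem sizes

The test suite simulates up to 120 variants at depth 2000 (240k read pairs)
for recovery and 50 variants at depth 2000 (100k pairs) for the
classification-oracle check; analysis drivers use the same scales. These
sizes give per-variant binomial standard errors near 1 percentage point,
small against the 0.5%–60% signal range.

## Known limitations

- Exact-match classification discards any read with an error inside the
  anchor or marker; throughput, not accuracy, degrades with error rate. A
  mismatch-tolerant mode would trade that conservatism for depth.
- The simulator draws one read pair per molecule; real amplicon libraries
  oversample molecules through PCR, so real depths are not independent
  draws.
- The affinity-decay truth model is a plausible stand-in, not a fitted
  biophysical model; conclusions about real variants should rest on the
  measured reference rates.
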
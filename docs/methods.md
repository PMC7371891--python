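# Methods

## Model

The package treats the somatic mutation catalog as the outcome of two
superimposed processes: a background mutagenesis process whose per-site rate
depends on the nucleotide substitution route and the ±2 flanking bases, and
a selection process that enriches functionally consequential events in
cancer samples. The background is summarized non-parametrically: each of
the 3072 (pentamer, alternate base) classes gets an empirical tendency

r_c = n_c / (s_p × N),

with n_c the class's mutation count in the catalog, s_p the number of sites
of the class's pentamer per coding genome, and N the number of cancer
genomes surveyed. No mutational-signature decomposition is attempted and no
per-sample rate heterogeneity is modeled; the tendency is a cohort-average
rate. Relative difficulty inverts tendencies against the easiest class,
D_c = r₀/r_c with r₀ = max_c r_c, so difficulties are scale-free in both
catalog depth and cohort size (multiplying all counts, or N, by a constant
leaves every D_c unchanged).

Selection is handled in two complementary ways. Upstream, events recurring
in more than five distinct samples are removed before tendency estimation
(the recurrence filter), because selection-enriched counts would masquerade
as high background rates. Downstream, the residual recurrence of an event
after difficulty correction — the revised count R = Σ_t O_t × D_{c,t} — is
read as evidence of selection, hence of functional impact.

## Assumptions

- The coding strand as annotated is the frame of reference; C→T and G→A are
  distinct classes and no reverse-complement collapsing is done. This keeps
  strand-asymmetric processes (e.g. transcription-coupled repair) visible.
- A ±2 context window captures the sequence dependence worth modeling;
  effects beyond the pentamer are averaged away.
- At most one count per sample per event: recurrence counts samples, not
  calls.
- Context-site denominators count 5-mer windows fully inside the CDS, while
  numerator contexts at CDS-edge sites may use genomic flank sequence when
  supplied. The two are therefore very slightly inconsistent at gene edges;
  the effect is a handful of windows per gene and is deliberately retained
  rather than papered over, because the denominator definition ("sites per
  coding genome") is part of the method's contract. One published worked
  example attributes the same ~200-fold difficulty to two different
  pentamers in different places (ACATC in one, CGATG in another — not
  reverse complements); the arithmetic here is generic and does not
  privilege either.

## Parameters

| parameter | default | meaning |
|---|---|---|
| recurrence threshold | 5 samples | events with O > threshold are excluded from tendency estimation only; 10/20/∞ reproduce the threshold sensitivity comparison |
| zero policy | `undefined` | classes with n_c = 0 are flagged and refuse lookups; `pseudocount` (α = 0.5 added to n_c) gives every sited class a finite difficulty |
| wt_max / lof_min | 700 / 900 revised counts | strict inequalities; the band [700, 900] is indeterminate. Both are tied to catalog scale (≈26k genomes) and should be recalibrated on other catalogs |
| calibration percentile | 95 | wt_max as a percentile of the synonymous revised-count distribution; synonymous events above it are reported as outliers (possible splice disruptors), not silently absorbed |
| min_samples (per-type tables) | 100 | cancer types with fewer samples fall back to the pan-cancer table; per-type rate estimates below this depth are too noisy to improve on the pooled table |
| neighbor window (shield) | 2 residues | recoding a codon can only perturb contexts within 2 nt, so ±2 codons bounds the reach exactly |

Difficulties are kept at full floating precision internally; report files
carry full precision and rounding is left to presentation.

## Revised counts and classification

Revised counts use *all* events, including recurrent ones — only tendency
estimation sees the filtered catalog. Per-type difficulties are used where
a type has its own table, the pan-cancer table otherwise. Classification is
monotone in R by construction. Events whose protein change is also produced
by a multi-nucleotide substitution in another sample are unscored unless
the SNV-derived R already exceeds lof_min: no difficulty is ever assigned
to a double substitution, so prediction is refused rather than guessed.
MNV records pass through the recurrence filter untouched and never enter
tendency estimation; their only role is setting this support flag (which
requires a genome, since matching is at the level of the translated
amino-acid change).

## Codon shielding

Shielding compares summed *tendencies* (rates), not difficulties: "chance
of generating" is a rate-space statement, and summing rates over the ≤ 9
SNVs of a codon that produce target amino-acid changes gives a quantity
proportional to the expected number of such events per cohort. The target
set of deleterious amino acids per residue is user input (e.g. everything
the revise step labels `lof`, or a literature list); the package does not
hard-code any gene's LOF spectrum. For candidate codons the whole sequence
neighborhood is recoded before context extraction, so both the mutated
position's class and the contexts of neighbors within 2 nt shift
accordingly; neighbor impact is reported as the change in each nearby
residue's own deleterious tendency sum (default target set: any amino-acid
change, including nonsense). T₁ = 0 is reported as complete shielding
rather than an infinite fold change being propagated into arithmetic.

## Synthetic data

The generator emulates the statistical structure the estimator assumes:
i.i.d. bases at a chosen GC content (default 0.41, coding-genome-like),
per-site-per-sample Bernoulli mutation with probability
rate(class) × type burden, and driver spiking with a per-sample enrichment
probability. Defaults fix the desk-scale study conditions used throughout
the tests: 10 genes × 3 kb = 30 kb of coding sequence, two cancer types of
100 samples each with burden multipliers 1 and 3 (hypermutating types run
several-fold hot in real cohorts), base rate 2 × 10⁻⁴ per site per sample,
and a 10× multiplier for C→T classes, mimicking the dominance of
deamination-driven transitions. These per-sample rates are orders of
magnitude above real somatic rates; they are chosen so that a 200-sample
desk-scale catalog yields class counts with usable signal-to-noise, while
leaving per-event recurrence low enough (mean O < 1) that the recurrence
filter removes essentially nothing from the background — the same regime,
rescaled, as a 26k-genome catalog at real rates.

What the generator does *not* emulate: signature mixtures and per-sample
burden heterogeneity within a type, indels, regional (replication-timing,
expression) rate covariates, and sequencing/calling artifacts. Passing
tests therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to real-data violations of them.

Randomness is split with `SeedSequence.spawn` into independent genome,
catalog and injection streams, so the genome is byte-reproducible from the
seed regardless of what is simulated on top of it.

## Numerical choices

- Isoform resolution: "major isoform" is taken as the longest CDS unless a
  canonical-transcript list says otherwise; ties break to the
  lexicographically smallest record id for determinism.
- Undefined classes (pentamer absent from the coding genome, or zero count
  under the default policy) raise on lookup with an actionable message
  rather than returning NaN into downstream sums.
- Percentile calibration uses linear interpolation between order statistics
  (numpy default); with ≥ 20 events the choice of interpolation rule moves
  wt_max by less than the sampling noise.
- The resistance index is undefined at G₁ ∈ {0, 1} and G₂ = 1 (zero
  denominators); these are rejected, not clamped.
- Catalog parsing accepts HGVS-style `c.NNNX>Y` and `c.N_MXX>YY` strings;
  indels and unparseable strings are skipped and counted, never guessed.

## Limitations

- Difficulty tables inherit the catalog's ascertainment: thresholds
  calibrated on one catalog snapshot (700/900 here) do not transfer to
  catalogs of different depth without recalibration.
- Per-type tables for sparse cancer types are noisy; the min_samples
  fallback trades type specificity for stability.
- A published residue-level example multiplies an original count by a
  single difficulty index yet reports a slightly different revised count
  than that product; revised counts here are always the cancer-type-weighted
  sum, and no single-index product identity is assumed.
- Synonymous-outlier flagging does not annotate splice sites; outliers are
  listed for manual review only.
- The shield module ranks candidates by rate reduction at the recoded site;
  it does not model codon-usage or mRNA-structure consequences of recoding.
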
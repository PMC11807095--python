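# Methods

## The measurement model

The unit of analysis is a short (default 200 bp) amplicon of the mutant
allele on the sense strand, carrying a G>A premature-stop mutation whose
transcript adenosine is the editing target. All other reference adenosines
are potential bystander-deamination sites; site labels `A_k` are 1-based
ordinals over the sense-strand adenosines, and coordinates are 0-based
half-open internally.

At each adenosine *j*, the editing rate is estimated as

    r_j = n_G / (n_A + n_G)

over quality-filtered, aligned reads. Non-A/G calls are excluded from the
denominator (they reflect sequencing error or alignment noise, not the A>G
deamination outcome being measured); masked bases and gap(-adjacent)
columns are tallied separately and excluded entirely. At every site the
four classes (A, G, other, masked) partition the retained reads, which the
tests assert as a conservation invariant.

## Read filtering and alignment

Reads with arithmetic-mean Phred ≤ 30 are discarded; in retained reads,
individual bases with Phred ≤ 20 are masked to `N` rather than discarding
the read — masking keeps coverage while removing unreliable calls, and the
strict inequalities are deliberate, documented semantics. Each read is
then scored against the reference in both orientations (orientation-mixed
single-end input emulates merged 2×250 paired-end data) and the better
orientation is kept; alignments with < 80% identity over aligned columns
are rejected and reported as alignment failures.

Two alignment routes produce the same per-reference-column representation.
Full-length reads take a vectorised ungapped route; anything else — and
any read the ungapped route cannot place at ≥ 80% identity, e.g. because
an indel shifted the frame — falls back to affine-gap dynamic programming
(Bio.Align.PairwiseAligner; match +2, mismatch −1, gap open −5, gap extend
−1, free end gaps). In the DP route, columns within one base of an indel
are masked, so alignment ambiguity around gaps cannot create false A>G
calls. The two routes are cross-checked read-by-read in the test suite.

## Off-target site calling

Per-site A/G counts are pooled (summed) over all replicates of a
condition. Each amplicon adenosine is tested against the pooled control
counts with a two-tailed Fisher exact test (scipy); p-values are
Benjamini–Hochberg adjusted (statsmodels) across all adenosines of the
amplicon for that one case/control contrast — contrasts form separate
families. Sites with adjusted p < 0.01 are flagged significant; the 5%
family rate is recorded in output metadata but the stricter threshold
drives the flags. The target site is tested like any other but labelled
on-target. Both kernels are verified in the tests against independent
oracles: exhaustive hypergeometric enumeration (ties accepted at relative
tolerance 1e−7, agreement to 1e−10) and the direct step-up formula.
p-values that underflow to zero at extreme tables are clamped to the
smallest positive float to preserve the p ∈ (0, 1] contract.

Condition summaries report the per-replicate on-target rate (mean ± SEM,
SEM = sd/√n), and an off-target scalar defined as the per-replicate *mean*
rate over significant non-target sites, averaged across replicates; a
per-replicate *sum* variant is also emitted, since either convention is
defensible, with the mean as the default. The on/off ratio is the ratio of
those two means and is flagged undefined when no off-target signal exists.

## Per-read precision

A read is *corrected* if it carries an unmasked G at the target adenosine,
and *clean* if additionally no other adenosine in the analysed region
carries G (masked/gap columns are ignored). Precision P = clean/corrected,
undefined (flagged) when no read is corrected. Under the engagement model
with independent bystander probabilities q_j and no sequencing error, P
converges to Π_j (1 − q_j), which the tests use as a closed-form check.

## The synthetic-data generator

The simulator draws each read independently: with probability *e* the
transcript is editor-engaged; engaged transcripts carry the target edit
with probability `on_target_prob_given_engaged` and flip each bystander
adenosine *j* independently with probability q_j; unengaged transcripts
flip adenosines with baseline probabilities q0_j (default zero).
Engagement makes bystander edits co-occur on the same molecules — a fully
independent per-site model would drive the bystander-free fraction of
corrected reads far below what per-read precision measurements of real
editors show, because real bystander edits concentrate on the transcripts
the editor actually engaged.

Sequencing is substitution-only uniform error at rate ε (each erroneous
base replaced by a uniformly chosen different base); an optional indel
rate exists to exercise gap handling. Phred scores are drawn from a
normal(37, 3) truncated to [0, 41], so quality filters are exercised but
rarely triggered at defaults. Output is byte-identical under a fixed seed:
a single seeded generator with fixed, sorted site-iteration order makes
the stream independent of dict insertion order. Half of the reads are
reverse-complemented in orientation-mixed mode.

Because the estimator reports r = n_G/(n_A+n_G), an error rate ε maps a
pre-error edit probability p to an expected measured rate

    r = (p·(1−ε) + (1−p)·ε/3) / ((1−ε) + ε/3),

which the generator inverts (`site_prob_for_observed_rate`) so that
cohorts can be parameterised directly on the measured-rate scale. The
generator does **not** model PCR duplicates/chimeras, library-prep bias,
paired-end structure, position-dependent quality, or strand-specific
error; passing recovery tests therefore demonstrate estimator correctness
under the stated noise model, not robustness to those real-data artefacts.

## Study-condition presets and problem sizes

`amped.study` fixes the cohort design the recovery suite runs at: six
replicates per condition, 20,000 full-length reads per replicate (the
typical post-filter yield of a targeted amplicon run), per-base error
1e−3, and named conditions at on-target means of 2.04%, 0.93% and 0.32%
with off-target summaries of 0.10% and 0.05% and a 0.36% hot bystander
site — the editing levels of AAV-delivered Cas13-ADAR constructs in
photoreceptors that the pipeline is designed to resolve. Off-target truths
are spread uniformly over the (up to 12) guide-window adenosines nearest
the target, so the mean-over-significant-sites summary equals the per-site
truth whenever all spread sites are detected.

Detectability sets one parameter: with ε = 1e−3 the A>G error floor is
ε/3 ≈ 0.033%, statistically inseparable from a 0.05% bystander site at
pooled depth 1.2×10⁵ — yet assays that report ~0.05% significant sites at
such depths necessarily operate with background well below the signal.
The off-target site-calling cohorts therefore use ε = 2×10⁻⁴ (background
0.0067%), one consistent choice for both conditions; on-target and
hot-site cohorts keep ε = 1e−3. Null calibration (case ≡ control) is
checked at the count level over 200 simulated amplicons, where the flagged
fraction at q < 0.01 stays below 1% of tested sites.

## Guide design geometry

A spacer is the reverse complement of a window of the sense-strand target
with 'C' substituted opposite the target adenosine. Mismatch distance *d*
counts spacer nucleotides inclusively from the mismatch to the
scaffold-proximal end (a mismatch at the terminal base has d = 1), which
makes tiling-series names like `50nt-36` map directly to d = 36. The
direct repeat is appended 3′ of the spacer by default and is supplied per
orthologue via a user scaffold table — placement and sequence differ among
Cas13 families and are configuration, not inference. Non-targeting guides
are random spacers screened to share no exact ≥ 15-nt match with any
forbidden reference on either strand. No secondary-structure scoring or
activity prediction is attempted.

## Luciferase normalisation

Background (transfection-reagent-only wells) is subtracted per channel as
the mean over background wells; negative results are floored at zero with
a flag. Technical duplicates are averaged on the ratio scale, and
efficiency is normalised between the plate's positive and negative control
mean ratios. E outside [−0.05, 1.05] is flagged, never clamped — clamping
would hide assay failure. A degenerate plate (equal control ratios) is
rejected. The normalisation is exactly invariant under common rescaling of
all luminescence, and the noiseless simulated-plate round trip recovers
truths to machine precision.

## Known limitations

- Alignment assumes amplicon-scale references; the DP route is quadratic
  per read and intended for short amplicons, not genome-scale mapping.
- The per-read precision metric requires reads long enough to span the
  analysed region; partial reads contribute only where they align.
- The engagement model uses a single engagement state; real editors may
  show dose- and structure-dependent per-site correlation that one global
  engagement probability cannot capture.
- BH families span one amplicon per contrast; joint adjustment across
  conditions, and transcriptome-wide off-target analysis, are out of
  scope.
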
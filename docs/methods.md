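# Methods

## The problem and the procedure

Microchip implantation is recorded only in the free-text examination field
of veterinary electronic patient records, so implantation dates must be
retrieved by keyword search and the search's reliability must itself be
measured. The pipeline mirrors how such a validation study is run against
a live clinical database:

1. every record's microchip field is validated (valid iff exactly 15
   ASCII decimal digits after trimming leading/trailing whitespace;
   blank, wrong-length and non-numeric fields are pooled as "invalid"
   with the reason retained);
2. candidate search terms (`implant`, `mchip`, `m chip`, `microc`,
   `m/c`, `micro-c`, `micro c`) are run as case-insensitive literal
   substring searches over the valid-chip cohort and ranked by records
   returned; the top term becomes the working search;
3. a fixed-size random sample of hits per cohort is classified into 17
   mutually exclusive categories; the implantation-event fraction is the
   search's positive predictive value (PPV);
4. implantation hits are split into individual and litter events; ages
   at implantation (visit date minus date of birth, whole days) are
   summarised and compared between species; concurrent interactions
   (vaccination, spay, castration, other surgery, other consult, none)
   are extracted from the same text;
5. patient IDs sharing one valid chip value are grouped and classified
   by demographic concordance.

## Classification by ordered rules

A chart-review study codes hits manually. Here the coding is an ordered
pattern table (`RuleSet`): case-insensitive regular expressions tried in
order, first match wins, default `none_of_the_above`. Rule order is part
of the configuration and serialises with results, which makes the coding
deterministic and auditable — a property human coders cannot offer.
Specific phrasings precede the broad implantation rule so that, e.g., a
complication note mentioning the "microchip implantation site" is not
read as a fresh implantation, and references to past chipping route to
`preexisting_chip_confirmation` rather than `implantation_event`
(implantation "on that day" requires the implantation phrasing in the
visit's own text).

The rule-based classifier is validated against the generator's ground
truth, not against human coding: with noise off it recovers 100% of
labels by construction, and under the default noise level it must recover
≥ 95%. This measures internal consistency of the pipeline, **not** the
accuracy a rule set would achieve on real clinical prose, which is far
more varied than the generator's templates.

## Statistics

* **PPV** is the exact fraction `true positives / sampled hits`.
* **2×2 tests** use the Pearson statistic with 1 df and the Yates
  continuity correction on by default: each `|O − E|` is reduced by 0.5
  and floored at 0 before squaring. The correction is implemented
  directly (rather than through a library contingency routine) because
  the floor matters for near-null tables; the test suite checks
  equivalence against a longhand expected-count oracle to 1e-9 and
  against `scipy.stats.chi2_contingency` away from the floor region.
* **Cohort comparisons** of false-positive reasons test each category's
  count against the *full* cohort sample size (e.g. 458/1000 vs
  385/1000), while the printed percentages use the false-positive totals
  as denominators. Both conventions are emitted and labelled. Categories
  whose combined count is below 10 (minimum expected cell < 5 under
  equal margins) are flagged "too infrequent" and not tested.
* **Sample size** uses the normal-approximation two-proportion formula
  plus the Fleiss continuity correction `2/|p1 − p2|`, rounded up. For
  (0.09, 0.19, power 0.80, confidence 0.95) this gives 187.8 + 20 →
  208 per group; `simulate_power` checks by Monte Carlo (vectorised
  binomial draws through the same Yates test) that nominal power is
  actually attained.
* **Ages** use linear-interpolation quantiles for median and IQR (the
  common default in mainstream statistics software; stated because
  quantile conventions differ). The species comparison is a two-sample
  t-test on natural-log ages, Welch (unequal variances) by default with
  a pooled-variance option; ages of exactly 0 days are shifted to 1 day
  before the log and the shift is recorded. Shifting only zeros breaks
  exact scale invariance when zeros are present; with the generator's
  strictly positive ages this never triggers.
* **Extrapolation** multiplies the total hit count by the sampled PPV
  and reports both the exact product and a 2-significant-figure
  rounding. **Compliance** is the fraction of ages ≤ 84 days, the
  12-week statutory deadline used by default.

## Duplicate-chip linkage

Only valid chip values participate. A group is a chip value with ≥ 2
distinct patient IDs (first record per patient is the representative).
Pairs are classified: species differ → species mismatch; else breed and
sex both differ → breed-and-sex; else sex; else breed; else full match.
Breed comparison is exact text equality after lowercasing and whitespace
collapse, so near-miss breeds ("Labrador" vs "Labrador cross") count as
mismatches — they plausibly name the same animal, but distinguishing
typography from true disagreement is not attempted. Groups larger than a
pair take the *worst* pairwise class (severity: species >
breed-and-sex > sex > breed > full); this is the package's convention,
since no standard one exists for multi-ID groups.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions:

| parameter | default | rationale |
|---|---|---|
| `dog_fraction` | 0.771 | dog share of unique patients in the target cohort |
| `valid_chip_fraction` | 0.734 | share of rows with a valid 15-digit chip field |
| `hit_fraction` | 0.0266 | search hits as a share of valid-cohort rows |
| `category_mixture` | valid-cohort proportions (implantation 0.257, blank form 0.458, …) | observed hit taxonomy; an invalid-cohort preset (normalised over its printed 999) is used for invalid-chip records |
| `concurrent_mixture` | per species (dogs: 79.2% vaccination …; cats: 41.0% vaccination, 29.5% castration …) | observed concurrent-event shares |
| age model | log-normal; dogs median 74.4 d / IQR 95.23 d, cats 127.0 d / 131.45 d | right-skewed, strictly positive, consistent with using a log transform to attain normality |
| `litter_fraction_valid` / `_invalid` | 11/257, 36/155 | litter share of implantation events per cohort |
| `duplicate_injection` | 4 full-match, 2 breed, 1 sex, 1 breed-and-sex, 1 species pairs | roughly proportional to observed duplicate rates at the default corpus size; each class maps to a tuple of group multiplicities so triples and larger groups can be injected |
| `confounder_rate` | 1e-4 | probability a non-hit record carries a confounder word (these become genuine `other_word_or_typo` hits, truth label updated) |
| `typo_rate` | 0.01 | probability a hit text's "microchip" is replaced by a misspelling that still contains `microc` — the pipeline's noise source |

The log-normal parameters follow in closed form from the (median, IQR)
targets: μ = ln(median), σ = asinh(IQR / (2·median)) / z₀.₇₅, which
reproduces the target IQR exactly. Ages are rounded to whole days with a
floor of 1. Dam ages for litter records use a separate log-normal
(median 730 d, IQR 500 d — a plausible breeding-age distribution; the
choice only affects the litter age histogram, which carries no
statistics). The dog median target of 74.4 d is used throughout; a
closely neighbouring value of 74.1 d is equally defensible and the
difference is far below sampling noise at any size used here.

One row is generated per patient. Duplicate groups are carved from the
tail of the patient list: members share a fresh valid chip and have
their demographics forced to the configured concordance class (so
injected class counts are recovered *exactly* by the linkage module).
Every hit-category text contains a `microc` match by construction — the
taxonomy classifies search hits — and non-hit texts contain none of the
search terms. The confounder vocabulary is restricted to genuine
`microc`-containing words (microcytic, microconvex, microcytosis,
"microcope" as a misspelt microscope, …).

What the generator does **not** emulate: real clinical vocabulary beyond
the category trigger templates; multiple rows per visit; correlation of
concurrent events with age beyond the litter/individual split; seasonal
visit patterns; missing or inconsistent demographics within a patient.
Passing end-to-end tests therefore demonstrates that the pipeline's
machinery is correct and internally consistent, not that the rule set
would achieve any particular PPV on real records.

## Determinism and problem sizes

All generator randomness flows from one `numpy` PCG64 generator seeded in
the configuration, so a configuration reproduces its corpus byte for
byte. Hit sampling uses a Mersenne-Twister `RandomState`, matching the
generator family of the spreadsheet RNG such samples are traditionally
drawn with; the pipeline derives independent per-cohort seeds from its
master seed via `SeedSequence`. Default problem sizes — a 10,000-patient
corpus for recovery checks, 20,000 for the pipeline demonstration, 5,000
draws for age-median recovery, 20,000 replicates for simulated power —
were chosen so each quantity's Monte-Carlo error is comfortably below
the tolerance being checked while the whole suite runs in seconds.

## Known limitations

* The rule set is tuned to the generator's templates; applying it to real
  EPRs would require re-deriving patterns from a manual review sample.
* Litter events contribute no ages to the species comparison (their
  recorded age may be the dam's), matching the individual-only analysis,
  but no dam/offspring disambiguation is attempted.
* Intersex animals are not modelled; sex values are compared literally.
* No multiple-testing adjustment is applied to the category comparison
  table, and none is claimed.
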
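# Methods

## Scope and pipeline

`percentaudit` audits the printed precision of percents in abstract text.
The unit of analysis is the *percent mention*: a number immediately
suffixed by `%` (at most one intervening space).  The pipeline is

1. **normalize** — strip `±`, map exotic spaces to ASCII space, unicode
   minus and dashes to `-`, full-width `％` to `%`, and the mid-dot decimal
   marker `·` (Lancet house style) to `.`;
2. **extract** — find every percent mention with its printed decimal
   places and significant figures;
3. **exclude labels** — drop mentions that name a statistical interval or
   significance level rather than report a result;
4. **classify** — compare printed decimals with the ideal number;
5. **summarise** — counts, proportions, credible intervals, per-journal
   tables, the all-ideal abstract share, and a 1%-bin histogram.

Only percents are audited: the `%` suffix makes them extractable with high
precision, unlike means or ratios.  Numbers followed by the words
"percent"/"per cent" are deliberately not extracted, ranges contribute only
the number adjacent to `%` ("5 to 10%" → 10%), and signs and comparison
prefixes are dropped ("–10%", "<10%" → 10%), since the object of study is
presentation, not direction.  Scientific notation ("1e-4%") is outside the
token grammar; such matches are skipped with a warning rather than
mis-parsed as the exponent.

## Label exclusion

A percent such as the "95%" of "95% CI 6–21%" names an interval's level.
Exclusion rules are data, not code: each rule pairs a trigger-value set
with a keyword list, a side constraint and a character window.  Defaults:

* interval rule — values {80, 90, 95, 99} printed with zero decimals,
  keywords: "confidence interval", "credible interval", "Bayesian credible
  interval", "uncertainty interval", "prediction interval", "posterior
  interval", the acronyms CI, PI, the transposed IC, and the observed typo
  "uncertainly interval"; window 30 characters, either side (covering both
  "95% CI" and "CI 95%");
* range rule — same triggers with keyword "range" at window 5, because
  "range" is common English and a wide window would over-exclude;
* significance rule — values {1, 5, 10} with "significance", "statistical
  significance", "alpha level"; window 30, either side.

The 30-character default spans bracketed constructions like
"12% [95% CI 6–21%]" while rarely crossing into a neighbouring clause; it
is a package decision, exposed in the rule config, not a published
constant.  Matching is case-insensitive; two-to-three-letter acronyms
require word boundaries so "CI" cannot fire inside an ordinary word.  A
trigger value printed *with* decimals ("95.0% CI") is never excluded — the
trigger is the conventional printed integer.  Known residual: dialects not
in the vocabulary ("95% fixed kernel density estimator") pass through;
rules are JSON-serializable precisely so users can extend them.

## Ideal decimal places

Cole's guidance — integers above 10%, one decimal place under 10% and in
90–100% when 100 is a natural upper bound, more decimals for very small
percents — is operationalized as the band table in the README.  The
published band list uses "between" without saying which endpoints are
closed; here every band is half-open, exactly 10 and 90 take the integer
rule (fewer decimals when ambiguous), and exactly 100 takes zero decimals
(a trailing ".0" at the bound conveys nothing).  Exactly 0 takes one
decimal place ("0.0%"), reflecting that a printed "0%" usually hides a
small nonzero value.  Two clauses of the guidelines are deliberately *not*
implemented: the allowance of two or more decimals when compared percents
differ by less than 0.1%, and the allowance of integers when the
denominator is under 100 — the first needs cross-mention comparison
semantics that apply to very few abstracts, the second needs sample sizes
that are not extracted.  Both omissions bias the audit toward flagging
defensible presentations, and the reported "just right" share should be
read as a lower bound.

`format_percent` inverts the rule: it rounds half away from zero to the
ideal decimals and keeps trailing zeros.  When rounding carries a value
across a band boundary (9.96% → "10.0" at one decimal, but 10 ideally
takes zero), the ideal is re-evaluated on the rounded value to a fixed
point, so the printed token always carries the ideal decimals of the
number it shows.  Half-away-from-zero matches common manuscript practice;
on the bundled worked examples banker's rounding would give identical
output, so the choice is not load-bearing.

## Sensitivity exclusions

Histograms of reported percents heap at multiples of 10 and at 75 —
thresholds and pre-rounded values rather than computed results, which are
"just right" by construction and inflate adherence.  The sensitivity
analysis drops (a) zero-decimal percents that are multiples of 10, or 75
(the multiple-of-10 test is exact integer arithmetic on the printed value;
"50.0" is not digit preference), and (b) all percents in the closed band
[90, 100], where a natural upper bound may or may not justify the extra
decimal.  Both exclusions are independently switchable; the bundled
"sensitivity" column applies both.

## Dirichlet-multinomial summaries

Category counts n = (n_too_few, n_just_right, n_too_many) are modelled as
multinomial with a Dirichlet prior, flat Dir(1,1,1) by default — the
minimal-information conventional choice, exposed in the API.  The
posterior is Dir(α + n); the marginal of component i is
Beta(αᵢ + nᵢ, Σⱼ≠ᵢ(αⱼ + nⱼ)), and equal-tailed credible intervals are read
off Beta quantiles (`scipy.stats.beta.ppf`) — deterministic and
reproducible, unlike HPD intervals which need optimisation.  A Monte-Carlo
mode samples the posterior Dirichlet instead and serves as an independent
cross-check in the tests (10⁶ draws agree with the quantile route to
within 2×10⁻³).  Reported proportions are the observed nᵢ/N, not posterior
means.  No adjustment is made for the clustering of multiple percents
within one abstract, so intervals are mildly anti-conservative on real
corpora; per-journal intervals use each journal's own counts and remain
honest for small journals.

## Synthetic corpus

The generator exists to make every stage falsifiable: it plants percent
tokens at recorded spans inside digit-free filler sentences, so planted
mentions are the only extractable tokens and extraction can be scored
exactly (precision = recall = 1 is a test, not a hope).  Design:

* **per-abstract counts**: 1 + NegativeBinomial(size = 1.03, prob = 0.23),
  grid-search calibrated (`scripts/calibrate_count_distribution.py`) so the
  quartiles are exactly (2, 3, 6) — median 3, IQR 2–6, matching observed
  abstracts — with ≥ 0.03 of CDF margin at each quartile boundary so
  sampled quartiles are stable;
* **values**: log-uniform on (0.002, 99) for computed-looking results,
  point masses at {10, 20, …, 90, 75} for ideally-printed round numbers
  and {1, 5, 95} for under-rounded ones (digit preference), and ~0.5% of
  values above 100 (integers in 101–1000);
* **categories**: each mention is planted too few / just right / too many
  with configurable probabilities (default 0.12/0.55/0.33); the printed
  token is produced by rounding the true value to the planted decimals,
  with rejection sampling so that rounding never silently shifts the value
  across a guideline band — the planted category always equals the
  category the classifier must recover;
* **labels**: a configurable fraction of abstracts (default 0.2) carries
  one interval or significance construction — "(95% CI 1.8–5.1%)" with the
  upper bound itself a planted result, the reversed dialect "(CI 95%: …)",
  or "alpha level of 5%" — with the label value flagged in the ground
  truth.  Label sentences are prefixed so keywords stay > 30 characters
  from the previous sentence's token, and estimates adjacent to keywords
  avoid integer trigger values, so exclusion recall and precision are both
  exactly 1 on synthetic data;
* **adversarial mode** injects decoys ("P = 0.05", "Phase 3", "5 mg") that
  must not be extracted.

What the generator does **not** emulate: real scientific language (the
filler is template text), non-enumerated label dialects, percents written
as words, thousands-separated or scientific-notation tokens, inconsistent
within-sentence precision as a *correlated* phenomenon, and clustering of
categories within an abstract (mentions are independent given the
abstract).  Passing end-to-end tests therefore demonstrates that the
machinery is self-consistent and that the planted statistical structure is
recovered; it does not demonstrate extraction robustness against the full
messiness of real abstracts, which the rule-based design addresses with a
deliberately conservative token grammar.

## Problem sizes and numerics

The bundled tests run the end-to-end audit on 1,000–2,000 synthetic
abstracts (≈4,500–9,000 mentions), interval coverage on 500 multinomial
replicates of n = 2,000, and the Monte-Carlo cross-check on 10⁶ Dirichlet
draws — sizes at which every stochastic check has comfortable margins
(recovered proportions are tested within 3 binomial standard errors;
empirical 95% coverage is required to land in 92–98%).  All randomness
flows through a single seeded `numpy` generator; corpora are byte-identical
across runs with the same seed.  Degenerate inputs are defined, not
special-cased: an empty abstract yields zero mentions, an empty corpus
tallies to zeros, a zero-count tally with a proper prior still yields
intervals, and a zero-count tally with a degenerate prior is an error.
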
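# Methods

## Scope and model

The package answers a bookkeeping question with regulatory weight: if
every product containing a candidate-for-substitution (CFS) active
substance must be comparatively assessed against CFS-free alternatives
for every shared authorised use, how large is the caseload?  It is a
static analysis — a snapshot of one substance list and one product
register — and deliberately excludes the comparative risk assessment
itself (no toxicity/exposure ratios, no "significantly lower risk"
decision rule), agronomic assessment, and any synonym or
broad-spectrum matching of use descriptions.

Three data structures carry the analysis: per-substance hazard
profiles (numeric endpoints, CLP-style classification labels, optional
pre-assessed booleans), per-substance CFS assessments (criterion
flags, PBT sub-flags, overall status, hazard basis), and a product
registry (products with active-substance composition plus a set of
normalized crop × pest uses per product).

## Classification rules

**Criterion 1 (low reference doses).**  For each endpoint (ADI, ARfD,
AOEL) separately, and within each use group a substance belongs to,
the empirical q-quantile of the *present* values is computed
(default q = 0.05, linear interpolation between order statistics — the
common spreadsheet convention; configurable because the convention in
the source assessments is not recorded).  A substance is flagged if
any of its present values lies strictly below the group quantile of
that endpoint in any of its groups.  Groups with fewer than
`min_group_size` (default 5) present values yield no flags; substances
with no use category belong to no group and cannot be flagged by this
criterion; multi-category substances participate in each of their
groups and qualify through any.  Missing values never qualify: absence
of data is distinguished from "below threshold" everywhere.

**Criterion 2 (two of three PBT).**  Persistence merges the three
compartment half-lives (strict > 60 d water, 180 d sediment, 120 d
soil); bioaccumulation is BCF strictly > 2000 L/kg; toxicity is either
aquatic (minimum present chronic NOEC strictly < 0.01 mg/L across
fish, daphnids, algae, other) or human (any CMR classification in the
configured class set — default {1A, 1B, 2} — or STOT RE 1/2).  The
criterion is met when at least two of {P, B, T} hold with
T = T_aqua ∨ T_human.  The thresholds are configuration with the
defaults above; when pre-assessed P/B/T booleans are supplied they
take precedence (default), because upstream assessments may have
merged evidence the raw table cannot carry.

**Criteria 3 and 5** are implemented as constant-false evaluators so
the seven-fold disjunction keeps its legal shape: no approved
substance was found to meet criterion 3, and 1A/1B carcinogens fall
under the approval cut-off rather than the substitution list.

**Criterion 6** merges existing and forthcoming reproductive-toxicity
classifications (1A or 1B in either).  **Criterion 7** implements the
interim endocrine rule literally: carcinogen category 2 *and* merged
reproductive toxicity exactly category 2 (a 1B repro classification
routes the substance to criterion 6, not 7).  **Criterion 4** returns
the abstracted non-active-isomer flag, falling back to a pre-assessed
boolean.

**Hazard basis.**  Environmental identification: the aquatic PBT route
(T_aqua with P or B) or criterion 4.  Human identification: criteria
1, 6, 7 or the human PBT route.  Both can hold.  A substance that is
CFS solely through P + B (no toxicity indicator) is attributed to the
configured side (default human, following the rule that everything not
explicitly environmental is human; the case is configurable because it
did not occur in the source data).

## Caseload metrics

A candidate product contains ≥ 1 CFS; under the environmental filter,
≥ 1 CFS whose basis is environmental or both.  Alternatives for a use
are the products authorised for that exact normalized use containing
*no* CFS at all — also under the environmental filter, so alternative
sets are always disjoint from every candidate set, and
candidate-vs-candidate comparisons are excluded by construction.

Counts are exact set cardinalities.  Distinct-use counts deduplicate
across candidates; the product×use pair counts do not (one pair per
candidate per use).  Means are kept unrounded internally and rounded
half-up only at display time.  The three-factor caseload estimate
(candidates × mean uses-with-alternatives per candidate × mean
alternatives per such pair) uses pair-weighted means, which makes it
*algebraically identical* to the exhaustive triple enumeration:
N·(U/N)·(A/U) = A.  The identity is asserted in the report path and
property-tested; a distinct-use-weighted second mean would break it.

Integer percentages use exact rational arithmetic with half-up
rounding (`pct(351, 1378) = 25`); availability histograms use the
fixed bins {0}, {1}, {2}, {3–5}, {6–10}, {11–20}, {21–50}, {51–100},
{>100}, which partition the non-negative integers.

## Synthetic data generator

No machine-readable deposit exists for either input, so the generator
emulates both with the documented marginals: 378 substances spread
over the published use-category counts, ~26% CFS, 1,378 products, a
309 × 477 crop–pest vocabulary, ~3,200–3,400 realized distinct uses,
uses-per-product with median ≈ 6–7, mean ≈ 13–14 and a long tail
capped at 340, ≈ 25% candidate products covering ≈ half of all uses,
and alternatives available for roughly half of candidate uses.

*Latent hazard states first.*  Each substance draws a PBT route
(environmental / both / human with probabilities 57/378, 13/378,
7/378), classification labels, and the isomer flag.  Numeric endpoints
are then sampled from log-normals *truncated to be consistent with the
latent state* (e.g. a persistent substance draws one compartment
half-life above its threshold, a non-PBT substance draws all NOECs
above the toxicity limit).  The classifier therefore reproduces the
configured rates through its real threshold logic.  Human reference
doses share one latent log-potency per substance (so ADI/ARfD/AOEL are
strongly correlated, as in real toxicology) and PBT substances are
shifted toward lower doses, concentrating criterion-1 flags on already
hazardous substances; the percentile criterion then contributes only a
small increment of CFS-by-criterion-1-alone, matching the source
pattern.

*Registry.*  Each substance draws a **territory** — the set of crop ×
pest combinations its products can be authorised for — with a
heavy-tailed (log-normal, stratified/Latin-hypercube) size.  Products
choose 1–3 substances from a popularity distribution that upweights
broad-spectrum substances and penalises hazard-latent ones (CFS are
rarer on the market), then cover a large random fraction (70–100%) of
their *primary* substance's territory plus a small slice of any
co-formulants' territories and at least one pick from a small shared
popular core.  Territories overlap their randomly assigned neighbours
at the edges.  Same-substance products thus share most uses (so
candidate-only uses exist in bulk, and most candidate uses have no
alternative unless they fall in an overlap, a co-formulant slice, or
the core), while the core guarantees that nearly every candidate
product has at least one use with alternatives — both prominent
features of the emulated register.  An earlier design that drew
per-product use counts independently of substances could not reproduce
the coexistence of ~5 products per use with a majority of
alternative-free candidate uses, and was replaced.

Every generator stage (latent state, substance records, endpoints,
product composition, use pool, authorisations) draws from its own
named substream of the seed, so enlarging one stage never perturbs
another, and the registry generator can reconstruct the latent mask
when (and only when) it is given the substance table its own
configuration generates.  Calibration of the free parameters
(market-weight penalty 0.82, territory median 4.1 / sigma 1.23,
overlap 8%, core 150 uses at 5% of draws) was done by simulation
against the targets above and then frozen.

*What the generator does not emulate:* real substance, crop or pest
identities; correlations between environmental endpoints (DT50 vs BCF
independence is assumed beyond the latent flags); temporal market
dynamics; and zonal/EU-wide structure.  Passing tests on synthetic
scenarios therefore demonstrate the correctness and calibration of the
pipeline, not facts about any real national register.

## Numerical and interface choices

Strict inequalities throughout the threshold logic (a BCF of exactly
2000 is not bioaccumulative; a value exactly at the group quantile is
not "below" it); ties therefore never flag.  Quantiles via
`numpy.quantile` with a configurable method.  Input tables are UTF-8
CSV with a documented fixed header (tab dialect via a flag);
multi-valued cells are `;`-separated; an empty cell is an absent
value, never zero.  Alias resolution maps product ingredient labels to
canonical substance ids and treats unresolved labels as validation
errors, never as silently new substances.  Registry reading
deduplicates authorisation rows per (product, normalized use), making
all distinct-use counts invariant under row duplication.

Problem sizes in the test suite follow the scenario definitions: the
preset scale (378 substances / 1,378 products) for calibration and
end-to-end checks over 20 seeds, and a structurally identical 60/50
small scenario for oracle comparisons and the 100-scenario identity
sweep.

## Known limitations

Criterion 1 depends on the quantile convention and on group
composition; with the data-driven percentile it flags a floor fraction
of every sufficiently large group, so a market with uniformly benign
reference doses would still produce criterion-1 candidates.  The
pre-assessed boolean path is the faithful reproduction route when
upstream per-criterion decisions exist; the raw-threshold path is a
documented operationalisation, not a re-derivation of those
assessments.  The hazard-basis attribution of P+B-only substances and
the inclusion of carcinogen category 2 in the human-toxicity indicator
are both configurable because the underlying texts do not fully pin
them down.
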
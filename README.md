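# cfs-caseload

Screening of pesticide active substances as **candidates for
substitution (CFS)** and quantification of the comparative-assessment
caseload that regulatory authorities face as a result.

Under the EU plant-protection-product regime, an approved active
substance becomes a candidate for substitution when it meets at least
one of seven hazard criteria, and every authorisation of a product
containing a CFS then triggers a comparative assessment against
CFS-free alternative products for each shared use.  The package
implements both halves of that analysis:

* a **rule engine** for the seven criteria, operating on per-substance
  hazard endpoints and classification labels;
* **registry linkage and caseload metrics**: candidate products,
  affected uses, availability of alternatives, and the number of
  pairwise product comparisons;
* a **seedable synthetic-data generator** emulating the structure of a
  national product register and of the substance hazard tables, since
  neither underlying dataset is deposited in machine-readable form.

## The classification rule

For substance *i* with hazard profile *x*ᵢ, the criteria are evaluated
as

1. **Low reference doses** — any of ADI, ARfD, AOEL (mg/kg bw/day)
   strictly below the empirical *q*-quantile (default *q* = 0.05,
   linear interpolation) of the same endpoint within any of the
   substance's use groups (acaricides, fungicides, herbicides, ...).
2. **Two of three PBT criteria** — persistent (any DT50 above
   60/180/120 d for water/sediment/soil), bioaccumulative
   (BCF > 2000 L/kg), toxic (minimum chronic NOEC < 0.01 mg/L across
   fish, daphnids, algae and other taxa — the aquatic indicator — or a
   CMR / STOT RE classification — the human indicator).
3. *Nature of critical effects* — constant false (no approved
   substance was found to meet it).
4. **Significant proportion of non-active isomers** (abstracted flag).
5. *Carcinogen 1A/1B* — constant false (covered by the approval
   cut-off instead).
6. **Toxic for reproduction 1A or 1B**, merging existing and
   forthcoming classifications.
7. **Interim endocrine-disruption rule** — carcinogen category 2
   together with reproductive toxicity category 2.

CFS(*i*) = c₁ ∨ c₂ ∨ … ∨ c₇.  Each CFS also receives a **hazard
basis**: environmental (aquatic PBT route or isomers), human health
(c₁, c₆, c₇ or the human PBT route), or both.

The caseload side defines, for a product set *P* and assessments over
its substances: candidates *C* = {p : p contains ≥ 1 CFS}, alternatives
for use *u* = products authorised for *u* containing no CFS, and the
pairwise-comparison count

    N = Σ_{c ∈ C} Σ_{u ∈ uses(c)} |alternatives(u)|
      = |C| · mean(uses with alternatives per candidate)
            · mean(alternatives per such candidate-use pair),

an identity the report checks on every run (means unrounded; rounding
is half-up and applied only for display).

## Worked example

`examples/01_classify_substances.py` classifies four hand-written
substances:

```
substance      criteria met   CFS   basis
soilbinder     2              True  env_only
reprotox-1b    6              True  human_only
interim-ed     7              True  human_only
benign         -              False none
```

`soilbinder` (soil DT50 180 d, daphnid NOEC 0.004 mg/L) meets two of
the three PBT criteria through the aquatic route, so it is a CFS on
environmental grounds; `reprotox-1b` and `interim-ed` are flagged by
the human-health classification criteria; nothing fires for `benign`.

`examples/03_german_like_scenario.py` runs the bundled
German-market-like scenario (378 substances, 1,378 products, 309 crops
× 477 pests; fixed seed 2013) end to end:

```
substances: 378, CFS: 111 (29%)
products: 1378, candidates: 405 (29%), environmental basis: 300 (22%)
uses: 3204, of candidates: 1817 (57%)
candidate uses with alternatives: 984 (54%)
pairwise comparisons (any basis): 12456
pairwise comparisons (environmental): 8780
```

About a quarter to a third of substances screen as CFS, candidate
products cover a disproportionate share of all authorised uses, and
the enumerated pairwise-comparison caseload lands in the tens of
thousands — the scale of work a "compare every candidate with every
alternative for every common use" mandate implies.  Individual numbers
move with the seed; the calibrated expectations are ≈26% CFS and ≈25%
candidate products.

A thin CLI wraps the same pipeline:

```sh
cfs-caseload simulate --preset german-like --seed 7 --out scenario/
cfs-caseload report --hazard-table scenario/hazard.csv \
    --products scenario/products.csv --uses scenario/uses.csv --out out/
```

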
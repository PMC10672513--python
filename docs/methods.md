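# Methods

## Scope and data model

`lipidchains` analyses replicate-level lipid concentration tables from
shotgun lipidomics of whole animals, organised as samples × species with a
group label per sample (here: age classes "Day1" and "Day19", 16 replicate
males each). Species names follow the LipidSearch-style shorthand. Fifteen
classes are modelled, with fixed chain counts: DG/PC/PE/PG/PI/PS and the
ether classes DGe/PCe/PEe/PEp/PSe carry 2 chains, TG/TGe 3, CL 4 and LPC 1.
Ether classes carry exactly one ether-linked chain — alkyl (`e`, plasmanyl)
or alkenyl (`p`, plasmenyl) — and acyl chains otherwise; ester classes carry
only acyl chains. Sphingolipids are outside the model.

### Nomenclature conventions

* Both `CLASS(...)` and bare `CLASS ...` dialects and both `_` and `/`
  separators are accepted; the canonical serialisation is `CLASS(...)` with
  `_`, ether chain first, acyl chains sorted by (carbons, double bonds).
* A single composition term on a multi-chain class is an unresolved *sum
  composition* (e.g. `TGe(32:1e)`): total carbons/double bonds only, no
  chain list.
* A class-level `e`/`p` designator with unsuffixed chain terms assigns the
  ether linkage to the first listed chain; a chain-level `p` overrides a
  class-level `e`. Rationale: exports and prose mix `PCe(20:0e_14:1)`-style
  and `PEe 36:0e`-style spellings.
* *sn*-position is not modelled — shorthand does not encode it — so chains
  are an unordered multiset apart from linkage. Odd-carbon and very short
  chains are accepted unfiltered.

## Class-level summaries

Relative abundance is computed per sample: each species' concentration as a
percentage of the sample's total, so each sample sums to 100 and class
percentages are comparable across samples with different total lipid yields.
"Detected in a group" means concentration > 0 in at least one of the group's
replicates (the minimum-replicate count is a parameter; the data never
defines detection explicitly). Class **diversity** is the number of detected
species; class **abundance** is the mean over replicates of the summed
per-sample class percentage, with SE = SD/√n over the n replicates.
Category rows (neutral lipids, phospholipids, ether neutral lipids, ether
phospholipids) are sums of their member classes.

The diversity–abundance correlation across classes is the squared Pearson
correlation after a log transform of both variables (default). The log
scale is a recorded design choice: recomputing the correlation from the
published rounded class rows reproduces the published r² values on the log
scale (0.70 and 0.75 vs 0.68 and 0.73) but not on the raw scale (0.61,
0.44), and class abundances span four orders of magnitude, where a raw-scale
Pearson r is dominated by the one or two largest classes. An identity
transform is available. Whether the original analysis used per-class means
(as here) or per-replicate points is unknown; per-class means are used.

## Chain-level profiles

Only chain-specified species enter chain-level statistics; unresolved sum
compositions are never pooled in. Each chain is categorised by length —
S (<C16), M (C16–C18 inclusive), L (>C18) — and saturation — 0, 1, X for
zero, one, more than one double bond — giving nine joint categories.

Per class, group and linkage group (acyl vs alkyl/alkenyl):

* **Mean chains**: the per-species mean carbons (and double bonds) over its
  chains in the linkage group, then mean ± SE across species. SE across
  species (not replicates) is the default and is undefined (NaN) for a
  single species, which matches the published single-PCe row carrying no SE;
  abundance weighting is available.
* **Category profile**: proportions of chains over the nine joint categories
  plus length-only and saturation-only marginals (sums of the joint).
  Species-count weighting is the default (each detected species contributes
  its chains once); chains repeated within a species count multiply
  (`TG(16:0_16:0_18:1)` contributes 16:0 twice).
* **Common chains**: a chain identity ("C:D") is common if it makes up at
  least 5% (inclusive) of the chains in at least one class × linkage × group
  cell; the full percentage matrix is reported.
* **Dichotomy overlap** for ether classes: Σ_chain min(freq_acyl,
  freq_alkyl/alkenyl) ∈ [0, 1]; 0 is a complete dichotomy between the acyl
  and ether-linked chain complements.

## The combination test

For each multi-chain ester class (DG, TG, CL, PC, PE, PG, PI, PS — LPC has
no combinations, ether classes mix linkage chemistries), and per replicate
sample:

1. marginal category probabilities p_t = Σ_l w_l · n_t(l)/k, where w_l is
   the species' relative abundance among the class's chain-specified species
   in that sample and n_t(l) counts category t among its k chains;
2. observed combination frequencies O_m = Σ_l w_l · 1[multiset(l) = m];
3. expected frequencies E_m = k!/∏ n_t! · ∏ p_t^{n_t} over all multisets of
   the categories with positive marginal mass.

Both O and E sum to 1 per sample. The per-replicate paired differences
O_m − E_m are tested with a two-sided one-sample t-test (df = n−1);
p-values are Bonferroni-multiplied by the number of combinations with
observed or expected mass in that class × group. Abundance weighting is the
default *in this module* because only abundances vary between replicates —
species-count weighting gives identical frequencies in every replicate and a
degenerate test. Three category schemes are supported (joint 9, length 3,
saturation 3); collapsing joint expectations to a marginal scheme equals
computing them directly in that scheme.

Numerical/degenerate choices: zero-variance differences are flagged
degenerate with p = 1 when the mean difference is 0 (and p = 0 otherwise);
the ratio mean(O)/mean(E) carries an SE from per-replicate ratios when all
E > 0 and from the delta method otherwise; E = 0 with O > 0 reports an
infinite ratio but is still tested via differences. Variants kept behind
flags: a day-pooled expectation (each replicate compared with the group mean
expectation) and a two-sample t-test, since the original description does
not pin down either choice; the per-replicate paired default gives a
well-defined n = 16 test per day.

The **large-bias screen** flags combinations with |O − E| strictly greater
than 5 percentage points (parameter) in at least one group and the same
direction of effect in both groups, labelled excess or deficit.

## Synthetic data generator

The generator emulates the study design: two groups × 16 replicates, ~380
species across all 15 classes with diversities near the study's (e.g. 220
TGs, 35 CLs, one PCe), class abundance shares matching the study's class
percentages, chain pools dominated by 16:0/16:1/18:0/18:1/18:2/18:3 with
rarer short/long/odd-carbon chains (e.g. 10:2 and 24:2 in PG), total
concentrations on a 500 ng/µL scale, and per-species × per-replicate
lognormal noise (sdlog 0.35 by default, i.e. a ~36% CV between individual
flies — typical of whole-organism lipidomics).

Chain association per ester class is controlled by θ ∈ [−1, 1] through a
mixture law over chain-identity multisets: θ = 0 gives the i.i.d. multinomial
law M(p); θ > 0 mixes in mass θ of "draw one type, repeat it k times";
θ < 0 moves mass |θ| to M(p | not homogeneous). θ < 0 is infeasible for a
single-type pool and rejected.

Two design choices matter for how the generator realises the null:

* **Mass-action abundances.** A class's concentration mass is distributed
  over multisets proportional to the (θ-tilted) law, not drawn independently
  per species. The combination test weights by abundance, so a dataset
  drawn with abundances independent of chain content would carry a
  persistent, replicate-independent accidental association of order
  1/√n_species between observed frequencies and plug-in expectations — the
  realised lipidome would *not* satisfy the null it is meant to embody, and
  a paired test over 16 replicates (whose only noise is abundance jitter)
  would detect that accident almost surely. Under mass action, θ = 0 makes
  the random-association null hold exactly before noise.
* **Closure species lists.** Each ester class realises *every* multiset over
  its chain pool, with pool sizes chosen so the closure matches the study's
  class diversities (10 TG chain types → 220 TGs, 4 CL types → 35 CLs, 6 PC
  types → 21 PCs, ...). Truncating to a sampled subset of multisets would
  leave first-order holes in the combination space and again bias O − E away
  from zero for every replicate.

Ether-class species draw their acyl and ether chains from separate pools
(reproducing the acyl vs alkyl/alkenyl dichotomy), with a configurable
fraction reported as sum compositions only and fixed singleton species for
the PCe and PSe; their abundances are i.i.d. lognormal, since ether classes
are outside the combination test. A ground-truth table records every
species' drawn chains, categories and θ, sufficient to recompute category
multisets without the parser.

What the generator does **not** emulate: detection dropout and
missing-at-random non-detections (species presence is identical across
replicates unless concentrations are zeroed by hand), day effects on class
abundances or chain pools, species-specific persistent abundance factors
(deliberately, see mass action above), annotation error, and any isomer
structure below the shorthand level. Passing tests therefore show the
machinery is correct under the stated model, not that real data meet these
assumptions — in real data the test conditions on the realised lipidome and
will legitimately flag any fixed compositional association, which is the
intended use.

## Simulation experiments

`lipidchains.calibration` packages two standard experiments on the default
design (sizes chosen to keep each run in the order of seconds):

* **Null calibration**: 100 independent θ = 0 datasets; all eight ester
  classes × two groups tested (~27k combination tests). Expected behaviour:
  Bonferroni-significant calls well below 5% (measured ~0.3–0.4%) and raw
  p-values approximately uniform. Uniformity is checked as a bound on the
  Kolmogorov–Smirnov sup-distance from U(0,1) (D < 0.1) rather than a KS
  p-value, because p-values from combinations of the same class are
  dependent (frequencies sum to 1), which a sample-size-n KS test would
  punish irrespective of calibration; gross miscalibration yields D ≈ 0.5.
* **Deficit recovery**: 50 datasets with θ = −0.5 on PC (the documented test
  setting); a repeat counts as recovered when at least one homogeneous
  joint-category pair (M0_M0, M1_M1, MX_MX, ...) is significant with a
  negative difference in both groups. Measured recovery: 100%.

## Known limitations

* The Bonferroni family is combinations within one class × group × scheme;
  no cross-class correction and no FDR alternative yet.
* The t-test treats per-replicate differences as exchangeable; heavy-tailed
  abundance noise at small n could distort raw p-values (the calibration
  experiment bounds this under the lognormal default).
* Published rounded class rows are used as worked-example inputs, so derived
  quantities (ratios, r²) inherit their 1-dp rounding error.
* The parser accepts any chemically self-consistent shorthand; it does not
  validate against a lipid database.
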
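# Methods

## Scope and model

`dustrisk` evaluates sieved road-dust campaigns: per-site, per-fraction
analyte concentrations (major oxides in wt%, trace elements in
mg kg⁻¹) are screened for analytical quality, summarised as mass-based
size distributions, indexed against a geogenic background, and fed
through a deterministic USEPA-style multi-route exposure model. There
is no probabilistic (Monte-Carlo) layer and no
bioaccessibility/bioavailability adjustment: doses are computed from
total concentrations, which is the standard, conservative convention
for screening-level dust assessments.

## Units and conversion

All internal arithmetic is on mg kg⁻¹ *element* basis. Oxide wt%
values convert as `value × 10⁴ × f`, with `f` the element mass
fraction of the stoichiometric oxide computed from IUPAC 2021 atomic
masses (e.g. f(Fe₂O₃) = 2·55.845/159.687 ≈ 0.6994). Conversion is
idempotent for element-basis input. Reports may re-express majors as
oxides; the enrichment factor is basis-invariant as long as sample and
background share a basis, which the loader guarantees by converting
both.

Censoring: a below-LOD cell stores a substituted value and keeps its
flag. The substitution rule is configurable among {0, LOD/2, LOD} with
LOD/2 as default — the usual compromise between bias and variance for
left-censored geochemical data. "Not measured" (absent cell, NaN) is
distinct from "censored" and propagates as absence.

## Sieve fractions

Bins are half-open intervals [lower, upper) µm so they partition the
size axis; the finest bin is [0, 45). The default scheme is the
800/500/250/125/45 µm stack with the >800 µm bin weighed but excluded
from chemical analysis (it is dominated by litter and debris). Mass
percentages keep the oversize bin in the denominator by default
(matching how sieving campaigns report them); a flag renormalises over
analysed bins only. The inhalable share is the mass percent in bins
wholly below 125 µm — the resuspendable size range — with the
threshold configurable (at 100 µm only the <45 µm bin qualifies, since
a sieve bin cannot be split).

Land-use aggregation is an unweighted mean across the sites of a
class; with single-site classes the class mean is that site, and
between-class contrasts with few sites per class are indicative, not
inferential.

## QA/QC

Accuracy: recovery = 100·measured/certified, pooled per analyte as an
unweighted mean over all CRM measurements (no per-CRM weighting, as
there is no principled weight without replicate counts). The pass
window is 70–120 %. Certificates below 10× the detection limit are
treated as LOD-proximal: a wild recovery there (>200 % happens
routinely) is annotated and excluded from the accuracy judgement
rather than read as bias. Precision: RPD = 100·|a−b|/mean(a,b) — the
standard analytical-chemistry definition — summarised per analyte by
the median (midpoint convention for even counts), flagged above a 10 %
ceiling. The totals screen lists (site, fraction) pairs whose
major-oxide + LOI sum leaves [98.5, 101] wt% for re-analysis; low
totals carry the conventional annotation (unscanned S/Li/F).

## Pollution indices

EF uses the conservative sum E_ref = Al₂O₃ + MgO + Na₂O + K₂O + TiO₂ +
P₂O₅, summed on the same basis for sample and background (the basis
cancels in the double ratio when consistent). Classification: <2
minimal, [2,5) moderate, [5,20) significant, [20,40) very high, ≥40
extremely high — upper classes left-closed as conventionally printed.

Igeo = log₂(C/(1.5B)); the 1.5 buffers natural background
fluctuation, so Igeo(1.5B) = 0 exactly. The published Müller scale
overlaps at 4 ("3 < Igeo ≤ 4" and "4 ≤ Igeo < 5"); we adopt
(−∞,0], (0,1], (1,2], (2,3], (3,4], (4,5), [5,∞) — 4 belongs to heavy
contamination — with the alternative convention behind a flag. Both
classifications are total functions partitioning their domains.

Cross-site summaries are unweighted means per (fraction, analyte);
the fine/coarse ratio is mean EF(<45)/mean EF(500–800).

## Exposure and risk

Doses (mg kg⁻¹ d⁻¹), per receptor r ∈ {child, adult}:

    ADD_ing  = C·IngR·CF·EF·ED/(BW·AT)
    ADD_inh  = C·InhR·EF·ED/(PEF·BW·AT)
    ADD_derm = C·SA·CF·AF·ABF·EF·ED/(BW·AT)

Default factors: IngR 200/100 mg d⁻¹, InhR 7.63/12.8 m³ d⁻¹, EF
27 d y⁻¹, ED 6/24 y, BW 15/70 kg, SA 1600/4350 cm², AF 0.2/0.7
mg cm⁻², ABF 0.001, CF 10⁻⁶ kg mg⁻¹, PEF 1.36×10⁹ m³ kg⁻¹, AT =
365·ED d (non-carcinogenic). These make ingestion dominate inhalation
by >10⁴ at equal concentration and fix the child:adult ingestion dose
ratio at (200/15)/(100/70) = 9.33….

HQ = ADD/RfD per route; HI is the sum of *available* route HQs — a
route with no reference dose is skipped and marked "not assessed",
never imputed or zero-divided. The same rule applies to slope
factors.

Carcinogenic risk integrates over both receptors:

    LADD = C·EF/AT_carc · Σ_r CR_r·ED_r/BW_r,   CRI = LADD·SF

with route contact rates CR_ing = IngR·CF, CR_inh = InhR/PEF (the
particulate emission factor applied exactly once, here), CR_derm =
SA·AF·ABF·CF. The circulating typeset form of this equation sums
CR + ED/BW and carries PEF in the global denominator while also
defining CR_inh = InhR/PEF; both are dimensional impossibilities read
literally, so the product/single-PEF form above is the implemented
default, with an `as_printed=True` mode retained for sensitivity
analysis. AT_carc defaults to a 70-year lifetime (25 550 d),
configurable — the non-carcinogenic AT = 365·ED cannot serve a
*lifetime* average.

CRI classes: negligible < 10⁻⁶, tolerable in the closed band
[10⁻⁶, 10⁻⁴], harmful above; an additional flag marks values above
the 10⁻⁵ threshold some regulators use. Every dose and risk quantity
is degree-1 homogeneous in concentration, and contribution shares
along any axis sum to 100 %.

## Synthetic-study generator

The generator emulates a six-site campaign (4 urban/suburban
residential, 1 industrial, 1 mixed) over the default sieve stack with
~40 analytes:

* concentrations C = B·g(bin)·ε with geogenic background B
  (upper-crust-like values; majors as oxide wt%), multiplicative
  lognormal noise ε (σ = 0.1 by default — typical ICP between-sample
  scatter), and per-analyte enrichment profiles g;
* PTE profiles are specified as *target mean EFs* per bin and
  converted to concentration multipliers through the conservative-sum
  profile, so at σ = 0 the pipeline's EF reproduces the target
  exactly. Zn, Sb, Sn and Cu interpolate reported urban fine/coarse
  mean-EF endpoints (10.8/5.7, 12.2/4.3, 9.0/1.5, 9.3/5.9); the other
  PTEs get moderate declining profiles, and K₂O, Na₂O and Ba carry
  the opposite (coarser-richer) trend;
* sieve masses are Dirichlet draws (precision 400) around land-use
  templates whose means reproduce the reported class contrasts:
  inhalable shares 33.0 % (industrial), 18.6 % (mixed), 17.3 %
  (urban), urban <45 µm 3.0 % and >800 µm 38.5 %;
* QC sets draw recoveries uniformly in [89, 118] % and duplicate RPDs
  half-normally with the scale set so the distribution median equals
  the 9 % target (median of |N(0,1)| ≈ 0.6745);
* mineral tables put phase mass = slope × fraction mass × (1+ε) with
  slopes 0.31 (muscovite), 0.17 (quartz, anorthite), 0.10 (calcite),
  0.09 (albite), 0.06 (dolomite), 0.04 (chlorite) and 1 % relative
  noise.

One seed fixes every draw; identical seeds give bit-identical bundles.

What the generator does **not** emulate: spatial correlation between
sites, correlated multi-analyte noise (real ICP errors co-vary through
drift and matrix effects), censoring patterns (all generated cells are
above LOD unless configured), seasonality, and any mineralogy beyond
the linear phase-mass law. Passing pipeline tests on synthetic studies
therefore demonstrates correctness of the computations and recovery of
the imposed structure, not validity of the model on any particular
real campaign.

## Numerical and statistical choices

* Percent closures are asserted to 10⁻⁶; cumulative curves are exact
  prefix sums.
* The mineral regression is ordinary least squares on linear axes
  (log-log display merely bends the fitted line); it requires ≥3
  positive-mass points and non-degenerate x variance.
* Profile-shape recovery is checked as Spearman rank correlation
  between estimated and target per-bin mean EF. Per-analyte bin means
  over 6 sites at σ = 0.1 carry ≈4 % sampling error, so rank recovery
  is asserted where the estimator has resolving power: on the strongly
  graded Sn profile (adjacent bins ≈36 % apart) and on the profile
  pooled across all declining-target PTEs (≈1.2 % pooled error).
  Closely spaced profiles (e.g. Cu's middle bins, ≈12 % apart) can
  legitimately swap ranks in a single draw.
* CSV round trips write full-precision floats and read with
  round-trip float parsing, so a written study reloads bit-exactly.
* Site sampling records report arithmetic yields unrounded; where a
  published summary disagrees with its own record arithmetic (one
  high-traffic site prints 130 g m⁻² against 5662 g/41 m² = 138), the
  arithmetic value is reported and the discrepancy documented rather
  than patched.

## Known limitations

* Reference doses and slope factors ship as a default table for the
  commonly assessed dust PTEs; campaign-specific toxicity tables
  should be supplied via the config for regulatory work.
* The dermal route treats micrometre particles as absorbable at a
  fixed ABF; mechanistically only nanometre particles cross the
  stratum corneum, so dermal HQ/CRI are upper-bound conveniences.
* Single-site land-use classes make class contrasts descriptive only.
* EF and Igeo are insensitive to anthropogenic inputs that sit near
  geogenic levels; low index values do not prove absence of
  anthropogenic sources.

## Problem sizes

Default test and acceptance runs use the 6-site × 5-fraction × ~40
analyte study (1 200 concentration cells), 30-point mineral
regressions, 40-analyte QC sets with 3 CRM measurements and 12
duplicates each — the scale of the emulated campaign itself, which
keeps every check comfortably fast on one CPU.
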
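# Methods

`citrusrisk` implements a complete computational chain for pesticide-residue
risk assessment of citrus fruit surveys: descriptive surveillance statistics,
a matrix residual-risk ranking, deterministic chronic and acute dietary
exposure, and probabilistic chronic risk by Monte Carlo simulation. This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Survey data model

A survey is a set of fruit samples, each assayed for a panel of pesticides.
Records carry a `detected` flag; non-detects are stored with concentration 0
and excluded from detection-based summaries (no LOD/LOQ substitution is
applied by default — values between LOD and LOQ are a policy question the
data model leaves to the caller by way of the `detected` flag). Frequencies
are reported as whole percents (survey reporting convention) with the raw
ratio retained. The MRL screen is inclusive: a concentration exactly at the
legal limit counts as an exceedance, and raising any concentration can never
un-flag a sample.

The `matrix_effect` helper (100 × response in matrix / response in solvent)
is the one QC quantity kept from the analytical-method side; chromatographic
processing, recoveries and RSDs are out of scope.

## Matrix residual-risk ranking

Each pesticide receives component scores: A (acute toxicity, from rat oral
LD50), B (toxic potency, from ADI), C (share of the commodity in total
diet), D (frequency of dosing, FOD = 100 × application days / growth days),
E (evidence of high-exposure groups, fixed at 3 when no data exist), and F,
the observed residue level

    F = (F0·1 + F1·2 + F2·3 + F3·4) / n ∈ [1, 4],

where F0..F3 count samples that are residue-free, below the MRL, at 1–10×
MRL, and at ≥10× MRL (a ratio of exactly 1 falls in the third class,
consistent with the inclusive exceedance rule). The composite score is the
grouped form

    S = (A + B)·C + (D + E)·F.

The grouped form is the scheme's structural reading (toxicity × dietary
share plus usage × observed residues); the flat reading A + B·C + D + E·F
is available via `grouped=False` for comparison. With the default bins a
frequently used, moderately toxic fungicide detected in nearly every sample
scores in the low twenties, which is what places it in the high band.

Default bins are 4-level reconstructions, user-overridable as a whole
(`ScoreTable`): A by WHO acute-hazard LD50 classes (<50, 50–500, 500–2000,
>2000 mg/kg → 4, 3, 2, 1), B by ADI decades (≤0.001, ≤0.01, ≤0.1, >0.1
mg/kg bw/day → 4, 3, 2, 1), C by diet share (<1, 1–5, 5–10, ≥10 % → 1, 2,
3, 4), D by FOD (<5, 5–25, 25–75, ≥75 % → 1, 2, 3, 4). Bands: S < 15 low,
15 ≤ S < 20 medium, S ≥ 20 high; the medium band's upper edge is half-open
("15 to 19.9" read as one-decimal reporting of [15, 20)).

FOD requires field-use records that a market survey does not have. Where
no per-pesticide FOD is supplied, the demonstration pipeline uses each
pesticide's detection frequency (percent of samples) as its FOD proxy: a
compound found in most samples is, for ranking purposes, one in frequent
use. Real assessments should supply measured FOD.

## Deterministic dietary exposure

Chronic: NEDI = STMR × Fi / bw (mg/kg bw/day), HQc = NEDI / ADI,
%ADI = 100 × HQc. The residue value STMR is interpreted per assessment
level: the per-sample hazard index uses that sample's own measured
concentration (the default, since indices are reported per fruit), while
the survey-level table uses the median over detected samples, with the
maximum as HR for the acute worst case.

Acute: the case-based IESTI, selected by edible unit weight Ue against
the 25 g threshold and the large portion LP (97.5th-percentile eater's
portion):

    case 1  (Ue < 25 g):       IESTI = LP·HR / bw
    case 2a (25 g ≤ Ue < LP):  IESTI = (Ue·HR·v + (LP − Ue)·HR) / bw
    case 2b (Ue ≥ LP):         IESTI = Ue·HR·v / bw

v is the between-individual variability factor, default 3 (the standard
value for unit-weighted commodities). The Ue = LP boundary is assigned to
case 2b; the two formulas agree there algebraically, so the assignment is
value-neutral (tested numerically to 1e-12). HQa = IESTI / ARfD; a pesticide
with no ARfD set yields a "not computable" flag rather than an error and is
excluded from the acute sum (counted in `n_skipped`).

Cumulative risk per sample is the hazard index HI = Σ HQ over the
pesticides detected in that sample, with per-pesticide contribution shares.
HI > 1 flags the sample as potentially unacceptable. Both HQ and IESTI are
homogeneous of degree 1 in concentration, so HI is linear in residues — a
property the tests exercise directly.

Default population profiles are adults (bw 70 kg, Fi 0.04 kg/day, LP 0.30
kg) and children (bw 20 kg, Fi 0.03 kg/day, LP 0.20 kg); unit edible
weights are orange 0.14, lemon 0.06, tangerine 0.07, grapefruit 0.26 kg.
Body weights are conventional reference values; the consumption figures are
plausible placeholders for a citrus-consuming European population and must
be replaced with population-specific survey data for any real assessment.

## Monte Carlo chronic risk

The cumulative chronic hazard index HI = Σ_p C_p·Fi / (bw·ADI_p) is
propagated through sampled inputs: concentrations C_p and ingestion rate Fi
lognormal, body weight normal truncated at zero (inverse-CDF sampling, so
no draw is nonpositive), reference doses fixed by default with an optional
uniform ±20% band, and point masses for anything held constant. Sampling is
plain Monte Carlo with a seeded generator and a fixed draw order, so a
repeated run is bit-identical; the default iteration count is 100,000.

Concentration distributions are fitted to detected residues by matching the
sample median and the log-scale SD (GSD = exp(SD of log concentrations));
a single detection degenerates to a point mass. Because every fitted
pesticide contributes to every draw, the simulated HI describes a
worst-case fruit carrying the survey's full detected panel — conservative
relative to the per-fruit co-occurrence actually observed, which is why the
simulated medians sit above the deterministic per-sample indices.

The output distribution is summarized by median (preferred: the
distribution is right-skewed, so the mean overstates the typical value),
mean, SD (n−1), 5th/95th percentiles (linear interpolation) and sample
skewness. Sensitivity is the Spearman rank correlation of each stochastic
input with the HI draws (ties mid-ranked); a constant input is reported as
NaN. For this formula the signs are analytic — intake positive, body weight
negative — and the tests require them. Latin-hypercube or partial-rank
alternatives were considered and not adopted: plain Monte Carlo and plain
rank correlation are the methods the pipeline models.

## Synthetic survey generator

The generator emulates a market surveillance study of 76 citrus samples
(28 oranges, 26 lemons, 17 tangerines, 5 grapefruits) screened for a
23-pesticide panel whose raw data are not publicly deposited. For each
sample and pesticide, detection is Bernoulli with the study's reported
frequency (imazalil 0.88, azoxystrobin 0.41, dimethomorph 0.37, boscalid
0.33, pyrimethanil 0.26, thiabendazole 0.24; the rest rare, down to
single-sample detections at 1/76); detected concentrations are lognormal,
clipped to a quantification floor (0.005–0.01 mg/kg) and, where the study
prints a maximum, to that maximum (thiabendazole 5.9 mg/kg). Medians and
GSDs are reconstructions constrained by the printed ranges and exceedance
counts: typical imazalil draws span 0.01–3.9 mg/kg with a ~1% tail above
its 5 mg/kg MRL, and the low-MRL compounds (dimethomorph, propiconazole,
fluazifop at 0.01 mg/kg MRL) are centred so their expected exceedance
counts match the study's reported 8/3/2 samples. Twenty-two panel members
are named in the study; the 23rd is not recoverable from the text and is
filled with tebuconazole, a common citrus fungicide, keeping the
EU-unapproved count at nine.

Detections are independent across pesticides by default. Real surveys show
co-occurrence (postharvest fungicides travel together); a Gaussian-copula
option (`cooccurrence=` correlation matrix) induces it, but no fitted
copula parameters are claimed — the option exists so correlated scenarios
can be studied, not to assert the study's dependence structure.

What the generator does *not* emulate: commodity-specific concentration
differences, analytical censoring between LOD and LOQ, seasonal or origin
effects, and the true joint distribution of residues. Tests passing on
generated surveys therefore validate the computation chain and its
statistical behavior, not any claim about real monitoring data.

The accompanying toxicology/MRL reference table (`default_reference_set`)
is likewise a synthetic reconstruction assembled from public reference
ranges; it is representative, not a regulatory snapshot, and real
assessments should load their own table from CSV.

## Numerical choices and degenerate inputs

- Percent rounding is half-away-from-zero to the nearest whole percent.
- Empty surveys raise an undefined-ratio error rather than returning 0%.
- An empty HQ set gives HI = 0 with no contributions; contributions are
  returned only when HI > 0 (they then sum to 1 exactly).
- Score bins must cover (0, ∞) without overlap by construction (edges +
  one score per interval); a value can therefore never fall outside the
  table.
- Lognormal GSD of exactly 1 (single detection) is a point mass, not a
  zero-variance sampling call.
- Reported problem sizes: the shipped pipeline runs at the emulated
  survey's own scale (76 samples, 23 pesticides) and the full 100,000 MC
  iterations.

## Known limitations

- Consumption parameters are placeholders; headline hazard quotients from
  the emulated survey are qualitative illustrations only.
- The acute (IESTI) pathway has no probabilistic counterpart; the Monte
  Carlo stage covers chronic risk only.
- Processing factors (peel/pulp partition) are not modelled; residues are
  whole-fruit, which overstates exposure for peeled commodities.
- The MC cumulative sum covers the survey's whole detected panel per draw
  (worst-case fruit) rather than resampling per-fruit co-occurrence.
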
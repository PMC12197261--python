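# Methods

## Data model and aggregation

A toxicity record is one endpoint measurement (species, genus,
acute/chronic, endpoint code, concentration in μg/L, literature source).
Screening enforces the endpoint whitelists (acute: LC50/EC50/IC50;
chronic: NOEC/LOEC/MATC plus chronic EC50/LC50), positive finite
concentrations and nonempty taxonomy; rejections are reported per rule,
never raised, so accepted ∪ rejected always equals the input. There is
no automatic outlier elimination: published datasets rarely state an
elimination criterion, so curated exclusions must be made explicit
through the per-record `exclude` flag, which the screener logs.

Aggregation is the geometric mean, exp(mean(ln c)), applied twice:
records → species value (SMAV/AVE or CVE), species → genus value
(GMAV). It is scale-equivariant, order-independent, bounded by the
member extremes and the identity on singletons; tests assert all four
properties. All arithmetic is done in full precision; 3-significant-
figure rounding is a display convention only.

### Acute-to-chronic ratio

ACR is estimated per species with both acute and chronic records as
gm(matched acute records)/gm(chronic records), then combined across
species by geometric mean. The default pairing policy is `same_source`:
the acute side is restricted to records sharing a `source_id` with the
species' chronic records, the usual "same experimental conditions"
convention for ACRs. On the packaged table this pairs *Daphnia pulex*
(ratio ≈ 15.9) and *Pimephales promelas* (≈ 38.3), overall ACR 24.7.
The `all_records` policy (every acute record of the species) is kept
for sensitivity analysis; it lowers the overall ACR to ≈ 19.8 because
two lower-valued *D. pulex* acute tests from an unrelated source enter
the numerator.

## SSD construction and fitting

Species values are log10-transformed ("lg") and ranked ascending.
Cumulative frequencies use F_R = (Σ_{r≤R} f_r)/(Σf + 1) with tied
values sharing one rank of frequency f = tie count; for n distinct
species this is R/(n+1), strictly inside (0, 1), so every empirical
point is attainable by a strictly monotone CDF.

The fitting criterion is nonlinear least squares of the candidate CDF
against the empirical frequencies — a curve-wise regression of y on x,
matching how SSD software reports a curve R². Candidates are the
logistic and normal CDFs on log10 concentration (the log-logistic and
log-normal SSDs); the same families on the raw scale are available but
not default, since concentration data spanning four orders of magnitude
make raw-scale fits degenerate. Initialisation is location = median(x),
scale = IQR(x)/2, with up to five deterministic perturbation restarts
(fixed sub-seed) keeping the lowest SSres iterate. Model selection
maximises R² = 1 − SSres/SStot (SStot about the mean empirical
frequency), breaking ties by lower RMSE = √(SSres/n), then by the
Anderson–Darling statistic of the fitted family against the x sample
(scipy's estimated-parameter A–D with its interpolated p-value, reported
as a diagnostic). HCp inverts the selected CDF and back-transforms,
10^quantile; at p = 0.05 the logistic quantile is the closed form
location − scale·ln 19, and the numeric inversion is tested against it
to 1e−9 relative. A maximum-likelihood fit of the same families is
provided as an option; it shows smaller small-sample HC5 bias but is
not the default because the reference procedure is the curve fit.

On the packaged acute data (18 species) the log-logistic fit gives
location 4.3151, scale 0.4821, R² = 0.954, HC5 = 786 μg/L; these exact
values are frozen as regression constants in the test suite. Least
squares on plotting positions is a biased HC5 estimator at this sample
size — in a 200-replicate simulation at n = 18 from a known log-logistic
SSD the fitted scale averages ≈ 8 % high and the median HC5 sits ≈ 17 %
low of the estimand, while the location estimate has standard deviation
≈ 0.21 log10 units (the information bound for logistic location at
n = 18, √(3σ²/n), is 0.204, so no estimator does materially better).
The recovery tests assert bands calibrated to that sampling
distribution.

## Criteria assembly

* **AF**: WQC = min(species acute values)/ACR. With ACR ≥ 1 the result
  never exceeds the most sensitive species' value.
* **TPR** (EPA 1985): with the four GMAVs whose P_R = R/(N+1) is
  nearest 0.05 (ties toward lower rank),
  S² = [Σ(lnG)² − (ΣlnG)²/4]/[ΣP − (Σ√P)²/4],
  L = (ΣlnG − S·Σ√P)/4, FAV = exp(S·√0.05 + L). The formula is exact
  when lnG is linear in √P and returns the common value for four equal
  GMAVs — both used as oracles in the tests. CMC = FAV/2;
  CCC = min over the populated subset of {FCV = FAV/ACR, FPV, FRV};
  no plant or residue values exist for Fe³⁺, so CCC = FCV here, with
  the omissions logged.
* **SSD**: SWQC = acute HC5/SAF. If at least `min_chronic_n` chronic
  species are available a chronic SSD supplies LWQC = HC5/LAF; otherwise
  LWQC = acute HC5/ACR (logged fallback). Defaults: SAF = LAF = 2 (the
  conventional factor when an SSD covers several trophic groups),
  `min_chronic_n` = 8 (common SSD guidance asks for ≥ 8–10 species;
  the packaged 4 chronic species trigger the fallback).

All criteria scale linearly under a global rescaling of the input
concentrations, which the suite asserts.

## Risk quotients

QR = MEC/PNEC per site, with the reported site mean as MEC and
SWQC/LWQC as the acute/chronic PNEC. Classes: low for QR < 0.1, medium
for 0.1 ≤ QR ≤ 1, high for QR > 1 — the two boundary points are
assigned to medium so the classes partition the line (stated in output
metadata). Sites reporting an SD get interval quotients from mean ± SD,
with the lower bound clipped at 0 before division. Records lacking a
mean are carried as `not_computable` and excluded from tallies and
means; means across sites are arithmetic. Basin is an input column (a
province→basin helper map ships as editable CSV data, since basin
merges are a reporting choice, not geography code should hard-code).

## Synthetic data

`generate_exposure` draws per-site replicate concentrations lognormally
(base-10 location/scale set per basin), summarising to mean/SD/min/max —
the shape of published monitoring summaries — with optional mean-free
sites emulating publications that report only ranges, and a basin list
that can encode a north/south contamination contrast. Defaults (12
replicates per site; basin log10-SD ≈ 0.15–0.4) span the within-site
variability typical of seasonal surface-water iron monitoring.
`generate_toxicity` draws species sensitivities from a configured
log-logistic or log-normal SSD and jitters per-species records with a
lognormal coefficient of variation, centred in log space so the species
geometric mean equals the drawn sensitivity exactly (cv = 0 degenerates
to identical records). Seeds split hierarchically
(master → basin/species → site) via `numpy.random.SeedSequence`, so
extending a configuration never perturbs existing draws.

What the generators do not emulate: spatial or temporal correlation
between sites, censored detection limits, mixed endpoint quality, or
taxonomic structure in sensitivities. Passing recovery tests therefore
demonstrates the estimators' statistical behaviour under the assumed
sampling model, not robustness to real-data pathologies.

## Numerical and degenerate-input choices

Scale parameters are bounded positive in the optimiser; fits need ≥ 3
distinct x values; duplicate x points are collapsed before fitting.
R² of a zero-variance target is defined as 1 for a perfect fit and −∞
otherwise. Empty aggregation inputs, nonpositive concentrations, an
ACR with no paired species, fewer than four genera for TPR, and
nonpositive criteria in the quotient all raise a validation error that
names the offence; screening-stage problems are reported, not raised.

## Known limitations

Criteria here are total-dissolved-iron proxies: no speciation chemistry
or bioavailability correction (pH, hardness, DOC) is applied, and
exposure means aggregated from heterogeneous publications carry
unmodelled sampling designs. The TPR route rests on only the four most
sensitive genera and is correspondingly unstable to the tail of the
dataset. Bootstrap confidence intervals on HC5 and 3-parameter SSD
families (e.g. Burr III) are out of scope.
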
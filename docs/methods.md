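# Methods

## The screening model

A screening plate measures promoter activation through a two-channel
fluorescence readout: TdTomato driven by the promoter of interest and
TagBFP2 as a constitutive transfection control. The analysis assumes that
per-well transfection efficiency acts multiplicatively and identically on
both channels, so the ratio `R = TdTomato / TagBFP2` cancels it; dividing
by the mean scramble-control ratio puts every well on a dimensionless fold
scale with the control mean pinned at exactly 1. Normalisation is computed
per well and folds are aggregated per condition — per-condition SEMs over
replicate wells require well-level values, so a plate-level reading of the
normalisation would be incompatible with the reported statistics. Two
readout modes are supported: bulk well sums, and per-cell sums from a
high-content reader, where the well value is the ratio of per-cell channel
means over the TagBFP2-positive cells.

## Candidate calling

Conditions are compared by classical one-way fixed-effects ANOVA on the
fold values, followed by Dunnett's many-to-one procedure against the
scramble control with the pooled within-group variance (df = N − k over
all groups). Two-sided comparisons are the default — activation is the
expected direction, but the procedure is symmetric and a
one-sided-greater variant is available (`alternative="greater"`).

Adjusted p-values are exact in the equal-replicate case: the k Dunnett
statistics are equicorrelated multivariate t with correlation 1/2, and
`P(max|T_i| ≤ q)` is computed by conditioning on the shared control-group
component (Gauss–Hermite, 48 nodes) and on the pooled scale (Gauss–Legendre
against the explicit chi density truncated at 1e-13 mass, 48 nodes). With
k = 1 this reproduces the pooled two-sample t-test p to ~1e-13, and the
test suite cross-checks the general case against an independent
implementation (`scipy.stats.dunnett`). Unequal group sizes use seeded
Monte Carlo (default 100,000 draws; the seed is then mandatory), with the
adjusted p floored at the raw p so the `adjusted ≥ raw` invariant cannot be
broken by simulation noise. α defaults to 0.05 and adjusted p-values are
binned into the conventional marks (\* ≤ 0.05 … \*\*\*\* ≤ 0.0001).

## Synergy

Each dual condition is evaluated against its two single-guide conditions
and the scramble. The interaction test is the 2×2 factorial ANOVA
interaction term (factors presence-of-A, presence-of-B), fitted by OLS via
statsmodels; for balanced designs this equals the cell-mean contrast
`n(m_AB − m_A − m_B + m_Scr)²/4` over the within-cell mean square, which
the tests verify to 1e-10. The Combination Index uses condition mean
folds: `E = act_A + act_B`, `CI = E/act_AB`. Classification requires the
interaction to be significant first, then CI ≷ 1 decides direction; no
tolerance band around CI = 1 is applied, and no multiple-testing
correction is applied across pairs by default (Holm is available behind a
flag).

Two different additivity baselines coexist by design: the interaction
contrast vanishes when `act_AB = act_A + act_B − act_Scr`, while CI = 1
when `act_AB = act_A + act_B`. They differ by the baseline of 1, and both
are reported (`expected_additive` and `ci` columns) rather than reconciled.
An observed combined activation ≤ 0 cannot arise from ratio data but is
guarded for user-supplied tables: CI is flagged undefined (NaN) and the
pair classified `undefined`.

Degenerate noiseless designs are given deterministic conventions: zero
residual variance with a zero interaction contrast reports p = 1 (no
evidence of interaction); zero residual variance with a non-zero contrast
reports p = 0.

## Promoter context

All interval arithmetic is promoter-local, 0-based, half-open. A TFBS
cluster is a single-linkage chain: sites overlapping or within 10 bp
(edge-to-edge) of each other merge transitively, and chains with ≥ 10
members are clusters. The chained reading is an interpretation — "within
10 bp of each other" could also mean pairwise — adopted because transitive
chaining is how genomic interval clustering is conventionally computed; a
union-find transitive-closure oracle in the tests pins the behaviour.
Guide-site annotation measures distance to TSS from the site midpoint
(symmetric under strand flips; the anchor is not dictated by the assay),
distance to the nearest cluster edge-to-edge (0 when overlapping, missing
— not infinite — when no clusters exist), and TFBS counts with inclusive
boundaries (≤ 50, ≤ 100) that include overlapping sites, preserving
`n_overlap ≤ n_within_50 ≤ n_within_100`. TFBS prediction itself is input
(a motif-scanner export); an optional score filter is provided but
stringency is the producer's concern. Association analyses are Pearson
correlation (two-sided p via the t transform, ≥ 3 pairs, zero-variance
inputs flagged undefined) and Welch's t-test with Satterthwaite df between
an externally supplied two-group split — the split is an explicit input
because the grouping in practice is visual, and inventing a threshold
detector would overstate the method.

## qPCR quantification

One formula covers both conventions in use: the efficiency-corrected
ratio `E_t^(ΔCt_t)/E_ref^(ΔCt_ref)` with per-gene efficiencies in (1, 2],
defaulting to 2, where it reduces exactly to `2^(−ΔΔCt)`. Per-primer
efficiencies are rarely reported, so E = 2 is the documented default
assumption. The control anchor is the mean Ct of the control condition for
each gene (not a per-plate calibrator), matching quantification relative
to control samples. Condition-level statistics are delegated to the same
ANOVA/Dunnett stage as the screen.

## Guide design

The PAM defaults to `NNGRRT` — the canonical motif of the *S. aureus*
Cas9 system implied by the sgRNA scaffold — and is configurable, as is the
22-nt spacer length. Scanning is exhaustive over both strands with IUPAC
codes honoured and overlapping matches reported; spacers truncated by the
window edge are dropped, as are candidates containing N. Genome-wide
alignment verification of scramble spacers is replaced by a deterministic
exact k-mer exclusion screen (default k = 12, both strands) against
user-supplied sequences; this is a desk-scale screen, not an off-target
predictor. Template-strand validation reduces to reporting the strand —
no published criterion exists to filter on. Shortlisting "top n" sites
uses a farthest-point spacing heuristic seeded with the window extremes;
it spreads candidates, it does not rank activity. Windows outside
500–600 bp warn rather than fail.

## Synthetic data

The generators encode the study conditions the analysis assumes:
29 conditions (7 singles, 21 pairs, scramble) with 3 replicate wells. The
default activation map places the twelve significantly activating
conditions of the Adam17 screen at their printed mean folds (4.01, 4.00,
6.64, … 6.66 for 1+5, 4.16 for 2+5) and everything else at baseline 1.
TagBFP2 well sums are LogNormal(μ = 9.2, σ = 0.5) — median ~10⁴ AU with
the 2–3× spread typical of transient transfection; reporter noise is
mean-one lognormal (σ = 0.2) applied to TdTomato only, so
`E[ratio] = baseline × activation` exactly and parameter-recovery tests
are unbiased in expectation; the baseline TdTomato/TagBFP2 ratio is 0.1
(a weak promoter against a strong constitutive control). TFBS maps place
uniform background sites plus clusters constructed with bounded jitter so
the default detection provably recovers them. Ct tables put the reference
gene at Normal(22, 0.15) cycles and shift the target down by log_E(fold).
All generators require an explicit seed and touch no global RNG state.

What the simulators do **not** emulate: plate-position and batch effects,
channel bleed-through, saturation, segmentation errors in per-cell mode,
cell-state heterogeneity, or epigenetic context — passing tests show the
statistics are implemented and calibrated correctly under the stated
model, not that the model captures every failure mode of real plates.

## Problem sizes and numerical choices

The calibration suites run at sizes chosen to make Monte-Carlo error
comfortably smaller than the tested tolerances while keeping the default
test run quick: 10,000 simulated null datasets for the family-wise error
check (±0.01 band at FWER 0.05), 2,000 plates for activation-multiplier
recovery (2% band, small reporter noise σ = 0.1 per the oracle's
construction), 200 random designs for each brute-force ANOVA oracle, and
1,000 random interval sets for the clustering oracle. The Dunnett
quadrature node count (48 × 48) gives ~1e-13 agreement with the closed
k = 1 case; the Monte-Carlo path uses ≥ 100,000 draws.

## Known limitations

No plate-effect or batch correction across plates; no robust or
nonparametric alternatives to the ANOVA stages; synergy is limited to
two-guide combinations and the response-additivity frame (no Loewe/Bliss
dose-response modelling); guide design performs no off-target scoring,
chromatin weighting or learned efficacy prediction; Ct calling and
melt-curve QC are instrument territory.
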
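# Methods

This note documents the models implemented in `acidstress`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Chemiosmotic PMF model (`acidstress.pmf`)

The proton motive force is the Mitchell decomposition
Δp = Δψ − Z·ΔpH with Z = ln(10)·R·T/F expressed in mV (≈61.54 mV at
310.15 K, ≈60.15 mV at 303.15 K). Sign conventions: Δψ = ψ_in − ψ_out,
ΔpH = pH_i − pH_e, so a healthy cell (pH 7.6 inside / 7.0 outside,
Δp = −160 mV) carries a negative pH-gradient force (−36.9 mV) and a negative
Δψ (−123.1 mV). The normal state is *closed* rather than fully specified:
given pH_i, pH_e and the target PMF, Δψ is solved from the decomposition.
Constants: R = 8.314 J·mol⁻¹·K⁻¹, F = 96485 C·mol⁻¹; default temperature
310.15 K (growth), 303.15 K selectable for plate-reader contexts.

Acid speciation is Henderson–Hasselbalch: protonated fraction
1/(1+10^(pH−pKa)), with octanoic acid at pKa 4.89. `equimolar_pH` recovers
the pKa by numerical inversion (Brent, xtol 1e−12) as a consistency check
rather than returning the constant.

**Shock branches.** An inorganic (fully dissociated) acid adds protons and
counter-anions in equal measure: Δψ is unchanged and the measured
intracellular pH (and, for unadjusted media, extracellular pH) are inputs —
the model never predicts the post-shock pH of an unadjusted medium. A
carboxylic acid enters as the neutral species and deprotonates inside; the
proton load is treated as uncompensated positive charge, shifting Δψ by
+Z·(pH_i,normal − pH_i,shock), the Nernst equivalent of the proton-pool
fold-increase. This is the minimal rule that produces the PMF inversion the
scenario describes; it is a modeling idealization, not a fitted quantity.

**Adaptation.** With pH values pinned, the solver returns
Δψ_adapted = target − ph_force (closed form), cross-checked by bisection and
required to hit the target within 0.1 mV. The carrier-ion fold change is
exp(|ΔΔψ|·F/RT) for a single monovalent ion — a deliberate simplification
(no multi-ion partitioning). Note that a pure Nernst conversion of the
required shift gives fold changes of order 10⁴ for the C8 scenario; the
often-cited ~3-fold anion accumulation from acetate-challenge measurements
is not derivable from this model and is neither hard-coded nor asserted.

## Reporter pH (`acidstress.reporter`)

Calibration standards (pH equilibrated across the membrane with a permeant
weak acid) are fitted with a linear fluorescence–pH model by least squares
over all replicate points; a monotone PCHIP spline through the standard
means is available behind `form="spline"`. Fitting requires ≥3 distinct pH
values spanning ≥1 unit with strictly increasing means. Replicate sample
readings are summarized by their mean; with ≥3 replicates a t-based 95%
interval on the inverted values is attached.

**Censoring.** The method's reliable detection limit is pH 5.5, but the
calibration itself extends slightly below it (standards down to pH 5.25), so
sharp acid shocks near pH 5.3 are resolved numerically. Estimates mapping
*below the calibrated span* are unreliable and are reported censored at the
5.5 limit — an upper bound, "the intracellular pH may be lower". No upper
censoring is applied. This mirrors experimental practice, where a value of
5.32 is reportable while long-term acidification is stated as ≤5.5.

## Differential expression (`acidstress.expression`)

Inputs are log2 intensity matrices; preprocessing is per-sample median
centering (probe-level background correction of real arrays is out of
scope). The test statistic is the classical equal-variance two-sample t —
the permutation supplies the null, so variance moderation is unnecessary;
a Welch variant would change nothing structurally.

**Permutation null.** Label splits are enumerated exhaustively when
C(n, n_treated) ≤ n_perm, otherwise n_perm seeded draws are taken. Two
constructions are offered. The *per-gene* null compares each gene with its
own permuted statistics (exhaustive p = fraction of splits with
|t*| ≥ |t|, identity included; sampled p = (b+1)/(B+1)). With 3 vs 3
replicates this has an exact floor of p = 2/20 = 0.1, which no multiplicity
correction can push under q = 0.05. The *pooled* null — the default for
`de_analysis` — therefore pools permuted |t| values across all genes,
excluding splits equivalent to the observed labeling and letting the
observed statistic supply the add-one; this borrows the null across the
transcriptome and yields the fine-grained p-values that few-replicate
designs need. The pooled null assumes approximately exchangeable gene-level
null distributions; strongly heteroskedastic genes would violate this.

q-values are Benjamini–Hochberg adjusted p-values (deterministic;
a Storey-type estimator would give smaller q at high signal density).
Significance is q < 0.05 (strict) and |log2 FC| ≥ 1 (inclusive); signed
linear ratios are +2^|FC| for increases and −2^|FC| for decreases. The
packaged C8 reference table ships as TSV with these conventions, sorted by
ratio.

## NCA (`acidstress.nca`)

Identifiability follows the standard NCA criteria: full (generic) column
rank of the support pattern, full rank of each TF's reduced subnetwork after
deleting that TF's column and target rows, and at least as many sample
columns as TFs. Generic rank is evaluated numerically on the support filled
with random values (best of three draws).

Estimation is alternating least squares over the support: the A-step solves
each gene's row restricted to its regulators, the P-step solves all
activities given A; each half-step is exact least squares, so the residual
trace is non-increasing within a run (asserted). The landscape has genuine
local minima even for identifiable noiseless systems, so five independent
standard-normal initializations (seeded) are run and the lowest-residual
solution kept. Stopping: relative residual decrease < 1e−8 or 500 sweeps;
rank-deficient subproblems fall back to a ridge solve (λ = 1e−8) with a
warning.

**Gauge.** (A·D, D⁻¹·P) is equivalent for any invertible diagonal D; the
representation is fixed by scaling each TF column of A so its
largest-magnitude weight is +1, with the column sign anchored to the
topology's majority edge sign when signs are provided. After gauge fixing,
activities from different starts coincide to ≤1e−6 on identifiable
noiseless data (tested).

**ΔTFA significance.** Mean treated-minus-control activity per TF, with an
empirical p from bootstrap resampling of group-centered replicate columns
(null of no difference), add-one estimator, default 1000 draws; p is omitted
with fewer than 2 replicates per group. TF activity magnitudes have no
external reference scale, so tests assert directional recovery on
simulations, not absolute values.

## Physiology metrics (`acidstress.physiology`)

Specific growth rate μ is the least-squares slope of ln(OD550) versus time
over a user-specified exponential window (≥3 points); percent inhibition is
100·(1 − μ_treated/μ_control). Lipid metrics partition the eight tracked
species into saturated {C12:0, C14:0, C16:0, C18:0} and unsaturated
{C16:1, C18:1, C17cyc, C19cyc} — cyclopropane fatty acids count as
unsaturated since they are methylenated derivatives of unsaturated
precursors. Average chain length is the mol%-weighted carbon count; the
default convention counts actual carbons (C17cyc = 17, C19cyc = 19), with a
"precursor" convention (16/18) selectable because either grouping is
defensible when 16- and 18-carbon families are compared. GABA accounting
uses 1:1 glutamate-decarboxylation stoichiometry; the proton count is a
lower bound because GABA can be further converted to succinate. The
Bonferroni utility is α/m (0.05/20 = 0.0025 for an amino-acid survey).

## Synthetic data (`acidstress.synth`)

Generators emit exactly the statistical structure the estimators assume,
plus a ground-truth record for recovery tests; identical seeds give
identical output.

* **Expression (NCA)**: A drawn on the support with magnitudes U(0.5, 1.5)
  and topology signs; E = A·P per condition plus Gaussian noise in log2
  space (default σ = 0.25 for DE studies, 0.05 for NCA recovery).
* **DE spikes**: baselines U(4, 12) log2 units, spiked genes shifted by 2
  log2 units (4-fold), 3 replicates per condition.
* **Growth**: exponential OD550 from 0.05 with lognormal 2% read noise,
  sampled every 15 min over 5 h — plate-reader-like density, chosen so the
  fitted-rate precision (~0.75 percentage points on the inhibition)
  supports a ±2-point round trip of the embedded 23% inhibition at 10 mM
  C8. μ_control = 0.50 h⁻¹.
* **Fluorescence**: linear truth F = 120·pH − 560 a.u. over standards at
  pH 5.25–8.0, 4 replicates, lognormal 2% noise; presets embed pH 5.32
  (unadjusted 20 mM HCl), 5.20 (long-term C8, below the floor), 6.80
  (producing strain), 7.60 (unstressed).
* **Lipids**: Dirichlet draws (concentration 2000, ≈0.5 mol% jitter —
  GC-FAME-level precision) around strain/dose-dependent means; wildtype
  ~9 mol% cyclopropanes, overexpresser ~35 mol%, knockout exactly 0. The
  wildtype dose response moves mass from C16:0 to C18:1 (S:U falls, length
  rises); the overexpresser instead shortens slightly, resisting the S:U
  drop.
* **GABA**: lognormal 10% noise around arm means (intracellular,
  extracellular): control (5, 5), +glutamate (2.5, 7.5) — export up, total
  conserved — +C8 (2, 2.5) and +C8+glutamate (1.5, 3), all pools suppressed.
  Means are order-constrained to the qualitative physiology, not fitted to
  published concentrations.

What passing these tests shows: the estimators are correct and
well-calibrated *under their own assumptions*. What they do not show:
robustness to probe-level microarray artifacts, non-linear reporter
response, non-exponential growth phases, chromatographic integration error,
or regulatory topologies with false edges — none of which the generators
emulate.

## Pipeline

`run_pipeline` derives one integer substream per stage from the run seed
(SeedSequence spawn, kept below 2³¹), executes enabled stages in dependency
order, and writes per-stage TSVs plus `summary.json`; reruns with the same
config are byte-identical. Default problem sizes (500 genes, 10 000
permutations, 1000 bootstrap draws, 3-TF demo topology) run in seconds.

## Known limitations

* The carboxylic-shock Δψ rule is a minimal idealization; real cells buffer
  part of the proton load chemically.
* The pooled permutation null assumes cross-gene exchangeability.
* NCA multi-start does not *guarantee* the global optimum on hard
  topologies; the residual trace and convergence flag expose failures.
* Lipid dose-response shapes are linear in dose by construction; real
  composition shifts saturate.
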
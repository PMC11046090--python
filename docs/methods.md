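# Methods

This note documents the models, defaults and design choices behind
`mrmquant`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic fixtures do
and do not demonstrate.

## Peptide chemistry

All mass arithmetic uses monoisotopic residue masses from a single
plain-text table (`src/mrmquant/data/monoisotopic_masses.tsv`), so that
independent test oracles and the implementation cannot drift apart. A
peptide's neutral mass is the residue sum plus water (18.010565 Da), plus
+57.021464 Da per cysteine for fixed carbamidomethylation (samples are
assumed reduced and alkylated with iodoacetamide; no variable modifications
are modeled), plus the heavy-label shift when the peptide is an internal
standard: +8.014199 Da for (¹³C₆/¹⁵N₂)-Lys, +10.008269 Da for
(¹³C₆/¹⁵N₄)-Arg, both computed from the ¹³C−¹²C (1.0033548 Da) and ¹⁵N−¹⁴N
(0.9970349 Da) isotope differences. m/z values follow the usual proton
convention, (M + z·1.007276)/z; only b- and y-series fragments are
produced (no neutral losses, no a/c/x/z ions, no isotope envelopes —
irrelevant at unit resolution on a triple quadrupole). Isoleucine and
leucine are distinct letters with identical mass; proteotypicity is a
sequence-level notion here.

Digestion is rule-based rather than kinetic: trypsin cleaves C-terminal to
K/R except before proline; LysC cleaves after every K including K|P; the
sequential LysC-then-trypsin protocol is modeled as the union of the two
cleavage-site sets, which reproduces the final peptide population without
simulating digestion order. Missed-cleavage products (contiguous unions up
to a configurable count) are exposed separately with their missed-site
count; assay design uses fully cleaved peptides only, since nothing in the
protocol suggests monitoring missed cleavages.

## QconCAT design

Selection criteria for proteotypic peptides are not uniquely fixed by
common practice, so they are explicit and configurable
(`SelectionRules`): fully cleaved, length 7–20, C-terminal K/R, unique as a
digest product across the entire proteome, and free of exclusion motifs —
methionine anywhere (oxidation), N-terminal Q (pyro-Glu), and ragged starts
(peptide beginning with K/R, i.e. born from a KK/RR/KR junction). When a
protein offers more candidates than requested, ranking is deterministic:
fewest soft flags (cysteine content, NG/DG deamidation motifs), then length
closest to 12 residues (a good MRM ionization/specificity compromise), then
lexicographic. Proteins with no acceptable candidate are returned in a
failure report, never dropped silently.

Constructs pack peptides in input order into ⌈n/capacity⌉ chunks
(capacity default 50). The single digestibility hazard between
K/R-terminated peptides under LysC+trypsin is an R|P junction (LysC rescues
K|P), so each chunk is reordered minimally by a greedy pass with an exact
feasibility lookahead, memoized over the only state that matters — counts
of peptide classes (C-terminal residue × starts-with-P) and the current
chain end. If no ordering works the assembler raises rather than emitting a
construct that cannot release its peptides; every emitted construct is
re-validated by in-silico digestion (each peptide released intact exactly
once). Terminal purification tags are supported as opaque optional
sequences and default to empty.

## Assay construction

Fragment choice defaults to singly charged y-ions y3…y(L−1), highest index
first, keeping `min_transitions` (default 3) — higher y-ions cover more
sequence and are the standard choice; b-ions are computable but not
selected by default. Precursors are 2+ unless the 2+ m/z exceeds 1250
(instrument mass range), then 3+. The voltage ramps are

* DP = 0.049·Q1 + 42.6
* CE = 0.036·Q1 + 6.9 (2+) and CE = 0.054·Q1 − 2.4 (3+) — the two ramps
  are assigned to 2+ and 3+ in that order, matching the vendor convention
  that the steeper ramp with lower intercept belongs to the higher charge
* CXP = 0.0391·Q3 − 2.23, which crosses zero at Q3 ≈ 57.03; below that the
  value is returned with a warning rather than clamped
* EP = 10 V constant; Q1/Q3 resolution is recorded as metadata ("unit",
  0.7 Da half-width) and not modeled as a peak shape.

Scheduling assigns each transition a symmetric window of
`detection_window_s` (default 120 s) around its predicted RT; predicted RT
is an input (from a table or the simulator), not a prediction model, which
keeps the builder deterministic. The concurrency report sweeps window
boundaries and computes per-cycle dwell as
(target_scan_time − n·overhead)/n with 2 ms overhead, warning below a 5-ms
floor.

Acylcarnitine precursor-ion scans use the common m/z 85.05 product and a
chain-length-dependent CE: −20 V for C0–C8, −25 V for C10–C14 (any
unsaturation or hydroxylation), −35 V for C16–C18. Chain lengths 9 and 15
belong to no published class and are rejected rather than interpolated;
counts outside 0–18 are rejected.

## Chromatogram simulator

Each trace is a Gaussian peak A·exp(−(t−rt)²/2σ²) plus a small constant
baseline (default 2 counts), sampled every target scan time (1 s) strictly
inside the transition's scheduled window. The light amplitude is
response × concentration × relative intensity; the heavy amplitude uses
the spiked amount and the *same* per-transition relative intensity
(Dirichlet-distributed per peptide) — this shared fragmentation pattern is
exactly what drives rdotp toward 1 for genuine peaks. Peak width defaults
to σ = 0.05 min (~3-s peaks, typical UHPLC); light/heavy RT shift defaults
to 0 (co-elution) and is configurable to exercise RT-matching failures.
Noise is multiplicative log-normal parameterized by CV
(σ_log = √ln(1+CV²)), applied pointwise; interference adds an extra
Gaussian (offset, amplitude-fraction) to chosen light transitions. All
draws come from one seeded generator; identical seeds give byte-identical
output, and changing only the noise seed leaves the ground truth intact.

What the simulator does *not* emulate: peak tailing, ionization
suppression/matrix effects, cross-run RT drift, detector saturation, and
correlated noise. Passing tests therefore certify the algorithmic logic
(integration, QC gating, ratio arithmetic), not robustness to real-matrix
pathology.

The study-matrix simulator mirrors a three-genotype design (default groups
WT/Tg/TgTg, n = 5 per group for protein-scale studies, n = 10 appropriate
for metabolite-scale ones): log-normal baseline abundances across analytes
(median 10, log-SD 1), multiplicative within-group noise at the stated CV
(default 10 %), planted fold changes multiplying a group's mean, and the
planted table embedded as ground truth. The default fixture size of 247
analytes matches the scale of a muscle metabolic-enzyme panel.

## Quantification engine

Peak areas are trapezoidal integrals above a baseline estimated as the mean
of the first and last three samples in the window (simple, deterministic,
and exact for a constant baseline under Gaussian fixtures), clamped at
zero. Apex RTs are read from the transition-summed trace per label.
rdotp is the cosine of the light and heavy area vectors, clipped to [0,1];
a zero-norm vector yields 0.

Interference elimination concretizes "transitions with observed
interference were eliminated" as a robust outlier rule on per-transition
light/heavy ratios: a transition is removed when it deviates from the
median ratio by more than k·MAD (k = 5) *and* by more than 20 % of the
median. The second gate exists because with 3–4 transitions the MAD is
estimated from 2–3 deviations and a pure k·MAD rule fires on ordinary
measurement noise almost half the time; genuine interference at ≥ 0.5×
peak amplitude inflates a ratio by ≥ ~50 % and is unaffected by the floor.
If removal would leave fewer than 3 transitions, nothing is removed and
the peptide is flagged `fail_min_transitions` — flagged, never silently
quantified.

The reported ratio is Σ(light areas)/Σ(heavy areas) over retained
transitions — summing weights transitions by signal, and is preferred over
averaging per-transition ratios (the alternative is one line of user code
on the returned areas). Concentration = ratio × spiked amount, in fmol/μg.
QC pass requires rdotp > 0.9 (strict), |ΔRT| ≤ 0.1 min (a tolerance chosen
as two peak sigmas; configurable), and ≥ 3 retained transitions; failures
carry no concentration. Protein roll-up is the mean of passing peptide
concentrations with n and CV reported; the best-peptide alternative was
rejected to keep protein values continuous under QC flips.

## Differential layer

Fold change is the ratio of arithmetic group means. The t test defaults to
Welch (unequal variances; n = 5 groups rarely justify pooling) with
Student available — the two differ and the choice is surfaced in every
API. Volcano selection uses strict gates, FC > 1.5 or FC < 1/1.5 (the
symmetric log-scale reading of "|fold change| > 1.5") and p < 0.05.
One-way ANOVA per analyte is followed by pairwise Student t tests against a
reference group, Sidak-adjusted with m = number of comparisons for that
analyte (the "versus reference" annotation style), not across analytes.
PCA is an SVD of the column-centered sample × analyte matrix with a
deterministic sign convention (largest-magnitude loading positive).
Heat-map preparation z-scores each analyte across samples (zero-variance
rows become zeros with a warning) and orders rows by average-linkage
hierarchical clustering on Euclidean distance with scipy's deterministic
leaf ordering. Statistical primitives (t, F, clustering, SVD) are
delegated to scipy/numpy; the Sidak closed form, gating logic and
conventions above are this package's.

## Problem sizes and numerical conventions

Test and acceptance runs use sizes that exercise the full logic while
staying desk-scale: 1,000 random sequences for digestion properties, 1,123
peptides/23 constructs for assembly, 200 peptides × 3 transitions × ~120
samples per trace for recovery, 100 seeded interference cases, and 1,000
(null) / 247 × 10 seeds (planted) analytes for the differential layer.
Noiseless closed loops recover ratios to ~1e-16 relative (trapezoid and
baseline subtraction are exact for these fixtures); tests assert 1e-9.
Ties and degeneracies are pinned throughout: strict QC inequalities,
closed RT-match boundary (|Δ| = tol passes), p = 1 for zero-variance
equal-mean t tests, and input-order tie-breaks in selection and
clustering.

## Known limitations

No RT prediction or iRT calibration; no cross-run alignment or label-free
mode; no FDR model for peak detection; no vendor method-file export; no
codon-level QconCAT construct design (expression, purification and
labeling efficiency are outside scope). The acylcarnitine module computes
scan settings only — metabolite chromatograms are not simulated.
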
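# Methods

## The screening model

A family 1 glycosyltransferase reaction adds one or two glucosyl units to
an acceptor of neutral monoisotopic mass M, so its products appear at
neutral mass M + kΔ, k ∈ {1, 2}. The hexose increment Δ defaults to
162.0533 Da, the screening community's rounded constant; elemental
summation of C6H10O5 gives 162.05282 Da, a ~0.5 mDa difference that is
negligible against the 50 ppm candidate window (≈ 22 mDa at m/z 430) and
the constant is configurable (`GlycoShift.unit_delta`). Products ionise in
positive-mode ESI as adducted species at m/z = (M + kΔ + δ_a)/z. Two adduct
sets are used, both configurable in YAML:

- *feature set* (MS2 admission, ±3 mDa absolute): [M+H]⁺, [M+Na]⁺,
  [M+NH4]⁺, [M−H2O+H]⁺;
- *identification set* (candidate assignment, ±50 ppm): [M+H]⁺, [M+Na]⁺,
  [M+2H]²⁺, [M+NH4]⁺, [M+ACN+H]⁺.

Adduct mass deltas are standard monoisotopic values (+1.00728, +22.98922,
+18.03383, −17.00329, +2.01456 at z = 2, +42.03383 Da).

The identification assumption is that a glycoside's collision-induced
fragments are dominated by aglycone ions, so glycoside references can be
*simulated* from aglycone library spectra by shifting only the expected
precursor. The package deliberately does not predict glycoside-specific
fragments (e.g. residual glycosylated ions); where those dominate a real
spectrum the cosine score drops and the product is missed — a conservative
failure mode.

## Preprocessing

Every MS2 spectrum (experimental and reference alike — both sides of each
comparison get identical treatment) is cleaned in four ordered steps:

1. remove the precursor and all fragments with m/z ≥ precursor − 1.6 Da
   (the margin is applied to the recorded precursor m/z regardless of
   charge);
2. remove fragments below 1% of the surviving base peak;
3. sum intensities into half-open 20 mDa bins anchored at zero,
   representative m/z = bin centre (centres avoid the systematic low bias
   of left edges);
4. normalise to base peak = 1.

Binning conserves total intensity exactly and is idempotent at fixed
width; normalisation is idempotent. The full four-step pipeline is *not*
exactly idempotent in one corner case: when binning merges peaks, the
merged base peak grows, and a second pass can floor peaks that were just
above 1% of the unmerged maximum. This is inherent to the stated step
order and left as-is; reference spectra are cleaned once and cached.

A "feature" is a single data-dependent MS2 scan whose recorded precursor
lies within ±3 mDa of an expected product ion of its reaction mix. MS1
data are used only for peak-area integration. This MS2-centric contract
replaces third-party MS1 feature finding: only MS2 spectra feed
identification, so isotope-envelope grouping would add machinery without
changing calls.

## Scoring and calling

The greedy cosine pairs peaks across two cleaned spectra within 0.15 Da,
accepting pairs in order of descending weight product w_q·w_r (weights
w = mz^0 · I^1 after base-peak normalisation and truncation to the 50
strongest peaks; ties at the rank-50 boundary go to lower m/z). Pair-order
ties break on smaller |Δm/z|, then smaller min(m/z) — deterministic and
symmetric. The score divides the accepted dot product by the full-vector
norms, so it lies in [0, 1] and equals 1 only for identical patterns.
Greedy acceptance can be suboptimal relative to maximum-weight matching;
the test suite and acceptance script verify greedy ≤ optimal on an
exhaustive-enumeration oracle and ≤ 1e−6 agreement with an independent
published implementation of the same algorithm.

A feature's candidates are the simulated-library entries of its own pool
within 50 ppm of the observed precursor (cross-mix matching is disabled).
All reference spectra of a candidate are scored and the best kept; the
feature is assigned to the highest-scoring candidate if the score strictly
exceeds the storage cutoff 0.5 ("exceeded" read as strict), with ties
broken by smaller precursor ppm error then entry id. Each MS2 scan is
assigned to at most one entry. Calls require score ≥ 0.85 (inclusive);
both thresholds are configurable and call counts are monotone
non-increasing in the threshold.

Control handling: the identical pipeline runs first on enzyme-free
(GFP-lysate) control runs; any sample call whose (compound, degree) was
called in a control of the same mix is removed, as are calls on
blacklisted background substrates. Subtraction is keyed on (mix, compound,
degree) — not adduct — so one background adduct suppresses all adducts of
that product in that mix.

## Quantification

The XIC for a call sums MS1 centroid intensities within ±5 mDa of the
matched entry's expected ion m/z, scan by scan, across ±0.5 min around the
triggering MS2 scan; leading/trailing scans below 1% of the apex are
trimmed; the retained per-scan signal is integrated by the trapezoid rule.
The expected (not observed) m/z is used as the window centre because it is
exact by construction while the observed precursor carries measurement
jitter. The 1% boundary trim costs up to ~7% of a Gaussian peak's area
(it cuts at ≈ ±3σ); with the trim disabled the trapezoid recovers analytic
Gaussian areas to < 0.1% at 7 scans per ±4σ peak. Areas are
intensity·minutes and are not comparable across compounds (ionisation
efficiency differs); no absolute quantification is attempted.

## Pool design

Pools must satisfy capacity (default 40) and pairwise neutral-mass
separation (default 0.01 Da — comfortably above the 3 mDa precursor
window; no numeric value is standard, so this is the package's choice).
The algorithm sorts compounds by mass and deals them round-robin into
ceil(n/capacity) pools, which by construction makes within-pool gaps about
n_pools times the median inter-compound gap, then repairs residual
violations by moves/swaps between pools. If repair fails, one pool is
added and the deal repeats, up to `max_pools` (unbounded by default, in
which case any input is feasible via singleton pools; a finite budget
makes infeasibility a real error that names the colliding masses).
Deterministic for a given input order and configuration.

## Shape descriptors

NPR1 = PM1/PM3 and NPR2 = PM2/PM3, from the eigenvalues PM1 ≤ PM2 ≤ PM3 of
the centre-of-mass inertia tensor. The inertia math is implemented in-repo
(testable without a cheminformatics toolkit) and validated on the exact
limits — rod (0, 1), disk (0.5, 0.5), sphere (1, 1) — and the rigid-body
inequality NPR1 + NPR2 ≥ 1. Conformers are generated from SMILES with
explicit hydrogens, 10 embeddings by default under a fixed seed, each
MMFF94-optimised, lowest energy selected. Ten conformers is a coarse
search; NPRs of floppy molecules can shift with the seed, which is why the
seed is an explicit argument and the default is documented rather than
hidden.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions end to end: substrate tables
with ≥ 0.02 Da mass separation over 150–800 Da, aglycone reference spectra
(5–20 fragments, ≥ 0.5 Da apart, log-uniform intensities in [0.02, 1]),
and per-pool runs in which each spiked product contributes a Gaussian MS1
elution peak (σ = 0.08 min, 7 scans across ±4σ, analytic area recorded as
ground truth) and one near-apex MS2 scan whose fragments are the aglycone
pattern under 5 mDa m/z jitter and 10% multiplicative intensity noise,
plus 10 noise peaks ≤ 5% of the base fragment. The fragment jitter is
deliberately between the 20 mDa bin width and the 0.15 Da tolerance so the
binning/tolerance interplay is exercised. Decoy MS2 scans sit at valid
glycoside precursor m/z values of unspiked (compound, degree, adduct)
slots with fragments borrowed from a different compound. All randomness
flows from one seed.

Not emulated: isotope envelopes, chimeric MS2 spectra, co-eluting isomers,
retention-time drift, matrix/ionisation-suppression effects, and real
fragmentation chemistry (fragments are random m/z values, not bond
cleavages). Passing the synthetic acceptance checks therefore demonstrates
that the pipeline's arithmetic, matching, thresholding, subtraction and
integration are correct under controlled noise — not that real screens
reach the same recall; on instrument data, spectrum quality and signal
intensity dominate.

Problem sizes in tests and the acceptance script (20–80 compounds, 1–2
pools, ~190 spiked products, 200 decoys) were chosen as the smallest
screens that give stable rate estimates; recall and false-call rates are
insensitive to the seed at these sizes.

## Numerical and interface choices

- Retention times are minutes everywhere after ingestion; m/z is full
  double precision in memory, 4 decimals in text outputs.
- mzML I/O is self-contained (lxml parser for 32/64-bit, zlib or
  uncompressed arrays; plain uncompressed writer) so fixtures round-trip
  without extra tooling; MGF goes through pyteomics; MSP is the NIST text
  dialect with `Comment:` fields carrying (compound, degree, adduct) for
  exact library reload; a JSON-lines scan format is the lossless fixture
  interchange.
- Reference-to-substrate matching is by case/whitespace-insensitive name,
  then with a leading parenthesised stereo-prefix stripped; an explicit
  record-to-compound cross-map overrides both.
- Configuration precedence is defaults < YAML < CLI flags; unknown keys
  are rejected; the effective configuration is written next to outputs.
- Degenerate inputs: empty cleaned spectra are valid and score 0; empty
  XIC windows return area 0 with a flag; an all-coincident point set is a
  geometry error.

## Known limitations

- Single-scan features mean chimeric spectra are scored as-is; a mixed
  spectrum scores lower rather than being deconvolved.
- One call per MS2 scan: a scan cannot support products of two different
  compounds even if both are within 50 ppm.
- Control subtraction is binary per (mix, compound, degree); a trace-level
  control signal suppresses a strong enzymatic signal.
- The greedy matcher is not maximum-weight matching; scores can be
  marginally below the optimum on dense spectra (bounded by the oracle
  checks).
- No FDR estimate is produced for real data; the decoy rate measured on
  synthetic screens is a property of the generator's noise model.
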
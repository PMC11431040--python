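# Methods

## Coordinate and read-out conventions

All coordinates are 1-based inclusive, matching residue numbering on
annotated mRNA maps; 0-based half-open conversion happens only at file
boundaries (BED6 export). A *cut at site p* severs the backbone bond 5′ of
nucleotide p, producing fragments (1, p−1) and (p, L); the reverse
transcriptase reading the downstream fragment stops so that a cDNA of
length k maps to template position `pairing_start − k = p`. Cut site,
fragment start and read-out position therefore coincide, which makes the
convention self-inverse: a simulated break at p is recovered exactly at p
(property- and exhaustively tested over a 500-nt construct). Position 1 has
no 5′ bond and is never a cut site; the full-length read of an intact
molecule appears at position 1.

Each primer owns the section between the previous primer's pairing start
and its own pairing start − 1; the 5′-most primer owns 1..(pairing start −
1). Contributions landing outside a primer's own section (possible at
section joints when a fragment spans two primers) are discarded rather than
averaged, because each ~500-nt window is read authoritatively by exactly
one primer. Primer footprints (the pairing intervals), anything 3′ of the
last pairing start (the poly(A) tail), and an optional exclusion margin of
first-extended nucleotides are reported as missing (NaN) — *unread*, which
is different from a read zero. An exclusion margin of 0 is the default: the
simulator's ideal RT makes the first extended nucleotide fully reliable,
and the margin exists for real traces where it may not be.

## Profile processing

**Normalization.** Box-plot (2%/8%) normalization — divide by the mean of
the 8% of values directly below the top 2% — is the community standard for
primer-extension reactivities and is applied per section by default, since
sections differ in primer labelling/annealing efficiency; factors are
recorded in the profile. Three modes exist:

* `per_section` — each sample normalized by its own factors;
* `anchored` — treated samples divided by the **control's** factors, keeping
  all doses on one comparable scale;
* `none` (pipeline default) — raw assembled intensities.

`none` is the default because percentile normalization is scale-invariant:
applied per sample it erases exactly the between-dose intensity growth that
a dose-response analysis needs, and on the simulator's sparse, shot-noise-
limited stop tables (most positions zero at low dose) the 2–8% reference
band can be empty. Dense real traces should use `per_section` within a
sample and `anchored` across a dose series.

**Control subtraction.** Per-position treated − control, negatives clamped
to 0 (degradation reactivity cannot be negative) with the clamp count
logged; missing propagates.

## Baseline and hotspot criterion

The baseline is the rescaled average line `IA(N) = A (1+q)^N` with N the
1-based position along the assembled profile. A is the regime's total
average degradation reactivity from the full dose-gradient test (the
bundled regime parameter sets are freeze–thaw A = 3.5, q = 10⁻⁶ and 37 °C
heating A = 8.8, q = 3.5 × 10⁻⁴); when not supplied, the pipeline derives A
as the mean of the gradient-average profile and uses q = 0. q is
configuration input only — no fitting procedure for it is implemented. A
position is *high intensity* iff its reactivity strictly exceeds the line
(ties are low).

"Several successive high nucleotides shared by both regimes" is made
algorithmic as: per condition, merge high positions within ≤ `max_gap` (3)
of each other into runs — real hotspots contain interior low-reactivity
bases, so exact runs would fragment them; merge overlapping runs across
conditions into candidate calls; require ≥ `min_high` (2) high members from
every required condition; clip the call span to the outermost high
positions. Calls are sorted, non-overlapping, and invariant to condition
order. Both parameters are exposed in configuration.

On shot-noise count data with a homogeneous background this above-average
criterion is deliberately permissive (a Poisson observation exceeds its
mean with probability approaching ½), so a default simulated run without
planted hotspots yields many weak calls; fold change over A is the ranking
statistic that separates genuine hotspots, and planted ×10 sites are
recovered with zero misses at 10⁴ molecules. The criterion performs no
significance testing, by design.

Fold change is the window mean divided by an **explicit** reference
average; the reference (regime A, or a window-specific average) is always
an argument and never inferred, because the appropriate reference depends
on the comparison being made.

## Structure classification

Dot-bracket structures (nested parentheses only; pseudoknot bracket layers
are rejected rather than mis-parsed) are loop-decomposed in one pass:
paired positions are `stem_5prime`/`stem_3prime` by strand (i < partner ⇒
5′); each loop is labelled by its closing-pair degree — hairpin loop (no
enclosed helix), bulge (one enclosed helix, unpaired bases on exactly one
strand), internal loop (both strands), multiloop (≥ 2 enclosed helices) —
and unenclosed positions are exterior. The classifier agrees with an
independent brute-force decomposition on **every** balanced dot-bracket
string of length ≤ 12 (24 870 strings) and handles lone pairs.

Hotspot context is operationalized as: `on_5prime_stem_side` — strict
majority of the span's paired positions on the 5′ strand; `has_apical_loop`
— walking the helix stack inward from the span's innermost pair (through
stacked pairs, bulges and internal loops) terminates in a hairpin loop
rather than a multiloop; `has_mid_stem_bulge` — a bulge/internal loop on
that walk or inside the span. No distance cutoff is imposed — the
nucleotide distances to the apical loop and nearest bulge are reported so
downstream analyses can apply their own — and the rule text is embedded in
the output metadata.

## CE integrity

Migration-time traces are mapped to the size axis piecewise-linearly in
log(size) against ≥ 2 ladder markers (electrophoretic mobility is
approximately linear in log length), with linear extrapolation beyond the
outermost markers. Integrity = 100 × trapezoidal area inside the main-peak
window / total area; the default window is 2100–3300 nt (bracketing an
intact ~2.9 kb product) and sizes below 100 nt are excluded from the
denominator so a co-run 20-nt alignment marker cannot dilute it. Average
fragment size is the area-weighted mean. Baseline correction is a
rolling-minimum subtraction (window in points, logged); the vendor smear
algorithms are proprietary, so this integrity % is an openly specified
analogue, not a re-implementation.

## Simulator

The generator emulates the statistical structure the read-out assumes, not
the chemistry. Per molecule the number of cuts is Poisson with mean
`per_event_rate × dose`; cut sites are drawn with probability proportional
to a deterministic propensity `base_weight(base) × context_weight(element)
× planted multiplier`. Defaults:

* **Base weights** — rescaled from the observed base composition of
  high-reactivity nucleotides under each stress (freeze–thaw trend
  C > G > A ≈ U → C 4.0, G 2.1, A 1.25, U 1.0; heating trend C > G ≈ U > A
  → C 4.0, G 2.9, U 2.1, A 1.0).
* **Context weights** — unpaired loops 1.4–1.6, 5′ stem strand 1.3, 3′
  strand 0.7: in-line attack needs backbone flexibility, and the 5′ strand
  is modestly favoured to reflect where sensitive sequences are found.
* **Event rates** — 0.012 cuts/molecule/freeze–thaw cycle and 0.010
  cuts/molecule/hour at 37 °C, calibrated once (3-seed scan, 10⁴ molecules)
  so the top of each ladder loses ≈ 12% (20 cycles) and ≈ 23% (48 h) of
  electropherogram mass from the 2100–3300 nt window, matching the scale of
  integrity loss such stresses produce on a ~2.9 kb mRNA.

RT processivity is ideal — every extension reaches the fragment end — so
the read-out is exactly invertible and oracle-testable; detection noise is
available only as additive Gaussian `noise_sd` on sized peaks (clamped at
zero). Fragment mass is conserved per molecule. The electropherogram is the
nucleotide-mass-weighted fragment-length histogram convolved with a
Gaussian sizing kernel (default SD 25 nt).

**What the simulator does not model:** RNase or free-radical chemistry
(suspected contributors at 37 °C beyond intrinsic transesterification),
RT drop-off and mispriming, signal decay along real capillary traces,
sequence-dependent mobility shifts, and lipid-nanoparticle or formulation
context. Passing tests therefore demonstrate that the *analysis* is
correct and self-consistent under the generative model, not that the
biology of any particular mRNA is reproduced.

## Reference fixture

The studied mRNA is not deposited, so `mprtseq.synthetic_reference`
generates a synthetic 2896-nt stand-in carrying the published construct
coordinates (5′ UTR 1–52, Luc 53–1702, linker 1703–1768, GFP 1769–2485,
stops 2486–2491, 3′ UTR 2492–2786, poly(A) 2787–2896), the six primer
pairing positions (554–573 … 2771–2788), the known sensitive motifs at
their published coordinates, deterministic per-regime profiles whose
hotspot windows reproduce the published fold changes, and a synthetic
structure placing each shared hotspot on the 5′ strand of a bulge–stem–loop
hairpin. Everything else about the sequence is seeded random filler. The
fixture is regenerated in code on demand; no data files ship with the
package.

## Problem sizes and determinism

Simulation-based tests use 10⁴ molecules and ≤ 5 seeds per condition —
enough for the Poisson means being compared to separate by many standard
errors — and the exhaustive structure check enumerates all 24 870 balanced
strings of length ≤ 12. All randomness flows through
`numpy.random.default_rng` seeded from a single user-visible seed; the
pipeline embeds the config hash and seed in every output, and identical
config + seed reproduces all numeric outputs byte-for-byte.

## Known limitations

* The hotspot criterion is descriptive (above an average line), not
  inferential; on noisy data use fold-change ranking or external
  replication.
* Eq.-style baselines with q > 0 grow monotonically 3′-ward; the provided
  regime parameters make the line nearly flat, and how q should be fitted
  is left open (q is input only).
* Whether normalization should be per section or global on real data is
  unresolved; both are implemented.
* Pseudoknots and non-nested structure are rejected; tertiary context is
  out of scope.
* The integrity metric is an open analogue of proprietary instrument smear
  analysis and will not numerically match vendor RQN-style scores.
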
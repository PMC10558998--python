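# Methods

This note records the model, the estimator conventions, the synthetic
study conditions, and the numerical and statistical choices behind
`hyperbispec`, including the places where the design was genuinely open
and what the shipped defaults do and do not demonstrate.

## Signal model and estimator

**Diagonal cross-bispectrum.** For a dyad (participant *a*, participant
*b*) and one channel from each, the feature is

    B(f) = (1/L) Σ_l X_{a,l}(f) X_{b,l}(f) X*_{b,l}(2f),

the magnitude of the complex mean over L sliding windows (4 s,
rectangular taper, 1 s step = 75 % overlap; 0.25 Hz native resolution,
diagonal bins 1.00–50.00 Hz = 197 bins). The statistic detects quadratic
phase coupling (QPC): a component at `2f` whose phase is twice the phase
at `f`, shared across the dyad. The phase closure `f + f − 2f = 0`
makes every diagonal magnitude invariant to a common time shift of both
signals, and the bispectrum of jointly Gaussian, independent signals
decays as `1/√L` (verified: log-log slope ≈ −0.47 over L ∈ {10, 100,
1000}).

**Factor convention.** The literature writes the cross-bispectrum
without fixing which participant supplies which factor. We assign the
`f` factor of participant *a* ("sender") and both the `f` factor and the
conjugated `2f` closure to participant *b* ("receiver"). Consequences,
both tested: scaling *a* by α scales `|B|` by α while scaling *b* by β
scales it by β²; ordered dyads (a→b) and (b→a) are different statistics,
and the scan covers both orders. The alternative closure (on *a*) would
give different per-pair values; nothing in the downstream machinery
depends on the choice.

**Windowing details.** "4-second windows with 75 % (1 s) overlap" is
implemented as a 1 s step. Window count in an interval of length T is
`floor((T − 4)/1) + 1`; windows overlapping a masked span are dropped,
and a fully masked interval raises an explicit empty-segment error.
No taper is applied by default (the sum is the literal DFT triple
product); tapering would reduce the bin-to-bin leakage discussed under
*Statistical calibration* below.

**Rest normalization.** `BS_N = (BS_seg − BS_EO)/BS_EO` against the
pre-trial eyes-open block of the same channel combination. Baseline
bins below `1e-12 ×` the median baseline magnitude are flagged invalid
(NaN) rather than divided. Band values average the valid native bins in
delta [1, 5), theta [4, 8), alpha [8, 13), beta [13, 30), gamma
[29.75, 50.25) — the unique half-open 0.25 Hz readings that give the
16/16/20/68/82 per-band sample counts; note the deliberate one-bin
delta/theta and beta/gamma overlaps. A coarse 50-bin 1 Hz summary grid
(bin c = native bins in [c − 0.5, c + 0.5)) exists for display only.

## Statistical discovery

Per (trial, segment, dyad, band) family, every ordered channel
combination is tested with a right-tailed Wilcoxon signed-rank on the
paired per-bin magnitudes (segment vs EO), Bonferroni-corrected within
the family (`α/n_channels²`; 0.05/3600 on the full 60-channel montage,
0.05/256 on the 16-channel desk profile). The paired samples are the
band's native bins, so n = 16…82 depending on band. Zero differences
are dropped; an all-zero family member returns p = 1 with a degenerate
flag. Ranking uses p ascending, ties broken by larger median paired
difference, then lexicographic labels, so `top_k` is deterministic.

**Matched estimation variance.** `|mean|` of L noisy triples is a
positively biased magnitude estimate with bias ∝ 1/√L. Comparing a long
segment against a short rest block therefore biases the *right-tailed*
test conservative (segment floor below rest floor) and can mask genuine
coupling. The desk-scale profile uses 60 s segments against the 60 s EO
block so both sides carry the same floor; with full 300 s segments the
method's sensitivity depends on genuine rest bispectral structure
dominating the estimator floor, which holds for real EEG (non-Gaussian)
but not for a Gaussian simulation.

**Statistical calibration (measured).** Under null synthetic sessions
the per-family probability of at least one Bonferroni rejection in the
gamma family was ≈ 0.05–0.08 (9 dirty seeds in 160), i.e. at or mildly
above the nominal 5 %. Two mechanisms, both properties of the method as
specified rather than of the implementation: (i) 75 %-overlap
rectangular windows leak across neighbouring 0.25 Hz bins, positively
correlating the "paired samples" within a band and inflating the
signed-rank variance in the far tail (the normal approximation itself is
*conservative* — the exact tail is lighter); (ii) for delta and theta,
`2f` falls inside the band itself, so different bins share DFT factors
outright — these bands are structurally anticonservative and should be
read with care. Family-wise control at extreme Bonferroni tails is
therefore approximate, not exact.

## Event-locked analysis

Temporal traces are single-window (L = 1) representations normalized to
the EO baseline and band-averaged, one value per second at window
centers. Around each annotated SP/DP event, a −60…+60 s trace
(121 points, annotation = 0 s) is cut, baseline-corrected by its
pre-event (−60…0 s) mean (idempotent; ×100 gives "BS change (%)"), and
tagged with the dyad's condition (passive-passive / passive-active /
active-active) from the design table. Events in masked spans or too
close to the trace edge are skipped and logged.

Because SP and DP groups have different sizes, the per-timepoint
comparison is an unpaired two-sample rank test (Mann–Whitney U,
alternative SP > DP), masked at pointwise p < 0.05 without correction
across timepoints. **Onset estimation** uses sustained significance —
the first run of ≥ 3 consecutive significant points — because with ~60
pre-event timepoints at α = 0.05 a single spurious point before the true
onset is near-certain; the pointwise mask is reported unchanged.

An important consequence of L = 1: a single-window bispectrum magnitude
is the product of its three factor magnitudes and is therefore
*invariant to pure phase re-coupling*. Event-locked traces can only
reflect events that also modulate oscillatory *power*. The generator
accordingly models SP/DP episodes as joint steps in phase coupling
(ρ ± δ) and in coupled-component amplitude (±40 % by default), starting
`lead_time` (default 3 s) before the annotated time — an anticipatory
band-power burst accompanying synchronized play. With that model the
measured SP-vs-DP onset is −3 s in essentially every seed.

## Synthetic study conditions

The generator emulates a three-musician session: pre/post eyes-open and
eyes-closed baselines (60 s each), three trials × three 5-minute
segments with staggered entry (each participant opens one trial), SP/DP
annotations, and a 64-channel 10-10 cap at 1000 Hz in which four
recorded channels (TP9/TP10/PO9/PO10) are physically repurposed as EOG —
which is why EOG identity is carried as channel-kind metadata, never
inferred from montage labels. The desk-scale profile used throughout the
test battery is 16 channels, 250 Hz, 60 s segments; the full montage is
a config change, not a code path.

* **Background**: independent 1/f pink noise, 10 µV rms per channel.
* **Coupling**: a comb of QPC tone pairs (default 30–50 Hz every
  0.5 Hz — band-wide synchrony is what a band-level rank test can see;
  a single tone elevates one bin out of 82 and is undetectable by
  design) between five channel-disjoint sender→receiver pairs
  (temporal/parietal → occipital). Total coupled variance is capped at
  10 % of background variance. Phases are redrawn every 4 s epoch, so
  bispectral evidence accumulates only through the coupling itself.
* **Stationary power**: the tone combs run through the entire session,
  baselines included; only the coupling ρ(t) (and, around events, the
  component amplitude) varies. Performance-only tones would let the
  magnitude-based test flag every combination touching a coupled
  channel; stationary power makes the segment-vs-rest contrast specific
  to phase coupling. Channel-disjoint pairs are enforced because stacked
  tone sets raise the incoherent floor and dilute the coherent fraction.
* **Artifacts**: ~300 ms biphasic blinks at 12/min on the vertical EOG
  pair (opposite polarities above/below the eye), mixed into EEG
  channels with a frontally weighted vector; mixing and onset times are
  returned as ground truth.
* **Determinism**: one seed fixes everything through a fixed
  `SeedSequence` spawn tree; identical configs give bitwise-identical
  sessions.

What passing tests do **not** show about real data: real EEG has
volume-conducted common sources, non-stationary rhythms, genuine rest
bispectral structure, and annotator timing jitter — none of which the
generator models. Recovery rates measured here characterize the
pipeline's behavior under its own stated conditions, not field
sensitivity.

## Preprocessing

Fixed order, logged per recording: polyphase resample to 250 Hz →
zero-phase 4th-order Butterworth 0.1–100 Hz → narrow zero-phase notch at
the line frequency and harmonics (−3 dB width 0.5 Hz; ≥ 20 dB drop at
the line, < 5 % change ±2 Hz away) → robust (median) average reference
over EEG channels only → H∞ adaptive EOG cancellation. Zero-phase
filtering is chosen to preserve event timing for the −3 s analysis; the
median reference approximates a "true" average reference while resisting
single-channel artifacts. Reference-pipeline cleanups (PREP), artifact
subspace reconstruction (κ = 15) and ICA are *not* reimplemented; run
them externally and ingest the result.

**H∞ canceller.** Per EEG channel, a weight vector over [EOG references,
bias 1] follows the time-varying H-infinity estimator

    P̃ = P (I − γ⁻² P + h hᵀ P)⁻¹,  K = P̃ h,
    w ← w + K (s − hᵀ w),           P ← P̃ + q I

with γ = 1.15 (worst-case energy bound), q = 1e-10 (weight drift),
P₀ = 0.5 I. The gain depends only on the references, so one P serves all
EEG channels. Loss of positive-definiteness (γ too small, or a reference
with no excitation — note the recursion *requires* persistently exciting
references; a noiseless, mostly-zero EOG trace is degenerate) raises an
error naming the first failing sample. Verified: ≥ 90 % blink-power
removal with a co-present 10 Hz oscillation preserved within 5 %, bias
drifts absorbed by the constant term, weights converging to the true
mixing gain.

## ROI aggregation

Thirteen regions (AF, LFC, MFC, RFC, LCP, MCP, RCP, LPO, MPO, RPO, LT,
RT, O) partition the 60 analyzed labels by geometric sector; the table
ships as an editable CSV mapping and the original study's exact
memberships are not recoverable, so ours is a declared default.
Significant combinations are pooled symmetrically ((r1, r2) ≡ (r2, r1))
per condition and band; cell counts sum exactly to the number of pooled
combinations, and shading is count / max count.

## Numerical choices and limitations

* Intervals are half-open `[start, end)` in seconds from session start.
* The ε floor for normalization denominators is 1e-12 × median baseline.
* `resample` refuses to upsample; `read_*` reject malformed or truncated
  files rather than returning partial data.
* The session container (HDF5) round-trips all fields exactly; design
  and annotations are stored as JSON attributes.
* Known limitations: approximate family-wise control at extreme
  Bonferroni tails (see *Statistical calibration*); delta/theta band
  tests share DFT factors across bins; the temporal trace is a power-
  weighted quantity at L = 1; no volume-conduction or source modeling.
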
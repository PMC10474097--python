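# Methods

## Scope and model

`pcgbeat` implements *direct* PCG segmentation: heart sounds are located
from the acoustic channel alone, and the reference ECG is used only to
score the result. The model of the signal is deliberately minimal: S1 and
S2 are short (≈100–150 ms) oscillatory bursts whose energy lies below
100 Hz, recurring once per beat, with the S1→S2 interval (systole) shorter
than the S2→S1 interval (diastole) at resting heart rates. Everything in
the detector follows from that picture; no morphology beyond burst energy
is used. The approach is therefore appropriate for resting rhythms
(roughly 60–90 bpm) and degrades by design near 130 bpm, where systole and
diastole converge and interval duration no longer separates the two
sounds.

## Pipeline stages and parameters

All filters are Butterworth designs applied forward–backward
(zero-phase), with symmetric signal extension, so no stage shifts event
timing; "order" means the low-pass prototype order (two poles per band
edge for order 2).

| Stage | Parameter | Default | Why |
|---|---|---|---|
| Band-pass | edges, order | 2–100 Hz, 2 | S1/S2 energy is below 100 Hz; <2 Hz removes baseline/motion drift |
| Wavelet denoise | wavelet, level | db12, 5 | smooth high-order Daubechies matched to low-frequency bursts |
| Normalization | window | 1 s | per-section scaling stops loud transients from suppressing sounds elsewhere |
| Shannon energy | order, log | cubic, natural log | emphasizes medium amplitudes; log base only rescales and cancels in the standardized thresholds |
| Envelope smoothing | cutoff, order | 10 Hz, 2 | merges within-burst oscillation into one hump per sound |
| Peak threshold | Th₁ | −0.9·μ/σ | 90% of the standardization shift: permissive, keeps weak sounds as candidates |
| Classification threshold | Th₂ | mean energy (0 on the standardized scale) | only loud peaks drive period estimation and K-means |
| Minimum spacing | gap | 150 ms | the typical duration of one heart sound |
| Period estimate | quantum | 10 ms | mode of lag-2 gaps needs binning; 10 ms ≪ systole/diastole difference at rest |
| K-means seeds | fractions | 0.35/0.65/1.0 of T̂ | resting systole/diastole occupy ≈35%/65% of the beat |
| Confirmation | factors, window | 0.8×, 1.3×, 300 ms | a same-label repeat <0.8·T̂ is false; a gap >1.3·T̂ hides a missed beat near +1·T̂ |
| ECG filters | band-pass, band-stop | 1–150 Hz, 48–52 Hz | standard monitoring band plus 50 Hz power-line notch |
| R detection | window, fraction, refractory | 5 s, 70%, 0.25 s | adaptive threshold per window; refractory prevents double-counting one QRS |
| T search | window | (R+0.12 s, R+0.40·T̄ᵣᵣ] | simple maximum-in-window; full T-wave delineation is out of scope |
| Evaluation windows | S1, S2 | [R, R+0.2·T̄ᵣᵣ), [R+1.2·T̄ᵣₜ, R+0.6·T̄ᵣᵣ) | HR-dependent expectation intervals for each sound |
| HR estimation | window | 2 s | median inter-event gap per window; HR = 60/median |

Every value is exposed in `PipelineConfig` and can be overridden from a
TOML file.

## Numerical and procedural choices

Decisions the stage descriptions above leave open were fixed once, as
follows.

- **Statistics scale.** μ and σ are computed over the *smoothed* energy of
  the whole recording — the signal that is actually peak-picked — so the
  thresholds are constant across the trace, and Th₂ is exactly 0 on the
  standardized scale.
- **Wavelet shrinkage rule.** Universal soft threshold σ̂·√(2 ln N) with σ̂
  estimated from the median absolute deviation of the finest detail band;
  the approximation band is untouched. This is the standard reproducible
  default; nothing downstream is sensitive to the exact rule at the SNRs
  of interest.
- **Minimum-spacing order.** The closest violating pair is resolved first
  (dropping its quieter member, ties dropping the later peak), iterating
  to a fixed point. This makes the outcome deterministic and
  insensitive to scan direction.
- **Period-mode ties** go to the smallest quantized value.
- **K-means degeneracies.** An empty cluster keeps its centroid for that
  iteration, so k = 3 survives sparse inputs; equidistant intervals go to
  the lower-index (shorter) centroid.
- **Confirmation order and termination.** One removal pass, then recovery
  passes to stability, repeated until a full round changes nothing.
  Recovery only promotes a candidate whose resulting same-label gaps both
  stay ≥ 0.8·T̂ — otherwise recovery and removal could undo each other
  indefinitely, and a promotion that immediately qualifies for removal is
  self-contradictory. Equidistant recovery candidates resolve to the
  earlier peak, with distances quantized to 1 ns so floating-point noise
  cannot flip the tie-break.
- **Degenerate inputs.** All-zero (sub-1e-12) normalization sections map
  to zeros; a trailing partial section is normalized by its own maximum;
  fewer than 3 above-Th₂ peaks aborts detection with a diagnosable error
  rather than guessing a period; records shorter than 3 s are rejected.
- **Scoring conventions.** Windows are half-open [start, end), clipped at
  the next R so one label's windows never overlap; windows truncated by
  the record end are dropped (the sound they would score may itself be cut
  off). One TP per window; extra detections in a credited window are FP.
  When S1 and S2 windows overlap (possible at high HR), S1 keeps
  precedence because each label is scored against its own window set. An
  undefined rate (no detections → PPV; no windows → SE) is reported as
  NaN, never 0.
- **Quartiles** use linear interpolation between order statistics (the
  numpy default), and IQR = Q3 − Q1.
- **Wilcoxon conventions.** Zero differences are discarded; the exact null
  distribution is used up to 25 non-zero pairs, the normal approximation
  with continuity correction above; all-zero differences report p = 1.
  At least 6 jointly defined 2 s windows are required.

## The synthetic generator

The generator produces the conditions the detector assumes, with ground
truth: beats at 60/HR spacing (optional Gaussian R–R jitter) running to
the record edge, as in a real recording that is simply cut off; S1 at
R + 40 ms (a fixed electromechanical delay); S2 at S1 + systole, where the
systole fraction rises linearly from 0.35 at 60 bpm to 0.50 at 130 bpm;
Hann-windowed tone bursts (S1: 35 Hz, 120 ms; S2: 50 Hz, 100 ms, relative
amplitude 0.8); an ECG channel of Gaussian R spikes and T bumps at
R + 0.25·RR; white noise at a requested SNR against the clean PCG,
baseline wander below 2 Hz (sinusoid plus scaled random walk), and
optional motion spikes. One seeded generator per record makes every
record bit-reproducible, and cohort seeds derive deterministically from a
master seed.

What the generator does *not* emulate: murmurs, S3/S4, respiratory
modulation of amplitude or rate, sensor-contact variation, split S2, or
any within-beat morphology beyond a windowed tone. Passing tests on this
synthetic data therefore demonstrate the correctness and internal
consistency of the pipeline under its own assumptions — not clinical
performance on real chest recordings, where contact quality, pathology,
and ambient noise dominate.

## Known limitations

- **Weak-S2 failure mode.** When S2 drops far enough (e.g. ×0.1) that it
  falls below the candidate threshold, the above-Th₂ peak train contains
  only S1, the lag-2 period estimate doubles, and the 0.8·T̂ removal rule
  then demotes every second S1: S2 sensitivity collapses *and* S1
  sensitivity falls to roughly half. This is a property of the method
  (interval-based labeling has no anchor once alternation is lost), and
  the test suite reproduces it deliberately; see
  `tests/test_acceptance.py::test_attenuated_s2_failure_mode`.
- **Tachycardia.** Near 130 bpm systole and diastole converge and the
  K-means seeds no longer separate the clusters; no tachycardia-specific
  rules are implemented.
- **T-wave location** is a simple maximum-in-window and is not a
  delineation algorithm; it is adequate for anchoring the S2 window on
  healthy rhythms only.
- **Problem sizes.** The validation cohort is 20 records of 60 s (about
  20 minutes of signal), chosen as ample for the per-beat statistics
  computed here; per-record scores stabilize well below that length.
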
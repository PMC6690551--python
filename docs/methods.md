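# Methods

## Scope and data model

The package quantifies single-channel courtship-song recordings
(`SongRecording`: voltage samples, sampling rate, genotype label).  Voltage
units are arbitrary — every threshold in the pipeline is relative — and all
times are seconds from recording start, with 0-based sample indices and
half-open `[start, end)` windows.  WAV (16-bit PCM or 32/64-bit float, mono)
is the only audio container; proprietary acquisition formats are out of
scope.  The nominal sampling rate is 10 kHz; other rates are accepted with a
warning, but the documented spectral grid assumes 10 kHz.

## Band-pass filtering

Analysis runs on a zero-phase band-passed trace: mean removal (exact DC
rejection), a 2nd-order Butterworth high-pass at 1 Hz and an 8th-order
Butterworth low-pass at 500 Hz, applied forward-backward (`sosfiltfilt`).
After the double pass the ripple across 10–450 Hz is under 1 dB and 2 kHz is
attenuated by ~96 dB.  The first and last 50 ms of the trace are
cosine-tapered before filtering; without this, an abrupt recording edge
excites a forward-backward transient large enough to masquerade as an event.

Working on the filtered trace (rather than the raw one) matters at realistic
noise levels: the band keeps only ~1/10 of white noise power, which is what
makes the slice-level classification stable at signal-to-noise ratio 10.

## Pulse detection

The slice level is defined per pulse from the pulse's own peak, so it cannot
bootstrap detection.  The detector instead uses an absolute threshold:

    threshold = max(multiplier × MAD_normal(filtered trace), 0.10 × max|trace|)

with `multiplier` = 5 and `MAD_normal` the normal-consistent median absolute
deviation (a robust noise-scale estimate that ignores the sparse pulses).
The 10%-of-maximum floor keeps noise-free recordings segmentable, where the
MAD of a mostly-silent trace is ~0.  Samples above threshold are clustered
(gaps ≤ 5 ms tolerated inside one event, comfortably above the half-period
zero-crossing gaps within a pulse and far below the ≥ 15 ms between pulses),
padded by 2 ms per side, and merged if overlapping.  Two validation rules
follow: an event must reach 1.5× threshold at its peak (rejecting rare noise
excursions just above threshold), and its above-threshold span must not
exceed 50 ms (rejecting sustained sine-song oscillation, which is not a
wing-beat pulse; a sine-dominated recording also raises the MAD and with it
the threshold).

## Baseline, peak height, cycle counting

The baseline is the mean of the 3 s immediately preceding the event window,
excluding samples inside any detected pulse window; with < 50 ms of usable
history the recording-wide median of non-pulse samples is used instead
(logged).  Peak height is the largest |sample − baseline| in the window,
earliest sample on ties, and both polarities qualify.

Cycle counting takes the local extrema of |signal − baseline| in the window
as candidates, keeps those above `slice_fraction × peak_height` (default
0.50; 0.60 as the stringent variant), and then enforces a separation rule:
counted peaks must be ≥ 1 ms apart and either have a zero-crossing of the
baseline-subtracted signal between them or dip below 50% of the smaller
peak.  Candidates are accepted greedily by descending amplitude (earliest
first on ties), which makes the counted set — and hence every cycle count —
non-increasing as the slice fraction is raised.  A pulse with one counted
peak is monocyclic; otherwise polycyclic.  The classification is invariant
to gain, DC offset and sign of the recording by construction.

## IPI analysis

IPIs are differences of consecutive primary-peak times within a bout,
expressed in ms; gaps longer than 100 ms split bouts and contribute no
interval.  The 100 ms bout break is ~3 wild-type IPIs, an order of magnitude
below typical interbout silences.  The distribution is summarized by a
bounded least-squares fit of a·exp(−(x−μ)²/2σ²) to the 1 ms-binned histogram
(initialized at the sample moments), mirroring how such histograms are
conventionally displayed; a moment-based MLE variant is available and agrees
with the histogram fit within 2% on genuinely Gaussian data.  Degenerate
input (zero variance, < 30 intervals, < 5 occupied bins) raises an error
rather than returning a meaningless fit, and a misspecified (e.g. bimodal)
distribution is flagged by a low r².

## Power spectra

Each pulse contributes one segment of the filtered trace, 25 ms centered on
its primary peak — a fixed span, so the spectral window does not inherit the
detector's variable event widths; 12.5 ms on each side covers the widest
pulse yet stays inside one IPI.  Segments are mean-removed, Hann-tapered,
centered in a zero-padded 1024-sample buffer and transformed; one-sided
periodograms are averaged across pulses (Bartlett-style), and the maximal
peak within 1–500 Hz is reported.  Power is scaled so a segment's total
equals its taper-corrected mean squared amplitude.  The noise spectrum
averages full 1024-sample windows tiled over stretches ≥ 10 ms away from
every pulse (requiring ≥ 1 s of song-free signal) and is subtracted bin-wise
with clamping at zero.  Class-stratified spectra repeat this for monocyclic
and polycyclic pulses separately.

The 1024-point window at 10 kHz (bin width 9.765625 Hz) is the single most
consequential numerical choice: the carrier-frequency landmarks of this
preparation — 234.375, 312.5 and 351.5625 Hz — are exact bin centers (bins
24, 32 and 36) of precisely this grid, so peak frequencies are reported at
full bin-center precision and rounded only for display.

## Statistics

* **Fisher's exact test**: all 2×2 tables sharing the observed margins have
  hypergeometric probabilities with a common denominator C(N, c₁), so the
  two-sided p (sum of probabilities ≤ the observed table's) is computed in
  exact integer arithmetic; practical for totals ≤ 10⁴.
* **Mann-Whitney U**: midranks throughout; exact permutation enumeration of
  the rank sum when min(n) ≤ 8 (valid under ties), otherwise the normal
  approximation with tie correction and continuity correction.
* **ANOVA + Bonferroni**: scipy's F test plus all-pairs pooled t tests with
  p multiplied by the number of pairs (capped at 1).
* **Dwass-Steel-Critchlow-Fligner**: each pair re-ranked on its own;
  √2·|standardized rank sum| referred to the studentized range with k groups
  and infinite degrees of freedom.  For per-group n ≤ 6 an exact variant
  substitutes the pair's exact permutation p, Bonferroni-adjusted — a
  deliberately conservative small-sample option.
* **Steel many-to-one**: treatments re-ranked jointly with the control; the
  comparisons share the control sample, inducing a one-factor correlation
  structure (ρᵢⱼ = √(λᵢλⱼ), λⱼ = nⱼ/(nⱼ+n₀), the classical equicorrelated
  0.5 at equal n).  The joint max-|Z| tail is evaluated by numerical
  integration over the shared factor, which is exact for this structure at
  any group sizes — no Monte-Carlo reference is needed.
* Stars follow the conventional thresholds: * 0.05, ** 0.01, *** 0.001.

## Synthetic song generator

The generator emulates the statistical structure of courtship pulse song
with exact per-pulse ground truth.  Pulses are placed in bouts (Poisson-sized,
mean 50 pulses, truncated at 1) separated by 1 s gaps; within a bout,
IPIs are drawn from Normal(μ, σ) and clipped below at 15 ms so pulses never
overlap.  Each pulse is polycyclic with the genotype's probability; its
cycle count is drawn from the mixture {2: 65%, 3: 34.5%, 4: 0.5%},
conditional on being polycyclic.  One pseudo-random stream is seeded per
call with a fixed draw order (bout sizes → IPIs → classes → cycle counts →
noise), so identical inputs give identical recordings.

A pulse waveform is a carrier sinusoid under a smooth monotone-cubic
envelope through prescribed crest heights: the counted lobes (primary at
100%, then ×0.85 per lobe — the 4th counted lobe still at 61%) framed by
sub-threshold flank lobes at 18/13/9/5/2% of peak.  This makes the
noise-free slice criterion exact by construction (exactly `cycle_count`
lobes exceed 50% of peak) while keeping the waveform oscillatory enough that
its spectral peak sits on the FFT bin nearest the carrier.  The flank
heights account for the analysis band: the ~500 Hz low-pass smooths the
sharp primary crest more than the flanks, inflating flank-to-peak ratios by
up to ~1.5× at a 350 Hz carrier, and the chosen profile keeps the largest
post-filter flank ratio near 0.36 — more than 3 noise standard deviations
below the 50% slice at signal-to-noise ratio 10.  Pulses are kept ≥ 0.1 s
clear of the recording end and the first bout starts at 0.5 s.

Presets (the study conditions):

| parameter | `wildtype` | `cro` |
|---|---|---|
| IPI mean ± SD (ms) | 35 ± 3 | 40 ± 4 |
| monocyclic carrier (Hz) | 232 | 313 |
| polycyclic carrier (Hz) | — | 350 |
| polycyclic fraction | 0 | 0.35 |
| noise SD (units of pulse amplitude) | 0.1 | 0.1 |

The mutant IPI mean of 40 ms encodes "prolonged relative to wild type";
no canonical mutant value exists, so it is a package convention.  The
default noise SD of 0.1 gives amplitude SNR 10, a realistic chamber
recording; noise-free variants are produced by overriding `noise_sd=0`.
Optional sine-song segments (carrier 120–180 Hz, default off) exist to test
that the pulse detector rejects sustained oscillation; they are inserted
into interbout gaps with 20 ms amplitude ramps.

What the generator does **not** model: microphone/amplifier transfer
functions, slow-vs-fast pulse-mode structure, amplitude variability across
pulses and within sine song, wing-switching asymmetries, and nonstationary
noise.  Passing the synthetic round-trip tests therefore demonstrates the
internal consistency and noise robustness of the measurement chain, not
performance on any particular hardware's recordings.

## Problem sizes in the shipped checks

The test suite and the acceptance script use 10–90 s recordings
(~200–1600 pulses each): large enough that binomial sampling error on class
fractions is a few percentage points and the IPI fit has ≥ 1000 intervals,
while keeping a full run in tens of seconds.  Statistical null-calibration
checks use 2000 simulations per test.

## Known limitations

* Detection assumes pulse amplitude well above the noise floor (the 5×MAD
  threshold); songs at SNR ≲ 3 will lose pulses.
* The noise spectrum is estimated from full-length windows but pulse
  segments are shorter and tapered, so noise subtraction is approximate at
  low SNR (it can over-subtract; clamping keeps power nonnegative).
* Overlapping pulses (IPIs below ~15 ms) are not resolved; the generator's
  IPI floor makes them impossible in synthetic data, but real recordings of
  other species may violate this.
* The DSCF exact small-sample variant is conservative (Bonferroni on exact
  pairwise p) rather than an exact joint reference.
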
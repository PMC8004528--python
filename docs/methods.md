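# Methods

This note documents the models, the statistical machinery, the defaults,
and the design choices behind `emipac`, in the order the pipeline applies
them.  It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Scope and data model

All analyses operate on a single uniformly sampled channel
(`TimeSeries`: samples + sampling rate).  Coupling is always between the
phase of a slow oscillation at frequency f_P (typically 1–12 Hz) and the
amplitude (wavelet energy) of a fast oscillation at f_A (typically
20–200 Hz), both taken from the same signal.  A dual-signal mode (phase
from one channel, amplitude from another) is a possible extension but is
not implemented.  The eMI is designed to detect phase-dependent
*augmentation* of fast power; phase-dependent attenuation is outside its
design.

## Reference estimators

dPAC and MI both extract Φ(t) and A(t) by zero-phase (forward–backward)
least-squares FIR band-pass filtering followed by the Hilbert transform.

- Filter order: the number of samples in three cycles of the band's low
  edge, with 15% relative transition bands — the convention of the
  classic two-way least-squares EEG filter.  The least-squares design can
  overshoot by a few percent in the passband, so the taps are normalised
  to unit gain at the band centre; MI and dPAC are scale-invariant, so
  this affects only the interpretability of intermediate envelopes.  For
  signals too short to support the nominal order (the 1–2 s points of the
  length sweep) the order is capped at a third of the signal length;
  surrogates use the identical filter, so significance stays calibrated.
- Slow band: f_P ± Δf_P/2 with Δf_P = 1 Hz by default.
- Fast band: f_A ± 2·max(f_P) of the analysed grid.  The width matters:
  amplitude modulation at the slow frequency puts side bands at
  f_A ± k·f_P, and a coupling with M modes per cycle concentrates its
  side-band power near k = M.  A band of ± max(f_P) attenuates the
  M = 3 side bands enough to hide genuinely multimodal coupling from the
  filter-based estimators, so the wider convention is used throughout.
  Consequently the lowest analysable f_A must exceed 2·max(f_P); the
  grid constructor enforces this with an explicit error.
- dPAC interprets the normalisation length as the number of samples, so
  a constant-amplitude, constant-phase series scores exactly 1.  The
  first and last second are discarded after filtering (edge effects); MI
  uses the whole series, matching the original conventions of each
  estimator.
- MI uses the natural logarithm (the ratio in its definition makes the
  base irrelevant) and J = 18 phase bins.  An empty phase bin contributes
  a zero mean amplitude and its 0·log 0 term is dropped (limit
  convention).

## The eMI pipeline

1. **Screening.**  Phase frequencies are analysed only if the signal's
   Welch spectrum stands out against a smooth background.  Welch
   parameters: Hann window, segment length max(2 s, 4 cycles of the
   slowest f_P), 50% overlap, constant detrend.  The background is a
   piecewise-cubic (PCHIP, in log power) interpolation through the
   spectrum's local minima with the band endpoints as anchors; with fewer
   than two interior minima it degrades to the line through the
   endpoints.  The significance threshold is the 95th percentile of the
   same spectrum-to-background ratio over 200 pink-noise realisations of
   equal length.  The pink-noise null depends only on the configuration,
   so it is cached and can be shared across a batch of equally long
   signals (`screen_seed`).
2. **Phase identification.**  The slow oscillation is extracted with a
   zero-phase 4th-order Butterworth band-pass (f_P ± Δf_P/2).  Local
   maxima with topographic prominence below 5% of the median prominence
   are discarded, as are maxima within 1.5 cycles of either signal end.
   Section lengths are one slow cycle (path A, coupling measurement) and
   three cycles (path B, diagnostics), in samples rounded and forced odd
   so windows centre exactly on a maximum sample.  Sections are chosen
   greedily from the first retained maximum so that windows do not
   overlap; adjacent windows may share their single boundary sample,
   because the odd-forced window is one sample longer than the cycle span
   and strict disjointness would skip every k-th cycle of a perfectly
   regular oscillation.  Fewer than three usable sections on either path
   abandons that f_P ("insufficient cycles"), which propagates as a NaN
   column of the comodulogram.
3. **Energy map.**  Morlet wavelet energy with wavenumber w = 5 by
   default (time-domain envelope std w/(2πf); frequency-domain std f/w,
   i.e. FWHM 2√(2 ln 2)·f/w).  FFT convolution with zero padding;
   w/min(f_A) seconds are trimmed from each end, which exceeds the
   wavelet half-support at the lowest frequency, so the padding mode
   cannot influence retained values.  Map sections whose window exceeds
   the trimmed extent are dropped.
4. **Averaging.**  One-cycle map sections are averaged into M_A; the
   averaged filtered slow cycle SP_A supplies the phase via its analytic
   signal.  Path B produces the three-cycle map M_B, the filtered average
   SP_B and the raw-signal average S_B.
5. **Surrogates.**  Each of N_s = 200 repetitions re-extracts the
   one-cycle sections with two perturbations: centres displaced by
   U(−1/(2 f_P), +1/(2 f_P)) seconds, and the section's time axis
   rescaled by an independent factor U(0.9, 1.1) before resampling back
   to the one-cycle sample count.  Resampling uses nearest-neighbour
   gathering: linear interpolation at fractional coordinates low-passes
   the energy rows and systematically deflates surrogate MI, which
   inflates the false-positive ratio.  A displaced window falling outside
   the trimmed map is redrawn up to ten times, then that maximum is
   skipped.  Each (seed, f_P) pair drives an independent random stream.
6. **Comodulogram.**  MI of each M_A row against the averaged phase;
   original and surrogate values are centred by the per-pair surrogate
   mean (centred values may be negative; only thresholding decides
   significance).  Centring makes pairs comparable, which the
   extreme-value statistic requires.
7. **Statistics.**  The maximum of each surrogate comodulogram forms the
   null of extremes; the threshold is its p_C = 95th percentile (linear
   interpolation between order statistics).  Each original value also
   receives its empirical percentile among the maxima (P_vals), capped so
   that the implied p-value is never below 1/(N_s + 1).  A second,
   per-pair rejection removes pairs whose phase-bin distribution P(j)
   never exceeds th(j), the p_PC = 95th percentile of the surrogate
   distribution of max_j P(j).  With a reduced surrogate count the
   interpolated 95th percentile of N_s maxima is slightly
   anti-conservative (expected exceedance ≈ 0.068 at N_s = 50,
   converging to 0.05 as N_s grows); the validation experiments use the
   published N_s where time permits and accept the small excess at
   reduced scale.
8. **Origin labels.**  8-connected significant regions are labelled
   Reliable/Ambiguous per phase-frequency column: the column's strongest
   f_A defines a congruence window of ± half the wavelet FWHM; the
   spectrum with the more pronounced content over the union of the
   region's f_A span and that window (average spectrum AS vs spectrum of
   the averaged signal SA, unit-normalised Blackman–Harris periodograms
   of the three-cycle sections; ties go to AS) is searched for a proper
   peak (strictly lower neighbours on both sides; ties toward lower
   frequency).  Reliable iff the peak falls inside the congruence window;
   a maximum on the lower grid edge is undecidable and yields Ambiguous
   with a warning.  A region is Reliable iff at least one column is
   (per-column labels are kept for audit).  Finally, regions whose
   centroid f_P is an integer multiple (strictly within Δf_P) of an
   Ambiguous region's centroid are relabelled Ambiguous; the relabelling
   is monotone and iterated so chains propagate.

## Synthetic models (the study conditions)

Defaults follow the validation protocol: slow 6 Hz of unit amplitude,
fast 77 Hz, amplitudes ratio 0.1, noise SD 0.1, 10 s at 512 Hz.

- **Coupled bursts** — Gabor atoms (σ = 10 ms) on a fixed slow phase
  (default: the slow maximum, matching the published appearance of the
  bursts "just before the peaks"; configurable) of a fraction `filling`
  of cycles, chosen uniformly without replacement.  No per-cycle
  amplitude jitter is assumed.
- **Random bursts** — same atom count, centres uniform in time; the
  no-coupling control.
- **Amplitude modulation** — fast sine with envelope
  Ā·((1−χ)sin(2πf_P t)+1+χ)/2; depth of modulation = 1−χ, default χ=0.1.
- **Multimodal** — envelope built from phase-lagged sawtooths passed
  through a zero-mean normal density and min-max normalised per mode;
  mode phases default to {4π/5, 3π/2, π/10}.  The density scale is
  σ = 0.1 on the sawtooth's [−1, 1] range (variance 0.01).  With
  variance 0.1 the three bumps overlap so heavily that the envelope is
  nearly flat and the 18-bin histogram loses its three maxima, which
  contradicts the model's published behaviour — see the width discussion
  above.
- **Filtered noise** — unit 6 Hz sine plus white noise band-passed
  76–78 Hz (Butterworth 2, zero phase) rescaled to max |value| = 0.1; the
  no-coupling control for the AM model.
- **Gaussian spike trains** — spikes of FWHM 15 ms and amplitude 2 or
  5 background-SD at quasi-periodic (100 ± 20 ms uniform) or uniformly
  random times on a background, then 1 Hz high-pass and 250 Hz low-pass
  (Butterworth 2, zero phase) and a 10 s fragment.  The background is
  pink noise of unit SD — a synthetic stand-in for a PAC-free EEG
  recording, which removes the only external-data dependency.  Pink
  noise itself is white noise shaped by a 1/√f FFT mask (PSD ∝ 1/f).

What the generators do *not* emulate: non-stationary oscillation
frequency and amplitude, 50/60 Hz line noise, movement artefacts,
multi-channel structure, and realistic EEG spectra beyond 1/f.  Passing
tests therefore demonstrate correctness of the estimators and calibration
of the statistics under idealised conditions, not robustness to every
property of real recordings.

## Detection protocols in the experiments

Two distinct questions require two distinct tests:

- *Is there any coupling?* (false-positive experiments): family-wise
  extreme-value threshold over the whole comodulogram.
- *Is the known, pre-specified pair coupled?* (parameter sweeps): the
  pair's value against the 95th percentile of its own surrogate
  distribution — no multiple-comparison correction is needed when the
  pair is fixed in advance, and correcting anyway would misstate the
  sweep's sensitivity.

Sweep detection onset is defined as the smallest swept value whose
detection rate is significantly above the 5% false-alarm floor
(one-sided binomial test at the 0.05 level; ≥ 3 detections out of 10
repetitions).  A bare "any repetition detected" rule would trigger on
the false alarms the test permits by construction.

For collated multi-epoch presentations, the per-epoch, per-f_A maxima of
Reliable coupling are selected first and Benjamini–Hochberg FDR at
q = 0.05 is applied to the p-values of those displayed maxima, pooled
across epochs.  Pooling *all* grid cells instead would make rejection
impossible at any realistic surrogate count, because the empirical
p-values are floored at 1/(N_s + 1).

## Desk-scale problem sizes

The validation suite and the acceptance script run the published
protocols at reduced scale, chosen once: 30–50 realisations and 50
surrogates for false-positive calibration; 10 repetitions and 100
surrogates per sweep point; a 9 × 17 grid (f_P 2–10 Hz step 1, f_A
40–120 Hz step 5) for the experiments and the full 23 × 91 grid (f_P
1–12 step 0.5, f_A 20–200 step 2) for localisation.  Caches exploit that
the pink-noise screening null and the reference methods' surrogate
phases are data-independent: both are computed once per configuration
and shared across realisations, which changes nothing statistically
(every surrogate remains an independent draw of its null process).

## Known limitations

- The Reliable/Ambiguous heuristic aggregates per-column labels with a
  permissive rule (any Reliable column ⇒ Reliable region) and detects
  harmonic structure by integer-multiple centroid chains; both rules are
  package choices where the procedure itself is underdetermined.
- dPAC under the pre-specified-pair test retains measurable sensitivity
  at burst fillings well below 0.5, where family-wise testing over a
  large grid would suppress it; which behaviour is "correct" depends on
  the question asked of the sweep.
- The screening step assumes a 1/f-like background; strongly coloured or
  line-noise-dominated spectra will distort the ratio threshold.
- Epoch artefact rejection is a plain amplitude criterion (|z| > k), not
  a substitute for proper artefact pipelines.
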
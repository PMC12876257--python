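# Methods

## Model and procedure

The package treats one EEG recording as a channels × samples matrix at a
stated sampling rate (default 1 000 Hz, 128 channels).  The analysis chain
is:

1. **Conditioning** — whole-recording linear detrend, zero-phase IIR notch
   at 50 Hz (quality factor 30), zero-phase 4th-order Butterworth band-pass
   2–48 Hz.  Zero-phase (forward–backward) filtering is used so event
   alignment is preserved; the filter family and order are standard scalp-EEG
   practice and configurable.
2. **Event alignment** — marker timestamps are advanced by the amplifier's
   anti-alias conversion delay (8 ms) plus the display refresh latency
   (14 ms), a 22 ms total.  The shift is applied to timestamps only; the
   signal is untouched.  Markers pushed past the end of the recording are
   clipped and flagged.
3. **Windowing** — contiguous non-overlapping 500 ms windows from t = 0;
   NW = ⌊L / 500 ms⌋, trailing partial window discarded.
4. **Spectra** — per electrode-window, a single-taper (Hann) periodogram
   zero-padded to one second.  A 0.5 s window natively resolves 2 Hz; the
   analysis grid of 45 bins at 4, 5, …, 48 Hz forces an interpolation
   choice, and zero-padding is the simplest one.  The estimator sits behind
   one function (`window_psd`) and can be swapped.  Consequence to keep in
   mind: the Hann main lobe of a 0.5 s window spans ±4 Hz on the padded
   grid, so a pure tone leaks substantially into its ±1–3 Hz neighbours and
   sharp band edges are smeared.  Tests that check spectral exactness
   therefore use either the tone's bin rank or a full-length leakage-free
   periodogram as the oracle.
5. **Indices** — with pᵢ = PWᵢ/TP over the 45 bins:
   H = −Σ pᵢ log₂ pᵢ (0·log 0 := 0); PSk = |mean − mode|/SD with
   probability-weighted frequency moments (Hz) and the mode the max-power
   bin; TP = Σ PWᵢ; DF = mode frequency; per recording,
   DFs = sample SD (n−1) across electrodes of each electrode's mean DF.
   The band-pass admits 2–48 Hz but the indices deliberately use only
   4–48 Hz; the 2–4 Hz content is filtered in but excluded from pᵢ.
6. **Aggregation** — level-wise means (windows → electrode → participant →
   group), never pooled, so unbalanced window counts cannot weight one
   electrode more than another.  Group summaries carry
   mean ± t₁₋α/₂,ₙ₋₁ · SD/√n (two-sided 95 % by default; degrees of freedom
   n − 1).
7. **Decisions** — per group, each unordered modality pair is tested per
   index with a Welch unequal-variance t-test (Satterthwaite df, two-sided,
   α = 0.05) on participant-level values; the four binary outcomes combine
   as Reject (3–4 rejections), Neutral (2), Accept (0–1).

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| band-pass | 2–48 | Hz | excludes drift below, muscle artifact above |
| notch | 50 (Q = 30) | Hz | power-line interference |
| window | 500 | ms | time resolution of the index dynamics |
| analysis bins | 4–48, step 1 | Hz | the index definition's frequency support |
| band table | Theta 4–8, Alpha 8–13, L-Beta 13–20, H-Beta 20–30, Gamma 30–48 | Hz | conventional edges; half-open [low, high), top band closed so bin 48 is Gamma |
| α | 0.05 | — | significance level of all pairwise tests |
| event shift | 8 + 14 = 22 | ms | hardware timing corrections |
| cohort | 11 + 9 | participants | meditator / non-meditator group sizes |

Ties: equal max power → lowest frequency; equal summed band power →
lowest band.  SD = 0 (single-bin spectrum) → PSk := 0, since the mean then
equals the mode.  All-zero windows raise an error at the single-window
level and are flagged and excluded at the recording level; a recording
with more than 50 % flagged windows is rejected as degenerate.

## Design choices where the design was open

- **PSk moments.** The skewness coefficient is read as frequency-weighted:
  mean and SD are moments of the spectral distribution *over frequency*
  (Hz), making |mean − mode|/SD dimensionless with a frequency mode.  The
  alternative reading (moments of the power values themselves) was
  rejected because the mode in the definition is explicitly a frequency.
- **Sensor montage.** The exact 128-channel → 12 × 12 assignment and the
  identity of the 14 doubled electrodes are conventions, shipped as a
  replaceable data file rather than code.  The bundled default respects
  left/right mirror symmetry of region labels (two 12 × 6 sub-matrices),
  leaves (1,3) and (1,10) empty as prefrontal reference markers, and
  doubles the whole back row vertically plus the two front corners
  sideways.  Users with a digitized montage should supply their own table.
- **Normalization.** For cross-modality comparison, H is scaled by its
  analytic maximum log₂ 45 (an absolute scale); PSk, TP and DFs are scaled
  by the maximum of the compared collection, jointly across groups and
  modalities.  Outputs always carry the method tag and factor so
  normalization is invertible.
- **Unit of analysis.** Pairwise tests run on participant-level values
  (one number per participant × modality × index), n = 11 vs 9, consistent
  with the aggregation hierarchy.
- **Borderline decisions.** A test with |p − α| < 0.005 is flagged
  borderline.  The bundled reference decision tables contain one cell
  whose published combined verdict (Reject) is inconsistent with its own
  four printed index decisions (2 rejections → Neutral by the rule); its
  TP decision is a borderline accept.  The plain rule reproduces 29 of the
  30 published combined cells; an explicit `borderline_as_reject` switch
  reproduces all 30.  Both behaviours are available; neither is silently
  preferred.

## The synthetic generator

Each state profile holds relative band weights, a 1/f^β exponent
(default β = 1) and a noise scale.  Per channel the signal is a sum of
random-phase band-limited Gaussian oscillations — drawn directly as
independent complex spectral coefficients, so band bins fill like
stochastic oscillations rather than pure tones — plus a pink 1/f^β
background and white noise.  Meditation is narrowly alpha-dominant with an
occipital/parietal alpha boost (×1.5 / ×1.3) and the largest amplitude;
video is the broadest, lowest-amplitude mixture; the other four states
interpolate so that alpha concentration decreases in the order
MED > SENT > WORDS > MM > IMG > VDO.  Meditators carry a multiplicative
group effect (alpha weight ×1.3, broadband noise ÷1.3).  Effect sizes are
property-driven constants frozen once; they reproduce the qualitative
ordering of the indices across states, not any particular numeric value.
Sub-seeds derive from `SeedSequence((master_seed, participant_idx,
modality_idx))`, so cohorts are reproducible and individual recordings can
be regenerated in isolation.

What the generator does **not** emulate: eye-blink/muscle artifacts,
volume conduction and inter-channel correlation, non-stationarity within a
state, event-locked responses, impedance drift, or realistic electrode
noise spectra.  Passing tests therefore demonstrate that the analysis
chain recovers known spectral structure and calibrates correctly under a
clean null — not that it is robust to real-world artifacts.

## Problem sizes used by the test suite

Monte-Carlo checks shorten recordings: state-separation runs use the full
128-channel montage with 6 s recordings (12 windows) over 50 master seeds;
null-calibration runs use a 16-channel auxiliary grid with 2 s recordings
over 200 replicates (under the null, spatial structure and duration only
scale the variance of participant summaries, not the level of the tests);
single-recording checks (alpha dominance, spectral fidelity) use 60 s.
Full protocol durations (7 min meditation, ~2 min video, 20/12/28/20-trial
schedules) remain the defaults of `experiment_schedule` and
`simulate_cohort`.

Null-calibration acceptance bands are binomial 99 % bounds around α plus a
small fixed allowance (+0.01) decided a priori, because the 15 pairwise
tests per replicate share samples and are therefore positively dependent;
strictly binomial bounds would understate the Monte-Carlo variance of the
pooled rejection rate.

## Known limitations

- The 1 Hz analysis grid is interpolated, not resolved; neighbouring bins
  within ±3 Hz are strongly correlated, which smooths H upward for very
  narrow spectra and blurs band edges (see Spectra above).
- DFs assumes one value per electrode; electrodes with zero valid windows
  are silently dropped from its computation (with a count in the logs).
- EDF files can be read (via the optional `mne` dependency) but not
  written; the native on-disk format is a delimited matrix with a YAML
  side-car.
- The robustness battery's repeated-measures entries require a balanced
  participant × modality design and are marked unavailable otherwise.
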
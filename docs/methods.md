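# Methods

## Problem and pipeline

`arousalstack` detects sleep arousals — abrupt EEG frequency shifts toward
alpha/theta/fast activity lasting at least 3 s — from a single central EEG
derivation (C3-M2) sampled at 200 Hz. Scoring practice reads such events in
30-s windows, so the detector is a per-window binary classifier. The
pipeline is:

1. **Anti-powerline filtering.** A low-pass with passband edge 40 Hz and
   stopband edge 42 Hz removes 60 Hz mains pickup while keeping all
   clinically used EEG bands. The nominal specification — order 127 with
   those edges — is internally awkward for an IIR realization (a
   127th-order recursive filter at these edges is numerically pathological),
   so the default realization is a linear-phase FIR with 128 taps designed
   by weighted least squares on the printed edges. `scipy.signal.firls`
   covers odd tap counts only, so the package solves the Type II (even
   length, symmetric) weighted least-squares design directly: with
   `h[n] = h[127-n]` the amplitude response is linear in the 64 free
   coefficients, and a dense-grid least-squares fit to the ideal response
   (1 below 40 Hz, 0 above 42 Hz) is a single `lstsq` call. The stopband
   weight (default 10) buys deep mains rejection: the realized response has
   DC gain 0.997, passband deviation below 5% up to 39 Hz, and about
   −64 dB at 60 Hz (the regression test requires at most −30 dB). The
   constant 63.5-sample group delay is compensated by a 64-sample shift
   with edge padding so per-sample labels stay aligned. An alternative
   8th-order IIR Butterworth realization (zero-phase via forward-backward
   filtering) is available as `FilterSpec(realization="iir")`.

2. **Segmentation and window labels.** The first and last hour of each
   overnight record are discarded (montage settling, lights-on artifacts),
   the remainder is cut into non-overlapping 30-s windows (6000 samples),
   and a trailing partial window is dropped. A window is labeled positive
   iff it contains a *contiguous* arousal run of at least 3 s (600
   samples) — the scoring rules fix the minimum event duration but not the
   window rule, so the threshold is configurable
   (`SegmentationConfig.min_arousal_run_seconds`); runs straddling a window
   boundary count only their in-window portion. Synthetic records are
   stationary from the first sample, so the synthetic pipeline uses a zero
   edge discard; the hour-long discard remains the default for real
   records.

3. **Multitaper band powers (29x8 per window).** Each window is analyzed in
   2-s frames (400 samples) hopped by 1 s — 29 frames — and each frame's
   PSD is the unweighted average of 8 single-taper periodograms on the 8
   most-concentrated DPSS (Slepian) tapers of length 400. The
   time-bandwidth product is not part of the nominal specification; the
   default NW = 4.5 is the smallest value for which K = 2NW − 1 = 8 tapers
   are all well concentrated, matching the fixed taper count. Scaling
   conventions are pinned so energy bookkeeping is exact: unit-energy
   tapers, |DFT|²/N_b periodograms, interior one-sided bins doubled (DC and
   the 100 Hz frame Nyquist not), no demeaning before tapering (the DC bin
   carries the frame mean). Under these conventions the one-sided PSD of
   unit-variance white noise sums to 1 in expectation, which the tests
   verify to 1% averaged over 200 frames. Band powers integrate the PSD
   over fixed bin ranges (delta bins 1–9, theta 10–17, alpha 18–25, beta
   30–61, full 1–81; 1-based, 0.5 Hz spacing) with composite Simpson
   quadrature; when a band spans an odd interval count the final three
   intervals use the Simpson 3/8 rule, keeping the quadrature exact for
   cubics. Three power ratios (delta/theta, theta/alpha, delta/alpha)
   complete the 8 features per frame; 0/0 is defined as 0 and x/0 (x > 0)
   is clipped at a configurable ceiling (default 1e6).

   With NW = 4.5 the spectral mainlobe is ±2.25 Hz wide, so a pure tone
   near a band edge leaves a fixed fraction of its energy in neighboring
   bands — e.g. a 10 Hz tone puts ~82% of its power in the alpha bins, not
   ~100%. This is inherent to the taper bandwidth, not a leakage bug.

4. **Expert features (1x42 per window).** Time domain (6): mean central-
   difference gradient, kurtosis, Hjorth activity/mobility/complexity,
   skewness. Frequency domain (36): min, mean, standard deviation and 95th
   percentile of each of the 8 band-power columns over the 29 frames, plus
   the kurtosis of the 4 sub-band columns. The moment conventions are
   deliberately non-textbook: kurtosis and skewness divide a 1/N central
   moment by the (N−1)-denominator sample standard deviation, so the
   Gaussian large-N kurtosis limit is still 3 (finite-N value
   3(N−1)²/N²); a `convention="textbook"` mode uses 1/N throughout. The
   95th percentile interpolates linearly between order statistics.

5. **Sub-models.** Four base classifiers, each emitting a (p_normal,
   p_arousal) pair:
   - a waveform 1-D CNN on the raw 6000-sample window: four blocks of two
     valid convolutions (kernels 50, 30, 10, 2; widths 20/20, 20/24, 12/12,
     12/12) with ReLU and max-pool 2, global average pooling to a
     12-vector, dense softmax (length trace 6000→5951→5902→2951→2922→2893→
     1446→1437→1428→714→713→712→356→12→2);
   - a band-power RNN: bidirectional LSTM (20 hidden per direction) over
     the 29x8 matrix, uni-directional LSTM (10 hidden, last state), dense
     32 + ReLU, dense softmax;
   - a random forest (scikit-learn; default 500 trees, unlimited depth,
     sqrt-features per split) on the 42 expert features;
   - a pre-merged CNN+RNN: the 12- and 32-vector embeddings concatenated
     into a 44-vector feeding a dense softmax head, initialized from the
     trained trunks and fine-tuned end to end (a flag freezes the trunks).

   The published layer tables print two parameter counts (the fifth and
   sixth conv layers) that contradict their own printed filter shapes; the
   shapes govern here (2892 and 1452 parameters), and those two rows are
   excluded from the architecture-fidelity checks.

   The neural models run on a small numpy core written for this package:
   FFT-based valid convolution (exact gradients, verified against
   numerical differentiation), LSTM with backpropagation through time,
   Adam. Convolution layers use He initialization — with eight ReLU
   convolutions and no normalization layers, Glorot scaling attenuates
   activations enough that training stalls at the class prior. Waveform
   inputs are z-scored per segment; band powers (which span decades) are
   log10-transformed then z-scored per column with training-set statistics.
   Training is mini-batch (64) Adam at 1e-3 with early stopping on a 15%
   validation split (patience 5 by default), fully seeded; the nominal
   specification states no optimizer, so these are package choices.

6. **Stacking meta-classifier.** The meta-input is p = (1, p₁, …, p₈): an
   intercept plus the four probability pairs. A plain logistic regression
   h_β(p) = exp(pᵀβ)/(1 + exp(pᵀβ)) is fitted by gradient descent on the
   unregularized mean cross-entropy from β = 0, with backtracking (Armijo)
   line search, stopping when the gradient infinity-norm falls below 1e-8
   or the descent decrement falls below float64 resolution. Because each
   pair sums to 1 and an intercept is carried, the design matrix is rank
   deficient; the cost is still convex, the fitted probabilities are
   unique, and gradient descent converges to a minimum-cost point. A
   `drop_redundant` mode keeps only the intercept and the four arousal
   probabilities for a full-rank parameterization. A window is declared an
   arousal when h_β is strictly greater than 0.5.

   How the meta-training set is built is genuinely open (in-sample
   stacking leaks sub-model overconfidence). Three protocols are
   implemented: `oof` (k-fold out-of-fold sub-model predictions; the
   library default), `holdout` (blending: sub-models train on part of the
   records and predict a dedicated stacking split), and `naive`
   (in-sample, for comparison). The reference study uses blending: it has
   the same no-leakage property as out-of-fold stacking at one-fifth of
   the training cost, and on the synthetic task the two are
   indistinguishable.

7. **Evaluation.** Accuracy, sensitivity, specificity and precision from
   exact confusion counts (an undefined ratio is reported as NaN with a
   warning); AUROC via trapezoidal integration over all thresholds
   (scikit-learn backend), verified in tests against the Mann–Whitney
   pairwise-concordance oracle to 1e-12. Cross-validation and train/test
   splits are assigned at the *record* level so segments of one subject
   never appear on both sides of a split.

## Synthetic data: what it emulates and what it does not

The generator produces a 200 Hz single-channel record as a sum of four
band-limited Gaussian noise processes (delta 0.5–4, theta 4–8, alpha 8–12,
beta 14–30 Hz; default amplitude weights 1.0/0.5/0.3/0.15 approximating the
1/f-like spectrum of quiet sleep), a broadband noise floor (0.05), and a
60 Hz sinusoid (amplitude 0.5) emulating powerline pickup. Arousal events
arrive as a Poisson process (candidate rate 63/h), last 5–15 s (uniform),
and respect the scoring constraints: no event shorter than 3 s, at least
10 s of event-free signal before each onset. During an event the alpha and
beta component amplitudes are multiplied by `arousal_band_shift` (default
3), realizing the "abrupt shift toward faster activity" as a known,
controllable spectral contrast. The candidate rate was calibrated once so
the default configuration yields ≈40% positive 30-s windows — the class
balance of the real overnight corpus this emulates — and left fixed.

Everything is driven by `numpy.random.Generator` seeds; identical
configuration gives byte-identical records, and dataset-level seeds are
spawned per record from the master seed.

What the generator does **not** model: sleep-stage architecture, spindles
and K-complexes, movement/EMG artifacts, electrode pops, inter-subject
spectral variability, or any arousal morphology beyond a sustained
alpha/beta amplitude shift (real scorers also key on theta shifts and
>16 Hz activity). Consequently, passing the synthetic study shows that the
pipeline is *correct* (features measure what they claim, models learn a
genuine spectral contrast, stacking does not hurt) — it does not certify
real-data performance, where class contrast is far weaker and noisier.

## Reference study and problem sizes

The canonical synthetic evaluation (`arousalstack.pipeline.reference_study`,
also what `scripts/acceptance.py` runs) uses 34 half-hour records →
2,040 segments at ~40% prevalence; 20% of records held out for testing;
blending with 25% of training records as the stacking split; reduced epoch
budgets (CNN 6, pre-merge 3, RNN 20 with early stopping) — on this
cleanly separable task the CNN converges within a few epochs, so longer
schedules only add cost. On the default study every sub-model reaches
held-out AUROC well above 0.85 and the stacked classifier matches or
exceeds the best sub-model.

## Numerical choices and degenerate inputs

- Constant signals: Hjorth activity 0, mobility/complexity reported as 0
  with a warning; zero-variance moments likewise 0 with a warning.
- Zero segments: all band powers 0, ratios 0 by the 0/0 convention.
- Softmax and the logistic function are computed in overflow-safe forms;
  log-loss probabilities are clipped at 1e-12.
- A NaN/inf training loss aborts with a diagnostic rather than continuing.
- Forest probability output degenerates gracefully when a fold contains a
  single class.
- WFDB writing scales each channel to a peak of 32,000 ADC units with its
  own gain recorded in the header; round trips are exact to half a
  quantization step.

## Known limitations

- The numpy neural core is CPU-only and single-threaded beyond BLAS; it is
  sized for the reference study, not for the 994-record real corpus.
- The amplitude scale of the pipeline is covariant (powers scale
  quadratically); only the documented scale-free features are invariant.
- The 3-s window-labeling rule is one defensible reading of the scoring
  guidance ("any arousal sample" and "majority" rules are also plausible);
  it is exposed as configuration rather than asserted as ground truth.
- Real-data evaluation requires downloading the public polysomnography
  corpus; the reader (`read_wfdb_record`) and the hour-discard
  segmentation defaults target that path but are exercised here only
  through synthetic WFDB round trips.
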
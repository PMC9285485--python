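# Methods

## Scope and model

`neoqc` detects two artifact families in multichannel neonatal EEG of
infants at term-equivalent age: flat-line segments (instrumental, from
lost electrode/head-box contact) and large-amplitude fluctuations
(movement, frequently with concurrent muscle activity). It removes the
affected intervals rather than attempting correction: a flat segment
contains no cortical signal to restore, and movement artifacts are too
variable across channels and waveforms for interpolation to be trusted.
Other artifact families (ocular, cardiac, isolated EMG) are out of scope.

The detector is threshold-based and fully deterministic: its output is a
function of the input samples and the configuration only.

## Signal views and filtering

Three aligned views of the recording feed the detectors:

| view | filtering | consumers |
|---|---|---|
| raw | none | flat-line detection |
| notched | 50 Hz IIR notch (Q = 30), zero phase | spectral ratio (RFC) |
| band | notch + 0.5–40 Hz Butterworth (order 4), zero phase | MAFD, MAA |

The split resolves an inherent tension: the high-frequency power ratio
needs content above 50 Hz that the 40 Hz low-pass edge would destroy, so
it is computed before band-passing; and a lost-contact segment is exactly
constant only before any filtering, so the flat-line stage consumes the
raw signal. All filters are applied forward–backward (`filtfilt`), so
event onsets are not displaced; filter edge transients at the recording
boundaries are tolerated because the detectors' padding and
window-granularity absorb them. Filtering never changes the sample count.

## Flat-line stage

1. **Second difference** `z(n) = x(n+2) − 2x(n+1) + x(n)` per channel —
   invariant to DC offset and to linear drift.
2. **Flagging**: samples with `|z| < 10⁻⁴ µV` (strict) are flagged when
   at least 2 of them fall in the same fixed, consecutive 1-s bin. Fixed
   bins were chosen over a sliding 1-s window as the simplest reading of
   a per-second count; a sliding window would count most samples several
   times. The minimum count of 2 is the smallest value consistent with
   requiring "multiple" hits; both are configurable.
3. **Grouping**: flagged sample times with successive gaps ≤ 2.5 s
   (edge-to-edge between sample times, boundary inclusive) chain into one
   candidate interval per channel.
4. **Consensus**: a sample belongs to an accepted interval iff at least
   `round(0.75·C)` channels have a candidate covering it — 14 of 19 and
   7 of 9 channels at the default fraction.
5. **Padding**: accepted intervals ≤ 5 s grow by 1 s per side, longer
   ones by 3 s, then re-merge and clip to the recording. A duration of
   exactly 5 s takes the short pad (tie left open by the rule's
   phrasing; configurable). Padding is applied after consensus, measured
   on the unpadded duration.

## Large-amplitude stage

Non-overlapping windows (default 3 s) tile the recording; a trailing
remainder ≥ 1 s becomes its own shorter window, a smaller remainder is
absorbed into the last full window so that every window supports a
stable Welch estimate.

Per channel and window: MAFD (max absolute first difference), MAA (max
absolute amplitude) on the band view; RFC (fraction of Welch power
strictly above 50 Hz) on the notched view, with Hamming sub-windows of
`min(256, window)` samples at 50% overlap — 256 gives ~1 Hz resolution
at 250–256 Hz; the exact sub-segment length is otherwise a free choice.
An all-zero window has RFC 0 by convention.

Channel-specific thresholds pool **all** windows of the recording:
`mafd_cut = 4.5·(median + MAD)` and `rfc_cut = 1.5·(median + MAD)`,
where the MAD is the *unscaled* median absolute deviation (no 1.4826
consistency factor). The four removal criteria (any channel suffices):

1. `MAFD > mafd_cut`;
2. `MAA > 150 µV` (PT150);
3. `100 µV < MAA < 150 µV` and `RFC > rfc_cut`;
4. doubtful-range MAA and the previous and/or next window already
   selected by criteria 1–3.

All comparisons are strict; equality never selects. Criterion 4 runs as
a single backward+forward sweep seeded only by criteria 1–3, so chains
of doubtful windows do not propagate selection. The doubtful-amplitude
channel and the neighbour's triggering channel may differ — the rule
does not bind them to one channel. Selected windows fuse when
consecutive; resulting intervals separated by ≤ 6 s (inclusive — the
boundary case is not specified and inclusion is the safer reading for
artifact removal) fuse again.

In the assembled pipeline the two interval sets are unioned; where they
overlap the flat-line label wins.

## Tunable parameters

| parameter | default | unit | role |
|---|---|---|---|
| `flat_threshold` | 1e-4 | µV | second-difference cut |
| `flat_min_flags_per_second` | 2 | count | per-bin flagging minimum |
| `flat_group_gap_s` | 2.5 | s | flag chaining gap |
| `consensus_fraction` | 0.75 | — | channel quorum fraction |
| `pad_short_s` / `pad_long_s` / `pad_cutoff_s` | 1 / 3 / 5 | s | duration-dependent padding |
| `window_s` | 3 | s | analysis window (1–7 sensible) |
| `pt100` / `pt150` | 100 / 150 | µV | physiological amplitude bounds |
| `mafd_mult` / `rfc_mult` | 4.5 / 1.5 | — | robust threshold multipliers |
| `rfc_cut_hz` | 50 | Hz | spectral split of RFC |
| `merge_gap_s` | 6 | s | interval merging gap |

The 3-s default window offers the best compromise between hit rate and
over-removal for sleep-staging applications; 2 s is the documented
alternative (slightly higher specificity, slightly lower hit rate). The
physiological bounds are specific to term-equivalent age — younger
preterm EEG has higher amplitudes and would need larger values.

## Synthetic data

The generator produces 1/f-shaped Gaussian noise per channel (FFT
amplitude shaping, scaled to a 20 µV RMS default), which reproduces the
amplitude regime and spectral tilt that the thresholds assume — peaks
stay below 100 µV in ≥ 99% of 1-s bins — but none of the sleep-stage
structure, inter-channel correlation, asymmetries or non-stationarity of
real neonatal EEG. Passing recovery tests on this background therefore
demonstrates the threshold logic, not clinical-grade performance.

Flat events hold the last pre-onset value exactly (optionally with a
one-sample ±500 µV deflection just outside each edge, mimicking the
transients around real contact losses). Bursts are Tukey-tapered
(α = 0.5) sinusoids rescaled so the largest sample equals the requested
peak: movement at 2 Hz (safely inside the pass-band), muscle at 60 Hz
(between the 50 Hz notch/RFC cut and the Nyquist rate, and removed by
the band-pass — visible to RFC only). A doubtful-range configuration
that only criterion 3 can catch is produced by co-locating a ~120 µV
movement burst with a muscle burst of comparable power. Everything is
deterministic given the spec's seed.

The reference study condition (`default_spec`) is a 9-channel, 250 Hz,
20-minute recording with two all-channel flat events (3 s and 10 s) and
six bursts at seeded random onsets; event density can be raised to
~20% artifact load by spec adjustment.

## Numerical choices and degenerate inputs

- Time is continuous seconds with half-open `[start, end)` intervals;
  sample `i` covers `[i/fs, (i+1)/fs)`, making interval sets and boolean
  masks exactly interconvertible and time exactly conserved by removal.
- Boundary probes of the detector logic (the acceptance sweeps) pass an
  unfiltered recording as both feature views, isolating the criteria
  from filter gain so that amplitude boundaries are exact at integer µV.
- Undefined metrics (empty denominators) are NaN, never 0; undefined
  per-class components are excluded from multi-class means with a
  warning.
- Channel thresholds refuse single-window recordings (no distribution to
  take a median over); RFC refuses windows of < 2 samples.
- The EDF fixture writer quantises to 16 bits over ±1000 µV (LSB
  ≈ 0.03 µV) in 1-s records; the reader rejects files whose selected
  channels disagree on sampling rate.
- Kruskal–Wallis / rank-sum statistics come from `scipy.stats`; only the
  effect sizes ε² = H(n+1)/(n²−1) and η² = Z²/n are computed here, both
  clipped to [0, 1]. The η² convention (Z²/n over pooled n) follows the
  usual rank-biserial-adjacent practice; other conventions exist.

## Known limitations

- Whole-bad-channel handling and interpolation are not implemented; the
  detector assumes no channel is flat or saturated for the entire
  recording.
- The consensus rule targets all-channel contact loss; flat lines
  confined to a minority of channels are deliberately ignored.
- Thresholds assume term-equivalent age and non-pathological EEG;
  seizures or preterm amplitude regimes need re-tuning.
- Synthetic validation bounds what the tests show (see above); no real
  annotated neonatal dataset ships with the package.
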
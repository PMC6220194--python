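# Methods

`padflux` quantifies microbial growth rates from impedance recordings of a
microfluidic yeast micro-chemostat, and ships a synthetic counterpart of the
device so the whole chain can be validated against known ground truth. This
note documents the model, the estimators, the numerical choices, and the
limits of what the synthetic validation demonstrates.

## The measurement model

Cells clamped under a PDMS pad grow as a 2D monolayer until the pad area is
full. From that point the colony size `K` is constant: every division pushes
one cell out of the colony, and the escaped cell is carried by the medium
flow over a coplanar electrode pair, producing a millidegree-scale transient
("peak") in the phase of the impedance signal at 1.12 or 1.5 MHz.

Escapes are treated as a homogeneous Poisson process. With per-cell escape
rate `g` (events/h per cell), the peak rate at the electrodes is `g·K`
events/h. The normalized peak rate for a counting window of length `w`
(hours) with count `c` is

    peak_rate_norm = c / (N̄ · w)       [per h per cell]

where `N̄` is the arithmetic mean of the cell counts under the pads at the
start and end of the recording session. `peak_rate_norm` estimates `g` and is
independent of colony size, so analysis units with different numbers of
filled pads are directly comparable.

A fraction BI (the budding index) of the passing cells is budded; mother and
bud pass the electrodes as one object and yield a single peak. Each peak
therefore carries on average `1 + BI` cells, and the absolute (biological)
growth rate is

    growth_rate = peak_rate_norm · (1 + BI)

Equivalently: the per-cell escape/peak rate `g` that the device measures is
the division rate divided by `(1 + BI)`. The form of the correction factor
is this package's design choice — the underlying observation it encodes is
only that budded passages yield single peaks. `ColonyParams.growth_rate_per_cell`
throughout the package is `g`, the peak rate, not the division rate.

### Per-condition statistics

Per media condition, the estimate is the arithmetic mean of per-window
normalized rates; its uncertainty is the standard error of that mean using
the sample (n−1) standard deviation over windows. The SEM is reported as 0
and flagged undefined when a condition retains a single window. Repeated
phases of the same condition (e.g. rich medium before and after a calcium
phase) are pooled into one estimate.

Relative changes between adjacent conditions are reported as
`100·(r_other − r_ref)/r_ref` with the **slower** condition as reference —
the convention under which recovery from a growth-inhibiting medium is a
positive change, and the only denominator choice consistent with both
worked-example pairs ((0.196, 0.32) → 63%, (0.25, 0.30) → 20%).

## Peak detection

1. **Bandpass**: 0.1–30 Hz 4th-order Butterworth (2 poles per skirt,
   `scipy.signal.butter(2, ..., "bandpass")`) applied forward–backward
   (`sosfiltfilt`). Zero-phase filtering preserves peak times, which
   windowed counting requires. Traces must be at least `3/band_low` = 30 s
   long.
2. **Thresholding**: every local maximum of the filtered signal above the
   threshold is an event; maxima closer than `min_separation` (default
   50 ms) are merged keeping the larger. Default thresholds are the
   midpoints of the device's operating ranges: 4×10⁻³ ° at 1.5 MHz,
   0.65×10⁻³ ° at 1.12 MHz, overridable per unit (thresholds in practice
   depend on medium and frequency).
3. **Edge margins**: the first and last `1/band_low` = 10 s of each
   contiguous segment are excluded from detection to avoid filter edge
   transients. Counting windows are laid out inside this valid span only, so
   the exclusion does not bias rates.
4. **Windowing**: half-open windows `[start, start+w)`; an event exactly on
   a boundary belongs to the later window; trailing partial windows are
   discarded. When a multiplexed segment's valid span is shorter than the
   nominal counting window (a 240 s recording window leaves a 220 s valid
   span), the whole span becomes a single counting window of its actual
   length; normalization always uses each window's own length, keeping the
   estimator unbiased.

The filter attenuates a 20 ms Gaussian bump to roughly 0.8 of its raw
amplitude (most of its energy is below 30 Hz but not all), which is why the
synthetic-run configs pair a 4×10⁻³ ° median injected amplitude with a
2×10⁻³ ° threshold — the low end of the 1.5 MHz operating range.

## Precision of the windowed Poisson rate estimate

For a unit sampled `k` times with windows of `w` seconds at true event rate
λ (events/s), the rate estimate (mean of per-window rates = total count /
total time for equal windows) has standard error

    SEM = sqrt(λ / (k·w))

Precision depends only on the total recording time `T = k·w`, not on its
partition — many short windows and few long ones are statistically
equivalent. Inverting gives the design rules implemented in
`padflux.precision`: `T = λ/SEM²` for a target absolute SEM, and for equal
*relative* precision ρ = SEM/λ across multiplexed units,
`T_i = 1/(λ_i·ρ²)` — slower-growing units need longer recording windows.
Equal relative precision is this package's formalization of that allocation
principle. Fractional cycle counts are floored, with a warning reporting the
achieved precision; analyzer switching overhead is a parameter (default 0).

## The synthetic device (what it emulates, what it does not)

`padflux.synthetic` generates:

- **Colony fill**: deterministic exponential `N(t) = min(N₀·e^{gt}, K)` by
  default (a stochastic Yule birth process is available). Only post-fill
  behaviour feeds the estimator, so the fill model mainly sets the fill
  time. Pre-filled pads (`N₀ = K`, the default) start events at t = 0.
- **Events**: post-fill Poisson process at `g·K` events/h, simulated by
  thinning against the maximum rate so media-driven rate changes are exact.
  Each event is budded with probability BI; coincident budded passage yields
  a single peak (amplitudes unchanged).
- **Media switches**: the per-cell rate follows the active condition as a
  step with a linear ramp over the 40 s switching transient. The true
  cellular response kinetics are unknown; the 40 s guard band used in
  condition segmentation discards the affected windows either way.
- **Traces**: slow sinusoidal baseline drift (default 5×10⁻³ °, 300 s
  period — far below the 0.1 Hz high-pass corner), white Gaussian noise
  (default 5×10⁻⁴ °), and one Gaussian bump per event: amplitude log-normal
  with median 4×10⁻³ ° and log-SD 0.15, FWHM Gaussian 20 ± 2 ms. The
  amplitude scale is anchored by the device's printed threshold ranges.
- **Multiplexing**: a round-robin schedule crops each unit's continuous
  trace into non-overlapping recorded segments (one shared analyzer).

Not emulated: the electrode-region field physics (peak shape vs cell size,
position and speed — the real signature may be bipolar; a unimodal bump plus
a minimum-separation rule is the simplest consistent model), flow dynamics,
cell clusters, signal differences between budded and single cells, electrode
drift between experiments, and microscopy imaging. Passing the synthetic
round-trip therefore demonstrates that the *analysis chain* is correct and
unbiased under the stated signal model; it does not validate the signal
model itself against hardware.

## Benchmark study designs (`padflux.scenarios`)

- `two_unit_same_strain`: one strain in two units with 2 and 3 filled pads
  (400 cells/pad), per-cell rate 0.288 /h, 6 h recording, 240 s round-robin
  windows. Checks that normalization cancels colony size.
- `calcium_switch_vph1`: one unit at 4 filled pads, rate 0.32 /h in rich
  medium for 6 h, 0.196 /h under 100 mM calcium for 10 h, then 0.32 /h again
  for 6 h; continuous recording, 240 s counting windows, 40 s switch guard
  band. Checks condition segmentation and per-condition recovery.

Simulated recordings in these designs use 250 Hz sampling — comfortably
above the 2×30 Hz band Nyquist, ~5 samples across a 20 ms FWHM — which keeps
a 22 h trace around 20 M samples; the library default elsewhere is 1 kHz.
With these sizes the calcium run recovers the calcium-condition mean to
within ~2% of truth with an SEM near 0.004 /h from ~148 windows, and the
two-unit run recovers 0.288 /h within 2 SEM (≈0.01 /h) for both units.

## Numerical and interface choices

- Times are seconds from experiment start (t = 0 at cell loading); `t_EIS`
  (recording onset) is carried as metadata, not applied as an offset. Rates
  are computed per second internally and reported per hour.
- Randomness: one integer seed per experiment; per-unit colony and trace
  streams are spawned from it via `numpy.random.SeedSequence`, so runs are
  bit-reproducible and units are statistically independent.
- All outputs are delimited text with headers (traces, events, window
  counts, metadata, summaries) plus JSON sidecars (ground truth, run log);
  every file is parseable by the package's own readers.
- Config validation is strict (pydantic, unknown keys rejected, errors carry
  field paths); defaults encode the device's operating point (band
  0.1–30 Hz, 240 s windows, BI 0.6, 40 s switch buffer).

## Known limitations

- Coincident distinct cells closer than `min_separation` merge into one
  peak: an undercount of order `λ·min_separation` (≈0.4% at 0.09 events/s),
  below one SEM in the benchmark designs.
- The budding correction treats BI as an externally supplied constant; the
  device cannot distinguish budded from single passages, so errors in BI
  propagate proportionally to absolute growth rates (not to normalized peak
  rates or relative changes).
- SEMs are reported over windows within a run; they do not capture
  between-replicate variability (e.g. ~8% inter-pad variability in real
  colony sizes).
- The Poisson model ignores clustering of passages and any flow-induced
  correlation; `allocate_windows` is static, not adaptive during a run.
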
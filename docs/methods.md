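# Methods and design notes

This note records the conventions, models and parameter choices behind
the package, the way the synthetic generators emulate real recordings,
and the limits of what passing tests demonstrate about real data.

## Sleep scoring

A minute is asleep iff it lies in a maximal run of consecutive
zero-count minutes of length ≥ 5 (`min_minutes`, configurable). The
scorer is deliberately literal about edge cases:

* Runs touching the recording's edges count as episodes when ≥ 5 min.
  No censoring is applied; a censoring variant can be had by masking
  the first/last minutes.
* Missing minutes (status-dropped or gap-filled rows) break inactivity
  runs and are never scored as sleep. The alternative — joining runs
  across gaps — would fabricate sleep from recording artifacts.
* Window attribution: sleep *minutes* are credited to the 12-hr window
  in which they occur, so sleep + wake (+ missing) minutes always equal
  the window length. An *episode* is counted once, with its full
  duration, in the window containing its first minute. An episode
  spanning lights-off therefore contributes its pre-boundary minutes to
  the light window's total, its post-boundary minutes to the dark
  window's total, and its bout statistics to the light window only.

ZT (Zeitgeber time) is half-open throughout: minute zt ∈ [0, 720) is
light, [720, 1440) dark; zt 0 is lights-on. This prevents any minute
from being double-counted at boundaries.

Activity while awake is total counts divided by waking minutes in the
window, and is reported as missing (NaN) — not zero — for a fully
asleep window. Day averages are arithmetic means over the selected
complete windows with missing values excluded metric-wise; the standard
assay averages the three complete recording days.

## DAM file handling

The default dialect is 10 tab-separated metadata fields (record index,
date `D Mon YY`, time `HH:MM:SS`, status, six device fields) followed
by 32 integer counts; status 1 marks a valid reading. Because DAMSystem
versions differ, the dialect is explicit configuration, never sniffed.
Rows with other status codes are dropped (or rejected, configurable);
timestamp gaps are an error by default, with an opt-in fill mode that
flags filled minutes as missing. Dead flies are excluded when their
trailing 24 h (configurable) contain zero counts — the standard
actigraphy criterion; the exclusion report lists every removed fly.
Experiments larger than one monitor use global channel numbers: channel
k lives on monitor (k−1)//32.

## Temperature-shift comparisons

The baseline window for a shift or recovery day is the single pre-shift
day of the same light/dark type, per fly (the protocol records one
baseline day; a multi-day baseline mean is available via
`baseline_day`/`paired_day_deltas`, which also supports alternating
baseline/target day pairings for multi-cycle designs). Per-fly deltas
are compared across genotypes with a two-sided Mann–Whitney test on the
delta lists; the error bar on a group difference is the quadrature
combination of the two group SEMs. The conservative-p rule reports
max(p vs GAL4 control, p vs UAS control). For constitutive (RNAi)
designs, the identical machinery runs on day-averaged raw metrics
instead of deltas.

## Rank statistics

Mann–Whitney U uses midranks for ties. With min(n, m) ≤ 8 and no ties
the two-sided p is exact, computed from the full null distribution of U
(dynamic-programming count of rank configurations; the two-sided p
doubles the lower tail of min(U, nm − U), capped at 1). Otherwise a
normal approximation with tie correction and a 0.5 continuity
correction is used. A pooled sample with all values identical returns
p = 1 by convention. Kruskal–Wallis uses the tie-corrected H against
chi-square with k − 1 df. With exactly two groups, H equals the square
of the MWU z-statistic without continuity correction, so the two tests
agree exactly in that regime and differ only by the continuity shift
otherwise. The imaging group comparison gates pairwise tests on
KW p < α (α = 0.05 by default, configurable) and reports the greatest
pairwise p.

## Trace analysis

ΔF/F uses the first frame as F₀ by default (so the series starts at
exactly 0); a pre-stimulus-mean F₀ is available and is the better
choice for noisy baselines. Response extraction takes the extremum of
the percent-change series over the whole recording by default — the
maximum for sensors that brighten with signal, the minimum for
Arclight — with an optional search window for recordings where
pre-stimulus artifacts matter. The extracted maximum of a noisy trace
carries a positive max-of-noise bias of order the noise SD; it is
shared across compared groups and therefore cancels in group contrasts.

For FRET pairs the default output is the CFP/YFP ratio normalized to
the first frame, as a percent change. Both Epac1-camps (cAMP) and
SuperClomeleon (chloride) lose FRET on ligand binding — donor CFP
rises, acceptor YFP falls — so this orientation reads positive for
rising signal. The raw YFP/CFP orientation is available, and the choice
is recorded in output metadata. No photobleach detrending is applied by
default (recordings are pre-exposed to stabilize baselines); both
generator and analysis expose bleaching options for sensitivity checks.

## PDM colocalization

Channel means are computed over the analysis mask on the *projected*
image (figures are made from projections), and
PDM(x) = (R(x) − mean R)(G(x) − mean G) per masked pixel. Consequences
used as invariants: the map is invariant to adding a constant to either
channel, equivariant under scaling a channel by k, and its masked mean
equals the population covariance of the channels. Background
subtraction is per-slice rolling-ball (default radius 50 px, recorded
in output metadata); both sum and max projections are supported and
logged. A channel that is constant over the mask yields an all-zero map
flagged degenerate. Rendering uses a diverging palette with symmetric
bounds ±max|PDM| so zero sits at the palette center; the palette is
cosmetic and untested.

## Synthetic data

**Sleep.** Each fly is a per-minute two-state (wake/sleep) Markov chain
with rates per (genotype, phase, light state): p_ws (wake→sleep), p_sw
(sleep→wake), and Poisson mean waking counts λ. Sleep minutes emit 0
counts; wake minutes emit Poisson(λ), so some wake minutes are
coincidentally inactive — exactly the ambiguity the 5-min rule faces on
real data. The default rates give ~520 min night sleep in ~15-min mean
bouts and ~200 min day sleep in ~10-min bouts, with λ = 2 counts/min.
Under these rates the within-fly window-to-window variability yields
baseline-subtracted delta SDs near 40 min, the repeatability regime the
paired-baseline design assumes. Effects ("−90 min night sleep on shift
days") are programmed by solving for the p_ws that shifts the chain's
stationary sleep fraction p_ws/(p_ws+p_sw) by the target amount with
p_sw fixed; the temperature-shift scenario adds a genotype-independent
heat response (default +40 min day, −30 min night) to all genotypes so
the double-differencing design is genuinely exercised. Ground truth
reports latent sleep, the 5-min rule applied to the latent states, and
the rule applied to the emitted counts, so estimator error, scoring
bias from Poisson zeros, and the rule's short-bout censoring can be
told apart. The chain has no circadian oscillator or sleep homeostat,
and no persistent between-fly individuality: passing recovery tests
shows the estimator is unbiased and calibrated for Markovian sleep of
realistic architecture, not that real effects of that size are always
detectable.

**Traces.** F_c(t) = B_c · bleach_c(t) · (1 + s_c (A/100) k(t)) + ε,
with k a double-exponential kernel (rise 5 s, decay 20 s) starting at
stimulus onset (default 30 s into a 2-min, 2-Hz recording) and
normalized so its *sampled* peak is exactly 1 — a noiseless trace
recovers the programmed amplitude A exactly. FRET pairs carry +A on CFP
and −A on YFP, giving a closed-form normalized-ratio peak of
100·((1+a)/(1−a) − 1), a = A/100. No motion, focus drift, or
wavelength-dependent bleaching is modelled.

**Images.** Two channels share Gaussian blobs (colocalized structure)
plus channel-private blobs, a linear background gradient, and per-slice
Gaussian noise, split evenly across z so a sum projection recovers the
noise-free fields. The truth labels each pixel shared / private-R /
private-G / background. Real confocal optics (PSF anisotropy, depth
attenuation, Poisson photon noise) are not modelled.

All generators are deterministic given a seed.

## Numerical choices and degenerate inputs

* Exact-MWU threshold min(n, m) ≤ 8: full enumeration stays trivial
  while covering the group sizes these assays use.
* Windows shorter than 720 min are flagged partial and excluded from
  day averages by default.
* Empty groups, missing controls, zero denominators, non-monotone
  timestamps and malformed rows raise errors naming the offending
  entity; nothing is silently repaired.
* Pipeline outputs are byte-deterministic for a fixed config and
  inputs; run logs record the package version and a config hash (the
  hash excludes the output directory so identical analyses hash
  identically).

## Problem sizes

The validation suite uses cohorts of 3 genotypes × 16 flies over 2
days (200 replicates for effect recovery), exhaustive checks over all
2^16 binary activity vectors plus 10^4 random days for the scorer,
2000 null replicates for test calibration, and 100×100-pixel image
checks — sizes at which every check is exact or tightly powered while
the whole suite runs in about a minute.
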
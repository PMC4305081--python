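# flysleeplab

Analysis toolkit for *Drosophila* sleep-circuit experiments: sleep
scoring from DAM beam-break actigraphy, temperature-shift sleep-change
analysis against dual genetic controls, ROI fluorescence trace analysis
(ΔF/F and ratiometric FRET), and per-pixel intensity-correlation (PDM)
colocalization — plus synthetic-data generators with known ground truth
so the whole stack is testable without any recordings.

It is aimed at fly behavioral neuroscientists who run thermogenetic
(dTrpA1 / Shibire^ts / Kir2.1) sleep experiments on Trikinetics DAM
monitors and functional-imaging experiments on genetically encoded
sensors, and want a scripted, reproducible replacement for spreadsheet
or ad-hoc analyses.

## What it computes

**Sleep scoring.** DAM monitors record beam-break counts in 1-min bins,
32 flies per monitor. Sleep is scored by the field-standard rule: a
minute is asleep iff it lies in a maximal run of ≥ 5 consecutive
zero-count minutes. Per 12-hr light (ZT0–12) and dark (ZT12–24) window
the package reports total sleep, number of sleep episodes, mean and
maximum episode duration, and activity while awake (counts per waking
minute), averaged across days; 30-min binned profiles are produced for
plotting.

**Temperature-shift analysis.** Heat itself changes fly sleep, so
thermogenetic effects are doubly differenced. For each fly,

    Δ_fly = sleep(31 °C window) − sleep(baseline window, same L/D type)

and the reported effect vs each single-transgene control is

    minutes gained/lost = mean(Δ_experimental) − mean(Δ_control),

with SEMs combined in quadrature and a two-sided Mann–Whitney U test on
the per-fly deltas. Two p values result (vs GAL4 control, vs UAS
control); only the most conservative (numerically greatest) is
reported.

**Rank statistics.** Mann–Whitney U (exact null distribution for small
tie-free samples, tie- and continuity-corrected normal approximation
otherwise) and tie-corrected Kruskal–Wallis are implemented from first
principles so small-sample behavior is exactly specified; results carry
the method used.

**Trace analysis.** Intensity sensors: ΔF/F = (Fₙ − F₀)/F₀ × 100% with
F₀ the first frame; the per-trace response is the series maximum, or
minimum for Arclight (voltage raises quench its fluorescence).
FRET sensors (Epac1-camps, SuperClomeleon): the per-frame CFP/YFP ratio
normalized to the first frame, in percent, which reads positive when
the sensed signal rises. Group comparisons use a Kruskal–Wallis gate
followed (only when significant) by pairwise Mann–Whitney tests against
each negative control, reporting the most conservative pairwise p.

**Colocalization.** Two-channel confocal stacks are background-
subtracted (rolling ball), Z-projected (sum or max), and converted to a
per-pixel Product-of-the-Differences-from-the-Mean map,

    PDM = (R − mean R) · (G − mean G),

whose positive values mark correlated (colocalized) staining and
negative values anticorrelated staining; the mean PDM over the mask
equals the channel covariance.

## Worked example

Simulate a three-genotype temperature-shift experiment (8 flies per
genotype, one baseline day, one 31 °C day, a programmed −90 min night
effect in the experimental genotype) and analyze it:

```bash
flysleeplab simulate dam --out-dir sim --seed 7 --n-flies 8 --night-effect -90
# write a config pointing at sim/monitor_1.txt with the design from sim/truth.json
flysleeplab tempshift config.yaml
cat out/sleep_change.csv
```

```
target_day,phase,light,control,minutes_gained,sem,n_exp,n_ctrl,U,p,conservative_p
1,shift,D,gal4_control,-74.25,31.2201,8,8,11,0.0281274,0.0281274
1,shift,D,uas_control,-80.125,28.74,8,8,8.5,0.0156378,0.0281274
1,shift,L,gal4_control,-27.75,30.8601,8,8,22.5,0.344207,0.95913
1,shift,L,uas_control,-4.5,30.5731,8,8,33,0.95913,0.95913
```

The experimental genotype lost ~74–80 min of night sleep relative to
each control (programmed truth −90 min, well within 2 combined SEMs),
with a conservative p of 0.028 for the dark window; the light window,
where no effect was programmed, is far from significance (conservative
p 0.96). The same machinery is available as a library
(`flysleeplab.sleep_compare.compare_to_controls` etc.); see
`docs/methods.md` for conventions and parameter choices.

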
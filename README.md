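# flockai

Frame-differencing **activity index (AI)** analysis for top-view poultry
video, built for precision-livestock-farming work on broiler movement. The
package answers a practical question: when you quantify flock movement by
differencing consecutive frames, how much accuracy do you lose by sampling
frames less often — every 0.2 s, 1 s, 10 s, 60 s or 300 s instead of the
camera's full 25 fps (0.04 s) stream?

It is aimed at researchers and engineers who monitor animal activity with
ceiling-mounted cameras and need a tested, reproducible implementation of
the AI pipeline plus a synthetic flock simulator to validate it against
exact ground truth.

## The statistic

For frames `I(x, y, t)` the binary motion mask is

    I_a(x, y, t) = 1   if |I(x, y, t) − I(x, y, t−1)| > τ      (absolute mode)
                   1   if  I(x, y, t) − I(x, y, t−1)  > τ      (onesided mode)
                   0   otherwise

with τ calibrated per clip as 15% of the maximal intensity over the first
20 empty-background frames. The activity index of a frame pair normalises
the changed-pixel count by the bird-representative pixels of the earlier
frame:

    AI(t) = Σ_xy I_a(x, y, t) / S(t−1)

`S` comes from background-reference segmentation (deviation from the median
empty-background frame above τ, small components removed). Per-pair AIs are
summed into 300-s **cumulative windows** — the unit of analysis — and each
sampling interval's cumulative AI is expressed as a percentage of the same
window's value at the 0.04-s baseline.

## Worked example

Simulate a continuously moving flock (five birds, 0.08 m/s walking speed,
half the time resting) in the standard 200 × 200 px / 0.71 × 0.71 m region
of interest and sweep the study's six sampling intervals:

```python
import flockai

cfg = flockai.FlockSimConfig(duration=300.0, transient_rate=0.0, seed=7)
table = flockai.interval_sweep_experiment(cfg, replicates=3)
for c in table:
    print(f"{c.interval:7g} s  cumulative AI {c.mean_cumulative_ai:7.1f}"
          f"   ratio {c.ratio_pct:5.1f} %")
```

```
   0.04 s  cumulative AI   295.8   ratio 100.0 %
    0.2 s  cumulative AI   287.1   ratio  97.1 %
      1 s  cumulative AI   236.8   ratio  80.1 %
     10 s  cumulative AI    51.1   ratio  17.3 %
     60 s  cumulative AI     9.4   ratio   3.2 %
    300 s  cumulative AI     1.9   ratio   0.6 %
```

Reading: the full-frame baseline captures the most motion by definition
(ratio 100%). Sampling at 0.2 s loses ~3% of the measured activity while
cutting the frame workload by 80%; at 300 s the index collapses to under
1% of baseline because every movement shorter than the gap between frames
is invisible to the difference image.

The same pipeline runs from the shell:

```bash
flockai simulate --duration 60 --n-birds 5 --seed 1 --out run/sim
flockai analyze --frames run/sim/frames --fps 25 --window 60 \
        --interval 0.04 --interval 0.2 --interval 1 --out run/analysis
flockai sweep --replicates 5 --transient-rate 0 --seed 1 --out sweep.csv
flockai summarize --windows run/analysis/windows.csv --key interval
```

## Layout

- `src/flockai/imaging_io.py` — frame loading/writing, cropping, grayscale
- `src/flockai/activity.py` — τ calibration, motion masks, segmentation, AI
- `src/flockai/sampling.py` — interval subsampling, cumulative windows, ratios
- `src/flockai/simulate.py` — synthetic flock generator with exact ground truth
- `src/flockai/pipeline.py` — end-to-end clip analysis
- `src/flockai/cli.py` — `flockai` command (simulate / analyze / sweep / summarize)
- `docs/methods.md` — model, assumptions, parameter choices, limitations
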
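# flycourt

Analysis pipeline for light-induced male–male courtship in *Drosophila*
group arenas: multi-fly video tracking, proximity interactograms,
chase/chain event detection, interval-based behaviour scoring across an
illuminance protocol, locomotor kinematics, and courtship-song
segmentation — plus an agent-based arena simulator that generates
trajectories, rendered video frames, song audio and a ground-truth event
log, so the whole pipeline is testable without any recordings.

## The experiment it models

Eight male flies walk in a 26-mm circular arena (ROI), filmed at
15 frames/s through a low → high → low light schedule (2 min at 0.4 klx,
2 min at 18 klx, 2 min at 0.4 klx).  Intense light elicits male–male
courtship: chasing, unilateral wing extension with pulse/sine song, and
*chaining* — a mobile single-file line of ≥ 4 flies, each courting the fly
ahead.  Per successive 10-s interval, each behaviour is marked present (1)
or absent (0); the per-epoch sum is the **total score**, 0–12 for a 2-min
epoch.  Pairwise proximity of identified flies (centroid distance
< 3.75 mm) is displayed as an **interactogram**: one colour band per fly,
darker segments marking intervals with another identified fly in range.

The quantitative backbone:

* interactogram: `I[a, b, t] = 1{ ‖x_a(t) − x_b(t)‖ < 3.75 mm }`
* chase: sustained (≥ 1 s) directed pursuit — proximity, both flies
  moving ≥ 2 mm/s, chaser heading within 60° of the bearing to its
  target, target nearest-in-cone
* chain: a simple directed path of ≥ 4 flies in the pursuit graph,
  mobile and ≥ 1 s
* scoring: bin mark = 1 iff any event overlaps the 10-s bin; epoch total
  ∈ [0, 12]; paired t-tests (low vs high) or one-way ANOVA with
  Bonferroni post hoc across epochs, the ROI being the replicate
* song: band-pass + envelope segmentation into pulse bouts
  (inter-pulse-interval statistics) and sine segments
  (frequency/duration); spectra normalized as E(λ)/E(peak)

See `docs/methods.md` for the model and every default.

## Worked example

Simulate four arenas under a shortened low/high/low protocol (60 s per
epoch), detect events, score intervals, and compare epochs:

```python
import flycourt as fc
from flycourt import pipeline

params = fc.SimParams(
    seed=7,
    epoch_schedule=[("low", 60, 0.4), ("high", 60, 18.0), ("low", 60, 0.4)],
)
results, comparison = pipeline.run_experiment(params, n_rois=4)
print(comparison.text())
```

```
Epoch comparison (paired, n = 4 ROIs)

behaviour epoch  mean      sem  n
    chase  low1  2.25 0.853913  4
    chase  high  6.00 0.000000  4
    chase  low2  1.50 0.500000  4
    chain  low1  0.25 0.250000  4
    chain  high  4.00 0.912871  4
    chain  low2  0.75 0.250000  4

behaviour     test   comparison  statistic        p significance
    chase paired t low1 vs high   4.391550 0.021875            *
    chase paired t high vs low2  -9.000000 0.002896           **
    chain paired t low1 vs high   4.391550 0.021875            *
    chain paired t high vs low2  -4.333333 0.022669           *
```

With 60-s epochs the ceiling is 6 intervals, and the high-light epoch
saturates chasing in every arena (mean 6.00 ± 0) while the flanking
low-light epochs stay near baseline; chaining shows the same
light-locked rise.  The paired t-tests confirm the increase under high
light and the recovery afterwards.  Passing
`through_video=True` reroutes the same computation through rendered
frames and the tracker instead of using the simulator's trajectories
directly.

The command line mirrors the library:

```bash
flycourt simulate --seed 7 --out out/sim
flycourt social --traj out/sim/trajectories.csv --out out/social
flycourt run-all --seed 7 --n-rois 4 --duration 60 --out out/run
```

Every output directory carries a provenance manifest (config echo and
hash, seed, versions); identical configurations reproduce identical
outputs.

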
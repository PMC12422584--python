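# capsakinesis

Quantitative toolkit for studying **chemokinesis-driven predation**: how a
unicellular predator that attaches irreversibly to its prey benefits from
simply *speeding up* near prey-derived chemicals, without any directional
bias. The model system is *Capsaspora owczarzaki* — a filopodiated
protist and symbiont of the snail *Biomphalaria glabrata* — preying on
schistosome sporocysts, with serum albumin (BSA) as the model
chemokinesis inducer.

The package is aimed at people analysing cell-tracking experiments
(time-lapse microscopy or plate-reader tracking) and at modellers who
want a tested, reproducible implementation of the accompanying
individual-based simulation.

## What's inside

| Module | Purpose |
|---|---|
| `capsakinesis.synth` | Synthetic persistent-random-walk tracks (with tracking artifacts), Hill-shaped dose-response readings, and calcium-indicator traces — all with known ground truth |
| `capsakinesis.analysis` | The track-filtering and motility statistics: step/gap/length filters, 70–240 µm annulus selection, chemotaxis net movement, 70–90 µm chemokinesis window, plate-reader mean velocity, distant-cell selection, calcium-trace normalisation |
| `capsakinesis.dose_response` | Hill-curve fitting (`v(c) = v0 + (vmax−v0)·c^h/(EC50^h+c^h)`), the speed law for the simulator, and the serum-albumin EC50 arithmetic |
| `capsakinesis.field` | 2-D (and radial) finite-difference diffusion of the prey's chemo-effector, with attachment-coupled sources and depleted-prey burst profiles |
| `capsakinesis.sim` | Agent-based Monte-Carlo simulation: 2000 persistent-walker predators hunting a stationary prey disk, with/without chemokinesis; attachment fractions, residence-time distributions, cumulative residence time |
| `capsakinesis.io` / `capsakinesis.cli` | Track CSV dialect, YAML configs with canonical hashing, run manifests, and the `capsakinesis` command line |

The core model: cells perform a persistent random walk (truncated-normal
turns, exponential step lengths). The prey exudes a chemical with
albumin-like diffusivity (60 µm²/s); a cell's speed at local
concentration *c* is the fitted dose-response `v(c)` (defaults: v0 = 1,
vmax = 3 µm/min, EC50 = 1 mg/ml). Cells crossing the prey boundary attach
irreversibly; the headline statistic is the **cumulative residence time**
(total cell-seconds attached over a 120-minute run), compared between
chemokinesis-enabled and -disabled conditions.

## Worked example

```python
import dataclasses
from capsakinesis import SimConfig, run_simulation, compare_conditions

cfg_on = SimConfig(seeds=(4, 5, 6))           # 2000 cells, 120 min, n=3
cfg_off = dataclasses.replace(cfg_on, chemokinesis=False)
comp = compare_conditions(run_simulation(cfg_on), run_simulation(cfg_off))
print(comp)
print("attachment on: ", comp.attachment_fraction_on)
print("attachment off:", comp.attachment_fraction_off)
print("earlier-attachment p:", round(comp.earlier_attachment_p, 5))
```

prints

```
cumulative residence on/off = 1.254 (on 4879066±51628 s, off 3889961±10906 s)
attachment on:  [0.604  0.5915 0.6105]
attachment off: [0.5065 0.499  0.4875]
earlier-attachment p: 0.00344
```

Read: with chemokinesis the population accumulates ~1.25× more total
attached time on the prey; more cells attach in every replicate (≈ 60% vs
≈ 50%), and the cells that do attach, attach significantly earlier
(one-sided rank test) — speed alone, with zero directional information,
is a real predation advantage for an irreversible attacher.

The same comparison from the shell, plus the filtering pipeline on
synthetic tracks:

```bash
capsakinesis simulate compare --seeds 4,5,6 --out out/compare
capsakinesis synth tracks --out out/synth
capsakinesis analyze kinesis --tracks out/synth/tracks.csv \
    --policy schistosome --ref 400 400 --out out/kinesis
```

Every output directory contains a `manifest.json` (command, canonical
config hash, seeds, package version) from which the artifact can be
regenerated.

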
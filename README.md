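# igradient

A toolkit for computing the **intensity gradient (IG)** — a cutpoint-free
summary of the physical-activity intensity distribution — from **count-based
accelerometry**, together with the full processing and validation chain
needed to compare an older count-only monitor (GT1M-style) with a modern
raw-acceleration monitor (GT9X-style): ENMO epoch summarisation, Evenson
cutpoint classification, inter-device lag alignment, three IG bin schemes,
and repeated-measures agreement statistics. A built-in synthetic
paired-device generator with known ground truth makes every stage testable
without any proprietary data.

It is aimed at physical-activity and epidemiology researchers who hold
historical epoch-count datasets (e.g. hip-worn uniaxial ActiGraph files)
and want to apply intensity-distribution metrics originally developed for
raw wrist acceleration.

## The metric

For a participant's wear-time epochs, accumulate the time spent in
equal-width intensity bins and fit by ordinary least squares

```
ln t_j = alpha + beta * ln m_j
```

where `t_j` is the minutes accumulated in bin `j` and `m_j` the bin's
midpoint intensity. The slope `beta` is the intensity gradient: always
negative in practice (less time at higher intensities), with steeper
(more negative) values indicating activity concentrated at low intensity.
Empty bins are excluded (`ln 0` is undefined). Three bin schemes are
provided:

| scheme           | data          | closed bins | width      | terminal bin |
|------------------|---------------|-------------|------------|--------------|
| `acc`            | ENMO (mg)     | 160         | 25 mg      | ≥ 4000 mg    |
| `count_fine`     | counts / 15 s | 160         | 25 counts  | ≥ 4000       |
| `count_adjusted` | counts / 15 s | 40          | 100 counts | ≥ 4000       |

Counts span a wider numeric range than ENMO, so under the fine scheme they
occupy several times more bins; this dilutes the influence of the sedentary
bin and makes the fine-binned count IG systematically shallower than the
acceleration IG. Coarsening to 100 counts per bin (`count_adjusted`)
restores comparable bin occupancy, and with it, agreement with the
ENMO-based IG. The `bin_occupancy_ratio` and `first_bin_composition`
diagnostics quantify both effects.

## Worked example

Simulate a small cohort of paired-device free-living days and compute all
three IG variants per participant (the acceleration IG runs through raw
30 Hz signal synthesis and ENMO epoch averaging):

```python
import numpy as np
from igradient import *
from igradient.simulate import SimConfig, simulate_day, simulate_raw_from_counts
from igradient.enmo import EnmoParams, enmo_epochs
from igradient.core import EpochSeries

cfg = SimConfig(seed=42, n_participants=4, days_per_participant=3)
fine, adj, acc = (make_bin_scheme(v) for v in
                  ("count_fine", "count_adjusted", "acc"))

print(f"{'participant':>11} {'countIG':>8} {'adjIG':>8} {'accIG':>8} {'occ.ratio':>9}")
for p in range(cfg.n_participants):
    pf, pa, pc = [], [], []
    for day in range(cfg.days_per_participant):
        d = simulate_day(cfg, p, day)
        counts = d.series_b
        pf.append(bin_time(counts, fine))
        pa.append(bin_time(counts, adj))
        wear_only = EpochSeries(d.participant_id, "B", counts.start_time,
                                counts.values[counts.wear], 15.0, units="counts")
        raw = simulate_raw_from_counts(wear_only, cfg)
        pc.append(bin_time(enmo_epochs(raw, EnmoParams()), acc))
    bf, ba, bc = merge_binned(pf), merge_binned(pa), merge_binned(pc)
    print(f"{d.participant_id:>11} {compute_ig(bf).slope:8.3f} {compute_ig(ba).slope:8.3f} "
          f"{compute_ig(bc).slope:8.3f} {bin_occupancy_ratio(bf, bc):9.2f}")
```

Output:

```
participant  countIG    adjIG    accIG occ.ratio
        P00   -1.629   -1.986   -1.984      2.52
        P01   -1.598   -1.963   -1.893      2.76
        P02   -1.625   -1.975   -1.961      2.62
        P03   -1.578   -1.890   -1.900      2.50
```

The fine-binned count IG is consistently shallower than the acceleration
IG, counts occupy ~2.5× more bins than ENMO, and the coarsened 40-bin
count IG tracks the acceleration IG closely — the pattern the adjusted
scheme exists to produce.

## Command line

```sh
igradient simulate --config cfg.yml --out data/     # synthetic cohort
igradient compare-devices --in data/ --out tables/  # lag + counts + min/day agreement
igradient compute-ig --in data/ --out tables/       # per-participant IGs + agreement
igradient fixtures --out fx/                        # small standard test dataset
```

All tables are delimited text with a version/config-hash comment header.

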
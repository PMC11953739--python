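# quadassay

Simulation and analysis of quadrant-count chemotaxis assays for freely
moving *C. elegans* populations.

Worms released at the center of a rectangular four-quadrant arena either
disperse (no odorant) or migrate along an odorant gradient. From the four
quadrant counts `(q1 .. q4)` — canonicalized so `q1` is the vehicle end and
`q4` the odorant end — the package computes:

- **dispersal**: base-2 Shannon entropy of quadrant proportions
  (2 bits = uniform spread, ~1 = central accumulation, ~0 = one quadrant);
- **response ratio**: `(q1 + q4) / n`, commitment to either extreme end;
- **chemotaxis index**: `(q4 - q1) / (q4 + q1)`, +1 attraction / -1 aversion;
- replicate statistics: medians, t-distribution 95% CIs, unpaired t-tests,
  and Cohen's *d* with equal-weight variance averaging.

A decision chart gates interpretation (every plate needs >100 worms and
the paired no-odorant controls must disperse uniformly), then an
eight-row high/low rubric over the three metrics yields a behavioral
verdict, sign-resolved into attraction or aversion. An
orientation-consistency check compares canonical indices between the two
opposing arena orientations to expose uncontrolled lab-frame gradients.

Because no laboratory input is required, an agent-based simulator
(`quadassay.synthetic_worms`) generates arena counts with the assumed
statistical structure: persistent random walkers with weathervane-style
gradient steering, reflective walls, and behavior modes (`normal`,
`locomotion_defect`, `origin_attraction`, `unknown_gradient`,
`chemotaxis`) that reproduce the dispersal regimes above.

## CLI

```bash
# simulate a paired experiment (both orientations + dispersal controls)
quadassay simulate --config sim.yml --out counts.csv --seed 7

# analyze a counts CSV: metrics table, JSON report, violations, optional plot
quadassay analyze --counts counts.csv --thresholds thresholds.txt \
    --out-prefix results/run1 --plot results/run1.png

# render a stored report
quadassay report --analysis results/run1_report.json --format text
```

`analyze` exits 0 when every odorant reaches a verdict, 3 when the data are
valid but not interpretable, and 2 on schema errors.

Simulation configs and threshold files are plain `key: value` text, e.g.

```yaml
mode: chemotaxis
bias: 0.7              # [-1, 1]; sign = attraction/aversion
n_worms: 150
n_arenas_per_orientation: 4
seed: 7
```

```yaml
dispersal_high_min: 1.8
response_ratio_high_min: 0.4
ci_high_min_abs: 0.5
min_worms: 101
```

The counts CSV schema is
`plate_id,assay_type,orientation,odorant,vehicle,cohort,c_left,c_midleft,c_midright,c_right`
with counts listed left-to-right in the lab frame; orientation `B` arenas
(odorant end on the left) are reversed during canonicalization.

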
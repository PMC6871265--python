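# paleobracket

Tools for bracketing lineage divergence times with fossil occurrence data:

- **Minimum constraints** from apomorphy-documented first appearances, with
  explicit dating envelopes.
- **Soft maximum constraints** ("how much older could the origin be?") via
  stratigraphic confidence intervals — extant basis `T_C = FAD·(1−C)^(−1/n)`,
  range basis `T_C = R·[(1−C)^(−1/(n−1)) − 1] + FAD` — plus axis-transformed
  (e.g. rock-thickness) and nonuniform-recovery generalizations.
- A **lognormal calibration prior** on the FAD-to-origin gap, parameterized so
  its mode is the average gap size `FAD/n` and its 95% quantile the
  extant-basis confidence bound.
- **Taphonomic-control** and successive-outgroup soft maxima.
- **Super-taxon projection**: combine multiple FADs through the relative
  branch depths of an uncalibrated ultrametric tree to bracket a clade's
  root age, with leave-one-out flagging of inconsistent calibration fossils.
- A **birth–death clade simulator** with fossil sampling, for
  missing-history experiments, Monte-Carlo coverage validation of the CI
  formulas, and demonstrating the declining-recovery failure mode.
- **Bracket assembly**: compose minima, soft-max candidates, coalescence and
  apomorphy-lag adjustments, and record-quality metrics into per-node
  brackets.

## CLI

Every subcommand prints machine-readable JSON on stdout and logs to stderr.

```sh
# stratigraphic confidence interval (occurrence table -> soft max)
paleobracket ci --record occurrences.csv --lineage hominin \
    --confidence 0.95 --basis range --endpoint older

# lognormal gap priors as a calibration table
paleobracket prior --record occurrences.csv --out priors.tsv

# super-taxon bracket from a tree and per-lineage FADs
paleobracket supertaxon --tree tree.nwk --fads fads.csv --confidence 0.95

# clade simulation emitting a standard occurrence table
paleobracket simulate --config sim.yaml --out occurrences.csv

# Monte-Carlo coverage check of the CI formulas
paleobracket coverage --n 5 --confidence 0.95 --reps 10000 --seed 1

# full node bracket (minimum + all soft-max candidates)
paleobracket bracket --record occurrences.csv --controls controls.csv \
    --config bracket.yaml --out brackets.json

# fossil-record quality metric
paleobracket qmetric --total 5500 --fossil 55 --turnover 26
```

Occurrence tables are CSV/TSV with named columns `taxon_id, lineage_id,
locality_id, horizon_id, age_older_ma, age_younger_ma, region,
axis_position, apomorphy, voucher` (the first three plus the two age
columns are required). Ages are Ma before present. Recovery curves are CSV
with `age_older_ma, age_younger_ma, relative_rate`.

## Layout

| module | contents |
| --- | --- |
| `paleobracket.core` | domain types: age intervals, occurrences, lineage records, recovery curves, ultrametric topologies |
| `paleobracket.io` | occurrence-table / recovery-curve / newick readers and writers |
| `paleobracket.ci` | confidence-interval estimators (extant, range, transformed-axis, nonuniform-recovery) and origin point estimates |
| `paleobracket.priors` | lognormal gap-prior fitting, quantiles, calibration-table export |
| `paleobracket.supertaxon` | FAD projection, root-age bracketing, outlier flagging |
| `paleobracket.simulate` | budding birth–death simulator, missing-history experiment, coverage experiments |
| `paleobracket.bracket` | minimum constraints, taphonomic/outgroup maxima, adjustments, bracket assembly |
| `paleobracket.cli` | `paleobracket` command-line interface |
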
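# addhrvr

Detect prolonged **additional (non-metabolic) heart rate variability
reductions** in ambulatory recordings.

Heart rate variability (RMSSD) drops both with physical activity and with
psychological stress. This package separates the two with a short,
person-specific calibration: during a scripted session (rest, standing,
lying, cycling, stairs) it fits an inverse model

```
expected_rmssd = b0 + b1 / acceleration
```

on 30-s epochs, then scans a subsequent ambulatory day for epochs whose
measured RMSSD falls more than `k` standard errors (default `k = 2`, SE of
the mean calibration RMSSD) below the movement-predicted level. Maximal
runs of at least `min_run` consecutive flagged epochs (default 15 epochs =
7.5 min) form episodes; hours containing at least one episode are coded 1.
Hourly codes can then be related to hourly self-reports (worry/stress
counts, affect ratings) via within/between-person decomposition and
person-level correlations.

## Layout

| module                | contents                                                        |
| --------------------- | --------------------------------------------------------------- |
| `addhrvr.io`          | CSV readers/writers and domain types (IBI, epoch, phase, report, model files) |
| `addhrvr.epoching`    | artifact cleaning, RMSSD, acceleration magnitude, epoch aggregation |
| `addhrvr.calibration` | inverse-model fit, SE, resting RMSSD, fit-quality exclusion gates |
| `addhrvr.detection`   | expected RMSSD, threshold, epoch flags, run-length episodes, hour coding |
| `addhrvr.association` | within/between decomposition, person summaries, Pearson correlation |
| `addhrvr.simulate`    | seeded synthetic calibration sessions, days with planted suppressions, coupled reports |
| `addhrvr.cli`         | `addhrvr` command-line interface                                |
| `addhrvr.config`      | YAML run configuration (detector, artifact, simulation parameters) |

## CLI

```bash
# generate a fully synthetic dataset (deterministic in --seed)
addhrvr simulate --out data/ --seed 1

# raw streams -> 30-s epochs
addhrvr epoch --ibi ibi.csv --accel accel.csv --out epochs.csv --person p001

# calibration epochs + phase annotation -> person model file
addhrvr calibrate --epochs calib_epochs.csv --phases calib_phases.csv \
    --out models.csv --person p001

# apply the model to an ambulatory day
addhrvr detect --model models.csv --epochs day_epochs.csv --person p001 \
    --episodes-out episodes.csv --hourly-out hourly.csv

# hourly codes + self-reports -> analysis tables and cohort rates
addhrvr analyze --hourly hourly.csv --reports reports.csv \
    --out-long analysis_long.csv --out-summary person_summary.csv

# everything end to end on synthetic data
addhrvr run-all --out run/ --seed 1
```

All commands accept `--config config.yaml` (sections `detector`,
`artifacts`, `sim`, plus `seed` and `log_level`; unknown keys are
rejected). Model exclusion statuses (`excluded_low_r2`,
`excluded_nonsignificant`, `excluded_no_inverse_fit`,
`excluded_insufficient_data`) are ordinary outputs recorded in the model
file, not process failures.

Note on the threshold convention: an epoch is flagged when
`rmssd < expected_rmssd - k * se` (strictly below the *expected* level by
`k` standard errors); ties are not flagged.

## File formats

Plain CSV with one header row; missing values are empty fields (never
zero); times are seconds from recording start. See `addhrvr/io.py` for the
exact schemas.

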
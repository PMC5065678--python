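# alarmaudit

Alarm-safety analytics for physiologic-monitor **audit logs** — the
chronological record of every alarm and clinician–monitor interaction
kept by a central monitoring station (e.g. Philips IntelliVue / PIIC iX
Information Center).

## Why audit logs?

Hospital alarm research usually relies on bedside observation or
vendor "alarm report" summaries. Both miss most of what actually
happened: observation samples a few hours, and summary reports drop
the per-event detail. The central station's *audit log* records every
alarm generation and end, every limit change, every silence/pause, for
every monitored bed — a complete, timestamped account of alarm burden
and alarm-management practice. But it is exported as a flat spreadsheet
of free-text messages, so it first has to be parsed, and its
alarm-start/alarm-end rows have to be re-joined into episodes before
any epidemiology can be done on it.

`alarmaudit` implements that pipeline end to end:

- **`alarmaudit.io`** — read vendor TSV/CSV/XLSX exports into typed
  records; write a canonical, byte-stable CSV.
- **`alarmaudit.grammar`** — a total parser for the message dialect:
  numerical alarms (`**PAPd 18 >16 Generated.`), categorical alarms,
  technical (INOP) alarms, sound events, and a 21-kind taxonomy of
  clinician actions including alarm-limit changes. Priority is carried
  by the marks: `*`/`**`/`***` for physiologic (advisory/yellow/red),
  `!`-marks for technical; soft INOPs have no mark and make no sound.
- **`alarmaudit.episodes`** — pair `Generated`/`Ended` rows into alarm
  episodes with durations, handling nested same-key alarms (LIFO),
  sub-second inversions (end row logged before its generation row),
  and left/right censoring at the observation window; with a
  conservation check that every alarm row is accounted for.
- **`alarmaudit.metrics`** — alarm counts and rates per parameter /
  priority / bed per bed-day (or patient-day/hour/minute), action
  summaries, and pre/post period comparison for interventions.
- **`alarmaudit.audits`** — safety audits: unsafe programmed limits
  (e.g. a Desat lower limit of 50%), inconsistent alarm priorities for
  the same condition, unit-level compliance (alarms that should be
  disabled), and retrieval planning under the export tool's 50-day
  window and 90-day retention limits.
- **`alarmaudit.chain`** — a simulator of the monitor's announcement
  algorithm: priority chains (PVC / beat detection / rate), the
  10-alarm display cap, latching red alarms, silence and pause
  semantics. It answers "which of the logged alarms did staff actually
  hear?"
- **`alarmaudit.synth`** — a seeded synthetic log generator with exact
  ground truth (episodes, rates, planted anomalies, connectivity
  gaps), used for validation and examples.
- **`alarmaudit.cli`** — the `alarmaudit` command-line tool wrapping
  all of the above.

## Worked example

The package bundles three miniature exhibits in the vendor's export
dialect (`alarmaudit.samples`). Write them to disk and run the
pipeline (output below is the tool's real output):

```python
from alarmaudit.samples import SAMPLE_UNIT_LOG, SAMPLE_DESAT_LIMITS, SAMPLE_HR_PRIORITY_PAIR
open("unit.tsv", "w").write(SAMPLE_UNIT_LOG)
open("desat.tsv", "w").write(SAMPLE_DESAT_LIMITS)
open("hr_pair.tsv", "w").write(SAMPLE_HR_PRIORITY_PAIR)
```

Alarm rates by priority over one minute of a 20-bed unit log:

```text
$ alarmaudit rates unit.tsv --group priority
denominator: 9 bed-days
total alarm events: 6
  priority=INOP: count=1 rate=0.1111 per bed-day
  priority=advisory: count=1 rate=0.1111 per bed-day
  priority=red: count=1 rate=0.1111 per bed-day
  priority=yellow: count=3 rate=0.3333 per bed-day
```

Episode pairing (note the 11 alarm rows collapse to 7 episodes — one
is the sub-second PAPd alarm whose end row precedes its generation
row):

```text
$ alarmaudit episodes unit.tsv -o episodes.csv
11 alarm events -> 7 episodes (conservation OK)
```

Unsafe-limit scan over six desaturation alarms whose programmed lower
limits range from 90% down to 50%:

```text
$ alarmaudit audit desat.tsv --limits
observed limit settings:
  Desat lower limit: min 50 max 90
```

Priority-consistency audit on the same heart-rate crossing announced
at two different priorities on two monitors:

```text
$ alarmaudit audit hr_pair.tsv --priority
INCONSISTENT: HR announced at priority levels [1, 2] for the same condition (trigger values 153) (rows [0, 1])
```

Retrieval planning for a 90-day study under the 50-day export window:

```text
$ alarmaudit plan --days 90
2 window(s): 50 + 40 days
```

Synthetic data with known ground truth:

```text
$ alarmaudit synth -o synth.csv --seed 5 --beds 4 --days 0.25
wrote 151 records (50 true episodes) to synth.csv
```

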
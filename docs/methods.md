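# Methods

This note records the model behind each analytic component, the
parameter choices that are conventions rather than facts derivable
from a log, and the known limitations of the synthetic generator.

## 1. Log model

An audit-log row is `(timestamp, bed label, MRN, message, device
name)`. Timestamps print as `M/D/YY H:MM:SS` or `M/D/YY H:MM`
(seconds default to `:00`); two-digit years pivot into the 2000s.
MRNs are masked to zeros in de-identified exports, so patient identity
falls back to `bed label | device name`. Footnote markers (`^a^`),
smart quotes, and the Unicode minus (`−`) are normalized before
parsing.

## 2. Message grammar

`parse_message` maps every message to exactly one variant:

- **Numerical physiologic alarm** — `<marks><param> <value> <cmp>
  <limit> Generated|Ended.` with `*`..`***` marks, flexible whitespace
  around the comparator, case-insensitive status. Carries trigger
  value, programmed limit, and direction (`>` → above, `<` → below).
- **Categorical physiologic alarm** — `<marks><name> Generated|Ended.`
  with no value/limit/direction (arrhythmias, Apnea, etc.).
- **Apnea special forms** — `Apnea X:YY` is numerical with
  `apnea_detail = 60·X + YY` seconds but *no* limit (the display
  carries no comparator); `Apnea > 20 sec` sets `apnea_over_20s`.
- **Technical (INOP) alarm** — no mark (soft, level 0, inaudible) or
  `!` / `!!` / `!!!` (levels 1–3).
- **Sound events** — `Red/Yellow alarm sound played.`, `INOP sound
  played.`
- **User actions** — a 21-kind taxonomy (Silence, Pause/Resume
  Alarms, Transfer, limit changes, alarm/measurement on/off, ...).
  Limit-change forms (`SpO2: Desat Limit 78.`, `ST: Al. Limits ST-V2
  High: 1.6 ST-V2 Low: −1.6.`) yield structured bounds; a
  single-bound form takes its side (upper/lower) from the parameter
  registry.
- **Unparsed** — anything else is carried, never dropped.

The star/exclamation count ↔ priority level mapping is a bijection
checked by a render/parse round-trip property test.

## 3. Episode pairing

Alarm rows are sorted by `(stream key, timestamp, row index)`, where
the stream key is `(patient, bed, device, parameter, priority marks)`
— the same parameter at different priorities forms distinct streams.
Each `Ended` row matches the nearest preceding unmatched `Generated`
of its stream (LIFO, so nested alarms pair innermost-first). An
`Ended` logged *before* its `Generated` at the same second (the
logger's sub-second inversion) pairs into a zero-duration episode. A
`Generated` with no end is right-censored at the window end; an
`Ended` with no start is left-censored at the window start. The
default window is the observed alarm span. `episode_conservation_
check` verifies 2·episodes_paired + censored = alarm rows, per stream.

## 4. Rates and comparisons

Rates are events per denominator unit. The default **bed-day**
denominator counts distinct `(bed label, calendar date)` pairs over
all parsed records — an approximation that treats any bed with any
logged activity on a date as monitored that whole day. When census
data exist, pass `census=` explicitly. Grouping refinement preserves
the grand total (additivity, tested). `compare_periods` computes
per-group rates on each side of a boundary timestamp; empty sides are
flagged, not silently zeroed; groups missing from one non-empty side
count as zero.

## 5. Audits

- **Limit scan** harvests programmed limits from numerical alarm
  messages (`>` → upper limit, `<` → lower) and from limit-change
  actions, reporting per-(parameter, side) extremes and findings
  against a user-supplied safe-range spec (none ships by default —
  safety policy is local).
- **Priority consistency** groups physiologic alarms by
  `(parameter, direction, limit)` (technical by name) and flags any
  signature announced at ≥ 2 priority levels.
- **Unit compliance** flags beds where an alarm expected to be
  disabled still fires.
- **Retrieval planning** splits a study span into export windows of
  at most 50 days (greedy; a remainder below the 15-minute minimum is
  borrowed from the previous window) and warns when the span exceeds
  the 90-day retention horizon.

## 6. Announcement chain simulator

Severity classes rank: red 60 > long yellow 50 > short yellow 40 >
advisory 30 > hard INOP 20 > moderate INOP 15 > low INOP 12 > soft
INOP 10. Advisory alarms and 1-mark INOPs are not placed by the
vendor's stated ordering; slotting them in mark-count order between
short yellow and the INOP tiers is a documented convention that only
affects orderings left open. Within each priority chain (PVC, beat
detection, rate) only the top-severity alarm may sound; alarms outside
the chains compete only with themselves; only alarms at the overall
top severity are announced, ties broken by recency. Soft INOPs are
displayed but never announced. The display drop-down holds at most 10
alarms, severity-major, recency-minor. Latching (red) alarms keep
sounding after the condition ends until silenced. Pause mutes audio
for a fixed interval or indefinitely; an optional yellow-only pause
mode leaves reds audible.

## 7. Synthetic generator

Per bed × alarm-mix entry, onsets are a homogeneous Poisson process
(`numpy.random.default_rng(seed)`, byte-stable) and durations are
exponential; both round to whole seconds, matching the log's
resolution. `rate_change_factor` rescales all rates after a
configurable boundary for pre/post experiments. Planted anomalies
(unsafe limits, priority pairs, disabled alarms) and connectivity
gaps (which delete rows and flag affected truth episodes) are recorded
in a manifest.

**Thinning:** a stream cannot re-trigger while it is active, so a new
onset arriving before the previous episode of the same stream ends
(plus one second) is dropped. This guarantees that pairing recovers
ground truth *exactly* (overlapping same-stream intervals would make
LIFO pairing ambiguous), at the cost of a slight (< 1% at default
rates) downward bias in realized rates — which is why statistical
tests compare against Monte-Carlo standard errors rather than exact
counts. Zero-duration episodes emit their end row before their
generation row, reproducing the logger's sub-second inversion.

**Limitations:** independence across beds and parameters (no shared
physiologic state), exponential durations (real alarm durations are
heavy-tailed), homogeneous rates within a period (no circadian
pattern), and a fixed 20-bed / masked-MRN unit layout.

## 8. Numerical choices

All parsing and pairing is exact integer/decimal work; no floating
tolerance is involved anywhere except Monte-Carlo assertions, which
use 3–4 standard-error bounds derived from Poisson counts. Output
files are byte-stable across runs (fixed field order, `\n` line
terminators, ISO timestamps).
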
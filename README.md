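# phonelog

A toolkit for working with smartphone usage event logs: the raw material of
objective screen-time research. Passive logger apps timestamp every
interaction a participant has with their device — screen on/off, app
foreground changes, notifications, installs — and export those rows for
analysis. `phonelog` provides the full desk-side pipeline around such
exports, plus a behaviorally structured simulator so every stage can be
developed and tested without touching a device:

- **Event model** — a closed taxonomy of 13 event types; validated,
  time-sorted streams of `(timestamp_ms, event, app)` rows from the
  *continuous* (prospective) and *past usage* (retrospective OS history)
  sources, and a merge that uses the retrospective history to backfill
  continuous-logging dropouts.
- **Simulator** — self-initiated pickups as an inhomogeneous Poisson
  process (default 80/day, circadian-weighted, zero during sleep),
  log-normal session durations, Markov app switching, per-app Poisson
  notifications that trigger additional pickups, plus injectable logging
  artifacts (double counts, idle clock-app nights, restarts, dropouts) —
  all with exact ground truth for oracle testing.
- **Secure export** — passwords derived from the incidental timing of
  consent-dialog taps ("user-generated randomness"), and an AES-256
  password-protected container (CTR + HMAC-SHA256, PBKDF2 key derivation;
  the AES core is verified against the standard known-answer vectors).
- **Cleaning** — double-count removal within a configurable few-ms window,
  flagging of multi-hour single-app idle episodes (the clock app left on
  while charging), and screen-event repair around crashes and restarts.
- **Metrics** — sessionization of screen-on→screen-off pairs, per-app
  durations from consecutive-event differences, hourly/daily/weekly
  summaries (local-time windows, Monday weeks), and classification of each
  pickup as notification-driven vs self-initiated.
- **Validation** — order-preserving alignment of validator-prompted actions
  against logged events and per-type n/mean/SD discrepancy tables
  (discrepancies can be negative: the kernel can hand the logger an event
  before the action is scheduled).
- **Visualization** — per-app totals, the 24-h usage "barcode" strip, and a
  colored per-app timeline, each with a machine-readable geometry sidecar.

## The core quantities

For a stream of screen events, a *session* is the half-open interval
[t_on, t_off); its length is one episode of use and the daily session count
is the *pickup* rate (~80/day in general populations). Total use over a
window W is Σ min(t_off, W_end) − max(t_on, W_start) over sessions
intersecting W. Per-app time sums differences between consecutive
app-foreground events within sessions. A session is *notification-driven*
when a notification from the session's first app was posted within τ
(default 30 s) before pickup. Timestamp validation reports, per event type,
the sample mean and SD (n−1) of `recorded − prompted` differences in
milliseconds.

## Worked example

Simulate a week, clean it, and summarize daily use:

```bash
$ phonelog simulate --days 7 --seed 11 --out continuous.csv --past-out past.csv
wrote 2359 events to continuous.csv
$ phonelog clean --in continuous.csv --out cleaned.csv
rows rejected:      0
duplicates removed: 0
idle flags:         0
session repairs:    0
$ phonelog metrics --in cleaned.csv --granularity day --out daily.csv
572 sessions (40 notification-driven), 7.72 h total use
$ head -4 daily.csv
window_start,total_s,pickup_count
2021-01-04 00:00:00+00:00,4776,85
2021-01-05 00:00:00+00:00,3909,88
2021-01-06 00:00:00+00:00,4742,99
```

572 sessions over 7 days is ~82 pickups/day — the self-initiated Poisson
baseline of 80/day plus notification-triggered pickups, thinned slightly
where a notification arrives mid-session. Each day holds roughly 65–80
minutes of screen time (`total_s` is seconds of use per local day) spread
over 85–99 pickups: mostly brief checks, the typical usage texture.

The same pipeline is available as a library:

```python
from phonelog import BehaviorParams, simulate_usage_log, sessionize

stream, truth = simulate_usage_log(BehaviorParams(n_days=30, seed=7))
sessions = sessionize(stream)          # equals truth.true_sessions exactly
```

Secure export round trip:

```python
from phonelog import ConsentTapLog, generate_password, encrypt_export, decrypt_export
from phonelog.readwrite import stream_to_csv_text

pw = generate_password(ConsentTapLog([1609718401123, 1609718404456, 1609718409789]),
                       length=16, rng_seed=2)
# 'n5BKUVA0#UH!17r8' — deterministic given taps, length and seed
box = encrypt_export(stream_to_csv_text(stream), pw, "continuous")  # AES-256
table, kind = decrypt_export(box, pw)
```

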
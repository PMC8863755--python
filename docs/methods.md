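# Methods

This note documents the models, conventions and numerical choices behind
`phonelog`, and what its tests do and do not establish about real data.

## Event model

An event is `(timestamp_ms, type, app_id, source)`. Timestamps are integer
UNIX milliseconds throughout: logger exports carry millisecond UNIX stamps
and timing validation is reported in milliseconds, so no coarser unit would
round-trip. The taxonomy is closed (13 types); app-level types
(foreground/background, install/uninstall, notification posted/removed)
must carry a reverse-domain package id, device-level types must not.
Validation sorts stably by `(timestamp, source, type)` — continuous before
past, then enum declaration order — a deterministic tie-break the data
itself cannot supply.

Merging continuous and past-usage exports assumes both clocks are the same
device clock (drift zero); a `window_ms` of 1000 ms absorbs the two
recording paths' scheduling jitter. Matching is one-to-one, greedy and
order-preserving per `(type, app)`; unmatched past events are kept anywhere,
which is what lets the retrospective history backfill continuous-logging
dropouts. When the two sources imply contradictory screen states the merge
keeps both rows and warns — discarding either would require knowledge the
data does not contain.

## The behavioral simulator

The simulator emulates what a logger records, not any fitted model of a
population; its defaults define the reference study conditions used across
the test suite.

- **Self-initiated pickups**: inhomogeneous Poisson process, daily
  intensity 80/day (the commonly cited general-population interaction
  rate) spread over hours by a fixed circadian weight vector — zero inside
  the sleep window (23:00–07:00), peaks morning, midday and evening. A
  pickup urge arriving while a session is open is deferred to just after
  that session ends (with a 1 s refractory gap plus ≤2 s jitter), so daily
  self-pickup counts are conserved rather than thinned; this is what makes
  the 80/day rate recoverable within sampling error.
- **Sessions**: log-normal durations, median 30 s (μ = ln 30, σ = 1.0),
  floor 2 s. Most pickups are brief checks; the long tail produces
  multi-minute sessions. Implied screen time is roughly 1–2 h/day.
- **App switching**: within a session, exponential holding times with a
  0.25/min switch hazard (minimum 1 s); apps drawn by popularity weight
  from an 8-app repertoire, switches never self-loop. App intervals tile
  each session exactly — that tiling is the ground truth for per-app
  duration tests.
- **Notifications**: per-app homogeneous Poisson, 5/day/app, spaced ≥2 s
  per app so genuine repeats can never be mistaken for double-count
  artifacts. During waking hours a notification triggers a pickup with
  probability 0.25 after an exponential latency (mean 10 s, +0.5 s floor);
  the triggered session opens on the notifying app. Notifications arriving
  mid-session trigger nothing (the phone is already in hand). Net effect:
  total pickups average ~85–90/day, i.e. "more than 80".
- **System noise**: ~5 flush/config rows per day, ≥500 ms apart per type.
- **Artifacts** (all opt-in; defaults are identity): double-logged rows
  1–10 ms after their originals; clock-app foreground spanning a night's
  sleep window (closed by an APP_BACKGROUND); shutdown/boot pairs; dropout
  windows that delete continuous rows. Ground-truth bookkeeping records
  every injected defect, which is what makes the cleaning oracles exact.

What the simulator does **not** model: typing or content of use, reactivity
to being observed, inter-individual heterogeneity, clock drift, timezone
changes mid-study, or OS throttling of background loggers. Tests passing
against simulated data therefore establish internal correctness of the
pipeline's rules, not robustness to every device quirk in the field.

The validation-protocol replay emits the standard scripted sequence —
20 alternating screen toggles, 2 installs, 2 uninstalls, 10 interleaved
notification post/remove pairs, 20 app opens — at exponential 5 s gaps
(the protocol's inter-action gap is our choice; nothing hinges on it).
Recorded timestamps are prompted times plus per-type normal jitter,
default bias 0 and SD 500 ms, sign-unrestricted: real loggers can receive
an event from the kernel before the action itself is scheduled, so
negative discrepancies are expected behavior, not errors.

## Secure export

Passwords: the tap-timestamp list is shuffled, one element drawn, and that
value seeds the character generator (Mersenne Twister keyed by
`timestamp × 1 000 003 + length`). Default length 16 over a 74-character
alphabet (26 upper + 26 lower + 10 digits + 12 symbols); one character per
class is drawn first and the sequence is then shuffled by the same
generator, so class coverage is guaranteed without a retry loop.

Container: the canonical CSV is encrypted with AES-256 in CTR mode and
authenticated with HMAC-SHA256 over header‖salt‖nonce‖ciphertext
(encrypt-then-MAC); encryption and MAC keys are independent halves of a
64-byte PBKDF2-HMAC-SHA256 derivation (200 000 iterations, 16-byte random
salt). The AES core is implemented in-package, vectorized over blocks with
numpy, and pinned by tests to the FIPS-197 AES-256 known-answer vector and
the SP 800-38A CTR vector. The contract is the round trip, the clean
wrong-password failure, and the 256-bit key length — not any particular
wrapper file format.

## Cleaning

- **Double counts**: `epsilon_ms` defaults to 100 ms — "a few
  milliseconds" widened generously because OS scheduling jitter reaches
  tens of milliseconds. Runs are detected within each `(type, app)`
  subsequence, not across globally adjacent rows: a screen event and its
  double count remain a pair even when an app event at the same
  millisecond is interleaved between them. Runs collapse transitively to
  their first member; the operation is idempotent.
- **Idle episodes**: maximal single-app foreground episodes longer than
  3 h (default) are flagged, never deleted — the analyst decides; a
  threshold rather than a model because the canonical case (clock app on
  charge, 7–8 h) sits far from any genuine session.
- **Repair**: orphan screen-ons are closed at the next device shutdown
  (restarts always bound a session) under the default policy, or dropped;
  orphan screen-offs are dropped. After repair, screen events strictly
  alternate — `sessionize` requires it and fails pointing here otherwise.

## Metrics conventions

Sessions are half-open `[on, off)`. Windows are local time via a fixed
`tz_offset_hours` (default UTC); days begin at local midnight, weeks on
Monday (epoch shifted by 3 days before flooring, 1970-01-05 being the first
epoch Monday). A boundary-straddling session contributes duration to every
window it touches but counts as a pickup only in its start window — so
pickups sum to the screen-on count while durations are conserved across
granularities. Notification attribution uses τ = 30 s: long enough to cover
realistic response latencies, short enough that coincidental notifications
rarely steal credit (label accuracy ≥ 95 % against simulated truth; the
residual errors are responses slower than τ, which no fixed cutoff can
recover). APP_BACKGROUND events close the current app interval early when
present; otherwise the next foreground event or screen-off closes it.

## Figures

Plots never carry assertions: each figure writes a geometry sidecar CSV
(bars, segments, their extents) and tests assert the sidecar against the
input intervals. SVG output is made byte-deterministic by fixing the SVG
hash salt and stripping the date metadata. The timeline colors its top-5
apps by duration (black/red/green/gold/blue) and pools the rest as grey
"other"; the barcode draws raw sessions without bridging micro-gaps —
whether visually "consistent use" should merge near-adjacent sessions is a
presentation question left to the caller.

## Validation statistics

Alignment is order-preserving within each event type (k-th prompt ↔ k-th
record): in-order detection is part of what a passing validation
establishes, so nearest-neighbor matching is deliberately not the default.
Unmatched prompts are misses; surplus recorded events are reported but
never paired. Discrepancy tables report per-type n, mean and *sample* SD
(n−1); with a single pair the SD is reported absent rather than zero.

## Problem sizes and determinism

The test suite runs on 30- and 60-day simulations (~10 000–22 000 events),
sizes at which every rate in the model is estimated to within a few
percent while the whole suite completes in well under a minute of compute
for the simulation-backed parts. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical parameters and seed reproduce
byte-identical streams. Property-based tests run derandomized.

## Known limitations

- The merge cannot distinguish a true duplicate from two genuinely distinct
  same-type events within the match window; 1 s keeps this risk negligible
  at realistic event densities.
- Dedupe cannot see double counts separated by more than `epsilon_ms`, nor
  should it: beyond a few tens of milliseconds, repetition is real behavior.
- Sessions interrupted by an undetected power loss (no shutdown row) are
  unrecoverable and are dropped by repair, slightly deflating totals.
- The idle flag is binary and app-agnostic; media apps genuinely used for
  > 3 h (navigation, video) will be flagged and should be whitelisted by
  the analyst via the `exclude` hook rather than a lower threshold.
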
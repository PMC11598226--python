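# Methods

## Sensing model and geometry

The package models a bed monitored by six overhead ultrasonic ranging
channels in fixed order `(H_R, H_L, A_R, A_L, R_L, L_L)` — head, abdomen
and leg pairs, right and left — plus a PIR occupancy flag. Geometry
defaults (all in metres): sensor height 2.4 above the bed plane, usable
ranging window 0.3–2.7 (inclusive at both ends), per-sensor footprint 0.47
(informational only). A body part under a channel raises the echo surface
by `body_elevation` = 0.25, so an occupied channel reads 2.15. Echo timing
follows distance = speed × ToF / 2 with speed 340 m/s; raw fixed-point
echo counts of the original hardware are abstracted as floating-point
seconds.

The presence rule is `bit = 1 iff valid AND d ≤ sensor_height − δ` with
δ = 0.15 by default. The source system never states how a distance becomes
a bit; δ was placed midway between the noise scale (cm) and the body
elevation (25 cm) so that bit flips need a ≈5σ noise excursion at the
default noise level. Readings outside the valid window are flagged and
treated as absence, never as errors: a streaming system must tolerate
dropouts. When PIR reads 0 the fusion word is emitted with all bits zero
and marked unoccupied; every downstream stage treats such words as "wait
for occupancy".

## Synthetic streams

A scenario is a sorted, non-overlapping schedule of half-open `[start,
end)` segments labelled with one of the eight standard postures, OFF_BED,
or UNDEFINED, sampled every 1/6 s (frames at integer multiples of the
period inside the schedule span, so a 10 s segment yields exactly 60
frames). Per-frame distances are the posture's two-level pattern plus
i.i.d. Gaussian noise, default sd 0.02 m (the source system gives no noise
characterisation; 2 cm is a realistic ultrasonic ranging jitter at ~2.4 m),
seeded and bit-reproducible. Supine don't-care head bits are emitted as
present (the head is physically there); the classifier masks them.
UNDEFINED — the stand-in for mid-roll frames, since the source only shows
transitions pictorially — emits the all-zeros pattern with PIR still 1;
gaps between schedule segments read the same way. OFF_BED clears PIR.

What the simulator does **not** model: beam spread, multipath, the 40 kHz
waveform, breathing micro-motion, multi-subject beds, and any realistic
intermediate geometry during a roll. Passing tests therefore demonstrate
the correctness of the fusion/classification/timing chain under the stated
sensing model, not field performance of a physical installation.

## Classifier

The truth table (don't-care X only in the supine head bits) is canonical;
construction rejects any table in which some 6-bit word matches two rows
with different labels. Exactly 11 of the 64 words match a row: 7 exact
rows plus the 4 supine expansions.

`build_tree` compiles the table into the early-exit tree: group rows by
the leg pair, then the abdomen pair, then the head pair; at each level
single-row groups become equality-test leaves (smallest groups tested
first) and the last group is the fall-through branch. For the default
table this reproduces the hardware structure — legs `00` → FP, `11` → SP,
`01` → {RY, LF, LLP} side, `10` → {LY, RF, RLP} side, abdomen `11` →
fetal, head `11` → yearner, else lateral. The compiled tree is verified
exhaustively against the table at build time; where the original pseudocode's
side-branch naming disagrees with the table, the table wins (the table and
the three worked reference words are mutually consistent; the prose is
not).

Non-strict classification is the pure tree walk: total over all 64 words,
bits off the tested path ignored — the streaming default, mirroring the
hardware's early exit. Strict mode re-checks the winning label's full
pattern and returns UNKNOWN on mismatch — the right contract wherever a
learned reference must be a complete pattern. The all-zeros word is the
canonical illustration: tree FP (legs `00` early exit), strict UNKNOWN.

## Learning

Stability is three consecutive bitwise-equal occupied words (a 3-deep
FIFO, 0.5 s at the sampling period). A stable word matching a table row is
registered under that label, overwriting any earlier pattern; a novel word
reuses the slot already holding the same pattern or claims the lowest free
`New_k` slot, and the ninth distinct novel pattern raises a slot-exhausted
error naming the subject. Profiles are bounded at 8 subjects with
least-recently-used eviction — the package's interpretation of "replace
unused subject data", since no explicit policy is stated. Subject identity
is an explicit caller-supplied id: the source never defines a recognition
mechanism, and inventing biometrics would overreach; a Hamming-distance
`best_match` helper is provided and explicitly labelled heuristic.
Adaptive slots are kept per subject (the source is ambiguous; per-subject
is the conservative reading). Profiles persist as JSON with ISO
timestamps.

## Adaptive evaluation

A debounce state machine consumes per-sample labels at strictly increasing
timestamps. A label equal to the confirmed pose extends its segment; a
different standard label must persist `count_step1` consecutive samples to
be confirmed (default 3, chosen to match the stability FIFO; with 1 the
machine degenerates to edge detection). UNKNOWN samples extend the
inter-segment gap and reset any pending candidate. On confirmation the
machine emits the closed SEGMENT and a TRANSITION whose TD runs from the
old segment's last confirmed sample to the new segment's first sample, so
for a gap of g UNKNOWN samples TD = (g + 1) × period — the extra period is
the boundary step itself, and back-to-back postures get TD = one period.
Segment dwell plus transition TDs tile the confirmed span exactly
(events are contiguous); against the *scheduled* durations each boundary
is accurate to one sample period. Counters tick per sample, not per device
clock; `clock_ticks` converts a duration to 100 MHz ticks for display
parity, and counters are unbounded integers rather than saturating 8-bit
registers.

Stream end closes the open segment at the caller-supplied end time;
unconfirmed candidates are dropped.

## Pipeline and numbers reported

The pipeline runs sequentially per frame (at 6 frames/s there is no
throughput constraint worth emulating): fusion → idle on PIR 0 → learning
(stability + registration) or monitoring (classification + evaluation).
Monitoring consults a supplied subject profile before the tree: a word
exactly matching a learned adaptive pattern takes that `New_k` label,
because the total early-exit tree would otherwise absorb novel postures
into a standard leaf. Schedule-recovery accuracy aligns recovered segment
labels to scheduled ones with a longest-common-subsequence match, so a
spurious or missed segment costs exactly the labels it displaces.

The acceptance script reports: exhaustive classifier fidelity (11 matching
words, 53 strict rejections over all 64); the latency model at the
reference point S = 8 stages, Tclk = 10 ns, N = 30 iterations (80 ns per
iteration, 370 ns total); learning fidelity over all eight postures;
schedule recovery on randomized 30-segment scenarios, noise-free and at
the default 0.02 m noise (segment durations 3–8 s, adjacent labels forced
distinct — equal neighbours would merge into one dwell); and the TD across
a 30-sample gap. Accuracy is always the plain arithmetic
100·n_correct/n_total — 29/30 is 96.67% — and the error rate is its exact
complement on the percent scale.

Problem sizes (30 segments of a few seconds at 6 Hz, ≈10⁴ frames per run)
keep every check deterministic-fast while matching the 30-trial validation
scale of the original study design.

## Known limitations

* The sensing model is two-level; real echoes from bedding folds, raised
  knees, or partial coverage produce intermediate distances the presence
  threshold must absorb.
* The transition model (UNDEFINED → all-zeros) is a convention, not a
  measurement; real mid-roll words are unmodelled.
* Subject recognition is out of scope; profiles are keyed by explicit ids.
* The dual-counter semantics of the original evaluation pseudocode are
  under-specified; they are implemented here as one debounce counter plus
  one dwell counter.
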
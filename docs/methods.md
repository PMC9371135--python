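# Methods

## The monitored system

The package models a small aeroponic lettuce greenhouse: plants sit
above a root chamber misted by sprinklers fed from an 83.5 L main
nutrient tank; excess mist drains into a 21.5 L recirculation tank and
is pumped back (160 L/h) once it accumulates past 16 L. Climate
sensors measure ambient and crop (leaf) temperature, ambient and crop
relative humidity and luminosity; tank sensors measure level and
temperature. A fog node polls the sensors, schedules irrigation and
cameras, stores telemetry in four 8-field time-series channels, and
serves a remote-control channel.

## Stress analytics

Saturation vapor pressure is the Tetens form,
`Psat(T) = 0.6108·exp(17.27·T/(T+237.3))` kPa, valid for T > −237.3 °C.
The leaf-to-air VPD evaluates the saturation term at leaf temperature
and the actual-vapor term at air temperature:
`VPD = Psat(Tc) − (RH/100)·Psat(Ta)`. A base-10 variant
(`610.7·[10^(7.5T/(T+237.3)) − …]` Pa) is implemented only as a
cross-check: since 17.27/ln 10 ≈ 7.5006, the two forms agree to within
0.2 % in a unit-adjusted sense. Because the agreement is between two
*differences* of near-equal terms, the natural statement is
`|VPD_pa/1000 − VPD| ≤ 0.002·max(|VPD|, 0.1 kPa)`: near the VPD
zero-crossing the absolute discrepancy stays below 0.002 kPa but the
relative discrepancy is unbounded, so a purely relative bound would be
the wrong claim.

Classification bands: DT_la = Tc − Ta in [+4, +6] °C ⇒ water stress; in
[−4, −1] °C ⇒ no stress; anything else is *indeterminate*, because the
published bands come from arid/semi-arid field studies and deliberately
do not cover the whole line. VPD strictly above 1 kPa is *harmful*
(1.0 itself reads "above 1" strictly, hence favorable); [0.5, 1] kPa is
*favorable*; below 0.5 kPa is reported as *intermediate*. Negative VPD
(leaf much cooler than near-saturated air) is physically awkward but
representable; it is reported as computed and flagged with a
`vpd_negative` marker, never clipped.

Which humidity enters the VPD is genuinely ambiguous in the source
material ("the relative humidity"); the default is ambient RH with an
`rh_source="RHc"` switch for crop RH.

Series summaries use the **sample** standard deviation (n−1), zero for
a single point; extremum-time ties break to the earliest timestamp.

## Synthetic device layer

The simulator is a stand-in for the physical greenhouse, not an
energy-balance model. Ambient temperature is a 24 h cosine attaining
`Ta_max` at `peak_time_Ta` (defaults 34.19 °C at 12:52) and `Ta_min`
12 h away; ambient humidity is anti-correlated with the clean
temperature curve inside [5.87, 97.43] %; leaf temperature is ambient
plus a diurnal offset confined to [−4.63, +0.24] °C, most negative at
midday (transpirative cooling); luminosity is a raised-cosine daylight
bump peaking at 9118 lux at 12:23 and exactly zero outside the daylight
window; crop humidity is ambient humidity plus bounded noise. All
defaults are the observed operating ranges of the reference deployment
and are configuration, not physics. Gaussian noise is added per
variable and clipped to the configured bounds; every noise stream
derives its generator from `(root_seed, stream_index)` so adding a
stream never perturbs the others and equal seeds give bit-identical
output.

Tank dynamics are bookkeeping: irrigation drains the main tank at
`irrigation_flow_l_per_h` (default 6 L/h — the per-sprinkler flow is
not specified anywhere, so this is a free parameter chosen to be
plausible for five fine-mist nozzles); `return_fraction` (default 0.9)
of the sprayed volume drains back to the recirculation tank; the
recirculation pump moves liquid back at 160 L/h; plant uptake is a
constant optional drain. Everything that permanently leaves the two
tanks (uptake, non-returned mist, overflow) accumulates in an explicit
`lost_l` field so `L_sol + L_res + lost_l` is conserved exactly and the
mass balance is directly testable (observed drift < 1e−12 L over 1000
steps; tolerance 1e−9 L). Level sensors report liters directly; the
ultrasonic distance-to-volume conversion is abstracted away (no tank
geometry is specified). Time is timezone-naive local clock time,
matching how the schedules are expressed ("6:00 … 19:30 h").

Synthetic root images render bright greenish backgrounds (hue jittered
inside the background band, V ≈ 0.8) with reddish root strands (hue
≤ 30 on the 0–179 scale, V ≈ 0.45–0.75). Strands are 3 px wide with
slow lateral drift so that a 2×2 opening preserves them nearly intact —
this is the *clean separation* regime the enhancement pipeline is
specified for. What the generator does **not** emulate: specular
highlights, shadows, hue overlap between dark root cores and
background, sensor blur, lens distortion. Passing the Dice ≥ 0.9 check
therefore validates the pipeline's mask algebra and band logic, not its
robustness on difficult real photographs.

## Fog services

- **Irrigation** events are anchored at each window's start (phase is
  not specified by the source; offset zero is the simplest testable
  choice) and repeat every `frequency_min` minutes; day/night windows
  may override period and on-time, and a window wrapping midnight is
  split at midnight with each part re-anchored.
- **Recirculation** turns on strictly above 16 L. Only the turn-on
  threshold is specified; a hysteresis low setpoint (default 0.5 L)
  prevents chatter, and the mixing pump runs for `mix_time_s` after a
  transfer completes.
- **Camera** status pulses: 3 = both cameras captured, 2 = upper-camera
  flaw, 1 = frontal-camera flaw, 0 = nothing captured. The stated code
  semantics are followed literally; the consequence that *both* cameras
  failing is indistinguishable from a downed camera service is a known
  limitation of the code itself.
- **Sensor polling** packs the eight environmental readings into one
  channel write per 30 s cycle. Bit k of the health register is field k
  of the environmental channel in its display order (two ambient
  thermometers, crop temperature, two humidities, luminosity,
  recirculation-tank temperature and level); the bit order is a
  documented convention, not specified by the source. Failed readings
  serialize as an explicit missing value (empty CSV cell, JSON null),
  never as 0, so a dead sensor cannot masquerade as a zero reading.
- **Failure detection**: a service fails over any pulse gap longer than
  `miss_factor` (default 2) times its expected period, including gaps
  against the window edges; sensor k is flagged when its health bit is
  zero in at least θ (default 0.5) of register samples; a camera flaw
  is a stagnation of ≥ 2 consecutive scheduled captures at code 2 or 1.
  The end-to-end pipeline supplies expectations for irrigation, sensor
  and camera services only: recirculation pulses have no fixed cadence
  (at default flows the 21.5 L tank takes several days to reach 16 L),
  so pulse absence there is not evidence of failure.
- **Alerts** are emitted once per distinct failure (idempotent across
  repeated reports); transport errors queue the event for retry at the
  next notification. The default transport is a JSON-lines log; SMTP or
  anything else can be plugged in behind the same one-method interface.

## Channel store

Four channels of up to eight numeric fields (32 slots; the default
allocation uses 27: 8 environmental, 8 manual, 7 service-status, 4
control — the exact split beyond the environmental and manual channels
is this package's own documented allocation). Writes are rejected when
closer than 15 s to the previous accepted write on the same channel, or
once 8200 writes have been accepted across all channels in a calendar
day (pooled account-level quota, day boundary at local midnight).
Rejected writes are logged with a reason and never partially applied.
CSV export uses shortest-round-trip float formatting so export→import
reproduces values bit-for-bit; import failures name the offending line
and apply nothing.

## Command codec

10-bit words: payload bits 0–7 (irrigation, recirculation, mixer,
camera trigger, config write, config read, two reserved — the
assignment of actuators to bits is this package's convention, fixed and
documented), attended-status bit 8, parity bit 9. Parity is **even**
and always computed at encode time. Exhaustive checks cover all 512
valid states and all 5120 single-bit corruptions; double-bit
corruptions are undetectable by construction (plain parity) and no
claim is made about them. Bit 0 is least significant; words print as
unsigned decimals.

## Root imaging

RGB→HSV uses the standard hexcone conversion; hue is scaled to 0–179
(the band (35, 140) only makes sense on that quantization — on 0–360 it
would truncate common green-background hues) and value to 0–255, both
scales configurable. Band membership is inclusive at both ends.
"Morphological filtering" is opening (erosion then dilation with an
all-ones 2×2 element; idempotent, anti-extensive) since the intent is
removal of sub-kernel noise; closing is available behind a flag. The
filtered mask keeps the root in the RGB image; for the HSV output the
ambiguity of "background removal on the HSV image" is resolved by
emitting both an HSV-valued array with the background zeroed *and* an
RGB rendering of it for viewing. Segmentation quality is scored with
the Dice coefficient (defined as 1 when both masks are empty).

## Reports

Each of the ten variable reports carries exactly the variables of the
deployment's variable→report matrix; the VPD report additionally
includes the computed VPD column and the temperature-difference report
the DT_la series with its stress class. (The matrix lists T_a and RH_c
under the VPD report while the VPD computation itself uses T_c, T_a and
RH — the report follows the matrix, the computation follows the
equation; the mismatch is surfaced rather than resolved.) The two
request reports are counter views (per hour / per channel) over
accepted writes. A variable with no stored data appears as an explicit
`missing` entry plus an all-NaN column. Reports are CSV; plots are
optional matplotlib renderings and never the data of record. The
manual-readjust workflow records HNO₃ / solution A / solution B dosing
amounts on the control channel; no dosing computation is defined for
the system, so none is invented.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic
data generated at call time: one simulated day at 30 s cadence (2880
samples), 256×256 root images, 1000-step tank sequences, exhaustive
512/5120-case codec sweeps, and a 35 000-write quota storm. The full
suite completes in well under a minute on one CPU. All randomness flows
from explicit seeds; property tests run derandomized.

## Known limitations

- No radiative/energy-balance greenhouse physics, no plant-growth
  model, no thermographic processing or leaf-area index.
- The diurnal generator cannot produce weather fronts, multi-day
  trends, or sensor drift; failure-detection results on it bound only
  the logic, not real-world detection performance.
- Quota accounting assumes well-ordered timestamps per channel;
  out-of-order backfills are only supported through the bulk CSV import
  path, which bypasses policy.
- The parity codec detects exactly one class of corruption; it is a
  faithful model of the protocol, not a robust channel code.
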
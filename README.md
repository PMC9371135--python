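# aerofog

An aeroponic-greenhouse monitoring stack in pure Python: a synthetic
device layer stands in for the physical greenhouse, and everything a
four-layer IoT monitor does above it — fog-layer microservices,
cloud-style channel storage, leaf-to-air water-stress analytics, a
remote command protocol, and root-image enhancement — is implemented
as an importable library with a thin CLI.

It is intended for people studying soilless cultivation and
precision-agriculture telemetry who want a controllable, reproducible
software twin of such a monitoring rig: agronomists exploring
irrigation/stress trade-offs, and engineers testing failure-detection
and storage-quota logic without hardware.

## What it computes

**Water-stress markers.** Saturation vapor pressure uses the Tetens
form (Allen / FAO-56):

    Psat(T) = 0.6108 · exp(17.27 T / (T + 237.3))      [kPa]

The leaf-to-air vapor pressure deficit takes the saturation term at the
crop (leaf) temperature T_c and the actual-vapor term at the air
temperature T_a with relative humidity RH:

    VPD = Psat(T_c) − (RH/100) · Psat(T_a)             [kPa]

An equivalent base-10 form (610.7·[10^(7.5T/(T+237.3)) − …] in Pa) is
kept for cross-validation; the two agree within 0.2 %. The second
marker is the crop-minus-air temperature difference DT_la = T_c − T_a.
Classification follows the arid/semi-arid literature: DT_la in
[+4, +6] °C means water stress, [−4, −1] °C means no stress; VPD above
1 kPa is potentially harmful, 0.5–1 kPa favorable.

**Fog services and protocol arithmetic.** Irrigation scheduling
(default: every 24 min for 30 s, day and night), recirculation of the
return tank strictly above 16 L with hysteresis, camera triggering at
nine scheduled times per day with status pulses (3 = both cameras ok,
2/1 = upper/frontal flaw), 30 s sensor polling packed into single
8-field channel writes, a one-byte sensor-health register (255 = all
eight sensors read successfully), failure detection from pulse absence
and stuck-at-zero health bits, and idempotent alerting. The channel
store enforces the free-tier contract: 4 channels × 8 fields, 15 s
minimum update interval, 8200 accepted messages per day pooled across
channels. Remote commands travel as 10-bit words (8 payload bits,
attended bit, even-parity bit); every single-bit corruption is detected.

**Root imaging.** Roots are enhanced by segmenting the greenish
background in hue (H ∈ (35, 140) on the 0–179 scale), keeping well-lit
pixels (V ∈ (100, 255)), ANDing the value mask with the negated hue
mask, and cleaning with a 2×2 morphological opening; the resulting mask
and its complement produce background-suppressed RGB and HSV views.

## Worked example

```python
>>> import aerofog as af
>>> af.saturation_vapor_pressure(25.0)
3.1677777175068473
>>> af.vpd_kpa(Tc=25, Ta=25, RH=50)      # kPa; > 1 kPa is harmful
1.5838888587534237
>>> af.classify_vpd(1.58).value
'harmful'
>>> af.dtla(Tc=20, Ta=25), af.classify_dtla(-5.0).value
(-5.0, 'indeterminate')
>>> w = af.encode(af.CommandState(irrigation=True)); w
513
>>> af.decode(w).irrigation
True
>>> af.encode_health([True]*8).value
255
```

`vpd_kpa(25, 25, 50) ≈ 1.584 kPa` says that air at 25 °C and 50 %
humidity can hold 1.58 kPa more vapor than it carries — well above the
1 kPa harm threshold, so the classifier reports conditions favouring
stomatal closure. The command word 513 is `0b1000000001`: payload bit 0
(irrigation) plus the parity bit that keeps the set-bit count even.

A full simulated day, end to end:

```python
>>> from aerofog.reporting import run_pipeline
>>> out = run_pipeline(af.SimConfig(), days=1, seed=7, out_dir="run")
>>> import json; s = json.load(open(out / "summary.json"))
>>> s["environmental_writes"], s["captures_frontal"], round(s["root_mask_dice"], 3)
(2880, 9, 0.999)
```

2880 environmental writes is exactly one packed write per 30 s polling
interval for 24 h; nine captures per camera match the inspection
schedule; the Dice score compares the enhanced root mask against the
synthetic image's ground truth. The run directory also contains the
telemetry CSVs, channel exports, stress-marker table, failure report,
alert log, enhanced root images and the twelve report CSVs.

The same stack is scriptable from the shell:

```
aerofog run --days 1 --seed 7 --out-dir run
aerofog analyze --in run/climate.csv --out stress.csv
aerofog report --kind vpd --store-dir run --out vpd.csv
aerofog enhance-root --in run/root_rgb.png --out-dir enhanced
aerofog decode-command 513
```

## Storage format

Channels export as CSV (`timestamp,<field1>,…`, ISO-8601 timestamps,
empty cell = missing reading). The optional persistent backend is
append-only JSON-lines per channel, one object per accepted write:
`{"t": "2021-11-01T00:00:00", "values": {"Ta_htu": 20.1, ...}}`.
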
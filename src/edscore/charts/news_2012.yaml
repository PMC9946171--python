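# National Early Warning Score aggregate chart (2012 RCP release).
# Bands are upper-edge intervals: a value v scores the first band with
# v <= upper; "upper: null" means +infinity. Bands partition the real line.
version: news-2012
parameters:
  respiratory_rate:
    unit: breaths/min
    bands:
      - {upper: 8, points: 3}
      - {upper: 11, points: 1}
      - {upper: 20, points: 0}
      - {upper: 24, points: 2}
      - {upper: null, points: 3}
  spo2:
    unit: percent
    bands:
      - {upper: 91, points: 3}
      - {upper: 93, points: 2}
      - {upper: 95, points: 1}
      - {upper: null, points: 0}
  temperature:
    unit: celsius
    bands:
      - {upper: 35.0, points: 3}
      - {upper: 36.0, points: 1}
      - {upper: 38.0, points: 0}
      - {upper: 39.0, points: 1}
      - {upper: null, points: 2}
  sbp:
    unit: mmHg
    bands:
      - {upper: 90, points: 3}
      - {upper: 100, points: 2}
      - {upper: 110, points: 1}
      - {upper: 219, points: 0}
      - {upper: null, points: 3}
  heart_rate:
    unit: bpm
    bands:
      - {upper: 40, points: 3}
      - {upper: 50, points: 1}
      - {upper: 90, points: 0}
      - {upper: 110, points: 1}
      - {upper: 130, points: 2}
      - {upper: null, points: 3}
supplemental_oxygen_points: 2   # any FiO2 above room air
not_alert_points: 3             # roused only by voice/pain, or unresponsive
room_air_fio2: 0.21
max_score: 20
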
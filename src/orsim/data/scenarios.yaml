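# Default scenario library: two uneventful and two eventful 30-minute
# "lunch break" scripts, each eventful script carrying three intraoperative
# events placed in consecutive ten-minute windows.  Between events all
# parameters return to baseline.
#
# Excursion fields: onset is seconds after (window start - 1), i.e. the last
# second still at baseline; the parameter then ramps linearly to `target`
# over `ramp_up` s, holds for `hold` s, and ramps back over `ramp_down` s.
# The symptomatic-bradycardia HR excursion instead anchors the first second
# strictly below the crossing threshold (`crossing: {threshold, at}`, absolute
# timestamp); its onset is derived from the ramp geometry.
#
# Only the hypovolemia trajectory shape and the bradycardia HR<60 crossing
# are externally fixed; every other amplitude/timing is a clinically
# plausible reconstruction and can be edited here.

duration_s: 1800
windows:
  - [1, 600]
  - [601, 1200]
  - [1201, 1800]

baseline:
  HR: 75.0
  SpO2: 98.0
  NIBP_sys: 120.0
  NIBP_dia: 80.0
  MAP: 93.0
  EtCO2: 35.0
  RR: 12.0
  PIP: 20.0
  TV: 500.0

scenarios:
  uneventful_1: []
  uneventful_2: []
  eventful_1: [circuit_disconnect, symptomatic_bradycardia, endobronchial_migration]
  eventful_2: [hypovolemia, pulmonary_embolism, light_anesthesia]

events:
  circuit_disconnect:
    excursions:
      - {parameter: EtCO2, onset: 120, ramp_up: 30, hold: 120, ramp_down: 30, target: 0.0}
      - {parameter: TV,    onset: 120, ramp_up: 30, hold: 120, ramp_down: 30, target: 0.0}
      - {parameter: PIP,   onset: 120, ramp_up: 30, hold: 120, ramp_down: 30, target: 5.0}
  symptomatic_bradycardia:
    excursions:
      - {parameter: HR, ramp_up: 200, hold: 150, ramp_down: 100, target: 45.0,
         crossing: {threshold: 60.0, at: 752}}
      - {parameter: NIBP_sys, onset: 150, ramp_up: 100, hold: 100, ramp_down: 100, target: 95.0}
  endobronchial_migration:
    excursions:
      - {parameter: SpO2, onset: 80, ramp_up: 120, hold: 120, ramp_down: 120, target: 88.0}
      - {parameter: PIP,  onset: 80, ramp_up: 120, hold: 120, ramp_down: 120, target: 34.0}
  hypovolemia:
    excursions:
      # HR rises gradually over 5 minutes but stays below the 100 bpm alarm
      # threshold; the systolic pressure later falls through the 90 mmHg
      # low-BP threshold; everything normalises before the window ends.
      - {parameter: HR,       onset: 30,  ramp_up: 300, hold: 60, ramp_down: 120, target: 95.0}
      - {parameter: NIBP_sys, onset: 330, ramp_up: 90,  hold: 60, ramp_down: 60,  target: 80.0}
      - {parameter: NIBP_dia, onset: 330, ramp_up: 90,  hold: 60, ramp_down: 60,  target: 55.0}
      - {parameter: MAP,      onset: 330, ramp_up: 90,  hold: 60, ramp_down: 60,  target: 63.0}
  pulmonary_embolism:
    excursions:
      - {parameter: EtCO2,    onset: 60, ramp_up: 20, hold: 240, ramp_down: 120, target: 18.0}
      - {parameter: HR,       onset: 60, ramp_up: 60, hold: 200, ramp_down: 120, target: 112.0}
      - {parameter: SpO2,     onset: 60, ramp_up: 90, hold: 170, ramp_down: 120, target: 91.0}
      - {parameter: NIBP_sys, onset: 60, ramp_up: 90, hold: 170, ramp_down: 120, target: 95.0}
  light_anesthesia:
    excursions:
      - {parameter: HR,       onset: 100, ramp_up: 120, hold: 120, ramp_down: 120, target: 108.0}
      - {parameter: NIBP_sys, onset: 100, ramp_up: 120, hold: 120, ramp_down: 120, target: 168.0}
      - {parameter: RR,       onset: 100, ramp_up: 120, hold: 120, ramp_down: 120, target: 20.0}
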
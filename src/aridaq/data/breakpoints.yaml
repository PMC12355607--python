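# Individual air quality index (IAQI) breakpoint tables, Chinese technical
# regulation HJ 633-2012.  Concentration nodes map one-to-one onto the IAQI
# nodes listed per pollutant.  Units: ug/m3 except CO (mg/m3).
# O3_8h is the daily maximum 8-h rolling mean; the regulation defines it only
# up to IAQI 300 (concentrations above 800 ug/m3 are beyond the index scale).
version: HJ633-2012
breakpoints:
  SO2:
    period: 24h
    unit: ug/m3
    concentration: [0, 50, 150, 475, 800, 1600, 2100, 2620]
    iaqi: [0, 50, 100, 150, 200, 300, 400, 500]
  NO2:
    period: 24h
    unit: ug/m3
    concentration: [0, 40, 80, 180, 280, 565, 750, 940]
    iaqi: [0, 50, 100, 150, 200, 300, 400, 500]
  PM10:
    period: 24h
    unit: ug/m3
    concentration: [0, 50, 150, 250, 350, 420, 500, 600]
    iaqi: [0, 50, 100, 150, 200, 300, 400, 500]
  PM2.5:
    period: 24h
    unit: ug/m3
    concentration: [0, 35, 75, 115, 150, 250, 350, 500]
    iaqi: [0, 50, 100, 150, 200, 300, 400, 500]
  CO:
    period: 24h
    unit: mg/m3
    concentration: [0, 2, 4, 14, 24, 36, 48, 60]
    iaqi: [0, 50, 100, 150, 200, 300, 400, 500]
  O3_8h:
    period: 8h_max
    unit: ug/m3
    concentration: [0, 100, 160, 215, 265, 800]
    iaqi: [0, 50, 100, 150, 200, 300]
levels:
  - {level: 1, label: excellent, upper: 50}
  - {level: 2, label: good, upper: 100}
  - {level: 3, label: mild pollution, upper: 150}
  - {level: 4, label: moderate pollution, upper: 200}
  - {level: 5, label: heavy pollution, upper: 300}
  - {level: 6, label: severe pollution, upper: null}
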
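# Grade-II ambient air quality evaluation limits (GB 3095-2012) used for the
# comprehensive (composite) pollution index: annual means for SO2/NO2/PM10/
# PM2.5, 95th percentile of daily means for CO, 90th percentile of daily
# maximum 8-h means for O3.
grade2_limits:
  SO2: 60      # ug/m3, annual mean
  NO2: 40      # ug/m3, annual mean
  PM10: 70     # ug/m3, annual mean
  PM2.5: 35    # ug/m3, annual mean
  CO: 4.0      # mg/m3, 95th percentile of daily means
  O3_8h: 160   # ug/m3, 90th percentile of daily max 8-h means
dust_pm10_daily_limit: 150  # ug/m3, Grade-II 24-h PM10 limit
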
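# Two-tailed critical values W_P of the Spearman rank correlation coefficient.
# A trend over n periods is significant at level alpha when |rs| >= W_P.
alpha_0.05:
  4: 1.000
  5: 0.900
  6: 0.886
  7: 0.786
  8: 0.738
  9: 0.700
  10: 0.648
  11: 0.618
  12: 0.587
  13: 0.560
  14: 0.538
  15: 0.521
  16: 0.503
  17: 0.485
  18: 0.472
  19: 0.460
  20: 0.447
  21: 0.435
  22: 0.425
  23: 0.415
  24: 0.406
  25: 0.398
  26: 0.390
  27: 0.382
  28: 0.375
  29: 0.368
  30: 0.362
alpha_0.01:
  6: 1.000
  7: 0.929
  8: 0.881
  9: 0.833
  10: 0.794
  11: 0.755
  12: 0.727
  13: 0.703
  14: 0.679
  15: 0.654
  16: 0.635
  17: 0.615
  18: 0.600
  19: 0.584
  20: 0.570
  21: 0.556
  22: 0.544
  23: 0.532
  24: 0.521
  25: 0.511
  26: 0.501
  27: 0.491
  28: 0.483
  29: 0.475
  30: 0.467
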
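{
  "k0.1_alpha0.1": 0.00010716414453104672,
  "k1_alpha0.1": 0.000640345960318145,
  "k5_alpha0.1": 0.0004008295687878416,
  "k10_alpha0.1": 0.00024983148836654756,
  "k20_alpha0.1": 0.0002470916947974189,
  "k50_alpha0.1": 0.00026340359312893025,
  "k100_alpha0.1": 0.00026605287850833825,
  "k0.1_alpha1": 0.005979909277777362,
  "k1_alpha1": 0.04048672474648496,
  "k5_alpha1": 0.038582126700330566,
  "k10_alpha1": 0.019864134775326114,
  "k20_alpha1": 0.017554520966083897,
  "k50_alpha1": 0.019302866619732684,
  "k100_alpha1": 0.019442354845535914,
  "k0.1_alpha1.5": 0.010796492234171895,
  "k1_alpha1.5": 0.07517397731811326,
  "k5_alpha1.5": 0.08271149755695972,
  "k10_alpha1.5": 0.0416280144986666,
  "k20_alpha1.5": 0.03425475750891238,
  "k50_alpha1.5": 0.03789348818950711,
  "k100_alpha1.5": 0.03846349500030921
}
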
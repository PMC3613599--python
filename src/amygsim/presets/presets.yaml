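# Shipped experiment presets. "extinction" selects which CSs receive
# omission trials during extinction epochs: "both_cs" extinguishes the two
# stimuli in alternation; "single_cs" extinguishes only CS1 while CS2
# remains paired with the US (the "confusing outcomes" paradigm).
normal:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: both_cs
cautious:
  f_I: 3.0
  E_ILd: 5.0
  E_ILv: 2.0
  extinction: both_cs
rapid_switch:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 5.0
  extinction: both_cs
lesion_itcd:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: both_cs
  lesions: {freeze_w_ld: true}
lesion_itcv:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: both_cs
  lesions: {freeze_w_bv: true}
confusing:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: single_cs
confusing_lesion_itcd:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: single_cs
  lesions: {freeze_w_ld: true}
confusing_lesion_itcv:
  f_I: 3.0
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: single_cs
  lesions: {freeze_w_bv: true}
generalization:
  f_I: 0.3
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: both_cs
phobic:
  f_I: 0.3
  E_ILd: 0.0
  E_ILv: 2.0
  extinction: single_cs
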
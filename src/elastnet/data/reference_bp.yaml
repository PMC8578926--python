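# Normative brachial and aortic blood-pressure values (mean, SD in mmHg)
# used by the physiological plausibility filter. A virtual subject is
# accepted only if every quantity lies within mean +/- 2.807 SD.
brachial:
  SBP: {mean: 123.0, sd: 15.0}
  DBP: {mean: 76.0, sd: 10.0}
  MAP: {mean: 92.0, sd: 10.0}
  PP: {mean: 47.0, sd: 12.0}
aortic:
  SBP: {mean: 112.0, sd: 15.0}
  DBP: {mean: 77.0, sd: 10.0}
  MAP: {mean: 92.0, sd: 10.0}
  PP: {mean: 35.0, sd: 11.0}
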
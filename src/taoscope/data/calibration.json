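{
 "conjunctival_congestion": {
  "feature": "sclera_redness",
  "coef": 46.45489711992261,
  "intercept": -9.220894521486004,
  "seed": 20220610,
  "n": 160
 },
 "eyelid_congestion": {
  "feature": "lid_redness",
  "coef": 57.07428578910456,
  "intercept": -21.348401997138744,
  "seed": 20220610,
  "n": 160
 },
 "eyelid_edema": {
  "feature": "lid_brightness_variance",
  "coef": 0.0,
  "intercept": 0.0,
  "seed": 20220610,
  "n": 160
 },
 "eyelid_retraction": {
  "feature": "aperture_ratio",
  "coef": 84.80933736727624,
  "intercept": -35.84491993976968,
  "seed": 20220610,
  "n": 160
 }
}
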
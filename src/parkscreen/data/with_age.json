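{
 "variant": "with_age",
 "intercept": 13.8134,
 "coefficients": {
  "hand_rotation_mv": -0.0251,
  "hand_rotation_mv_squared": 0.00001,
  "finger_tapping_mv": -0.0081,
  "pegboard_time": 0.0374,
  "age": 0.0685
 },
 "units": {
  "hand_rotation_mv": "deg/s",
  "hand_rotation_mv_squared": "deg^2/s^2",
  "finger_tapping_mv": "deg/s",
  "pegboard_time": "s",
  "age": "years",
  "output": "UPDRS3 points"
 },
 "inputs": "non-dominant hand, first kinematic trial",
 "version": "published-1"
}
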
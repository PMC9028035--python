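{
  "n_neurons": 2,
  "weights": [
    [
      2.9952491809502337,
      -16.0
    ],
    [
      16.0,
      5.414202326334978
    ]
  ],
  "biases": [
    -9.267863182619434,
    4.888567151956354
  ],
  "time_constants": [
    1.0,
    1.0
  ]
}
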
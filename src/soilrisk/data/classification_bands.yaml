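# Classification bands for the pollution and ecological-risk indices.
# Each band is [upper_bound, label]; a value v gets the first label with
# v <= upper_bound (boundaries belong to the lower band). ".inf" = unbounded.
pi:
  - [1.0, unpolluted]
  - [2.0, mild]
  - [3.0, moderate]
  - [.inf, heavy]
nemerow:
  - [0.7, safe]
  - [1.0, warning]
  - [2.0, light]
  - [3.0, moderate]
  - [.inf, heavy]
igeo:
  - [0.0, unpolluted]
  - [1.0, light]
  - [2.0, moderate]
  - [3.0, moderate-heavy]
  - [4.0, heavy]
  - [5.0, heavy-extreme]
  - [.inf, extreme]
er:
  - [40.0, low]
  - [80.0, moderate]
  - [160.0, considerable]
  - [320.0, high]
  - [.inf, very high]
ri:
  - [80.0, low]
  - [160.0, moderate]
  - [320.0, considerable]
  - [.inf, high]
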
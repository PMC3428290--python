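{
  "description": "Reference parameters for the single-exponential native-contact decay Qb(t) = A exp(-t/tau) + B of the miR369-3:mRNA duplex opening in the PAZ-dsRNA-KH quadruple complex. Only tau is anchored to the reported opening time scale of that system; the amplitude A and offset B are synthetic repository choices.",
  "A": 0.6,
  "tau_ns": 4.96,
  "B": 0.4,
  "n": 5000,
  "dt_ps": 10.0,
  "sigma": 0.0
}
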
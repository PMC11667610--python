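d_cm,value,kind
3,1.025,tau_L
13,1.004,tau_L
23,0.984,tau_L
33,0.959,tau_L
43,0.940,tau_L
53,0.921,tau_L
103,0.803,tau_L
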
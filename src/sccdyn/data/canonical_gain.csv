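d_cm,value,kind
3,0.1764,gain
13,0.1974,gain
23,0.2224,gain
33,0.2512,gain
43,0.2804,gain
53,0.3130,gain
103,0.4984,gain
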
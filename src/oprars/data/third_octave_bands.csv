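center_hz,importance
160,0.0083
200,0.0095
250,0.0150
315,0.0289
400,0.0440
500,0.0578
630,0.0653
800,0.0711
1000,0.0818
1250,0.0844
1600,0.0882
2000,0.0898
2500,0.0868
3150,0.0844
4000,0.0771
5000,0.0527
6300,0.0364
8000,0.0185
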
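center_hz,importance,retspl_db
250,0.0617,11.4
500,0.1671,4.4
1000,0.2373,2.4
2000,0.2648,-1.3
4000,0.2142,-5.4
8000,0.0549,12.6
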
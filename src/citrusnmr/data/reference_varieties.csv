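variety_id,acceptability,ratio_60mhz,ratio_400mhz
B475B,7.4,10.85,9.31
F7P3,6.9,11.53,10.12
B475A,5.5,8.45,7.70
B79,4.8,6.75,6.34
M16,3.6,3.88,4.16
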
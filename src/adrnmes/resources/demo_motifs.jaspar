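>RBPJ_SYN RBPJ_SYN
A  [      1.00       1.00       1.00       1.00       1.00       1.00      97.00      97.00 ]
C  [     97.00       1.00       1.00       1.00       1.00       1.00       1.00       1.00 ]
G  [      1.00      97.00       1.00      97.00      97.00      97.00       1.00       1.00 ]
T  [      1.00       1.00      97.00       1.00       1.00       1.00       1.00       1.00 ]
>HES_SYN HES_SYN
A  [      1.00      97.00       1.00       1.00       1.00       1.00       1.00       1.00 ]
C  [     97.00       1.00      97.00       1.00      97.00       1.00       1.00       1.00 ]
G  [      1.00       1.00       1.00      97.00       1.00      97.00       1.00       1.00 ]
T  [      1.00       1.00       1.00       1.00       1.00       1.00      97.00      97.00 ]
>RBPJ_SYN_shuf RBPJ_SYN_shuffled
A  [      1.00       1.00       1.00      97.00      97.00       1.00       1.00       1.00 ]
C  [      1.00       1.00       1.00       1.00       1.00       1.00       1.00      97.00 ]
G  [     97.00      97.00      97.00       1.00       1.00      97.00       1.00       1.00 ]
T  [      1.00       1.00       1.00       1.00       1.00       1.00      97.00       1.00 ]
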
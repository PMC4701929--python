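1 1 0.000000 0.000000 0.000000 5.000000 -1
2 3 0.000000 5.000000 0.000000 1.000000 1
3 3 0.000000 10.000000 0.000000 1.000000 2
4 3 6.000000 18.000000 0.000000 0.500000 3
5 3 -6.000000 18.000000 0.000000 0.500000 3
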
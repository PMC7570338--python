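imidazole
  molcolor

  5  5  0  0  0  0  0  0  0  0999 V2000
    0.0000    1.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
   -0.9511    0.3090    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5878   -0.8090    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    0.5878   -0.8090    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.9511    0.3090    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  2  0  0  0  0
  3  4  1  0  0  0  0
  4  5  2  0  0  0  0
  5  1  1  0  0  0  0
M  END
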
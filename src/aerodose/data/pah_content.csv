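analyte,CAP,CAP_sd,JEP,JEP_sd,NIST1650B,NIST1650B_sd,NIST2975,NIST2975_sd
Naphthalene,ND,,ND,,0.007,0.0004,0.004,0.0001
Acenaphthylene,0.009,0.0009,0.01,0.002,0.001,0.00004,ND,
Acenaphthene,ND,,ND,,0.0002,0.00002,0.0005,0.00003
Fluorene,0.001,0.00007,0.001,0.0002,0.001,0.00004,0.003,0.0002
Phenanthrene,0.008,0.0005,0.001,0.00008,0.07,0.004,0.02,0.0003
Anthracene,ND,,0.001,,0.008,0.0004,0.00005,0.000002
Fluoranthene,0.008,0.00007,0.001,0.00008,0.05,0.001,0.03,0.0005
Pyrene,0.04,0.0007,0.007,0.00007,0.04,0.001,0.002,0.0002
Benz(a)anthracene,ND,,ND,,0.006,0.0004,0.001,0.00004
Chrysene,ND,,ND,,0.01,0.0006,0.006,0.0001
Benzo(b)fluoranthene+Benzo(k)fluoranthene,0.01,0.0009,0.02,,0.009,0.0009,0.01,0.003
Benzo(a)pyrene,0.005,0.0004,0.009,0.0004,0.001,0.0001,0.0008,0.00004
Dibenz(a.h)anthracene,ND,,ND,,0.0004,0.00008,0.0005,0.00005
Indeno(1.2.3-cd)pyrene,ND,,ND,,0.004,0.0002,0.002,0.0001
Benzo(g.h.i)perylene,ND,,ND,,0.006,0.0003,0.002,0.00009
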
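#  BLOSUM62 target (pair) frequencies, lower triangle, 4 decimal places.
#  SYNTHETIC RECONSTRUCTION: the original NCBI toolkit frequency file is not
#  redistributed here.  This table was transcribed from the published BLOSUM62
#  target frequencies and every cell was checked for consistency with the
#  integer half-bit log-odds matrix via s = round(2*log2(q_ab/(p_a*p_b)));
#  cells that failed the check beyond the 4-decimal rounding band were
#  replaced by the nearest 4-decimal value inside the band implied by the
#  integer matrix.  Marginals reproduce the published BLOSUM62 background
#  amino-acid frequencies to 4 decimals.
   A    R    N    D    C    Q    E    G    H    I    L    K    M    F    P    S    T    W    Y    V
0.0215
0.0023 0.0178
0.0019 0.0020 0.0141
0.0022 0.0016 0.0037 0.0213
0.0016 0.0004 0.0004 0.0004 0.0119
0.0019 0.0025 0.0015 0.0016 0.0003 0.0073
0.0030 0.0027 0.0022 0.0049 0.0003 0.0035 0.0161
0.0058 0.0017 0.0029 0.0025 0.0006 0.0014 0.0019 0.0378
0.0011 0.0012 0.0014 0.0010 0.0002 0.0010 0.0014 0.0010 0.0093
0.0032 0.0012 0.0010 0.0012 0.0011 0.0009 0.0012 0.0014 0.0006 0.0184
0.0044 0.0024 0.0014 0.0015 0.0016 0.0016 0.0020 0.0021 0.0010 0.0114 0.0371
0.0033 0.0062 0.0024 0.0024 0.0005 0.0031 0.0041 0.0025 0.0012 0.0016 0.0025 0.0161
0.0013 0.0008 0.0005 0.0005 0.0004 0.0008 0.0007 0.0007 0.0003 0.0025 0.0049 0.0009 0.0040
0.0016 0.0009 0.0008 0.0008 0.0005 0.0005 0.0009 0.0012 0.0008 0.0030 0.0054 0.0009 0.0012 0.0183
0.0022 0.0010 0.0009 0.0015 0.0004 0.0008 0.0014 0.0014 0.0005 0.0010 0.0014 0.0016 0.0005 0.0005 0.0191
0.0063 0.0023 0.0031 0.0028 0.0010 0.0019 0.0030 0.0038 0.0011 0.0017 0.0024 0.0031 0.0009 0.0012 0.0017 0.0126
0.0037 0.0018 0.0022 0.0019 0.0009 0.0014 0.0020 0.0022 0.0007 0.0027 0.0033 0.0023 0.0010 0.0012 0.0014 0.0047 0.0125
0.0004 0.0003 0.0002 0.0002 0.0002 0.0002 0.0003 0.0005 0.0002 0.0003 0.0007 0.0003 0.0002 0.0008 0.0001 0.0003 0.0003 0.0066
0.0013 0.0009 0.0007 0.0006 0.0004 0.0007 0.0009 0.0008 0.0015 0.0014 0.0022 0.0010 0.0006 0.0042 0.0005 0.0010 0.0009 0.0009 0.0102
0.0051 0.0013 0.0012 0.0013 0.0014 0.0012 0.0017 0.0018 0.0006 0.0120 0.0095 0.0019 0.0023 0.0026 0.0012 0.0024 0.0036 0.0004 0.0015 0.0196
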
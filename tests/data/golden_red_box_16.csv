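158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240,158,201,240
154,154,146,154,154,146,154,154,146,127,127,121,127,127,121,154,154,146,154,154,146,154,154,146,127,127,121,127,127,121,127,127,121,154,154,146,154,154,146,127,127,121,127,127,121,127,127,121
127,127,121,154,154,146,154,154,146,154,154,146,127,127,121,127,127,121,127,127,121,127,127,121,154,154,146,154,154,146,154,154,146,154,154,146,127,127,121,127,127,121,127,127,121,154,154,146
127,127,121,154,154,146,127,127,121,154,154,146,127,127,121,154,154,146,127,127,121,154,154,146,127,127,121,154,154,146,127,127,121,154,154,146,127,127,121,154,154,146,127,127,121,154,154,146
181,181,171,98,98,95,183,183,174,184,184,175,95,95,92,186,186,176,186,186,177,94,94,91,187,187,177,94,94,91,95,95,91,185,185,176,96,96,93,97,97,94,182,182,173,100,100,96
76,76,74,206,206,195,207,207,196,73,73,71,209,209,197,209,209,198,71,71,70,71,71,70,210,210,198,209,209,198,71,71,70,72,72,70,208,208,197,73,73,72,74,74,73,205,205,194
220,220,208,59,59,59,59,59,58,58,58,57,223,223,211,224,224,211,57,57,56,57,57,56,224,224,212,224,224,211,57,57,57,57,57,57,223,223,210,222,222,210,221,221,209,60,60,60
230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,230,230,217,230,230,217,199,23,23,199,23,23,51,51,51,51,51,51,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51
230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,163,19,19,163,19,19,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51
230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,163,19,19,163,19,19,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51
230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51
51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217
51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217
51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217
230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51,51,51,51
230,230,217,230,230,217,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,51,230,230,217,230,230,217,230,230,217,230,230,217,230,230,217,230,230,217,51,51,51,51,51,51
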
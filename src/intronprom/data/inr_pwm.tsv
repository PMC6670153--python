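# Initiator (INR) core-promoter element position frequency matrix.
# Canonical mammalian initiator consensus YYANWYY (pyrimidine/pyrimidine/
# A(+1)/any/A-or-T/pyrimidine/pyrimidine), frequencies hand-set to that
# consensus profile after Bucher-style Inr descriptions; not the matrix of
# any single prediction server, which is why the matrix is a configurable
# input to the scanner rather than a constant.
# plus_one_offset=2
# pseudocount=0.01
A	C	G	T
0.08	0.36	0.10	0.46
0.07	0.49	0.06	0.38
0.82	0.04	0.08	0.06
0.30	0.22	0.24	0.24
0.39	0.11	0.09	0.41
0.10	0.42	0.08	0.40
0.09	0.37	0.11	0.43
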
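c_position	ref	alt	rsid	effect	aa_change
33	C	A		unknown
82	C	T		unknown
191	G	A	rs1801279	nonsynonymous	p.Arg64Gln
282	C	T	rs1041983	synonymous	p.Tyr94=
341	T	C	rs1801280	nonsynonymous	p.Ile114Thr
345	C	T		unknown
481	C	T	rs1799929	synonymous	p.Leu161=
518	A	G		unknown
590	G	A	rs1799930	nonsynonymous	p.Arg197Gln
609	G	T		unknown
622	T	C		unknown
803	A	G	rs1208	nonsynonymous	p.Lys268Arg
857	G	A	rs1799931	nonsynonymous	p.Gly286Glu
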
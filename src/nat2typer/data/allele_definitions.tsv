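name	snps	function	group
NAT2*4	(none)	rapid	*4
NAT2*5A	c.341T>C,c.481C>T	slow	*5
NAT2*5B	c.341T>C,c.481C>T,c.803A>G	slow	*5
NAT2*5C	c.341T>C,c.803A>G	slow	*5
NAT2*6A	c.282C>T,c.590G>A	slow	*6
NAT2*7B	c.282C>T,c.857G>A	slow	*7
NAT2*11A	c.481C>T	rapid	*11
NAT2*12A	c.803A>G	rapid	*12
NAT2*12B	c.282C>T,c.803A>G	rapid	*12
NAT2*12C	c.481C>T,c.803A>G	rapid	*12
NAT2*13A	c.282C>T	rapid	*13
NAT2*14B	c.191G>A,c.282C>T	slow	*14
NAT2*5AA	c.82C>T,c.341T>C,c.481C>T	slow	*5
NAT2*5BA	c.33C>A,c.341T>C,c.481C>T,c.803A>G	slow	*5
NAT2*5BB	c.341T>C,c.345C>T,c.481C>T,c.803A>G	slow	*5
NAT2*5CA	c.33C>A,c.341T>C,c.803A>G	slow	*5
NAT2*12Q	c.33C>A,c.803A>G	unknown	*12
NAT2*12R	c.518A>G,c.609G>T,c.803A>G	unknown	*12
NAT2*12S	c.33C>A,c.481C>T,c.803A>G	unknown	*12
NAT2*13H	c.33C>A,c.282C>T	unknown	*13
NAT2*28	c.622T>C	unknown	*28
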
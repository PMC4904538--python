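year,months,concentration,potency,description,group,end_year
1965,4,1,6,Plant A,Product A,
1966,2,1,6,Plant A,Product A,
1966,10,1,1,,misc. products,
1967,12,1,1,,misc. products,
1968,12,1,1,,misc. products,
1969,11.5,1,1,,misc. products,
1970,12,1,1,,misc. products,
1969,0.5,1,6,,Product A,
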
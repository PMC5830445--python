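# rumenmags 0.1.0 config=334ec7f2416b
pul_id	genome_id	contig_id	start	end	n_genes	signature	simple
demo:demo_c1:1	demo	demo_c1	10001	11900	2	susC-susD	1
demo:demo_c2:1	demo	demo_c2	10001	17900	8	GH43-GH10 | GH67-GH35-susC-susD-unc-GH10	0
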
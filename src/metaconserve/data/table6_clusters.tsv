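sample	total	singleton	mixed	dna_only	rna_only	ident_mixed	ident_dna_only
OMZ 50 m	213683	180311	1804	26505	5063	77.0	85.2
OMZ 200 m	257388	209564	2712	40401	4711	79.4	83.7
HOT 75 m	353573	297850	5681	44163	5879	80.3	82.9
HOT 500 m	500413	425524	4677	66151	4061	73.7	79.7
Soil	1277816	1046744	29980	141158	59934	72.6	87.5
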
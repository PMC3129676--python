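site	depth	dna_all	dna_only	dna_shared	rna_all
OMZ	50	37.6	38.2	36.0	42.8
OMZ	85	38.2	38.4	36.7	44.9
OMZ	110	41.1	42.6	38.1	42.8
OMZ	200	40.9	41.9	38.6	45.6
BATS216	20	34.5	35.4	33.8	42.8
BATS216	50	35.2	36.4	33.9	40.3
BATS216	100	33.7	34.7	32.9	37.8
HOT186	25	35.5	36.0	34.8	44.0
HOT186	75	34.9	35.2	34.4	41.4
HOT186	110	36.0	36.4	35.0	40.0
HOT186	500	43.2	43.1	43.5	50.6
Soil	Surface	62.7	63.1	62.5	62.6
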
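site	depth	pool	shared	dna_only	rna_only	all_genes
OMZ	50	DNA	71.0	59.8	NA	60.8
OMZ	50	RNA	73.8	NA	72.2	72.7
OMZ	85	DNA	67.3	59.5	NA	59.8
OMZ	85	RNA	68.4	NA	67.9	68.1
OMZ	110	DNA	65.7	58.7	NA	59.7
OMZ	110	RNA	68.5	NA	71.1	70.2
OMZ	200	DNA	64.3	58.5	NA	59.1
OMZ	200	RNA	67.0	NA	65.9	66.4
BATS216	20	DNA	72.5	59.5	NA	62.7
BATS216	20	RNA	75.6	NA	71.6	72.9
BATS216	50	DNA	76.4	61.5	NA	64.4
BATS216	50	RNA	78.3	NA	71.2	74.1
BATS216	100	DNA	76.8	60.5	NA	63.9
BATS216	100	RNA	78.6	NA	71.6	74.8
HOT186	25	DNA	75.3	63.7	NA	65.7
HOT186	25	RNA	76.4	NA	69.1	72.0
HOT186	75	DNA	77.3	64.1	NA	65.6
HOT186	75	RNA	77.5	NA	69.1	72.9
HOT186	110	DNA	80.0	60.7	NA	62.4
HOT186	110	RNA	81.3	NA	73.0	77.1
HOT186	500	DNA	63.1	59.4	NA	59.6
HOT186	500	RNA	64.0	NA	66.0	65.0
Soil	Surface	DNA	58.9	55.0	NA	56.1
Soil	Surface	RNA	59.8	NA	61.1	60.5
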
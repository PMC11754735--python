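chr1	toy	gene	1001	4000	.	+	.	gene_id "TG1"; gene_type "protein_coding"; gene_name "ALPHA";
chr1	toy	gene	15001	18000	.	+	.	gene_id "TG2"; gene_type "protein_coding"; gene_name "BETA";
chr1	toy	gene	16001	17000	.	-	.	gene_id "TG3"; gene_type "lncRNA"; gene_name "GAMMA";
chr2	toy	gene	501	2500	.	-	.	gene_id "TG4"; gene_type "protein_coding"; gene_name "DELTA";
chr2	toy	gene	30001	33000	.	+	.	gene_id "TG5"; gene_type "protein_coding"; gene_name "EPSILON";
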
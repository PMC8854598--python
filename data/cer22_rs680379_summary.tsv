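# Published GWAS summary associations of rs680379 (SPTLC3 region) with plasma
# Cer22:0, per SD of the log-transformed, variance-standardized phenotype
# (EPIC-Potsdam, EUROSPAN) or per uM (FHSOC).  Allele codes are reconstructed
# (synthetic labels): the sources print betas without alleles, and the sign
# pattern implies EPIC-Potsdam and FHSOC report the opposite effect allele
# from EUROSPAN.
cohort	snp	effect_allele	other_allele	beta	se	p	n
epic_potsdam	rs680379	A	G	-0.201	0.039	2.3e-07	1094
eurospan	rs680379	G	A	0.054	0.007	1.3e-13	4034
fhsoc	rs680379	A	G	-0.031	0.005	4.0e-11	2217
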
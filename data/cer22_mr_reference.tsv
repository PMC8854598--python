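# Published single-instrument MR of Cer22:0 on type 2 diabetes using the
# EUROSPAN SNP-exposure association and DIAGRAM SNP-outcome summary data
# (74,124 cases / 824,006 controls).  The DIAGRAM outcome association itself
# is not printed in the source; it is recovered from this row as
# beta_outcome = WR x beta_exposure, se_outcome = SE x beta_exposure.
cohort	snp	wr	se	p
eurospan	rs680379	0.259	0.120	0.031
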
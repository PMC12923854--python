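# Upload-file dialect for the batch phenotyping web service.
#
# The exact header spelling used by the hosted tool is not reproduced in
# the open literature; this file documents the assumed spelling so it can
# be corrected without code changes.  Probe columns are named
# "<rsid>_<counted allele>" in catalog order.
sample_column: sampleid
na_token: "NA"
probe_column_pattern: "{rsid}_{counted_allele}"
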
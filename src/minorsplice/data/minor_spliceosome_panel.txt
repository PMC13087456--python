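# Minor spliceosome gene panel (one gene per line; optional second column: coding flag).
# The snRNA components are non-coding; protein components are coding.
# This list is an editable placeholder panel and can be replaced by the user.
RNU4ATAC	noncoding
RNU6ATAC	noncoding
RNU11	noncoding
RNU12	noncoding
RNPC3	coding
ZRSR2	coding
ZCRB1	coding
PDCD7	coding
SNRNP25	coding
SNRNP35	coding
SNRNP48	coding
CENATAC	coding
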
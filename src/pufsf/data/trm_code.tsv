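pos1	pos5	base	provenance
N	Q	U	canonical Pumilio-repeat code; NQ edge pair reads uracil
C	Q	A	canonical code; CQ edge pair reads adenine
S	Q	A	canonical code; SQ edge pair reads adenine
S	E	G	canonical code; SE edge pair reads guanine
S	R	C	engineered-repeat code; SR edge pair reads cytosine
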
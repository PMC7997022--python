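individual	CFAP65:p.T1023A	RFT1:p.A463G	NRXN2:p.G849D	TEP1:p.Y412C	CCNF:p.C363S
III-8	present	present	present	present	present
III-7	present	present	present	present	present
IV-2	present	present	present	present	present
III-6	present	present	present	present	present
III-2	present	absent	absent	absent	absent
III-4	absent	absent	absent	absent	present
IV-1	absent	absent	absent	absent	present
III-1	absent	absent	absent	absent	present
III-5	absent	absent	absent	absent	absent
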
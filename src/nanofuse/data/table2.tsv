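sample_id	group	rin_class	truth_fusion	called_fusion
CBTS-1	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-18	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-6	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-4	A	>3	SSBP2::CSF1R	SSBP2::CSF1R
CBTS-22	A	>3	NUP214::ABL1	NUP214::ABL1
CBTS-23	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-24	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-2	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-3	A	>3	P2RY8::CRLF2;MYO18B::ABL1	P2RY8::CRLF2;MYO18B::ABL1
CBTS-8	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-17	A	>3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-7	A	>3	NUP214::ABL1	NUP214::ABL1
CBTS-16	A	>3	PAX5::JAK2	PAX5::JAK2
CBTS-25	A	>3	ZBTB5::JAK2	ZBTB5::JAK2
CBTS-15	A	>3	ETV6::ABL1	-
CBTS-9	A	>3	-	-
CBTS-10	A	>3	-	-
CBTS-11	A	>3	-	-
CBTS-12	A	>3	-	-
CBTS-13	A	>3	-	-
CBTS-14	A	>3	-	-
CBTS-5	A	>3	-	-
CBTS-19	A	>3	-	-
CBTS-20	A	>3	-	-
CBTS-21	A	>3	-	-
CBTS-26	A	>3	-	-
CBTS-30	B	<=3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-27	B	<=3	P2RY8::CRLF2	P2RY8::CRLF2
CBTS-29	B	<=3	EBF1::PDGFRB	EBF1::PDGFRB
CBTS-32	B	<=3	EBF1::PDGFRB	EBF1::PDGFRB
CBTS-35	B	<=3	PAX5::JAK2	PAX5::JAK2
CBTS-28	B	<=3	NUP214::ABL1	-
CBTS-34	B	<=3	P2RY8::CRLF2	-
CBTS-31	B	<=3	-	-
CBTS-33	B	<=3	-	-
CBTS-36	C	unknown	EBF1::PDGFRB	EBF1::PDGFRB
CBTS-38	C	unknown	IGH::EPOR	ENSG00000277856::EPOR
CBTS-37	C	unknown	unknown::CRLF2	-
CBTS-39	C	unknown	unknown::CRLF2	-
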
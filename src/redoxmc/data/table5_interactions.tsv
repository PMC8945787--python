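res	id	FX_S1	FX_S2	FX_S3	FX_S4	FX_tot	FA_S1	FA_S2	FA_S3	FA_S4	FA_tot	FB_S1	FB_S2	FB_S3	FB_S4	FB_tot
K	C51	-3.2	-2.6	-2.3	-1.8	-9.9	-5.5	-16.9	-5	-5.6	-33	-0.8	-0.7	-1.5	-1.2	-4.2
R	A583	-3.5	-1.9	-1.8	-2.2	-9.4	-2.5	-4.1	-6.2	-4.3	-17			-0.5	-0.5	-1
R	C65	-1.8	-2.2	-1.7	-1.3	-7	-2.1	-2.9	-1.4	-1.9	-8.3	-0.9	-1.1	-2.1	-1.6	-5.7
H	C2	-1.4	-1	-1.1	-0.8	-4.3	-1.9	-2.7	-2.1	-1.3	-8					0
R	D60	-1.1	-0.6	-0.7	-0.8	-3.2	-1.4	-1.6	-3.2	-1.6	-7.8					0
R	B674	-4.1	-2.3	-3.3	-3.2	-13	-0.8	-1.5	-1.3	-0.9	-4.5					0
R	B570	-1.5	-2.2	-1.5	-1.2	-6.4	-0.9	-1.4	-0.7	-1.1	-4.1	-0.5	-0.8	-1	-1	-3.3
K	D61					0	-2.3	-1.3	-2.7	-1.7	-8	-0.5		-0.5		-1
R	B18	-1.6	-1.1	-1.6	-1.2	-5.5	-0.7	-1.2	-0.8	-0.6	-3.3					0
R	C43					0	-2.1	-1	-1.6	-1.2	-5.9	-0.7		-0.7	-0.5	-1.9
K	A569	-2.4	-1.6	-1.6	-2.5	-8.1	-0.6	-0.9	-1.1	-0.9	-3.5					0
K	D134	-0.7	-0.6	-0.8	-0.5	-2.6		-0.7			-0.7					0
R	C74					0	-0.8	-0.7	-1.4	-0.6	-3.5					0
R	A694	-2.1	-4	-2.6	-3.1	-12		-0.6		-0.5	-1.1					0
K	A555	-2	-1.4	-1.7	-2.3	-7.4		-0.6	-0.7	-0.6	-1.9					0
K	B556	-1.7	-2.3	-2.9	-1.9	-8.8		-0.6			-0.6					0
R	A437	-0.8	-0.6	-0.6	-0.9	-2.9		-0.5	-0.6	-0.5	-1.6					0
R	A564	-0.7	-0.5	-0.5	-0.7	-2.4		-0.5	-0.7		-1.2					0
R	B399	-0.7	-0.6	-0.9	-0.6	-2.8		-0.5			-0.5					0
T	C22					0	-0.5	-0.5	-3	-0.5	-4.5					0
T	A586	-1.7				-1.7					0					0
K	B542	-1.3	-1.8	-2.3	-1.7	-7.1					0					0
H	A734	-0.9	-1.1	-1.2	-1.6	-4.8					0					0
R	A575	-0.8	-0.9	-0.7	-1.1	-3.5					0					0
R	B712	-0.8	-0.8	-5.2	-1.3	-8.1					0					0
R	A720	-0.7	-1.3	-0.9	-1	-3.9					0					0
R	A728	-0.7		-0.5	-1.9	-3.1					0					0
H	B392	-0.7	-0.6	-0.9	-0.6	-2.8					0					0
H	A411	-0.6	-0.6	-0.6	-0.8	-2.6					0					0
H	B28	-0.5		-0.7	-0.5	-1.7					0					0
K	B418	-0.5	-0.6	-0.7	-0.5	-2.3					0					0
R	A418				-0.5	-0.5					0					0
H	A542				-0.5	-0.5					0					0
H	A56		-0.5		-0.6	-1.1					0					0
H	B534			-0.5	-0.5	-1					0					0
T	B573		-1.9			-1.9					0					0
I	B708			-0.5		-0.5					0					0
Q	C15					0					0	-0.5	-0.5		-1.2	-2.2
R	C18					0	-0.5		-0.5	-0.7	-1.7	-0.6			-0.5	-1.1
K	C5					0	-0.5				-0.5			-0.5		-0.5
T	C55					0					0					0
T	C59					0					0		-0.6	-0.5		-1.1
I	C64					0					0			-0.5		-0.5
R	D109					0	-0.6				-0.6	-1		-0.6	-0.5	-2.1
N	D113					0	-0.6				-0.6					0
K	D26					0					0					0
R	D73					0	-0.6		-0.6	-0.7	-1.9					0
R	D84					0	-0.5		-0.7		-1.2					0
R	E11					0					0	-0.5	-1.2	-0.8	-0.6	-3.1
K	E33					0					0	-0.5	-0.8	-0.7		-2
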
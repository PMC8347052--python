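protein	variant	avg_ddg	sd
TYR	R402Q	-0.5	0.5
TYR	S192Y	-0.27	0.78
TYR	R402Q+S192Y	-0.77	1.09
OCA2	A481T	-1.01	0.52
OCA2	H615L	0.17	0.39
OCA2	N489D	-1.05	1.08
OCA2	P743L	-0.9	0.45
OCA2	R419Q	-0.54	0.33
OCA2	V443I	-0.54	0.48
SLC45A2	G198V	-0.51	0.25
SLC45A2	L374F	-0.84	0.47
TPC2	K376R	-0.49	0.3
TPC2	M484L	-0.86	0.33
TPC2	M546I	-0.1	0.67
TPC2	V219I	-0.11	0.32
ATP7A	C1002F	-1.2	0.74
ATP7A	G666R	-0.21	0.7
ATP7A	D1044E	-0.8	0.53
ATP7A	I1264V	-1.1	0.74
ATP7A	K742R	0.01	0.35
ATP7A	M1311V	-0.79	0.35
ATP7A	R844C	-0.48	0.39
ATP7A	S653Y	-0.45	0.54
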
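name	mode	value
a	0	0.719818957493
a	1	2.32330068539
a	2	0.719818957493
b	0	2.54526435119
b	1	4.57271321739
b	2	2.54526435119
c	0	1.17865949704
c	1	0.656065634859
c	2	1.17865949704
d	0	4.24210725198
d	1	7.62118869566
d	2	4.24210725198
e	0	0.719818957493
e	1	2.32330068539
e	2	0.719818957493
f	0	2.54526435119
f	1	4.57271321739
f	2	2.54526435119
h	0	1.17865949704
h	1	0.656065634859
h	2	1.17865949704
p	0	4.24210725198
p	1	7.62118869566
p	2	4.24210725198
IE	0	2.58146438881
IE	1	2.03380346806
IE	2	4.72622449282
II	0	2.58146438881
II	1	2.03380346806
II	2	4.72622449282
m	0	-0.0452605246862
m	1	-0.0251929203786
m	2	-0.0452605246862
n	0	-0.0452605246862
n	1	-0.0251929203786
n	2	-0.0452605246862
A00	0	0.332816581119
A01	0	0.598453793354
A02	0	0.332816581119
A10	1	0.185252417795
A11	1	0.333111444703
A12	1	0.185252417795
A20	2	0.332816581119
A21	2	0.598453793354
A22	2	0.332816581119
B00	0	0.332816581119
B01	0	0.598453793354
B02	0	0.332816581119
B10	1	0.185252417795
B11	1	0.333111444703
B12	1	0.185252417795
B20	2	0.332816581119
B21	2	0.598453793354
B22	2	0.332816581119
C00	0	0.332816581119
C01	0	0.598453793354
C02	0	0.332816581119
C10	1	0.185252417795
C11	1	0.333111444703
C12	1	0.185252417795
C20	2	0.332816581119
C21	2	0.598453793354
C22	2	0.332816581119
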
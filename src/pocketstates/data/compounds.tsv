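compound_id	kd_molar	formula	note
4	820e-6	C7H4I2O3	3,5-diiodosalicylic acid scaffold; KD 820 +/- 70 uM (NMR)
9	21e-6	C11H7I2NO3	scaffold 4 with 1H-pyrrol-1-yl at position 4; KD 21 uM (ITC)
1	125e-6		PhiKan083 carbazole; KD 125 +/- 10 uM (ITC)
2	470e-6		indole fragment; KD 470 +/- 90 uM (NMR)
3	9.7e-6		iodophenol-acetylene; KD 9.7 uM (ITC)
5	1040e-6		bromo compound, halogen bond to Leu145 O; KD 1040 +/- 110 uM (NMR)
6	940e-6		substituted indole; KD 940 +/- 110 uM (NMR)
7	2400e-6		pyrazole PhiKan7242; KD 2400 +/- 300 uM (NMR)
11	4800e-6		subsite-III fragment; KD 4800 +/- 900 uM (NMR)
12	1270e-6		chlorophenol amide; KD 1270 +/- 570 uM (NMR)
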
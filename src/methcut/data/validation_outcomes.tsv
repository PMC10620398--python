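gene	comparison	meth_outcome	expr_outcome	agreement
AP5Z1	T30_vs_T0	N.S.	Down-regulation
AP5Z1	T90_vs_T0	De-methylation	Up-regulation	Yes
AP5Z1	T90_vs_T30	De-methylation	Up-regulation	Yes
ARFGAP2	T30_vs_T0	N.S.	Down-regulation
ARFGAP2	T90_vs_T0	De-methylation	N.S.
ARFGAP2	T90_vs_T30	De-methylation	Up-regulation	Yes
EVI5	T30_vs_T0	N.S.	N.S.
EVI5	T90_vs_T0	De-methylation	N.S.
EVI5	T90_vs_T30	De-methylation	N.S.
GRID1	T30_vs_T0	Methylation	N.S.
GRID1	T90_vs_T0	De-methylation	N.S.
GRID1	T90_vs_T30	N.S.	N.S.
LHX1	T30_vs_T0	Methylation	N.S.
LHX1	T90_vs_T0	N.S.	N.S.
LHX1	T90_vs_T30	N.S.	N.S.
RADIL	T30_vs_T0	N.S.	Down-regulation
RADIL	T90_vs_T0	De-methylation	N.S.
RADIL	T90_vs_T30	De-methylation	Up-regulation	Yes
ATP2A3	T30_vs_T0	Methylation	Down-regulation	Yes
ATP2A3	T90_vs_T0	Methylation	N.S.
ATP2A3	T90_vs_T30	N.S.	Up-regulation
RGS19	T30_vs_T0	Methylation	Down-regulation	Yes
RGS19	T90_vs_T0	N.S.	N.S.
RGS19	T90_vs_T30	N.S.	Up-regulation
SCAND1	T30_vs_T0	N.S.	N.S.
SCAND1	T90_vs_T0	De-methylation	Up-regulation	Yes
SCAND1	T90_vs_T30	De-methylation	N.S.
TTC7A	T30_vs_T0	N.S.	Down-regulation
TTC7A	T90_vs_T0	N.S.	N.S.
TTC7A	T90_vs_T30	De-methylation	Up-regulation	Yes
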
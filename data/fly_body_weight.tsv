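line_id	mean	se	n
WT	91.49	0.40	579
eyw	89.59	2.79	564
w1118	104.78	2.61	514
WTxeyw	102.66	1.03	410
w1118xWT	109.90	1.06	445
eywxWT	109.05	2.54	419
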
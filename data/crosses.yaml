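# Body-weight crosses: father x mother -> F1, line ids per data/fly_body_weight.tsv
crosses:
  - cross_id: WTxeyw
    f1: WTxeyw
    father: WT
    mother: eyw
  - cross_id: w1118xWT
    f1: w1118xWT
    father: w1118
    mother: WT
  - cross_id: eywxWT
    f1: eywxWT
    father: eyw
    mother: WT
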
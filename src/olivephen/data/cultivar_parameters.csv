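cultivar,maturity_class,tc,cr,tb,tx_base,hr_bloom,hr_pit
Carolea,early,9.5,-115,5.9,31.5,437,1074
Picholine,early,8.2,-122,7.0,28.3,568,1003
Moraiolo,mid-late,11.2,-133,4.5,29.5,370,1315
Frantoio,mid-late,9.7,-137,5.3,26.3,388,1275
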
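cultivar,maturity_class,phase,jday
Carolea,early,sprouting,96
Carolea,early,blooming,138
Carolea,early,pit_hardening,186
Picholine,early,sprouting,97
Picholine,early,blooming,140
Picholine,early,pit_hardening,187
Frantoio,mid-late,sprouting,124
Frantoio,mid-late,blooming,148
Frantoio,mid-late,pit_hardening,214
Moraiolo,mid-late,sprouting,134
Moraiolo,mid-late,blooming,151
Moraiolo,mid-late,pit_hardening,215
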
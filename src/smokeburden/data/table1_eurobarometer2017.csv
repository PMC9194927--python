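country,prev_current,prev_current_lo,prev_current_hi,rank_current,pack_years,pack_years_lo,pack_years_hi,rank_pack_years,disc_pack_years,disc_pack_years_lo,disc_pack_years_hi,rank_disc_pack_years
AT,28.3,25.2,31.6,9,10.6,9.3,11.8,3,7.4,6.3,8.4,3
BE,19.2,16.6,22.0,25,7.8,6.8,8.8,15,4.6,3.9,5.3,19
BG,36.1,33.2,39.2,2,8.9,8.0,9.8,8,7.0,6.2,7.8,4
HR,35.3,32.3,38.4,4,11.9,10.6,13.2,2,8.9,7.8,10.1,2
CY,27.5,23.4,32.1,12,10.2,8.5,11.9,5,6.7,5.4,7.9,6
CZ,28.9,26.1,31.9,8,8.3,7.3,9.2,12,6.1,5.3,7.0,8
DK,18.6,16.1,21.4,26,8.2,7.3,9.2,13,4.7,4.0,5.4,18
EE,23.3,20.4,26.5,20,5.7,5.0,6.4,26,4.1,3.5,4.8,26
FI,20.1,17.5,23.0,22,6.7,5.9,7.4,22,4.1,3.5,4.8,26
FR,35.9,32.6,39.4,3,9.9,8.8,11.0,6,7.0,6.1,7.9,4
DE,25.8,23.3,28.6,16,8.8,7.8,9.8,9,5.6,4.8,6.4,13
EL,36.6,33.5,39.8,1,13.9,12.5,15.2,1,10.0,8.9,11.2,1
HU,26.6,23.8,29.6,14,8.1,7.2,9.0,14,6.0,5.2,6.7,11
IE,19.4,16.9,22.2,24,6.4,5.6,7.3,24,4.2,3.5,4.8,23
IT,24.6,22.0,27.5,18,7.6,6.7,8.5,16,4.9,4.2,5.6,16
LV,32.2,28.4,36.3,5,7.4,6.2,8.6,17,5.7,4.6,6.7,12
LT,29.1,26.0,32.5,7,5.8,5.1,6.5,25,4.5,3.9,5.2,21
LU,21.0,17.3,25.3,21,7.0,5.7,8.4,20,4.6,3.5,5.7,19
MT,24.0,19.7,28.9,19,10.3,8.3,12.3,4,6.1,4.6,7.5,8
PL,29.8,26.9,32.9,6,8.7,7.7,9.6,10,6.4,5.5,7.2,7
PT,25.6,23.0,28.4,17,5.2,4.5,6.0,28,4.8,4.1,5.5,17
RO,28.0,25.2,30.9,10,7.2,6.2,8.3,19,5.5,4.6,6.4,14
SK,26.4,23.5,29.6,15,5.7,5.0,6.4,26,4.3,3.7,4.9,22
SI,27.9,25.0,31.0,11,9.4,8.3,10.5,7,6.1,5.2,6.9,8
ES,27.5,24.8,30.4,12,8.6,7.6,9.5,11,5.0,4.3,5.7,15
SE,7.2,5.3,9.7,28,6.5,5.4,7.6,23,2.2,1.6,2.8,28
NL,19.5,17.0,22.3,23,7.3,6.5,8.2,18,4.2,3.5,4.9,23
UK,17.5,15.2,20.1,27,6.8,6.0,7.7,21,4.2,3.6,4.8,23
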
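symbol	group	meg_direction	deg_direction	class
AFTPH	responder	up	down	good
ALOX5	responder	up	down	good
ATG7	responder	up	down	good
MYD88	responder	up	down	good
LILRB1	responder	up	down	good
PRKAB1	responder	up	down	good
PSEN1	responder	up	down	good
VAMP3	responder	up	down	good
AGFG1	responder	up	up	bad
CHM	responder	up	up	bad
IGLL1	responder	down	down	bad
PELI1	responder	up	up	bad
PTEN	responder	up	up	bad
NAP1L4	nonresponder	down	down	bad
MMS19	nonresponder	down	down	bad
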
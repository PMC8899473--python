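species	genus	toxin_name	clade	mature_sequence
Turris babylonia	Turris	Tba9.3	I	DACPGNEAKCFSTECTNPSSHGYDSQECQDACQYVWDYCSEE
Turris guidopoppei	Turris	Tgd9.1	I	DACPEYEAKCFSTECTDEDSDGYDSPECQAACQYVWDHCSED
Turris hidalgoi	Turris	Thd9.5	I	DACPENKVKCFSTECMNLESDGYDSAECQAACQYVYDQCPEE
Turris normandavidsoni	Turris	Tnr9.2	I	DACPENEAKCYSTECTNQQADGYDSSECQAACQYVWNHCSYE
Purpuraturris nadaensis	Purpuraturris	Pnd9.13	II	DLCDESLANCTSSSCQAELENENGSSACTEACDYWVANCQE
Purpuraturris cryptorrhaphe	Purpuraturris	Pcr9.4ii	II	DLCDEYLENCTSPYCQEQSNIQNGSSACNEACNYWDKNCRTPDEEQ
Purpuraturris cryptorrhaphe	Purpuraturris	Pcr9.4	II	DLCDEYLENCTSPYCQEQSNIQNGDGACNEACNYWDKNCRTPDEEQ
Purpuraturris nadaensis	Purpuraturris	Pna9.11	II	ACEDSLEECTSEFCIEQSATQNGNAACNSACNYWYHNCQE
Purpuraturris nadaensis	Purpuraturris	Pna9.12	II	DACEDHLEYCTSEFCIEQSYIQNGNATCQNACYDWYQNCQ
Purpuraturris nadaensis	Purpuraturris	Pna9.31	II	DACEDNLEDCTSEFCIEQSATQNGNAACNSACSDWYHNCQ
Purpuraturris cristata	Purpuraturris	Pcs9.1	II	DACESNLETCTSLECMTELQTQTASPACNNACSNYTSNC
Purpuraturris nadaensis	Purpuraturris	Pna9.29	II	DACQETFEYCTSDFCMEELEYEDANVTCVDACNIWLANCQ
Purpuraturris nadaensis	Purpuraturris	Pna9.10	II	DVCEENRVHCTSPFCQEELEYEDANVTCVDACNIWLANCQ
Purpuraturris nadaensis	Purpuraturris	Pna9.10ii	II	﻿DVCEENRVHCTSPFCQEELEYEDANVTCVDACNIWLANCQ
Purpuraturris undosa	Purpuraturris	Pun9.4	II	DVCEENRVHCTSPFCQEELEYEDANVTCVDACNIWLANCQ
Purpuraturris nadaensis	Purpuraturris	Pna9.2ii	II	DVCEDNRVYCTSPFCQEELEYEDANVTCVDACNIWLANCQE
Purpuraturris nadaensis	Purpuraturris	Pna9.2	II	DVCEDNRVYCTSPFCQEELEYEDANVTCVDACNIWFANCQE
Turris hidalgoi	Turris	Thd9.1	III	QNNNCGCGSADVGRNCPGFGFCSDGTCSVSNTCEF
Turris spectabilis	Turris	Tsp9.1	III	QNNNCGCASTDVGKPCPGSGLCGSGTCSVLNTCDFE
Turris spectabilis	Turris	Tsp9.2ii	III	NNNNCGCGSTDVGQPCPGYGLCNDGICSALNTCDFSVN
Turris spectabilis	Turris	Tsp9.2	III	NNNNCGCGSTDVGQPCPGYGLCNDGICSALNTCDFEI
Turris guidopoppei	Turris	Tgd9.5	III	QSNCGCGNTNVGLPCPGTGLCSGICSIAHTCESVDL
Turris hidalgoi	Turris	Thd9.2	III	QNCGCGNTGVDQPCPGSGMCINGICTVAYTCKT
Turris babylonia	Turris	Tba9.4	III	QNNCGCGHINVNQPCPESGSGCSGGYYSSAHTCEY
Turris babylonia	Turris	Tba9.5	III	QNNCGCSNRNAGYPCPESSNECSGGVCSLAHTCEL
Turris hidalgoi	Turris	Thd9.10	IV	WYDCTCEGVEVGSTCSGNNCAAVCRSDGGCWF
Turris normandavidsoni	Turris	Tnr9.4	IV	DDCSCEGVEVDSTCSGNSCAAICRSDGRCWI
Turris guidopoppei	Turris	Tgd9.6	IV	WYDCTCVEVGSTCSGNSCAAVCRSDVGCWI
Turris guidopoppei	Turris	Tgd9.15	IV	LYDCTCEGVEVGSTCSGNSCAAVCRSDGGCWI
Turris normandavidsoni	Turris	Tnr9.3ii	IV	HGCSCEGVEVGSTCSGNDCAAVCRSDGGCWIST
Turris normandavidsoni	Turris	Tnr9.3	IV	HGCSCEGVEVGSTCSGNDCAAVCRSDGGCWIST
Turris dollyae	Turris	Tdo9.4	IV	HGCSCEGVEVGSTCAGNDCAAVCRSDGGCWIST
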
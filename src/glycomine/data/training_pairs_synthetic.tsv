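pair_id	molecule	g	m	b
pair01	avilamycin	11111011000000000000000000000000100000000000000000	011000	11111011000000000000000000000011100010100000000100
pair02	2-deoxystreptamine	00000000000111100000000000000000000000000000000000	000000	00000000000111000000000000000010000000000000000000
pair03	acarbose	11000000010000000000000111000000000000000000000000	010000	11000000010000000000000100000011000000000000000000
pair04	apramycin	01100000000111100000000000000000000000000000000000	100000	01100000000111000000000000000010000001000000110000
pair05	butirosin	00000000000111100000000000000000000000000000000000	100001	00000000000111000000000000000011000000001100000000
pair06	fortimicin	00000000000000000000000000000100000000000000000000	100000	00000000000000000000000000000010000001100000100000
pair07	gentamicin	01000000000000000000000000001000010000000000000000	110000	01000000000000000000000000001011000000000000000000
pair08	hygromycin	11101011000000011000000000000000000000000000000000	000000	11101011000000010000000000000010000000000000000000
pair09	istamycin	00000000000000000000000000000100000000000000000000	100000	00000000000000000000000000000111000000000000000000
pair10	kanamycin	10000000101111100000000000000000000000000000000000	100000	10000000101111100000000000000010000000000000110000
pair11	lividomycin	11000011001111100000000000000000000000000000000000	001010	11000011001111100000000000000011000000000000000000
pair12	kasugamycin	01000000000000000000000000100000000100000000000000	010000	01000000000000000000000000100010000100000000000000
pair13	neomycin	00000000001111100000000000000000000000000000000000	100010	00000000001111000000000000000011000000000000110000
pair14	paromomycin	00000000001111100000000000000000000000000000000000	100010	00000000001111000000000000000010000000000000000000
pair15	ribostamycin	00000000000111100000000000000000000000000000000000	100010	00000000000111000000000000000011000000000010100000
pair16	sisomicin	01000000000100000000000000000000001000000000000000	110000	01000000000100000000000000000010000001000000100000
pair17	spectinomycin	11000000000000011000000000110000000000000000000000	000000	11000000000000011000000000110011000000000000000000
pair18	tobramycin	10000000101111100000000000000000000000000000000000	100000	10000000101111100000000000000010000000000000101000
pair19	streptomycin	11000110000000011111111000000000000000000000000000	000000	11000110000000011111000000000011000000000000000000
pair20	dhurrin	11101000000000000000000000000000000000000000000000	010000	11000000000000000000000000000010000000000000000000
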
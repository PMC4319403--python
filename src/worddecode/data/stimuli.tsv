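# Broad phonemic transcriptions of the eight animal-noun stimuli.
# Convention: non-rhotic British-style English (no coda /r/ in horse,
# shark) and broad standard Dutch (final devoicing in eend, paard; voiced
# glottal fricative in haai).  Long vowels carry the length mark and are
# single symbols; symbols are space-separated.
word	language	phonemes
bull	english	b ʊ l
duck	english	d ʌ k
horse	english	h ɔː s
shark	english	ʃ ɑː k
stier	dutch	s t iː r
eend	dutch	eː n t
paard	dutch	p aː r t
haai	dutch	ɦ aː i
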
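# Example weighted cholinergic gene list — NON-AUTHORITATIVE.
# A small illustrative list of well-known cholinergic-pathway genes for
# trying the scoring stage.  It is NOT the curated 102-gene list used in
# published serum analyses; supply your own list for real-data runs.
# Columns: gene, tier (core -> weight 5; peripheral -> weight 1),
# functional_class.
gene,tier,functional_class
CHAT,core,ACh synthesis
ACHE,core,ACh hydrolysis
BCHE,core,ACh hydrolysis
SLC5A7,core,choline transport
SLC18A3,core,ACh vesicular transport
CHRNA7,peripheral,nicotinic receptor
CHRNA4,peripheral,nicotinic receptor
CHRNB2,peripheral,nicotinic receptor
CHRM1,peripheral,muscarinic receptor
CHRM2,peripheral,muscarinic receptor
CHRM3,peripheral,muscarinic receptor
CHRM5,peripheral,muscarinic receptor
CHKA,peripheral,choline metabolism
CHKB,peripheral,choline metabolism
PCYT1A,peripheral,choline metabolism
CHPT1,peripheral,choline metabolism
IL6,peripheral,cytokine
TNF,peripheral,cytokine
IL1B,peripheral,cytokine
NFKB1,peripheral,inflammatory signaling
STAT3,peripheral,inflammatory signaling
PRKCA,peripheral,downstream signaling
PRKCB,peripheral,downstream signaling
MAPK1,peripheral,downstream signaling
CREB1,peripheral,transcription
ARNTL,peripheral,circadian
CLOCK,peripheral,circadian
PER1,peripheral,circadian
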
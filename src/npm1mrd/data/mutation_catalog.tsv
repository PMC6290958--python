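# NPM1 exon-12 insertion catalog for the packaged synthetic amplicon.
# Types A/B/D carry the literature-standard inserted tetramers (TCTG/CATG/CCTG);
# insGCCA is the published novel 4-bp insertion c.873_874insGCCA; the eight
# "fixture-*" entries are synthetic stand-ins for the assay's uncommon subtypes.
label	hgvs
type A	c.863_864insTCTG
type B	c.863_864insCATG
type D	c.863_864insCCTG
insGCCA	c.873_874insGCCA
fixture-1	c.865_866insAGTC
fixture-2	c.867_868insTGAC
fixture-3	c.869_870insGACT
fixture-4	c.875_876insCTGA
fixture-5	c.877_878insTACG
fixture-6	c.879_880insGTCA
fixture-7	c.881_882insACGT
fixture-8	c.883_884insCAGT
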
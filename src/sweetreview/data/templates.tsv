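# Review-text templates for the synthetic corpus generator.
# Levels: oversweet (real complaint about the product), decoy (contains an
# oversweet phrase about some OTHER product), under-sweet, neutral,
# sweet-only (bare sweet-family word, no categorized phrase), none.
# Decoys deliberately share the comparison vocabulary (other/another/brands)
# so the classifier stage has a learnable, deterministic signal.
level	template
oversweet	way too sweet for me, i could not finish it
oversweet	this is much too sweet and it ruined my morning coffee
oversweet	sickly sweet, i had to throw the rest away
oversweet	overly sweet to the point of being undrinkable
oversweet	far too sweet, it left a syrupy film in my mouth
oversweet	cloyingly sweet and heavy, one bite was plenty
oversweet	too much sweetness in every bite, i gave mine away
oversweet	so sweet that my teeth hurt, will not buy this again
oversweet	extremely sweet, i had to water it down to get through a cup
oversweet	this tastes insanely sweet straight out of the bag
decoy	i have had waffles from other mixes that are too sweet. this mix is very good and easy to prepare
decoy	unlike other brands that are way too sweet, this one is balanced and mild
decoy	most other granolas are far too sweet but this one is perfect
decoy	i tried another brand that was sickly sweet, glad i switched to this
decoy	other syrups i bought were too sweet for me, this one tastes clean
decoy	my old brand was overly sweet, this replacement from another maker is great
under-sweet	not sweet enough for my taste, i had to add honey
under-sweet	barely sweet at all, pretty bland honestly
under-sweet	this lacks sweetness and tastes flat
under-sweet	could be sweeter in my opinion
under-sweet	hardly any sweetness, i expected more flavor
under-sweet	not sweet at all, very disappointing
under-sweet	wish it was sweeter, it needs more sugar
neutral	perfectly sweet and creamy, great texture
neutral	lightly sweetened and easy to drink
neutral	mildly sweet with a nice vanilla note
neutral	naturally sweet from the fruit, very pleasant
neutral	just sweet enough without being heavy
neutral	a little sweet, smooth, and satisfying
neutral	not too sweet, exactly how i like it
neutral	slightly sweet aftertaste that works well
sweet-only	the sweet flavor comes through nicely
sweet-only	i enjoy a sweet snack in the afternoon
sweet-only	this has a sweet smell when you open the jar
sweet-only	sweet and salty combo that works for trail days
sweet-only	my kids love how sweet it smells
none	arrived quickly and the packaging was intact
none	good value for the price, will order again
none	the texture is crunchy and fresh
none	works great in smoothies and baking
none	my whole family enjoys this for breakfast
none	decent quality but the bag was half empty
none	great taste and easy to store
none	satisfies my sweet tooth without any guilt
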
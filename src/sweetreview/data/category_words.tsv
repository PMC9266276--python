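# Word-category lists for review-frequency reporting.  Curated for this
# artifact; editable.  Columns: category, word (lowercase, single token).
category	word
taste	taste
taste	tastes
taste	tasty
taste	flavor
taste	flavour
taste	flavors
taste	flavours
taste	delicious
taste	sweet
taste	sweetness
taste	sweeter
taste	sweetest
taste	sweetened
taste	sweets
taste	salty
taste	saltish
taste	salt
taste	sour
taste	tart
taste	tangy
taste	bitter
taste	biter
taste	umami
taste	savory
taste	savoury
taste	bland
texture	texture
texture	crunchy
texture	crispy
texture	crisp
texture	creamy
texture	chewy
texture	soft
texture	hard
texture	smooth
texture	gritty
texture	grainy
texture	mushy
texture	soggy
texture	dense
texture	fluffy
texture	sticky
price	price
price	prices
price	cheap
price	expensive
price	cost
price	costs
price	value
price	bargain
price	overpriced
price	affordable
customer service	shipping
customer service	delivery
customer service	delivered
customer service	refund
customer service	seller
customer service	service
customer service	arrived
customer service	packaging
customer service	package
customer service	return
customer service	customer
health	healthy
health	health
health	calories
health	calorie
health	diet
health	nutrition
health	nutritious
health	organic
health	gluten
health	vitamin
health	vitamins
health	protein
health	fiber
health	diabetic
health	wholesome
olfaction	smell
olfaction	smells
olfaction	aroma
olfaction	scent
olfaction	odor
olfaction	odour
olfaction	fragrance
chemesthesis	spicy
chemesthesis	hot
chemesthesis	burn
chemesthesis	burning
chemesthesis	tingle
chemesthesis	tingling
chemesthesis	cooling
chemesthesis	pungent
chemesthesis	numbing
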
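# Packaged sweetener catalog: canonical name, '|'-separated synonyms, caloric class.
canonical_name	synonyms	caloric_class
sucrose	sucrose|sugar|cane sugar|brown sugar|raw sugar|beet sugar|coconut sugar|evaporated cane juice	caloric
glucose	glucose|dextrose|glucose syrup	caloric
fructose	fructose|crystalline fructose	caloric
lactose	lactose|milk sugar	caloric
corn syrup	corn syrup|corn syrup solids|light corn syrup|dark corn syrup	caloric
high fructose corn syrup	high fructose corn syrup|hfcs	caloric
honey	honey	caloric
agave	agave|agave nectar|agave syrup	caloric
maple syrup	maple syrup	caloric
molasses	molasses|blackstrap molasses	caloric
sucralose	sucralose|splenda	non-caloric
steviol glycosides	steviol glycosides|stevia|stevia extract|stevia leaf extract|rebaudioside a|reb a	non-caloric
aspartame	aspartame	non-caloric
acesulfame potassium	acesulfame potassium|acesulfame k|ace k	non-caloric
saccharin	saccharin|sodium saccharin	non-caloric
monk fruit	monk fruit|monk fruit extract|luo han guo	non-caloric
erythritol	erythritol	sugar alcohol
xylitol	xylitol	sugar alcohol
maltitol	maltitol|maltitol syrup	sugar alcohol
sorbitol	sorbitol	sugar alcohol
inulin	inulin|chicory root fiber|chicory fiber	sugar fiber
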
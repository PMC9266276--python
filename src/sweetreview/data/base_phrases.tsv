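# Seed sweetness phrases, curated for this artifact (not a published inventory).
# Levels: oversweet, under-sweet, neutral, excluded.
# The bare word "sweet" is deliberately absent: unmatched sweet-family tokens
# fall through to the "sweet-only" category.
surface	level
too sweet	oversweet
way too sweet	oversweet
much too sweet	oversweet
far too sweet	oversweet
very sweet	oversweet
really sweet	oversweet
so sweet	oversweet
quite sweet	oversweet
extremely sweet	oversweet
insanely sweet	oversweet
ridiculously sweet	oversweet
absurdly sweet	oversweet
outrageously sweet	oversweet
super sweet	oversweet
ultra sweet	oversweet
mega sweet	oversweet
crazy sweet	oversweet
beyond sweet	oversweet
sickly sweet	oversweet
sickeningly sweet	oversweet
cloyingly sweet	oversweet
disgustingly sweet	oversweet
nauseatingly sweet	oversweet
overwhelmingly sweet	oversweet
overpoweringly sweet	oversweet
unbearably sweet	oversweet
terribly sweet	oversweet
awfully sweet	oversweet
incredibly sweet	oversweet
exceedingly sweet	oversweet
excessively sweet	oversweet
seriously sweet	oversweet
shockingly sweet	oversweet
intensely sweet	oversweet
immensely sweet	oversweet
painfully sweet	oversweet
obnoxiously sweet	oversweet
syrupy sweet	oversweet
sugary sweet	oversweet
overly sweet	oversweet
over sweet	oversweet
overly sweetened	oversweet
heavily sweetened	oversweet
too much sweetness	oversweet
so much sweetness	oversweet
sweetness overload	oversweet
sweet overload	oversweet
overdose of sweetness	oversweet
not sweet	under-sweet
not sweet enough	under-sweet
not sweet at all	under-sweet
not at all sweet	under-sweet
barely sweet	under-sweet
barely any sweetness	under-sweet
hardly sweet	under-sweet
hardly any sweetness	under-sweet
scarcely sweet	under-sweet
lacks sweetness	under-sweet
lacking sweetness	under-sweet
needs more sweetness	under-sweet
could be sweeter	under-sweet
should be sweeter	under-sweet
wish it was sweeter	under-sweet
wish it were sweeter	under-sweet
no sweetness	under-sweet
zero sweetness	under-sweet
under sweetened	under-sweet
sweet enough	neutral
just sweet enough	neutral
perfectly sweet	neutral
perfectly sweetened	neutral
pleasantly sweet	neutral
nicely sweet	neutral
nicely sweetened	neutral
mildly sweet	neutral
mild sweetness	neutral
lightly sweet	neutral
lightly sweetened	neutral
light sweetness	neutral
slightly sweet	neutral
slightly sweetened	neutral
subtly sweet	neutral
subtle sweetness	neutral
gently sweet	neutral
gentle sweetness	neutral
delicately sweet	neutral
moderately sweet	neutral
medium sweet	neutral
semi sweet	neutral
fairly sweet	neutral
somewhat sweet	neutral
a little sweet	neutral
a bit sweet	neutral
kind of sweet	neutral
sort of sweet	neutral
naturally sweet	neutral
naturally sweetened	neutral
right amount of sweetness	neutral
right level of sweetness	neutral
good sweetness	neutral
nice sweetness	neutral
balanced sweetness	neutral
touch of sweetness	neutral
hint of sweetness	neutral
sweet tooth	excluded
sweet leaf	excluded
sweetener	excluded
sweeteners	excluded
sweet potato	excluded
sweet potatoes	excluded
sweet corn	excluded
sweet pea	excluded
sweet peas	excluded
sweet cream	excluded
sweet spot	excluded
sweet onion	excluded
sweet chili	excluded
sweet and sour	excluded
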
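# Filler words removed from raw ingredient strings before tokenization.
# One word per line; '#' starts a comment.
ingredients
ingredient
contains
contain
may
with
and
or
of
the
a
an
as
to
for
in
from
preserve
freshness
added
less
than
2%
following
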
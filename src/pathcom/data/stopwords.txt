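# Default stop-word list for pathway-name tokenisation: a standard short
# English function-word list plus a few generic fillers that appear in
# gene-set names without carrying meaning. Domain terms such as
# "pathway", "process" and "regulation" are deliberately KEPT — in GO
# and REACTOME names they distinguish otherwise identical concepts.
a
an
and
as
at
br
be
but
by
for
from
in
into
is
it
its
of
on
or
s
t
than
that
the
their
then
this
through
to
up
upon
via
vs
with
within
without
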
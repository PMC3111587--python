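a
about
above
across
after
against
all
along
although
among
an
and
another
any
anybody
anyone
anything
around
as
at
because
before
behind
below
beneath
beside
between
beyond
both
but
by
despite
down
during
each
either
enough
ever
every
everybody
everyone
everything
except
few
for
from
he
her
hers
herself
him
himself
his
how
i
if
in
inside
into
it
its
itself
like
many
me
mine
myself
near
neither
no
nobody
none
nor
of
off
on
once
one
onto
or
ours
ourselves
out
outside
over
past
per
several
she
since
so
some
somebody
someone
sufficient
than
that
the
theirs
them
themselves
these
they
this
those
though
through
throughout
till
to
toward
under
underneath
until
up
upon
us
we
what
whatever
when
where
whether
which
whichever
while
who
whoever
whom
whomever
with
within
without
yet
you
yours
yourself
yourselves
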
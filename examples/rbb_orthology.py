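"""Infer reciprocal-best-hit orthologues from 12-column similarity output.

Two tiny hit tables are built inline: the forward search of two reference
proteins against a target proteome and the reciprocal search back.  Only q1
reciprocates (s1's best hit points back at it); q2's top hit prefers q1 on
the way back, so q2 gets no orthologue.
"""

import io

from ciliaprofile import parse_hits, rbb_pairs

FORWARD = """\
q1\ts1\t85.2\t210\t28\t2\t1\t210\t3\t212\t1e-60\t310
q2\ts1\t64.0\t190\t60\t4\t1\t190\t1\t188\t1e-22\t120
q2\ts2\t70.1\t200\t50\t3\t1\t200\t1\t199\t1e-30\t160
"""

REVERSE = """\
s1\tq1\t85.2\t210\t28\t2\t3\t212\t1\t210\t1e-58\t300
s2\tq1\t66.3\t180\t55\t4\t1\t180\t1\t178\t1e-35\t170
s2\tq2\t70.1\t200\t50\t3\t1\t199\t1\t200\t1e-28\t150
"""

forward = parse_hits(io.StringIO(FORWARD), source="chlamy", target="human")
reverse = parse_hits(io.StringIO(REVERSE), source="human", target="chlamy")

pairs = rbb_pairs(forward, reverse, queries=["q1", "q2"], evalue_threshold=1e-5)
for p in pairs:
    print(f"{p.query_protein} <-> {p.target_protein} ({p.target_species})")
print(f"{len(pairs)} reciprocal pair(s); non-reciprocating top hits are discarded.")
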
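"""Curate a RepeatMasker annotation: fuse fragments, group proviruses.

Builds a six-row RepeatMasker ``.out`` file containing a fragmented LTR
(two rows sharing the ID column) and an LTR-internal-LTR provirus, then
runs the two curation passes and prints the resulting units.
"""

import tempfile
from pathlib import Path

from tcgtscan import curate, parse_rmsk_out

OUT_TEXT = """\
   SW  perc perc perc  query  position in query  matching repeat
score  div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID
  463  12.1  0.0  0.0  chr8  120001 120400 (0) + LTR12C LTR/ERV1 1 400 (0) 7
  430  13.0  0.0  0.0  chr8  122601 123000 (0) + LTR12C LTR/ERV1 1 400 (0) 7
  900   4.0  0.0  0.0  chr8  165001 165450 (0) + LTR7   LTR/ERV1 1 450 (0) 8
  900   5.2  0.0  0.0  chr8  165501 167500 (0) + HERVH-int LTR/ERV1 1 2000 (0) 9
  900   4.4  0.0  0.0  chr8  167601 168050 (0) + LTR7   LTR/ERV1 1 450 (0) 10
  300  18.9  0.0  0.0  chr8  180001 180300 (0) C AluY   SINE/Alu 1 300 (0) 11
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "repeats.out"
    path.write_text(OUT_TEXT)
    records = parse_rmsk_out(path)
    units = curate(records)

print(f"{len(records)} RepeatMasker rows -> {len(units)} curated units\n")
for u in units:
    frags = ", ".join(f"{f.start}-{f.end}" for f in u.fragments)
    group = u.erv_group_id or "-"
    print(f"{u.unit_id}  {u.unit_name:<10} role={u.role:<19} erv_group={group:<9} fragments: {frags}")

# The two LTR12C rows share a linkage ID, so they become one two-fragment
# unit (one interrupted insertion). The LTR7 / HERVH-int / LTR7 trio is
# grouped into a single provirus (roles ltr5 / internal / ltr3); the AluY
# stays a solo unit on the minus strand.
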
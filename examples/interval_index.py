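"""Nested containment lists: how overlapping annotations are indexed.

Builds the index over a handful of intervals, shows the containment
structure, and runs a range query. Contained intervals live in their
container's sublist, so a query descends only into branches it overlaps.
"""

from trackkit.core import Feature, GenomicInterval
from trackkit.nclist import build_nclist, query_nclist

intervals = [(0, 10), (2, 5), (3, 4), (6, 9), (12, 20)]
features = [
    Feature(interval=GenomicInterval("chr1", a, b), id=f"iv{a}-{b}")
    for a, b in intervals
]

top = build_nclist(features)["chr1"]


def show(nodes, depth=0):
    for node in nodes:
        iv = node.interval
        print("  " * depth + f"[{iv.start}, {iv.end})")
        show(node.sublist, depth + 1)


print("containment structure (indent = stored in the sublist above):")
show(top)

hits = query_nclist(top, 4, 7)
print("\nquery [4, 7) overlaps:", [(f.start, f.end) for f in hits])
print("query [10, 12) overlaps:", [(f.start, f.end) for f in query_nclist(top, 10, 12)])
print("(half-open semantics: [0,10) and [12,20) both miss [10,12))")
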
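"""Combination tracks: set operations on footprints, arithmetic on signals.

A footprint is the flattened set of bases a track covers; set operations
have per-base semantics. Quantitative tracks combine pointwise over the
union of their breakpoints.
"""

from trackkit.core import GenomicInterval, SignalInterval
from trackkit.trackops import (
    Footprint,
    SignalTrack,
    combine_features,
    combine_signals,
    feature_coverage,
)

gi = lambda a, b: GenomicInterval("chr1", a, b)

peaks = Footprint.from_intervals([gi(0, 10), gi(20, 30)])
motif_hits = Footprint.from_intervals([gi(5, 25)])

for op in ("union", "intersection", "difference", "xor"):
    result = combine_features(peaks, motif_hits, op)
    print(f"{op:>12}: {[(iv.start, iv.end) for iv in result.get('chr1')]}")

chip = SignalTrack.from_signal_intervals([SignalInterval(gi(0, 10), 2.0)])
input_ctrl = SignalTrack.from_signal_intervals(
    [SignalInterval(gi(5, 15), 3.0), SignalInterval(gi(15, 20), 0.0)]
)
print("\nadd      :", [(s.interval.start, s.interval.end, s.value)
                       for s in combine_signals(chip, input_ctrl, "add").get("chr1")])
# division by zero and missing operands leave gaps rather than inventing data
print("divide   :", [(s.interval.start, s.interval.end, s.value)
                     for s in combine_signals(chip, input_ctrl, "divide").get("chr1")])

depth = feature_coverage([gi(0, 5), gi(3, 8)])
print("\ncoverage of reads [0,5) and [3,8):",
      [(s.interval.start, s.interval.end, s.value) for s in depth.get("chr1")])
print("(value at each base = number of intervals containing it)")
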
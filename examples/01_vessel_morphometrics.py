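"""Measure a small vessel network: junctions, lengths, density, hierarchy.

Builds a Y-shaped network by hand (one 100 µm feeder splitting into two
50 µm sprouts) inside a 1 mm² circular ROI and prints every morphometric
parameter the CAM pipeline scores.
"""

import math

from angiocam import RingROI, Segment, VesselGraph, compute_metrics

nodes = {
    "inlet": (0.0, 0.0),
    "fork": (100.0, 0.0),
    "tip_up": (100.0 + 50.0 / math.sqrt(2), 50.0 / math.sqrt(2)),
    "tip_down": (100.0 + 50.0 / math.sqrt(2), -50.0 / math.sqrt(2)),
}
edges = [
    Segment.make(0, "inlet", "fork", (nodes["inlet"], nodes["fork"])),
    Segment.make(1, "fork", "tip_up", (nodes["fork"], nodes["tip_up"])),
    Segment.make(2, "fork", "tip_down", (nodes["fork"], nodes["tip_down"])),
]
graph = VesselGraph(nodes=nodes, edges=edges, roots=(0,))
roi = RingROI(center=(50.0, 0.0), inner_radius=0.0,
              outer_radius=math.sqrt(1.0e6 / math.pi))  # exactly 1 mm²

m = compute_metrics(graph, roi)
print(f"junctions          : {m.junction_count}")
print(f"segments           : {m.segment_count}")
print(f"total length (um)  : {m.total_length:.2f}")
print(f"mean length (um)   : {m.mean_length:.2f}")
print(f"density (um/mm^2)  : {m.density:.2f}")
print(f"branch degrees 1-4 : {m.branch_counts}")
print(f"hierarchy ratio    : {m.hierarchy_ratio:.3f}")
print()
print("The fork is the single junction; the feeder is a 1st-degree vessel and")
print("the two sprouts are 2nd-degree, so the (3rd+4th)/(1st+2nd) ratio is 0.")
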
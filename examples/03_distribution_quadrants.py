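"""Classify arrays into quality quadrants by distribution shape.

Degraded samples show up in the shape of their raw intensity distribution:
a healthy array has a wide interquartile range and a roughly symmetric
distribution (quartile skew near 0.5); dead probes collapse the IQR and
pile mass at the background floor, driving the skew statistic toward 0.
"""

from collections import Counter

from arrayqc import (
    OutlierSpec,
    SimulationConfig,
    classify_quadrant,
    generate,
)

config = SimulationConfig(p=2000, n=20, seed=5, outlier_specs=[
    OutlierSpec("dead_collapse", 2, severity=0.85),
    OutlierSpec("skewed_degradation", 2, severity=0.8),
    OutlierSpec("range_compression", 1, severity=0.9),
])
em, truth = generate(config)

iqrs, skews, quadrants, n_degenerate = classify_quadrant(
    em, iqr_cut=2.0, skew_cut=0.2)

print(f"{'sample':<8}{'truth':<22}{'IQR':>7}{'skew':>7}  quadrant")
for j, sid in enumerate(em.sample_ids):
    print(f"{sid:<8}{truth.labels[j]:<22}{iqrs[j]:>7.2f}{skews[j]:>7.2f}  "
          f"{quadrants[j]}")

print(f"\nquadrant counts: {dict(Counter(quadrants))}")
print()
print("R1 (IQR > 2, skew > 0.2) is the well-behaved quadrant.  Dead-probe")
print("and range-compressed arrays fall to R3/R4 (small IQR); skewed")
print("degradation lands in R2: the spread survives but the skew statistic")
print("(Q2-Q1)/IQR collapses because most probes sit at the floor.")
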
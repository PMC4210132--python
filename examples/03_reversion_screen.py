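"""Which enzyme subsets bring the DDC-treated AJ liver back to normal?

Each of the 63 non-empty subsets of the six perturbed activities is reset
to its control value and the steady state re-solved; a metabolite counts
as restored when it lands within 10% of the all-normal reference state.
"""

from eicokin import load_conditions
from eicokin.perturb import reversion_screen

conditions = load_conditions()
screen = reversion_screen(conditions[("AJ", "DDC")], conditions[("AJ", "control")])

restoring = sorted(
    (s for s, ok in screen.overall_restored.items() if ok), key=len
)
print(f"{len(screen.per_subset)} subsets screened; "
      f"{len(restoring)} fully restore the metabolic state:")
for subset in restoring:
    print("  " + " + ".join(sorted(subset)))

print("\nSmallest near-misses (what still deviates):")
for subset, calls in screen.per_subset.items():
    bad = [m for m, c in calls.items() if c == "not_restored"]
    if 0 < len(bad) <= 2 and len(subset) >= 4:
        print(f"  {' + '.join(sorted(subset)):42s} -> {', '.join(bad)}")
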
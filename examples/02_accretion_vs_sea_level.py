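"""Can a reef's vertical growth keep pace with projected sea-level rise?

Net carbonate production (kg CaCO3 m^-2 yr^-1) converts to potential vertical
accretion (mm yr^-1) through a concave empirical curve; the result is compared
against end-of-century sea-level-rise rates for four RCP scenarios.
"""

import numpy as np

from reefbudget.budget import DEFAULT_SCENARIOS, keeps_up, vertical_accretion

print("net production -> accretion")
for gross in (1.3, 5.0, 10.0, 16.4, 18.5, 25.65):
    print(f"  {gross:5.2f} kg m^-2 yr^-1  ->  {vertical_accretion(gross):5.1f} mm yr^-1")

print("\nkeep-up table (+ keeps pace, - drowns)")
header = "  accretion  " + "  ".join(f"{s.name:>7s}" for s in DEFAULT_SCENARIOS)
print(header)
for acc in (1.3, 5.0, 6.6, 9.0, 11.2, 11.8):
    marks = "  ".join(
        f"{'+' if keeps_up(acc, s) else '-':>7s}" for s in DEFAULT_SCENARIOS
    )
    print(f"  {acc:6.1f} mm  {marks}")

# the conversion peaks: beyond ~25.65 kg m^-2 yr^-1 extra production no longer
# buys extra height
grid = np.linspace(0, 50, 501)
peak = grid[np.argmax(vertical_accretion(grid))]
print(f"\naccretion maximised at {peak:.1f} kg m^-2 yr^-1 of net production")
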
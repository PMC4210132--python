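"""In-silico drug test: inhibit each enzyme 3-, 6- and 9-fold in AJ-DDC.

Each knockdown divides one activity ratio, re-solves the steady state,
and classifies every metabolite against the untreated DDC baseline with
the 1.5-fold band.  The GPX row shows the screen's signature prediction:
blocking the peroxidase piles up its substrate (15-HPETE) while the
product (15-HETE) is pinned by the upstream flux balance.
"""

from eicokin import load_conditions
from eicokin.model import STATE_IDS
from eicokin.perturb import SCREEN_ENZYMES, drug_screen

conditions = load_conditions()
screen = drug_screen(conditions[("AJ", "DDC")])

symbols = {"up": "+", "down": "-", "unchanged": "."}
print("enzyme    factor  " + "  ".join(f"{m:>9s}" for m in STATE_IDS))
for enzyme in SCREEN_ENZYMES:
    for factor in (3.0, 6.0, 9.0):
        calls = screen.classifications[(enzyme, factor)]
        row = "  ".join(f"{symbols[calls[m]]:>9s}" for m in STATE_IDS)
        print(f"{enzyme:9s} 1/{int(factor):<5d} {row}")
print("\n'+' up, '-' down, '.' unchanged vs the unperturbed DDC steady state")
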
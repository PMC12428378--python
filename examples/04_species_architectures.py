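"""Desk-scale analogs of the great-ape Y-centromere HOR architectures.

Each analog plants the published higher-order structure (unit size, type
economy, row scheme, canonical/variant arrangement) with synthetic monomer
sequences, then lets the pipeline re-discover it.  Copy counts are scaled
down here for speed; scripts/acceptance.py runs them at full scale.
"""

from horscan import analyze
from horscan.benchmarks import (
    chimpanzee_y_analog,
    gorilla_y_analog,
    human_y_analog,
    orangutan_y_analog,
)

analogs = [
    ("orangutan Y", orangutan_y_analog(seed=1, n_copies_58=40, n_copies_45=20)),
    ("human Y", human_y_analog(seed=4)),
    ("chimpanzee Y", chimpanzee_y_analog(seed=5, n_copies=60, n_canonical=50)),
    ("gorilla Y", gorilla_y_analog(seed=3, n_copies=80, n_canonical=50)),
]

for name, (seq, info) in analogs:
    res = analyze([seq], **info["params"])
    for fam in res.families:
        s = fam.summary
        print(
            f"{name:>13}: {s['period']}mer {s['hor_type']:<9} "
            f"{s['n_copies']} copies ({s['n_canonical']} C), "
            f"{s['distinct_types']} types, rows {s['row_counts']}, "
            f"divergence {s['mean_divergence_pct']:.2f}%"
        )
print("Willard's-type units use every monomer type once (one row);")
print("cascading units repeat types internally (multi-row schemes).")
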
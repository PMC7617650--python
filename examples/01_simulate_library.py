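"""Simulate a chimeric proximity-ligation library and its control.

Builds a 2-kb transcript with two planted duplexes (stems), draws an
interaction library (structure + random-ligation background) and a
matched reverse-crosslinked control (pure background), and writes both
as hyb-style tables.
"""

import numpy as np

import chimeramap as cm

transcript = cm.random_transcript(2000, gc=0.45, seed=1)
model = cm.StructureModel(
    transcript,
    stems=[
        cm.StemSpec((200, 240), (1500, 1540), weight=2.0),
        cm.StemSpec((600, 630), (900, 930), weight=1.0),
    ],
    background_rate=0.2,
)

interaction = cm.simulate_chimeras(model, 10_000, seed=2)
control = cm.simulate_control(model, 10_000, seed=2)
cm.write_hyb(interaction, "interaction.hyb.tsv")
cm.write_hyb(control, "control.hyb.tsv")


def stem_fraction(records, stem):
    lo1, hi1 = stem.strand5[0] - 20, stem.strand5[1] + 20
    lo2, hi2 = stem.strand3[0] - 20, stem.strand3[1] + 20
    hits = [
        lo1 <= r.midpoints()[0] <= hi1 and lo2 <= r.midpoints()[1] <= hi2
        for r in records
    ]
    return np.mean(hits)


for i, stem in enumerate(model.stems):
    fi = stem_fraction(interaction, stem)
    fc = stem_fraction(control, stem)
    print(f"stem {i} ({stem.strand5}x{stem.strand3}, weight {stem.weight}):")
    print(f"  chimera fraction near stem: interaction {fi:.3f}  control {fc:.4f}")

# The interaction library concentrates chimeras on the planted duplexes
# in proportion to stem weight (~0.53 and ~0.27 of reads here), while in
# the control the same windows capture only the uniform background rate.
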
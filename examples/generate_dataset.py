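"""Generate synthetic cytology datasets and inspect their composition.

Builds the seven-class preset at one-tenth scale (92 images) plus a 10:1
imbalanced two-class set, then prints per-class counts and the clinical
group percentages computed from the full-scale published count tables.
"""

import tempfile
from pathlib import Path

from cytorl.synthetic import (HERLEV_CLASS_COUNTS, HERLEV_GROUPS,
                              SIPAKMED_CLASS_COUNTS, SIPAKMED_GROUPS,
                              SIPAKMED_PRINTED_TOTAL, generate_dataset,
                              group_percentages, herlev_like_preset,
                              imbalanced_pair_specs)

with tempfile.TemporaryDirectory() as tmp:
    m = herlev_like_preset(Path(tmp) / "herlev_like", seed=1, scale=0.1)
    print("seven-class preset at scale 0.1:")
    for cid, name in m.class_names.items():
        print(f"  {name:<24s} {m.class_counts[cid]:>4d}")
    print(f"  total {len(m)}")

    imb = generate_dataset(imbalanced_pair_specs(), seed=1, size=(64, 64),
                           out_dir=Path(tmp) / "imbalanced")
    print(f"\nimbalanced pair: counts {dict(imb.class_counts)} "
          f"(minority fraction {imb.class_counts[1] / len(imb):.3f})")

# Group percentages recomputed from the published per-class count tables.
# The five-class collection's printed total (4049) exceeds its row sum
# (4031); percentages use the printed denominator.
her = group_percentages(HERLEV_CLASS_COUNTS, HERLEV_GROUPS)
sip = group_percentages(SIPAKMED_CLASS_COUNTS, SIPAKMED_GROUPS,
                        SIPAKMED_PRINTED_TOTAL)
print(f"\nseven-class collection: normal {her['normal']:.1f}% / "
      f"abnormal {her['abnormal']:.1f}%")
print(f"five-class collection:  normal {sip['normal']:.1f}% / "
      f"abnormal {sip['abnormal']:.1f}% / benign {sip['benign']:.1f}%")
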
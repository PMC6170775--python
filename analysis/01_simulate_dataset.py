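"""Generate the default synthetic study dataset and write it to disk.

40 extant species in three locomotor groups on a pure-birth phylogeny
(groups occupy clades), 30 3-D landmarks and a ~2,000-element stress
field per specimen, plus 10 unlabeled fossils. Later scripts read the
dataset back through the package's I/O layer.
"""

from pathlib import Path

from taloco.io import write_dataset
from taloco.synthetic import SynthConfig, make_dataset

SEED = 0
OUT = Path("results/dataset")

if __name__ == "__main__":
    bundle = make_dataset(SynthConfig(seed=SEED))
    write_dataset(bundle, OUT)
    meta = bundle.metadata
    extant = meta[~meta["is_fossil"]]
    print(f"wrote dataset to {OUT}/ (seed={SEED})")
    print(f"  extant: {len(extant)}  fossils: {int(meta['is_fossil'].sum())}")
    print("  group counts:", extant["locomotor_class"].value_counts().to_dict())
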
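"""Phylogenetically informed statistics on the extant sample.

Kmult for shape and for the stress percentiles; PGLS of stress on
talar volume and of shape on centroid size (allometry checks);
standard and phylogenetic two-block PLS between shape and stress; and
the phylomorphospace node projection for the first two PCs.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from taloco.fea import stress_summary
from taloco.io import load_dataset
from taloco.phylo import kmult, pgls, phylo_pls, phylomorphospace, two_block_pls
from taloco.shape import gpa, shape_pca

DATA = Path("results/dataset")
SEED = 0
N_PERM = 9999

if __name__ == "__main__":
    bundle = load_dataset(DATA)
    extant = bundle.metadata[~bundle.metadata["is_fossil"]]
    ids = extant["specimen_id"].tolist()
    taxa = extant["species"].tolist()
    by_id = {lm.specimen_id: lm for lm in bundle.landmarks}
    aligned = gpa([by_id[s] for s in ids])
    flat = aligned.flat()
    summaries = [stress_summary(bundle.stress_fields[s]) for s in ids]
    perc = np.array([[s.M25, s.M50, s.M75, s.M95] for s in summaries])
    volumes = np.array([s.total_volume for s in summaries])

    k_shape = kmult(flat, bundle.tree, taxa, n_perm=N_PERM, seed=SEED)
    k_stress = kmult(perc, bundle.tree, taxa, n_perm=N_PERM, seed=SEED + 1)
    pg_sv = pgls(perc, volumes, bundle.tree, taxa, n_perm=N_PERM, seed=SEED + 2)
    pg_sc = pgls(flat, aligned.centroid_sizes, bundle.tree, taxa, n_perm=N_PERM, seed=SEED + 3)
    pls = two_block_pls(flat, perc, n_perm=N_PERM, seed=SEED + 4)
    ppls = phylo_pls(flat, perc, bundle.tree, taxa, n_perm=N_PERM, seed=SEED + 5)

    pca = shape_pca(aligned)
    nodes = phylomorphospace(bundle.tree, taxa, pca.scores[:, :2])
    pd.DataFrame(nodes).T.rename(columns={0: "PC1", 1: "PC2"}).to_csv(
        "results/phylomorphospace_nodes.csv"
    )
    payload = {
        "kmult_shape": {"K": k_shape.statistic, "p": k_shape.p_value},
        "kmult_stress": {"K": k_stress.statistic, "p": k_stress.p_value},
        "pgls_stress_on_volume": {"F": pg_sv.f_statistic, "R2": pg_sv.r_squared, "p": pg_sv.p_value},
        "pgls_shape_on_size": {"F": pg_sc.f_statistic, "R2": pg_sc.r_squared, "p": pg_sc.p_value},
        "pls": {"r_pls": pls.r_pls, "p": pls.p_value},
        "phylo_pls": {"r_pls": ppls.r_pls, "p": ppls.p_value},
        "n_perm": N_PERM,
    }
    Path("results/phylo_stats.json").write_text(json.dumps(payload, indent=2))
    print(f"Kmult shape : {k_shape.statistic:.4f} (p={k_shape.p_value:.4g})")
    print(f"Kmult stress: {k_stress.statistic:.4f} (p={k_stress.p_value:.4g})")
    print(f"PGLS stress~volume: R2={pg_sv.r_squared:.3f} p={pg_sv.p_value:.3g}")
    print(f"PGLS shape~size   : R2={pg_sc.r_squared:.3f} p={pg_sc.p_value:.3g}")
    print(f"r-PLS={pls.r_pls:.3f} (p={pls.p_value:.4g}); "
          f"phylogenetic r-PLS={ppls.r_pls:.3f} (p={ppls.p_value:.4g})")
    print("wrote results/phylo_stats.json and results/phylomorphospace_nodes.csv")
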
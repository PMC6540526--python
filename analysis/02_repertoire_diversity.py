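#!/usr/bin/env python
"""Compute repertoire diversity/clonality profiles for the cohort.

Reads results/sim/clones.tsv, computes the per-sample measurement vector
(abundance, richness, Shannon entropy, Gini-Simpson, evenness, top-clone
proportions, mean V-region identity against the bundled germline panel),
the chain-presence matrix, and the pairwise Spearman correlation of IGHG
measurements.
"""

from pathlib import Path

import pandas as pd

from repclonity import io, pipeline, simulate, stats

SIM = Path("results/sim")
OUT = Path("results")
OUT.mkdir(exist_ok=True)

libs = io.read_library_sizes(SIM / "libs.tsv")
reps = io.read_clone_table(SIM / "clones.tsv", library_sizes=libs)
germline = simulate.bundled_germline()

profiles = pipeline.profiles_frame(reps, germline=germline)
profiles.to_csv(OUT / "profiles.tsv", sep="\t", index=False, na_rep="NA")

clinical = io.read_clinical_table(SIM / "clinical.tsv")
presence = io.chain_presence_matrix(reps, [c.sample_id for c in clinical])
presence.to_csv(OUT / "chain_presence.tsv", sep="\t", index_label="sample_id")

ighg = profiles[profiles.chain == "IGHG"].set_index("sample_id")
rho, pval = stats.spearman_matrix(
    ighg[["total_count_norm", "richness", "shannon", "gini_simpson",
          "evenness", "top_clone_prop", "mean_v_identity"]])
rho.to_csv(OUT / "ighg_spearman_rho.tsv", sep="\t")
pval.to_csv(OUT / "ighg_spearman_p.tsv", sep="\t")

print(f"profiles: {profiles.shape[0]} (sample, chain) rows "
      f"-> {OUT / 'profiles.tsv'}")
print(f"IGHG present in {presence['IGHG'].sum()} of {presence.shape[0]} samples")
print("median IGHG metrics:")
print(ighg[["total_count_norm", "richness", "shannon", "gini_simpson",
            "evenness", "mean_v_identity"]].median().round(3).to_string())
print("evenness vs abundance Spearman rho: "
      f"{rho.loc['evenness', 'total_count_norm']:.2f} "
      "(clonally restricted repertoires are the more abundant ones)")
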
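#!/usr/bin/env python
"""Vessel transcriptome overlap analysis on simulated DEG tables.

Reproduces the set-algebra layer with the study's design counts as
generating parameters: 1097 DEGs (576 down / 521 up) in a 15k-gene
universe, sex-stratified Venn structure (85 / 109 common genes), mapping
to a mouse vascular marker atlas, and the two-stage healthy-human /
AD-human overlap.  Writes results/omics_counts.json and
results/atlas_overlap.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from vasotrace import synthgen as sg
from vasotrace import vasc_omics as vo

UNIVERSE = 15000


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    gene_ids = [f"g{i:05d}" for i in range(UNIVERSE)]

    chosen = rng.choice(UNIVERSE, 1097, replace=False)
    effects = {gene_ids[i]: (-1.5, False) for i in chosen[:576]}
    effects.update({gene_ids[i]: (1.5, False) for i in chosen[576:]})
    # mouse vascular marker atlas: downregulated genes concentrated in mural
    # cells, upregulated in microglia/endothelium, mirroring the cell-type
    # structure of the bulk signal
    marker_sets = {
        "vsmc": {gene_ids[i] for i in chosen[:121]},
        "pericyte": {gene_ids[i] for i in chosen[130:161]},
        "microglia": {gene_ids[i] for i in chosen[576:646]},
        "capillary_endothelial": {gene_ids[i] for i in chosen[650:693]},
    }
    spec = sg.OmicsSimSpec(gene_universe_size=UNIVERSE, deg_effects=effects,
                           marker_sets=marker_sets,
                           seed=int(rng.integers(2 ** 31)))
    deg, atlas_tab, truth = sg.simulate_omics_tables(spec)

    down = vo.filter_deg(deg, direction="down")
    up = vo.filter_deg(deg, direction="up")
    counts = {"degs_total": len(vo.filter_deg(deg)),
              "degs_down": len(down), "degs_up": len(up)}
    print(f"{counts['degs_total']} DEGs at FDR<0.05 "
          f"({counts['degs_down']} down, {counts['degs_up']} up)")

    atlas = vo.atlas_from_table(atlas_tab, provenance="mouse-top500",
                                max_depth=500)
    mapped_down = vo.map_to_atlas(down, atlas)
    mapped_up = vo.map_to_atlas(up, atlas)
    overlap = pd.concat([mapped_down.assign(direction="down"),
                         mapped_up.assign(direction="up")])
    overlap[["cell_type", "direction", "n_overlap"]].to_csv(
        args.out / "atlas_overlap.csv", index=False)
    for _, r in overlap.iterrows():
        if r.n_overlap:
            print(f"  {r.n_overlap} {r.direction}regulated genes map to {r.cell_type}")

    # two-stage human translation on the mural-cell lists
    human_healthy = vo.MarkerAtlas(
        {"vsmc": sorted(set(list(marker_sets["vsmc"])[:18]))[:100],
         "pericyte": sorted(set(list(marker_sets["pericyte"])[:7]))[:100]},
        provenance="human-top100", max_depth=100)
    human_ad = vo.MarkerAtlas(
        {"vsmc": sorted(set(list(marker_sets["vsmc"])[:9])),
         "pericyte": sorted(set(list(marker_sets["pericyte"])[:3]))},
        provenance="human-AD-DEG")
    stage, unmatched = vo.cross_species_overlap(
        mapped_down[mapped_down.cell_type.isin(["vsmc", "pericyte"])],
        human_healthy, human_ad)
    for _, r in stage.iterrows():
        print(f"  {r.cell_type}: {r.n_stage1} genes shared with the healthy "
              f"human atlas, {r.n_stage2} also AD DEGs in humans")
    counts["stage1_vsmc"] = int(stage.set_index("cell_type").loc["vsmc", "n_stage1"])
    counts["stage2_vsmc"] = int(stage.set_index("cell_type").loc["vsmc", "n_stage2"])

    # sex-stratified venn with the study's common-gene structure
    for label, (n_m, n_f, n_common, sign) in {
            "down": (1080, 548, 85, -1), "up": (1074, 538, 109, +1)}.items():
        picks = rng.choice(UNIVERSE, n_m + n_f - n_common, replace=False)
        tabs = []
        for sel in (picks[:n_m],
                    np.concatenate([picks[:n_common], picks[n_m:]])):
            eff = {gene_ids[i]: (sign * 1.5, False) for i in sel}
            sp = sg.OmicsSimSpec(gene_universe_size=UNIVERSE, deg_effects=eff,
                                 seed=int(rng.integers(2 ** 31)))
            t, _, _ = sg.simulate_omics_tables(sp)
            tabs.append(vo.filter_deg(t, direction=("down" if sign < 0 else "up")))
        v = vo.sex_stratified_venn(*tabs)
        counts[f"venn_{label}_male_only"] = v.n_male_only
        counts[f"venn_{label}_female_only"] = v.n_female_only
        counts[f"venn_{label}_common"] = v.n_common
        print(f"venn ({label}): {v.n_male_only} male-only, "
              f"{v.n_female_only} female-only, {v.n_common} common; "
              f"{len(v.opposing_sign_genes)} opposing-sign genes")

    (args.out / "omics_counts.json").write_text(json.dumps(counts, indent=2))


if __name__ == "__main__":
    main()
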
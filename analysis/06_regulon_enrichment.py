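#!/usr/bin/env python
"""Score the planted regulons' activity per bin (AUCell) and their
enrichment per true region; check that every regulon's most enriched
region is its planted home region."""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import stereopipe as spp
from stereopipe.binning import bin_spots
from stereopipe.simulate import read_regulons


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--top-fraction", type=float, default=0.05)
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    section = spp.read_gem(args.data_dir / "section1.gem")
    regions = pd.read_csv(args.data_dir / "section1.regions.tsv", sep="\t")
    truth_map = regions.pivot(index="y", columns="x", values="region").to_numpy()
    regulons = read_regulons(args.data_dir / "regulons.tsv")
    homes = pd.read_csv(
        args.data_dir / "regulons_home_regions.tsv", sep="\t", index_col=0
    )["home_region"]

    bins = bin_spots(section, 1)
    activity = spp.aucell_matrix(
        np.asarray(bins.X.todense()), bins.var_names, regulons,
        top_fraction=args.top_fraction,
    )
    labels = truth_map[bins.obs["bin_y"].to_numpy(), bins.obs["bin_x"].to_numpy()]
    enrichment, dropped = spp.region_enrichment(activity, labels)
    enrichment.to_csv(args.results / "regulon_enrichment.tsv", sep="\t")

    argmax = {n: int(enrichment[n].idxmax()) for n in enrichment.columns}
    out = {
        "n_regulons": len(regulons),
        "dropped_below_floor": dropped,
        "argmax_region": argmax,
        "home_region": {n: int(homes[n]) for n in homes.index},
        "home_region_recovered": all(
            argmax[n] == int(homes[n]) for n in enrichment.columns
        ),
        "mean_activity": activity.mean().round(4).to_dict(),
    }
    (args.results / "regulon_summary.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
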
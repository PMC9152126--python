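#!/usr/bin/env python
"""Simulate the benchmark dataset: two replicate stripe-tissue sections,
coordinate-barcoded reads with 10% CID errors, a nuclei-staining image,
and region-coupled regulons. Large raw files go to scratch/sim/; a small
summary of what was generated lands in results/simulation_summary.json."""

import argparse
import json
from pathlib import Path

import numpy as np
import tifffile

import stereopipe as spp
from stereopipe.demux import write_reads_tsv
from stereopipe.simulate import write_regulons


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.data_dir
    out.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    spec = spp.TissueSimSpec(seed=args.seed)
    section1, truth = spp.generate_expression(spec)
    section2, _ = spp.generate_expression(spp.TissueSimSpec(seed=args.seed + 1000))
    spp.write_gem(section1, out / "section1.gem")
    spp.write_gem(section2, out / "section2.gem")
    truth.write(out / "section1")

    wl = spp.make_whitelist(spec.grid_width, spec.grid_height)
    wl.write_tsv(out / "whitelist.tsv")
    # reads for a smaller sub-study so demultiplexing stays desk-sized
    read_spec = spp.TissueSimSpec(
        grid_width=60, grid_height=60, n_genes=40, markers_per_region=4,
        baseline_mean=0.6, seed=args.seed
    )
    read_matrix, _ = spp.generate_expression(read_spec)
    read_wl = spp.make_whitelist(60, 60)
    read_wl.write_tsv(out / "reads_whitelist.tsv")
    spp.write_gem(read_matrix, out / "reads_truth.gem")
    reads, read_truth = spp.generate_reads(
        read_matrix, read_wl, cid_error_rate=0.1, seed=args.seed
    )
    write_reads_tsv(reads, out / "reads.tsv")
    read_truth.to_csv(out / "reads_truth_assignments.tsv", sep="\t", index=False)

    img, label_truth = spp.generate_nuclei_image(
        200, (1024, 1024), radius_px=20, seed=args.seed
    )
    tifffile.imwrite(out / "nuclei.tif", img)
    tifffile.imwrite(out / "nuclei_truth_labels.tif", label_truth.astype(np.int32))

    regulons, homes = spp.generate_regulons(
        truth, spec.gene_names, n_regulons=5, genes_per_regulon=8,
        region_coupling=1.0, seed=args.seed
    )
    write_regulons(regulons, out / "regulons.tsv")
    homes.to_csv(out / "regulons_home_regions.tsv", sep="\t")

    summary = {
        "grid": [spec.grid_width, spec.grid_height],
        "n_regions": spec.n_regions,
        "n_genes": spec.n_genes,
        "markers_per_region": spec.markers_per_region,
        "marker_fold": spec.marker_fold,
        "section1_total_umi": section1.total_umi,
        "section2_total_umi": section2.total_umi,
        "n_reads": len(reads),
        "reads_mutated": int(read_truth["cid_mutated"].sum()),
        "image_cells": 200,
        "n_regulons": len(regulons),
    }
    (args.results / "simulation_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print("simulated:", json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
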
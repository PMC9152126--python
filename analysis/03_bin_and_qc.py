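#!/usr/bin/env python
"""Bin the two replicate sections, compute per-bin QC, and measure the
replicate agreement as the Pearson r^2 of log per-gene pseudobulk."""

import argparse
import json
from pathlib import Path

import stereopipe as spp
from stereopipe.binning import bin_spots, bin_qc, replicate_correlation


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/sim"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--bin-size", type=int, default=10)
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    s1 = spp.read_gem(args.data_dir / "section1.gem")
    s2 = spp.read_gem(args.data_dir / "section2.gem")
    b1 = bin_spots(s1, args.bin_size)
    b2 = bin_spots(s2, args.bin_size)
    qc1, summary1 = bin_qc(b1)
    qc1.to_csv(args.results / "bin_qc_section1.tsv", sep="\t")

    out = {
        "bin_size": args.bin_size,
        "bin_side_um": spp.bin_physical_side_um(args.bin_size, s1.pitch_nm),
        "section1": summary1,
        "umi_conserved": int(b1.X.sum()) == s1.total_umi,
        "replicate": replicate_correlation(b1, b2),
    }
    (args.results / "bin_qc_summary.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
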
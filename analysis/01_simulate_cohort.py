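#!/usr/bin/env python
"""Simulate the study cohorts: healthy controls vs IBS-M patients.

Draws genus-level relative-abundance profiles for both groups under the
configured dysbiosis signature, plus a random genus taxonomy for UniFrac,
and writes them under the output directory for the later stages.
"""

import argparse
from pathlib import Path

import numpy as np

import microdiet as md
from microdiet import io
from microdiet.config import load_config, stage_seed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--out-dir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = load_config(args.config, overrides={"seed": args.seed} if args.seed is not None else None)
    cc = cfg.cohort
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    spec = md.default_cohort_spec(
        n_healthy=cc.n_healthy, n_ibs=cc.n_ibs, n_taxa=cc.n_taxa,
        effect_taxa=dict(cc.effect_taxa), log_sd=cc.log_sd,
        zero_inflation=cc.zero_inflation, seed=stage_seed(cfg.seed, "cohort"))
    table, labels = md.generate_cohort(spec)
    tree = md.generate_tree(table.taxon_names, seed=stage_seed(cfg.seed, "tree"))

    io.write_abundance(table, out / "abundance.tsv")
    io.write_metadata(labels.to_frame(), out / "metadata.tsv")
    io.write_tree(tree, out / "taxonomy.nwk")

    shannon = np.array([md.shannon(r) for r in table.values])
    print(f"wrote {table.n_samples} samples x {len(table.taxon_names)} genera -> {out}")
    print(f"zero fraction: {np.mean(table.values == 0):.3f}")
    for grp in ("healthy", "ibs"):
        print(f"mean Shannon ({grp}): {shannon[(labels == grp).to_numpy()].mean():.3f} bits")


if __name__ == "__main__":
    main()
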
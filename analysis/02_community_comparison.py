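#!/usr/bin/env python
"""Compare the two cohorts at the community level.

Computes the unweighted UniFrac distance matrix, tests the group difference
with PERMANOVA, and screens every genus with a Mann-Whitney U test under
Benjamini-Hochberg correction.
"""

import argparse
from pathlib import Path

import microdiet as md
from microdiet import io
from microdiet.config import load_config, stage_seed
from microdiet.diversity import distance_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=None)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--out-dir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = load_config(args.config, overrides={"seed": args.seed} if args.seed is not None else None)
    out = args.out_dir
    table = io.read_abundance(out / "abundance.tsv")
    labels = io.read_metadata(out / "metadata.tsv")["group"]
    tree = io.read_tree(out / "taxonomy.nwk")

    dm = distance_matrix(table, metric="unifrac", tree=tree)
    res = md.permanova(dm, labels, n_permutations=cfg.stats.n_permutations,
                       seed=stage_seed(cfg.seed, "permanova"))
    screen = md.taxon_screen(table, labels)

    dm.to_data_frame().to_csv(out / "unifrac.tsv", sep="\t")
    screen.to_csv(out / "taxon_screen.tsv", sep="\t", index=False)
    io.write_json({"permanova": vars(res)}, out / "permanova.json")

    print(f"PERMANOVA on unweighted UniFrac: pseudo-F = {res.pseudo_f:.3f}, "
          f"p = {res.p_value:.4g} ({res.n_permutations} permutations)")
    top = screen.nsmallest(5, "q_value")
    print("top discriminating genera (q-value, direction ibs vs healthy):")
    for _, row in top.iterrows():
        arrow = "up" if row.direction > 0 else "down"
        print(f"  {row.taxon:<22} q = {row.q_value:.4g}  ({arrow} in IBS)")


if __name__ == "__main__":
    main()
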
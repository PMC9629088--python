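#!/usr/bin/env python
"""Train and validate the microbiome-derived IBS index.

Runs repeated stratified cross-validation of the boosted-tree classifier on
the simulated cohorts, then fits the final index model on all samples and
saves it as a JSON artifact.
"""

import argparse
from pathlib import Path

import microdiet as md
from microdiet import io
from microdiet.config import load_config, stage_seed
from microdiet.index_model import TrainingConfig


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

    if cfg.cv.n_tuning_trials > 0:
        train_config = md.tune_hyperparameters(table, labels,
                                               n_trials=cfg.cv.n_tuning_trials,
                                               seed=stage_seed(cfg.seed, "tuning"))
        print(f"tuned hyperparameters over {cfg.cv.n_tuning_trials} trials: {train_config}")
    else:
        train_config = TrainingConfig()

    report = md.cross_validate(table, labels, k=cfg.cv.cv_folds,
                               n_seeds=cfg.cv.n_seeds, config=train_config,
                               seed=stage_seed(cfg.seed, "cv"))
    model = md.train_index_model(table, labels, train_config,
                                 seed=stage_seed(cfg.seed, "train"))
    model.save(out / "index_model.json")
    io.write_json({"cv": report.to_dict()}, out / "cv_report.json")

    print(f"{cfg.cv.cv_folds}-fold CV x {cfg.cv.n_seeds} seeds: "
          f"mean ROC-AUC = {report.mean_auc:.3f} (sd {report.sd_auc:.3f}), "
          f"mean accuracy = {report.mean_accuracy:.3f}")
    scores = model.score(table)
    ibs = scores[(labels == 'ibs').to_numpy()]
    healthy = scores[(labels == 'healthy').to_numpy()]
    print(f"index on training data: IBS {ibs.mean():.3f} vs healthy {healthy.mean():.3f}")


if __name__ == "__main__":
    main()
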
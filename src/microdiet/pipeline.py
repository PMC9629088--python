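"""End-to-end study replica: simulate → compare cohorts → train the index →
optimize modulations → recommend nutrients → simulate the intervention →
score clinical outcomes.

One master seed drives every stage through :func:`microdiet.config.stage_seed`,
so a (config, seed) pair reproduces every number in the report. Stage outputs
are written as files under the output directory so any stage can be audited
or rerun in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .clinical import (EffectSizeReport, InterventionSummary, associate_scores,
                       intervention_summary)
from .config import RunConfig, stage_seed
from .diet import NutrientProfile, NutrientResponseModel, design_diet
from .diversity import PermanovaResult, distance_matrix, paired_t, permanova, shannon, taxon_screen
from .index_model import CVReport, IBSIndexModel, TrainingConfig, cross_validate, \
    train_index_model, tune_hyperparameters
from .modulation import ModulationParams
from .synth import (InterventionScenario, default_cohort_spec, generate_clinical,
                    generate_cohort, generate_tree, simulate_intervention)


@dataclass
class StudyReport:
    """Every analysis artifact of one study run, reproducible from (config, seed)."""

    config: dict
    cohort_summary: dict
    permanova_result: PermanovaResult
    screen: pd.DataFrame
    cv_report: CVReport
    modulation_digests: list[dict]
    nutrient_profiles: dict[str, dict[str, float]]
    index_summary: dict  # per arm: pre/post mean, sd, paired t, p
    intervention: dict[str, InterventionSummary]
    effect_sizes: dict[str, EffectSizeReport]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "cohort_summary": self.cohort_summary,
            "permanova": vars(self.permanova_result),
            "screen": self.screen.round(10).to_dict(orient="records"),
            "cv": self.cv_report.to_dict(),
            "modulations": self.modulation_digests,
            "nutrient_profiles": self.nutrient_profiles,
            "index_summary": self.index_summary,
            "intervention": {arm: s.to_dict() for arm, s in self.intervention.items()},
            "effect_sizes": {g: r.to_dict() for g, r in self.effect_sizes.items()},
        }


def run_study(config: RunConfig, out_dir=None) -> StudyReport:
    """Execute the full pipeline under one config and master seed."""
    seed = config.seed
    cc = config.cohort
    if cc.n_personalized + cc.n_control > cc.n_ibs:
        raise ValueError("arm sizes exceed the IBS cohort")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort simulation -----------------------------------------
    spec = default_cohort_spec(
        n_healthy=cc.n_healthy, n_ibs=cc.n_ibs, n_taxa=cc.n_taxa,
        effect_taxa=dict(cc.effect_taxa), log_sd=cc.log_sd,
        zero_inflation=cc.zero_inflation, seed=stage_seed(seed, "cohort"),
    )
    table, labels = generate_cohort(spec)
    tree = generate_tree(table.taxon_names, seed=stage_seed(seed, "tree"))
    if out is not None:
        io.write_abundance(table, out / "abundance.tsv")
        io.write_metadata(labels.to_frame(), out / "metadata.tsv")
        io.write_tree(tree, out / "taxonomy.nwk")

    alpha = pd.Series([shannon(row) for row in table.values], index=table.sample_ids)
    cohort_summary = {
        "n_healthy": cc.n_healthy, "n_ibs": cc.n_ibs, "n_taxa": cc.n_taxa,
        "mean_shannon_healthy": float(alpha[labels == "healthy"].mean()),
        "mean_shannon_ibs": float(alpha[labels == "ibs"].mean()),
    }

    # --- stage: community comparison --------------------------------------
    dm = distance_matrix(table, metric="unifrac", tree=tree)
    perm = permanova(dm, labels, n_permutations=config.stats.n_permutations,
                     seed=stage_seed(seed, "permanova"))
    screen = taxon_screen(table, labels)
    if out is not None:
        dm.to_data_frame().to_csv(out / "unifrac.tsv", sep="\t")
        screen.to_csv(out / "taxon_screen.tsv", sep="\t", index=False)

    # --- stage: IBS-index model -------------------------------------------
    if config.cv.n_tuning_trials > 0:
        train_config = tune_hyperparameters(
            table, labels, n_trials=config.cv.n_tuning_trials,
            seed=stage_seed(seed, "tuning"),
        )
    else:
        train_config = TrainingConfig()
    cv_report = cross_validate(table, labels, k=config.cv.cv_folds,
                               n_seeds=config.cv.n_seeds, config=train_config,
                               seed=stage_seed(seed, "cv"))
    model = train_index_model(table, labels, train_config, seed=stage_seed(seed, "train"))
    if out is not None:
        model.save(out / "index_model.json")
        io.write_json({"cv": cv_report.to_dict()}, out / "cv_report.json")

    # --- stage: modulation + nutrient design for the personalized arm ------
    ibs_ids = [s for s in table.sample_ids if labels[s] == "ibs"]
    personalized = ibs_ids[: cc.n_personalized]
    control = ibs_ids[cc.n_personalized: cc.n_personalized + cc.n_control]
    # signature nutrients act along the dysbiosis axis, as a curated
    # nutrient database would (ingredients known to modulate relevant taxa)
    response = NutrientResponseModel.random(
        table.taxon_names, seed=stage_seed(seed, "response"),
        signature={t: -f for t, f in cc.effect_taxa.items()},
    )

    mod_digests, profiles, doses = [], {}, {}
    for i, sample in enumerate(personalized):
        params = ModulationParams(
            p_perturb=config.metropolis.p_perturb,
            kernel_sd=config.metropolis.kernel_sd,
            temperature=config.metropolis.temperature,
            n_iterations=config.metropolis.n_iterations,
            distance_budget=config.metropolis.distance_budget,
            seed=stage_seed(seed, f"metropolis:{sample}"),
        )
        baseline = table.data.loc[sample, model.feature_names].to_numpy(dtype=float)
        result, profile, predicted = design_diet(model, baseline, params, response)
        profiles[sample] = {k: round(v, 10) for k, v in profile.doses.items()}
        doses[sample] = profile.doses
        mod_digests.append({
            "sample_id": sample,
            "baseline_index": result.baseline_index,
            "best_index": result.best_index,
            "aitchison_distance": result.aitchison_distance,
            "n_accepted": result.n_accepted,
            "predicted_post_index": predicted,
        })
    if out is not None:
        io.write_json({"modulations": mod_digests}, out / "modulations.json")
        Bdf, bounds = response.to_frames()
        io.write_nutrient_response(Bdf, bounds, out / "response_matrix.tsv",
                                   out / "response_bounds.tsv")
        pd.DataFrame(profiles).T.to_csv(out / "nutrient_profiles.csv",
                                        index_label="sample_id")

    # --- stage: simulated intervention ------------------------------------
    arm_of = {s: "personalized" for s in personalized} | {s: "control" for s in control}
    treated_table = table.subset(personalized + control)
    scenario = InterventionScenario(
        baseline=treated_table, nutrient_doses=doses, response=response,
        noise_sd=0.05, seed=stage_seed(seed, "intervention"),
    )
    post_table = simulate_intervention(scenario)
    if out is not None:
        io.write_abundance(post_table, out / "abundance_post.tsv")

    pre_index = pd.Series(model.score(treated_table), index=treated_table.sample_ids)
    post_index = pd.Series(model.score(post_table), index=post_table.sample_ids)

    index_summary = {}
    for arm in ("personalized", "control"):
        ids = [s for s in treated_table.sample_ids if arm_of[s] == arm]
        res = paired_t(pre_index[ids].to_numpy(), post_index[ids].to_numpy())
        index_summary[arm] = {
            "pre_mean": float(pre_index[ids].mean()), "pre_sd": float(pre_index[ids].std(ddof=1)),
            "post_mean": float(post_index[ids].mean()), "post_sd": float(post_index[ids].std(ddof=1)),
            "delta_mean": res.mean_delta, "t": res.t, "p_value": res.p_value, "n": res.n,
        }

    # --- stage: clinical outcomes ------------------------------------------
    clin = config.clinical
    pre_clinical = generate_clinical(pre_index, slope=clin.slope, intercept=clin.intercept,
                                     noise_sd=clin.noise_sd,
                                     seed=stage_seed(seed, "clinical_pre"))
    post_clinical = generate_clinical(post_index, slope=clin.slope, intercept=clin.intercept,
                                      noise_sd=clin.noise_sd,
                                      seed=stage_seed(seed, "clinical_post"))
    if out is not None:
        io.write_clinical(pre_clinical, out / "clinical_pre.csv")
        io.write_clinical(post_clinical, out / "clinical_post.csv")

    intervention, effect_sizes = {}, {}
    all_idx, all_total = [], []
    for arm in ("personalized", "control"):
        ids = [s for s in treated_table.sample_ids if arm_of[s] == arm]
        intervention[arm] = intervention_summary(pre_clinical.loc[ids], post_clinical.loc[ids])
        idx = np.concatenate([pre_index[ids], post_index[ids]])
        tot = np.concatenate([pre_clinical.loc[ids].sum(axis=1),
                              post_clinical.loc[ids].sum(axis=1)])
        effect_sizes[arm] = associate_scores(idx, tot)
        all_idx.append(idx)
        all_total.append(tot)
    effect_sizes["combined"] = associate_scores(np.concatenate(all_idx),
                                                np.concatenate(all_total))

    report = StudyReport(
        config=config.model_dump(),
        cohort_summary=cohort_summary,
        permanova_result=perm,
        screen=screen,
        cv_report=cv_report,
        modulation_digests=mod_digests,
        nutrient_profiles=profiles,
        index_summary=index_summary,
        intervention=intervention,
        effect_sizes=effect_sizes,
    )
    if out is not None:
        io.write_json(report.to_dict(), out / "study_report.json")
        report_tables(report, out)
    return report


def report_tables(report: StudyReport, out_dir) -> dict[str, Path]:
    """Render the report's headline tables as TSV files.

    Emits the arm-level delta table, the per-item pre/post table, the index
    pre/post table, and the effect-size table; all parse back with the
    package's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    delta_rows, item_rows = [], []
    for arm, summ in report.intervention.items():
        for measure, row in summ.stats.iterrows():
            item_rows.append({"arm": arm, "measure": measure, **row.to_dict()})
            delta_rows.append({
                "arm": arm, "measure": measure,
                "delta_mean": row["delta_mean"], "delta_sd": row["delta_sd"],
                "p_value": row["p_value"],
            })
    paths["deltas"] = out / "table_deltas.tsv"
    pd.DataFrame(delta_rows).to_csv(paths["deltas"], sep="\t", index=False)
    paths["items"] = out / "table_items.tsv"
    pd.DataFrame(item_rows).to_csv(paths["items"], sep="\t", index=False)

    paths["index"] = out / "table_index.tsv"
    pd.DataFrame([
        {"arm": arm, **vals} for arm, vals in report.index_summary.items()
    ]).to_csv(paths["index"], sep="\t", index=False)

    paths["effect_sizes"] = out / "table_effect_sizes.tsv"
    pd.DataFrame([
        {"group": g, **r.to_dict()} for g, r in report.effect_sizes.items()
    ]).to_csv(paths["effect_sizes"], sep="\t", index=False)
    return paths
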
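"""IBS-SSS scoring, severity categories, intervention statistics, and the
effect-size analysis linking microbiome index scores to symptom scores.

The IBS Symptom Severity Scale (IBS-SSS) has five items, each 0–100: pain
severity, pain frequency (days of pain), distension, dissatisfaction with
bowel habits, and interference with quality of life. The total (0–500) is
banded into remission (< 75), mild (75–174), moderate (175–299) and severe
(≥ 300) using the instrument's standard cut-offs.

Effect sizes for the index→symptom regression follow the one-predictor
ANOVA decomposition:

    ω² = (SS_effect − df_effect · MS_error) / (SS_total + MS_error),  df_effect = 1
    f² = ω² / (1 − ω²)

``ω²`` is a small-sample-adjusted share of explained variance and may be
negative; ``f²`` is computed from ω² (not R²).

The module also ships the arm-level summary statistics published by the
pilot trial this pipeline replicates (per-item and total pre/post means and
SDs, index summaries, and printed effect sizes), used to reproduce the
trial's cross-table arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import PairedTResult, paired_t
from .io import CLINICAL_ITEMS

SEVERITY_ORDER = ("remission", "mild", "moderate", "severe")
#: Lower edges of mild / moderate / severe on the 0-500 total.
SEVERITY_CUTOFFS = (75.0, 175.0, 300.0)


@dataclass
class SSSRecord:
    """One subject's five symptom items (each 0-100)."""

    sample_id: str
    pain: float
    pain_freq: float
    distension: float
    dissatisfaction: float
    qol: float

    def items(self) -> tuple[float, ...]:
        return (self.pain, self.pain_freq, self.distension, self.dissatisfaction, self.qol)


def sss_total(record) -> float:
    """Total symptom score: the sum of the five items, range [0, 500].

    Accepts an :class:`SSSRecord`, a mapping/Series with the item names, or a
    plain length-5 sequence in item order.
    """
    if isinstance(record, SSSRecord):
        items = record.items()
    elif isinstance(record, (pd.Series, dict)):
        items = tuple(float(record[k]) for k in CLINICAL_ITEMS)
    else:
        items = tuple(float(v) for v in record)
        if len(items) != 5:
            raise ValueError("expected exactly five item scores")
    for name, v in zip(CLINICAL_ITEMS, items):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"item {name} = {v} outside [0, 100]")
    return float(sum(items))


def severity_category(total: float) -> str:
    """Band a total score: remission < 75 ≤ mild < 175 ≤ moderate < 300 ≤ severe."""
    if not 0.0 <= total <= 500.0:
        raise ValueError(f"total {total} outside [0, 500]")
    mild, moderate, severe = SEVERITY_CUTOFFS
    if total < mild:
        return "remission"
    if total < moderate:
        return "mild"
    if total < severe:
        return "moderate"
    return "severe"


@dataclass
class InterventionSummary:
    """Pre/post statistics for one arm: per-item and total deltas plus the
    severity transition matrix."""

    stats: pd.DataFrame  # index: item names + 'total'; columns: pre_mean, pre_sd,
    #                      post_mean, post_sd, delta_mean, delta_sd, t, p_value
    transitions: pd.DataFrame  # severity category counts, pre (rows) x post (columns)
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "stats": self.stats.round(6).reset_index().to_dict(orient="records"),
            "transitions": self.transitions.to_dict(),
        }


def intervention_summary(pre: pd.DataFrame, post: pd.DataFrame,
                         pairing: dict[str, str] | None = None) -> InterventionSummary:
    """Paired pre/post analysis of clinical records for one arm.

    ``pre`` and ``post`` are item DataFrames indexed by sample ID. By default
    records pair by identical sample ID; an explicit ``pairing`` maps post IDs
    to pre IDs. Every post record must pair to a pre record.
    """
    if pairing is None:
        pairing = {s: s for s in post.index}
    unpaired = [s for s in post.index if pairing.get(s) not in set(pre.index)]
    if unpaired:
        raise ValueError(f"unpaired post sample: {unpaired[0]!r}")
    pre_aligned = pre.loc[[pairing[s] for s in post.index]]

    measures = list(CLINICAL_ITEMS) + ["total"]
    pre_vals = pre_aligned[list(CLINICAL_ITEMS)].copy()
    post_vals = post[list(CLINICAL_ITEMS)].copy()
    pre_vals["total"] = pre_vals.sum(axis=1)
    post_vals["total"] = post_vals[list(CLINICAL_ITEMS)].sum(axis=1)

    rows = []
    for m in measures:
        res: PairedTResult = paired_t(pre_vals[m].to_numpy(), post_vals[m].to_numpy())
        rows.append({
            "measure": m,
            "pre_mean": float(pre_vals[m].mean()), "pre_sd": float(pre_vals[m].std(ddof=1)),
            "post_mean": float(post_vals[m].mean()), "post_sd": float(post_vals[m].std(ddof=1)),
            "delta_mean": res.mean_delta, "delta_sd": res.sd_delta,
            "t": res.t, "p_value": res.p_value,
        })
    stats_df = pd.DataFrame(rows).set_index("measure")

    pre_cat = pre_vals["total"].map(severity_category)
    post_cat = post_vals["total"].map(severity_category)
    transitions = pd.crosstab(pre_cat, post_cat).reindex(
        index=SEVERITY_ORDER, columns=SEVERITY_ORDER, fill_value=0
    )
    return InterventionSummary(stats=stats_df, transitions=transitions, n=len(post))


def omega_squared(x, y) -> float:
    """Adjusted explained variance of the simple linear regression of y on x.

    ``ω² = (SS_effect − MS_error) / (SS_total + MS_error)`` with one effect
    degree of freedom; can be negative when the fit explains less than one
    error mean-square.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("omega squared requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_error = float(((y - fitted) ** 2).sum())
    ss_effect = ss_total - ss_error
    ms_error = ss_error / (n - 2)
    if ss_total + ms_error == 0:
        raise ValueError("y is constant")
    return float((ss_effect - 1.0 * ms_error) / (ss_total + ms_error))


def cohens_f2(omega_sq: float) -> float:
    """Cohen's effect size f² = ω² / (1 − ω²); requires ω² < 1."""
    if omega_sq >= 1:
        raise ValueError("omega squared must be < 1")
    return float(omega_sq / (1.0 - omega_sq))


@dataclass
class EffectSizeReport:
    r_squared: float
    omega_squared: float
    cohens_f2: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared, "omega_squared": self.omega_squared,
            "cohens_f2": self.cohens_f2, "slope": self.slope,
            "intercept": self.intercept, "n": self.n,
        }


def associate_scores(index_scores, sss_totals) -> EffectSizeReport:
    """Regress symptom totals on microbiome index scores; report R², ω², f²."""
    x = np.asarray(index_scores, dtype=float)
    y = np.asarray(sss_totals, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    if np.ptp(x) == 0:
        raise ValueError("index scores are constant")
    fit = stats.linregress(x, y)
    w2 = omega_squared(x, y)
    return EffectSizeReport(
        r_squared=float(fit.rvalue**2),
        omega_squared=w2,
        cohens_f2=cohens_f2(w2) if w2 < 1 else float("inf"),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Published arm-level summaries of the pilot trial (packaged data)

def load_trial_summary() -> pd.DataFrame:
    """Arm-level pre/post means and SDs published by the pilot trial.

    Rows: (arm, measure) for the five items, the total, and the microbiome
    index; columns n, pre_mean, pre_sd, post_mean, post_sd.
    """
    with resources.files("microdiet.data").joinpath("pilot_trial_summary.csv").open() as fh:
        return pd.read_csv(fh).set_index(["arm", "measure"])


def load_effect_sizes() -> pd.DataFrame:
    """Published index→symptom effect sizes (R², ω², printed f²) per group."""
    with resources.files("microdiet.data").joinpath("pilot_effect_sizes.csv").open() as fh:
        return pd.read_csv(fh).set_index("group")


def arm_mean_changes(summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean post−pre change per (arm, measure) recomputed from the summary table."""
    if summary is None:
        summary = load_trial_summary()
    out = summary.copy()
    out["delta_mean"] = out["post_mean"] - out["pre_mean"]
    return out[["n", "pre_mean", "post_mean", "delta_mean"]]
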
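"""Relative qPCR quantification (2^-ddCt) and group statistics.

Quantification follows the Livak method: each sample's target Ct is
normalized against the arithmetic mean of the reference-gene Cts (equivalent
to the geometric mean of their quantities), giving dCt; groups are then
normalized against a control group, giving ddCt and fold change 2^-ddCt.
Hypothesis tests are run on dCt values, which are approximately normal;
folds are reported on the ratio scale.

Multiple comparisons against the control use Dunnett's procedure, with the
adjusted p-values estimated by seeded Monte Carlo sampling of the null
distribution of the maximum |t| over comparisons under the pooled-variance
correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CT_CEILING = 45.0  # qPCR cycle ceiling: Ct at/above -> not expressed


class ExpressionTable(NamedTuple):
    """Group-level results plus the per-replicate values behind them."""

    results: pd.DataFrame
    replicates: pd.DataFrame
    not_expressed: list[tuple]


def significance_category(p: float) -> str:
    """GraphPad-style star category for a p-value."""
    if not np.isfinite(p):
        return "ns"
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# ddCt quantification
# ---------------------------------------------------------------------------

def delta_delta_ct(ct: pd.DataFrame, targets: list[str], references: list[str],
                   control_condition: str | None = None,
                   control_timepoint=None,
                   ct_ceiling: float = DEFAULT_CT_CEILING) -> ExpressionTable:
    """Per-gene dCt/ddCt/fold relative to a control group.

    Groups are (condition, timepoint) cells. The control group for a cell is
    obtained by substituting *control_condition* and/or *control_timepoint*
    into its key — e.g. ``control_condition='control'`` compares each
    treated timepoint against the untreated sample at the same timepoint,
    while ``control_timepoint=14`` compares later ages against day 14 within
    each condition. Adding a constant to every Ct of one sample cancels in
    dCt, so results are invariant to per-sample offsets.

    Ct values at or above *ct_ceiling* (or missing) are treated as not
    expressed: the replicate is dropped and fully absent gene/cells are
    reported in ``not_expressed`` rather than folded into statistics.
    """
    if control_condition is None and control_timepoint is None:
        raise ValueError("specify control_condition and/or control_timepoint")
    df = ct.copy()
    df["expressed"] = df["ct"].notna() & (df["ct"] < ct_ceiling)

    # per-sample reference mean
    ref_rows = df[df["gene_id"].isin(references) & df["expressed"]]
    ref_mean = ref_rows.groupby("sample_id")["ct"].agg(["mean", "count"])
    missing_ref = ref_mean[ref_mean["count"] < len(references)]
    all_samples = df["sample_id"].unique()
    for sample in all_samples:
        if sample not in ref_mean.index or sample in missing_ref.index:
            raise ValueError(f"sample {sample!r} is missing a reference gene Ct")

    rep_rows = []
    not_expressed: list[tuple] = []
    for gene in targets:
        sub = df[df["gene_id"] == gene]
        if sub.empty:
            not_expressed.append((gene, None, None))
            continue
        for (cond, tp), cell in sub.groupby(["condition", "timepoint"]):
            expressed = cell[cell["expressed"]]
            if expressed.empty:
                not_expressed.append((gene, cond, tp))
                continue
            for _, row in expressed.iterrows():
                rep_rows.append({
                    "gene_id": gene, "condition": cond, "timepoint": tp,
                    "replicate": row["replicate"], "sample_id": row["sample_id"],
                    "delta_ct": row["ct"] - ref_mean.loc[row["sample_id"], "mean"],
                })
    replicates = pd.DataFrame(rep_rows)

    def control_key(cond, tp):
        return (control_condition if control_condition is not None else cond,
                control_timepoint if control_timepoint is not None else tp)

    results_rows = []
    if not replicates.empty:
        grouped = replicates.groupby(["gene_id", "condition", "timepoint"])
        means = grouped["delta_ct"].mean()
        for (gene, cond, tp), cell in grouped:
            ckey = (gene, *control_key(cond, tp))
            if ckey not in means.index:
                not_expressed.append((gene, *control_key(cond, tp)))
                continue
            control_mean = means.loc[ckey]
            ddct = means.loc[(gene, cond, tp)] - control_mean
            results_rows.append({
                "gene_id": gene, "condition": cond, "timepoint": tp,
                "n": len(cell), "mean_delta_ct": means.loc[(gene, cond, tp)],
                "delta_delta_ct": ddct, "fold": 2.0 ** (-ddct),
                "is_control": (cond, tp) == control_key(cond, tp),
            })
        replicates["fold"] = [
            2.0 ** (-(row.delta_ct
                      - means.loc[(row.gene_id, *control_key(row.condition,
                                                             row.timepoint))]))
            if (row.gene_id, *control_key(row.condition, row.timepoint))
            in means.index else np.nan
            for row in replicates.itertuples()
        ]
    results = pd.DataFrame(results_rows)
    return ExpressionTable(results=results, replicates=replicates,
                           not_expressed=not_expressed)


# ---------------------------------------------------------------------------
# ANOVA + Dunnett
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DunnettResult:
    anova_f: float
    anova_p: float
    t_stats: dict
    dunnett_p: dict
    unadjusted_p: dict


def anova_dunnett(groups: dict, control_label, mc_draws: int = 100_000,
                  seed: int | None = None) -> DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a control.

    Observed statistics use the pooled variance across all groups. The
    Dunnett adjustment is the tail probability of the maximum |t| across
    comparisons under the null, estimated by Monte Carlo: group means and a
    shared pooled variance are redrawn *mc_draws* times, reproducing the
    correlation between comparisons induced by the common control group.
    Unadjusted p-values come from the same draws, so adjusted >= unadjusted
    holds by construction.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    labels = [l for l in groups if l != control_label]
    if not labels:
        raise ValueError("need at least one non-control group")
    arrays = {l: np.asarray(v, dtype=float) for l, v in groups.items()}
    for l, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {l!r} needs at least 2 replicates")
    if all(np.ptp(v) == 0 for v in arrays.values()):
        raise ValueError("degenerate: zero within-group variance everywhere")

    f_stat, anova_p = stats.f_oneway(*arrays.values())

    n0 = len(arrays[control_label])
    total_n = sum(len(v) for v in arrays.values())
    k = len(arrays)
    dof = total_n - k
    pooled = sum((len(v) - 1) * v.var(ddof=1) for v in arrays.values()) / dof
    mean0 = arrays[control_label].mean()
    t_obs = {
        l: (arrays[l].mean() - mean0)
        / np.sqrt(pooled * (1.0 / len(arrays[l]) + 1.0 / n0))
        for l in labels
    }

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(mc_draws) / np.sqrt(n0)
    s2 = rng.chisquare(dof, size=mc_draws) / dof
    t_null = np.empty((len(labels), mc_draws))
    for idx, l in enumerate(labels):
        ng = len(arrays[l])
        zg = rng.standard_normal(mc_draws) / np.sqrt(ng)
        t_null[idx] = (zg - z0) / np.sqrt(s2 * (1.0 / ng + 1.0 / n0))
    max_abs = np.abs(t_null).max(axis=0)

    dunnett_p = {}
    unadjusted_p = {}
    for idx, l in enumerate(labels):
        c = abs(t_obs[l])
        dunnett_p[l] = float((np.count_nonzero(max_abs >= c) + 1)
                             / (mc_draws + 1))
        unadjusted_p[l] = float((np.count_nonzero(np.abs(t_null[idx]) >= c) + 1)
                                / (mc_draws + 1))
    return DunnettResult(anova_f=float(f_stat), anova_p=float(anova_p),
                         t_stats=t_obs, dunnett_p=dunnett_p,
                         unadjusted_p=unadjusted_p)


def matched_control_max_t(comparisons: dict, mc_draws: int = 100_000,
                          seed: int | None = None) -> dict:
    """Family-wise adjusted p-values for treated-vs-matched-control tests.

    *comparisons* maps a key to (treated values, control values); each
    comparison has its own control group (e.g. treated vs untreated at the
    same timepoint), so the test statistics share only the pooled variance.
    The adjustment is the tail probability of the maximum |t| over the
    family, estimated by seeded Monte Carlo, mirroring the shared-control
    Dunnett construction.
    """
    if not comparisons:
        raise ValueError("no comparisons")
    arrays = {k: (np.asarray(t, float), np.asarray(c, float))
              for k, (t, c) in comparisons.items()}
    dof = 0
    ss = 0.0
    for t, c in arrays.values():
        for v in (t, c):
            if len(v) < 2:
                raise ValueError("each group needs at least 2 replicates")
            dof += len(v) - 1
            ss += (len(v) - 1) * v.var(ddof=1)
    if ss == 0:
        raise ValueError("degenerate: zero within-group variance everywhere")
    pooled = ss / dof
    t_obs = {
        k: (t.mean() - c.mean()) / np.sqrt(pooled * (1 / len(t) + 1 / len(c)))
        for k, (t, c) in arrays.items()
    }
    rng = np.random.default_rng(seed)
    s2 = rng.chisquare(dof, size=mc_draws) / dof
    t_null = np.empty((len(arrays), mc_draws))
    for idx, (k, (t, c)) in enumerate(arrays.items()):
        zt = rng.standard_normal(mc_draws) / np.sqrt(len(t))
        zc = rng.standard_normal(mc_draws) / np.sqrt(len(c))
        t_null[idx] = (zt - zc) / np.sqrt(s2 * (1 / len(t) + 1 / len(c)))
    max_abs = np.abs(t_null).max(axis=0)
    return {
        k: float((np.count_nonzero(max_abs >= abs(t_obs[k])) + 1)
                 / (mc_draws + 1))
        for k in arrays
    }


# ---------------------------------------------------------------------------
# Full per-gene analysis
# ---------------------------------------------------------------------------

def expression_analysis(ct: pd.DataFrame, targets: list[str],
                        references: list[str],
                        control_condition: str | None = None,
                        control_timepoint=None,
                        mc_draws: int = 100_000,
                        seed: int | None = None) -> ExpressionTable:
    """ddCt quantification plus ANOVA/Dunnett statistics per gene.

    For each target gene, dCt replicate values of all non-control groups are
    compared against the control group; results rows gain ``anova_p``,
    ``dunnett_p`` and a star ``significance`` category.
    """
    table = delta_delta_ct(ct, targets, references,
                           control_condition=control_condition,
                           control_timepoint=control_timepoint)
    results = table.results
    if results.empty:
        return table
    anova_col, dunnett_col, star_col = {}, {}, {}
    rng = np.random.default_rng(seed)
    matched_mode = control_condition is not None and control_timepoint is None
    for gene, sub in table.replicates.groupby("gene_id"):
        groups = {
            key: cell["delta_ct"].to_numpy()
            for key, cell in sub.groupby(["condition", "timepoint"])
        }
        usable = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            continue
        sub_seed = int(rng.integers(0, 2**31))
        try:
            if matched_mode:
                # treated vs untreated at the same timepoint, family-wise
                # adjusted over timepoints (and conditions)
                comparisons = {
                    (cond, tp): (vals, usable[(control_condition, tp)])
                    for (cond, tp), vals in usable.items()
                    if cond != control_condition
                    and (control_condition, tp) in usable
                }
                if not comparisons:
                    continue
                adjusted = matched_control_max_t(comparisons,
                                                 mc_draws=mc_draws,
                                                 seed=sub_seed)
                f_stat, anova_p = stats.f_oneway(*usable.values())
                for key in usable:
                    anova_col[(gene, *key)] = float(anova_p)
                for key, p in adjusted.items():
                    dunnett_col[(gene, *key)] = p
                    star_col[(gene, *key)] = significance_category(p)
            else:
                # one common control group: classic Dunnett
                gene_rows = results[results["gene_id"] == gene]
                controls = gene_rows[gene_rows["is_control"]]
                if controls.empty:
                    continue
                control_key = (controls.iloc[0]["condition"],
                               controls.iloc[0]["timepoint"])
                if control_key not in usable:
                    continue
                stat = anova_dunnett(usable, control_key, mc_draws=mc_draws,
                                     seed=sub_seed)
                for key in usable:
                    anova_col[(gene, *key)] = stat.anova_p
                    if key != control_key:
                        dunnett_col[(gene, *key)] = stat.dunnett_p[key]
                        star_col[(gene, *key)] = significance_category(
                            stat.dunnett_p[key])
        except ValueError:
            continue
    keys = list(zip(results["gene_id"], results["condition"], results["timepoint"]))
    results["anova_p"] = [anova_col.get(k, np.nan) for k in keys]
    results["dunnett_p"] = [dunnett_col.get(k, np.nan) for k in keys]
    results["significance"] = [star_col.get(k, "ns") for k in keys]
    return ExpressionTable(results=results, replicates=table.replicates,
                           not_expressed=table.not_expressed)


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternCall:
    gene_id: str
    pattern: str      # {monotone-up, peak-mid, monotone-down, static}
    evidence: dict = field(default_factory=dict, hash=False, compare=False)


def classify_aging_pattern(gene_id: str, means: dict,
                           timepoints=(14, 21, 28)) -> PatternCall:
    """Classify a three-timepoint expression trajectory.

    monotone-up: strictly rising across all three ages; peak-mid: middle age
    strictly above both ends; monotone-down: strictly falling; anything else
    (including exact ties) is static.
    """
    try:
        m1, m2, m3 = (means[t] for t in timepoints)
    except KeyError as exc:
        raise ValueError(f"gene {gene_id}: missing timepoint {exc}") from None
    if m3 > m2 > m1:
        pattern = "monotone-up"
    elif m2 > m1 and m2 > m3:
        pattern = "peak-mid"
    elif m1 > m2 > m3:
        pattern = "monotone-down"
    else:
        pattern = "static"
    return PatternCall(gene_id=gene_id, pattern=pattern,
                       evidence={"means": dict(means)})


def classify_treatment_response(timepoint_results: list[tuple],
                                alpha: float = 0.05) -> str:
    """Label a gene's treatment response across timepoints.

    *timepoint_results* is a list of (timepoint, fold, dunnett_p) tuples for
    the non-control timepoints. upregulated: at least one significant fold
    above 1 and no significant fold below 1; downregulated symmetric;
    static: nothing significant; mixed: significant changes in both
    directions.
    """
    if not timepoint_results:
        raise ValueError("no timepoints to classify")
    sig_up = any(f > 1 and p < alpha for _, f, p in timepoint_results
                 if np.isfinite(p))
    sig_down = any(f < 1 and p < alpha for _, f, p in timepoint_results
                   if np.isfinite(p))
    if sig_up and not sig_down:
        return "upregulated"
    if sig_down and not sig_up:
        return "downregulated"
    if not sig_up and not sig_down:
        any_sig = any(p < alpha for _, _, p in timepoint_results
                      if np.isfinite(p))
        return "mixed" if any_sig else "static"
    return "mixed"
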
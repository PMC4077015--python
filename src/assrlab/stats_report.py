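"""Two-level group statistics and report writing.

The study reports every contrast twice: *per animal* (channels averaged
within animal first, n = number of mice) and *per channel* (each electrode
one observation).  Group differences use the pooled-variance (Student)
unpaired t with Cohen's d (pooled SD, n-1 denominators, sign convention
``(mean_a - mean_b) / pooled_sd``).  Epoch-by-genotype band-power tables
are assessed with a classic mixed-design (split-plot) repeated-measures
ANOVA — between factor genotype, within factor epoch, subject nested in
genotype, no sphericity correction — followed by Bonferroni-adjusted
paired epoch comparisons within each genotype.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    statistic_t: float
    df: int
    p_value: float
    cohens_d: float
    n_per_group: tuple[int, int]
    design: str = "per_animal"  # or "per_channel"


@dataclass
class RmAnovaResult:
    F_between: float
    df_between: tuple[int, int]
    p_between: float
    F_within: float
    df_within: tuple[int, int]
    p_within: float
    F_interaction: float
    p_interaction: float
    posthoc: pd.DataFrame
    n_comparisons: int
    sphericity_corrected: bool = False  # classic split-plot F, no GG correction
    degenerate: bool = False


def aggregate_per_animal(
    values: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Unweighted mean across channels within animal.

    ``values`` must carry ``animal_id`` (and usually ``genotype``); any
    animal with zero rows simply does not appear, but an explicit NaN value
    is an error.
    """
    if "animal_id" not in values.columns:
        raise ValueError("values must be tagged with animal_id")
    if values[value_col].isna().any():
        raise ValueError("NaN values cannot be aggregated")
    keys = ["animal_id"] + (["genotype"] if "genotype" in values.columns else [])
    return values.groupby(keys, as_index=False)[value_col].mean()


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Classic Cohen's d: (mean_a - mean_b) / pooled SD (n-1 denominators)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / pooled)


def unpaired_t(
    group_a: Sequence[float], group_b: Sequence[float], design: str = "per_animal"
) -> GroupComparison:
    """Two-sided pooled-variance Student's t with Cohen's d."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    d = cohens_d(a, b)
    if d == 0.0 and a.var(ddof=1) + b.var(ddof=1) == 0:
        # identical constant groups: t = 0, p = 1 by convention
        return GroupComparison(0.0, a.size + b.size - 2, 1.0, 0.0, (a.size, b.size), design)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        float(t), a.size + b.size - 2, float(p), d, (a.size, b.size), design
    )


def _split_plot_f(table: pd.DataFrame) -> dict:
    """Classic split-plot sums of squares on a balanced long table.

    Columns: subject, group, epoch, value.  Between factor = group,
    within factor = epoch, subject nested in group.
    """
    wide = table.pivot_table(index=["group", "subject"], columns="epoch", values="value")
    if wide.isna().any().any():
        raise ValueError("missing cells: every subject needs all epochs")
    groups = wide.index.get_level_values("group").unique()
    a = len(groups)
    counts = wide.groupby(level="group").size()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")
    b = wide.shape[1]
    grand = wide.values.mean()
    g_means = wide.groupby(level="group").mean().mean(axis=1)          # per group
    s_means = wide.mean(axis=1)                                        # per subject
    e_means = wide.mean(axis=0)                                        # per epoch
    ge_means = wide.groupby(level="group").mean()                      # group x epoch

    n_per = counts.to_dict()
    N = wide.shape[0]
    ss_a = sum(n_per[g] * b * (g_means[g] - grand) ** 2 for g in groups)
    ss_subj = b * sum(
        (s_means[(g, s)] - g_means[g]) ** 2
        for g, s in wide.index
    )
    ss_b = N * ((e_means - grand) ** 2).sum()
    ss_ab = sum(
        n_per[g] * (ge_means.loc[g, e] - g_means[g] - e_means[e] + grand) ** 2
        for g in groups
        for e in wide.columns
    )
    ss_total = ((wide.values - grand) ** 2).sum()
    ss_err = ss_total - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, N - a
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = df_subj * df_b
    ms = lambda ss, df: ss / df if df > 0 else np.nan
    ms_subj, ms_err = ms(ss_subj, df_subj), ms(ss_err, df_err)
    degenerate = not (ms_subj > 0 and ms_err > 0)
    if degenerate:
        f_a = f_b = f_ab = np.nan
        p_a = p_b = p_ab = np.nan
    else:
        f_a = ms(ss_a, df_a) / ms_subj
        f_b = ms(ss_b, df_b) / ms_err
        f_ab = ms(ss_ab, df_ab) / ms_err
        p_a = sps.f.sf(f_a, df_a, df_subj)
        p_b = sps.f.sf(f_b, df_b, df_err)
        p_ab = sps.f.sf(f_ab, df_ab, df_err)
    return dict(
        F_between=f_a, df_between=(df_a, df_subj), p_between=p_a,
        F_within=f_b, df_within=(df_b, df_err), p_within=p_b,
        F_interaction=f_ab, p_interaction=p_ab, degenerate=degenerate,
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, float)
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)


def mixed_rm_anova(
    table: pd.DataFrame,
    value_col: str = "mean_power",
    subject_col: str | None = None,
    design: str = "per_animal",
) -> RmAnovaResult:
    """Mixed-design rmANOVA on one band of a state table.

    ``table`` is tidy with columns animal_id, channel_id, genotype, epoch
    and ``value_col`` for a single band.  In the per-animal design the
    subject is the animal (channels averaged first); in the per-channel
    design each (animal, channel) pair is a subject.  Post-hoc: paired t
    over all epoch pairs within each genotype, Bonferroni-adjusted with m =
    total number of pairs tested across genotypes.
    """
    df = table.copy()
    if subject_col is None:
        if design == "per_animal":
            df = (
                df.groupby(["animal_id", "genotype", "epoch"], as_index=False)[value_col]
                .mean()
            )
            df["subject"] = df["animal_id"]
        elif design == "per_channel":
            df["subject"] = df["animal_id"].astype(str) + "/" + df["channel_id"].astype(str)
        else:
            raise ValueError(f"unknown design {design!r}")
    else:
        df["subject"] = df[subject_col]

    long = df.rename(columns={"genotype": "group", value_col: "value"})[
        ["subject", "group", "epoch", "value"]
    ]
    res = _split_plot_f(long)

    # post-hoc: epoch pairs within genotype, paired over subjects
    epochs = list(dict.fromkeys(long["epoch"]))
    pairs = [(e1, e2) for i, e1 in enumerate(epochs) for e2 in epochs[i + 1 :]]
    rows = []
    for g in long["group"].unique():
        sub = long[long["group"] == g].pivot(index="subject", columns="epoch", values="value")
        for e1, e2 in pairs:
            x, y = sub[e1].values, sub[e2].values
            if np.allclose(x, y):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(x, y)
            rows.append({"group": g, "epoch_a": e1, "epoch_b": e2,
                         "t": float(t), "p_raw": float(p)})
    posthoc = pd.DataFrame(rows)
    m = len(posthoc)
    if m:
        posthoc["p_bonferroni"] = bonferroni(posthoc["p_raw"].values, m)
    if res["degenerate"]:
        logger.warning("degenerate ANOVA table (zero error variance); F reported as NaN")
    return RmAnovaResult(
        F_between=res["F_between"], df_between=res["df_between"], p_between=res["p_between"],
        F_within=res["F_within"], df_within=res["df_within"], p_within=res["p_within"],
        F_interaction=res["F_interaction"], p_interaction=res["p_interaction"],
        posthoc=posthoc, n_comparisons=m, degenerate=res["degenerate"],
    )


# ---------------------------------------------------------------------------
# Report writing

def _comparison_row(name: str, band: str, cmp: GroupComparison) -> dict:
    return {
        "measure": name,
        "band": band,
        "design": cmp.design,
        "t": cmp.statistic_t,
        "df": cmp.df,
        "p": cmp.p_value,
        "cohens_d": cmp.cohens_d,
        "n_a": cmp.n_per_group[0],
        "n_b": cmp.n_per_group[1],
    }


def anova_summary_rows(band: str, design: str, res: RmAnovaResult) -> list[dict]:
    base = {"band": band, "design": design, "degenerate": res.degenerate,
            "sphericity_corrected": res.sphericity_corrected,
            "n_posthoc_comparisons": res.n_comparisons}
    return [
        {**base, "effect": "genotype", "F": res.F_between,
         "df1": res.df_between[0], "df2": res.df_between[1], "p": res.p_between},
        {**base, "effect": "epoch", "F": res.F_within,
         "df1": res.df_within[0], "df2": res.df_within[1], "p": res.p_within},
        {**base, "effect": "genotype_x_epoch", "F": res.F_interaction,
         "df1": (res.df_between[0]) * (res.df_within[0]), "df2": res.df_within[1],
         "p": res.p_interaction},
    ]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def make_report(results: dict, out_dir) -> list[Path]:
    """Write analysis outputs as TSV tables plus a JSON manifest.

    ``results`` maps table names to DataFrames (written as ``<name>.tsv``)
    and may carry a ``manifest`` dict (written as ``manifest.json``).
    Returns the written paths.  Empty results produce a manifest only,
    with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {k: v for k, v in results.items() if isinstance(v, pd.DataFrame)}
    if not tables:
        logger.warning("no result tables to write; emitting manifest only")
    for name, df in sorted(tables.items()):
        path = out_dir / f"{name}.tsv"
        write_tsv(df, path)
        written.append(path)
    manifest = dict(results.get("manifest", {}))
    manifest["tables"] = [p.name for p in written]
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written


def comparison_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["measure", "band", "design", "t", "df", "p", "cohens_d", "n_a", "n_b"],
    )


def group_compare_tidy(
    values: pd.DataFrame,
    value_col: str,
    measure: str,
    band: str,
    design: str,
) -> dict:
    """Run the control-vs-mutant t-test on a tidy value table."""
    ctrl = values.loc[values["genotype"] == "control", value_col].values
    mut = values.loc[values["genotype"] == "mutant", value_col].values
    return _comparison_row(measure, band, unpaired_t(ctrl, mut, design=design))
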
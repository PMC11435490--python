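"""Rank-based group statistics for the gait-index tables.

Cross-sectional layer: tie-corrected Kruskal-Wallis omnibus with the
eta-squared effect size (H - k + 1)/(n - k), Dunn pairwise z tests on
pooled mean ranks with Holm's step-down correction, Pearson chi-square
(no continuity correction) for 2x2 categorical tables and the two-sided
Mann-Whitney test for continuous two-group comparisons.

Longitudinal layer: nonparametric repeated-measures analysis for a
two-group (between) x two-timepoint (within) design, using mid-rank
relative treatment effects and ANOVA-type statistics with Box-type
degrees-of-freedom approximation.  Post-hoc contrasts are gated on a
significant interaction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import block_diag

logger = logging.getLogger("trunkgait")


# ---------------------------------------------------------------------------
# cross-sectional tests
# ---------------------------------------------------------------------------

def kruskal_wallis_eta(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Kruskal-Wallis H (tie-corrected), chi-square p and eta-squared.

    eta^2 = (H - k + 1) / (n - k), clipped at zero.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    h, p = stats.kruskal(*samples)
    k, n = len(samples), len(values)
    eta2 = max((h - k + 1) / (n - k), 0.0)
    return float(h), float(p), float(eta2)


def _tie_term(values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups, for Dunn's variance correction."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def dunn_holm(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn pairwise z statistics with Holm-adjusted two-sided p-values.

    z uses pooled mean-rank differences with the tie-corrected variance
    and the large-sample normal approximation for all sample sizes.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    n = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: float(np.mean(ranks[groups == g])) for g in labels}
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    var_base = n * (n + 1) / 12.0 - _tie_term(values) / (12.0 * (n - 1))

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p_raw": float(2.0 * stats.norm.sf(abs(z)))})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# nonparametric repeated measures (two groups x two timepoints)
# ---------------------------------------------------------------------------

@dataclass
class RepeatedMeasuresResult:
    """ANOVA-type statistics for Time, Group and Time x Group."""

    relative_effects: pd.DataFrame
    time: dict = field(default_factory=dict)
    group: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    n_subjects: dict = field(default_factory=dict)
    posthoc_gated: bool = False


def _ats(p_hat: np.ndarray, v_hat: np.ndarray, contrast: np.ndarray,
         n_total: int) -> tuple[float, float]:
    """ANOVA-type statistic and its numerator df for one contrast matrix."""
    m = contrast.T @ np.linalg.pinv(contrast @ contrast.T) @ contrast
    mv = m @ v_hat
    tr = float(np.trace(mv))
    if tr <= 0:
        return 0.0, 1.0
    statistic = n_total * float(p_hat @ m @ p_hat) / tr
    f_num = tr ** 2 / float(np.trace(mv @ mv))
    return statistic, f_num


def rank_repeated_measures(
    data: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "subject_id",
    group_col: str = "group",
    time_col: str = "timepoint",
    alpha: float = 0.05,
) -> RepeatedMeasuresResult:
    """Rank-based two-group x two-timepoint repeated-measures analysis.

    Subjects missing a timepoint are dropped with a warning.  Relative
    treatment effects come from mid-ranks over all observations; each
    effect is tested with the ANOVA-type statistic: within-subject effects
    against F(f, inf), the between-subject effect against F(f, f0) with a
    Box-type denominator df pooled over groups.
    """
    df = data[[subject_col, group_col, time_col, value_col]].copy()
    times = sorted(df[time_col].unique())
    t = len(times)
    complete = df.groupby(subject_col)[time_col].nunique()
    keep = complete[complete == t].index
    dropped = set(df[subject_col]) - set(keep)
    if dropped:
        logger.warning("dropping %d subject(s) missing a timepoint: %s",
                       len(dropped), sorted(dropped))
        df = df[df[subject_col].isin(keep)]
    groups = sorted(df[group_col].unique())
    a = len(groups)
    if a < 2:
        raise ValueError("need two groups for the repeated-measures analysis")

    df["_rank"] = stats.rankdata(df[value_col].to_numpy())
    n_big = len(df)  # total observations = n * t

    # subject x time rank matrices per group
    rank_mats = []
    n_per_group = {}
    for g in groups:
        sub = df[df[group_col] == g].pivot_table(
            index=subject_col, columns=time_col, values="_rank")
        sub = sub[times]
        rank_mats.append(sub.to_numpy(dtype=float))
        n_per_group[g] = len(sub)
    n_subjects = int(sum(n_per_group.values()))

    # relative effects per cell (group-major order) and their covariance
    p_hat = np.concatenate([ (mat.mean(axis=0) - 0.5) / n_big for mat in rank_mats ])
    blocks = []
    for g, mat in zip(groups, rank_mats):
        ni = len(mat)
        if ni < 2:
            raise ValueError(f"group {g} needs >= 2 complete subjects")
        cov = np.cov(mat, rowvar=False, ddof=1) / n_big ** 2
        cov = np.atleast_2d(cov)
        blocks.append(n_subjects / ni * cov)
    v_hat = block_diag(*blocks)

    # contrast matrices on the a*t cell means
    p_a = np.eye(a) - np.full((a, a), 1.0 / a)
    p_t = np.eye(t) - np.full((t, t), 1.0 / t)
    ones_a = np.full((1, a), 1.0 / a)
    ones_t = np.full((1, t), 1.0 / t)
    c_group = np.kron(p_a, ones_t)
    c_time = np.kron(ones_a, p_t)
    c_inter = np.kron(p_a, p_t)

    result = RepeatedMeasuresResult(
        relative_effects=pd.DataFrame(
            {"group": np.repeat(groups, t), "timepoint": times * a,
             "relative_effect": p_hat}),
        n_subjects=n_per_group,
    )

    for name, c in (("time", c_time), ("group", c_group), ("interaction", c_inter)):
        statistic, f_num = _ats(p_hat, v_hat, c, n_subjects)
        if name == "group":
            # Box-type denominator df pooled over the group-diagonal blocks
            m = c.T @ np.linalg.pinv(c @ c.T) @ c
            traces, dfs = [], []
            off = 0
            for g, mat in zip(groups, rank_mats):
                blk = slice(off, off + t)
                traces.append(float(np.trace(m[blk, blk] @ v_hat[blk, blk])))
                dfs.append(len(mat) - 1)
                off += t
            denom = sum(tr ** 2 / d for tr, d in zip(traces, dfs))
            f_den = (sum(traces) ** 2 / denom) if denom > 0 else np.inf
            p = float(stats.f.sf(statistic, f_num, f_den))
            setattr(result, name, {"statistic": statistic, "df_num": f_num,
                                   "df_den": f_den, "p": p})
        else:
            p = float(stats.chi2.sf(statistic * f_num, f_num))
            setattr(result, name, {"statistic": statistic, "df_num": f_num,
                                   "df_den": np.inf, "p": p})

    result.posthoc_gated = result.interaction["p"] < alpha
    return result


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

GAIT_INDEX_COLUMNS = (
    "gait_speed", "hr_v", "hr_ml", "hr_ap", "slle_v", "slle_ml", "slle_ap",
    "ldlj_v", "ldlj_ml", "ldlj_ap", "si_stance", "si_swing", "si_double", "si_single",
)


def build_t0_report(
    indexes: pd.DataFrame,
    index_cols: tuple[str, ...] = GAIT_INDEX_COLUMNS,
    group_col: str = "group",
) -> pd.DataFrame:
    """Cross-sectional table: per-group mean (SD), H, p, eta^2 and Dunn pairs.

    Indexes absent from the input raise; groups with too few observations
    produce NA test columns with a warning.
    """
    missing = [c for c in index_cols if c not in indexes.columns]
    if missing:
        raise KeyError(f"index column(s) missing from input: {missing}")
    groups = list(pd.unique(indexes[group_col]))
    rows = []
    for col in index_cols:
        sub = indexes[[group_col, col]].dropna()
        row: dict = {"index": col}
        for g in groups:
            vals = sub.loc[sub[group_col] == g, col]
            row[f"mean_{g}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{g}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        try:
            h, p, eta2 = kruskal_wallis_eta(sub[col].to_numpy(), sub[group_col].to_numpy())
            row.update(H=h, p=p, eta2=eta2)
            for _, d in dunn_holm(sub[col].to_numpy(), sub[group_col].to_numpy()).iterrows():
                pair = f"{d['group_a']}_vs_{d['group_b']}"
                row[f"dunn_z_{pair}"] = d["z"]
                row[f"dunn_p_{pair}"] = d["p_holm"]
        except ValueError as exc:
            logger.warning("omnibus unavailable for %s: %s", col, exc)
            row.update(H=np.nan, p=np.nan, eta2=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def build_longitudinal_report(
    indexes: pd.DataFrame,
    index_cols: tuple[str, ...],
    subject_col: str = "subject_id",
    group_col: str = "group",
    time_col: str = "timepoint",
) -> pd.DataFrame:
    """Repeated-measures table: Time / Group / Interaction p per index."""
    rows = []
    for col in index_cols:
        if col not in indexes.columns:
            raise KeyError(f"index column {col} missing from input")
        long = indexes[[subject_col, group_col, time_col, col]].dropna()
        long = long.rename(columns={col: "value"})
        res = rank_repeated_measures(long, subject_col=subject_col,
                                     group_col=group_col, time_col=time_col)
        rows.append({
            "index": col,
            "time_stat": res.time["statistic"], "time_p": res.time["p"],
            "group_stat": res.group["statistic"], "group_p": res.group["p"],
            "interaction_stat": res.interaction["statistic"],
            "interaction_p": res.interaction["p"],
            "posthoc_gated": res.posthoc_gated,
        })
    return pd.DataFrame(rows)
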
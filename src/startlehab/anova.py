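"""Mixed-design (split-plot) ANOVA on mean TDT20.

The assay's design crosses one between-subjects factor (group: control vs
concussed) with one within-subjects factor (test time, six levels), each
fish measured at every time.  The analysis stack is:

* the 2 x 6 mixed-design ANOVA (group, time, group x time) from the
  classical split-plot sums-of-squares decomposition

      SS_total = SS_group + SS_subjects(group) + SS_time
                 + SS_group:time + SS_residual

  with the group effect tested against subjects-within-groups and the
  within effects against the residual;
* Greenhouse-Geisser correction of the within-effect degrees of freedom
  (epsilon estimated from the pooled within-group covariance of the six
  repeated measures and applied unconditionally, no sphericity-test
  gating);
* follow-up one-way repeated-measures ANOVAs per group;
* all 15 pairwise time contrasts from paired differences, p-values
  adjusted for multiplicity (Bonferroni by default).

All sums of squares are computed directly from the decomposition rather
than delegated, so they can be checked against hand arithmetic on tiny
designs; only the F survival function and the multiplicity adjustment come
from scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["EffectResult", "MixedAnovaResult", "PairwiseTable",
           "make_tdt20_table", "mixed_anova", "rm_anova_per_group",
           "pairwise_times", "greenhouse_geisser_epsilon"]


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F, raw and epsilon-corrected dfs, p."""

    effect: str
    ss: float
    df_num: float
    df_den: float
    F: float
    p_raw: float
    gg_epsilon: float = 1.0
    df_num_gg: float = None
    df_den_gg: float = None
    p_gg: float = None

    def __post_init__(self):
        if self.df_num_gg is None:
            object.__setattr__(self, "df_num_gg", self.df_num)
            object.__setattr__(self, "df_den_gg", self.df_den)
            object.__setattr__(self, "p_gg", self.p_raw)


@dataclass(frozen=True)
class MixedAnovaResult:
    effects: dict                       # name -> EffectResult
    gg_epsilon: float
    marginal_means: pd.DataFrame        # group x time cell means and SEs
    n_subjects: int
    n_groups: int
    n_times: int
    epsilon_warning: bool = False
    ss_table: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairwiseTable:
    frame: pd.DataFrame                 # time_i, time_j, mean_diff, se, t, p, p_adjusted
    correction: str


def make_tdt20_table(traces) -> pd.DataFrame:
    """Per-fish TDT20 table (fish_id, group, test_time, tdt20) from traces."""
    from .habituation import tdt20
    rows = [(t.fish_id, t.group, t.test_time, tdt20(t)) for t in traces]
    return pd.DataFrame(rows, columns=["fish_id", "group", "test_time", "tdt20"])


def _pivot(table: pd.DataFrame, time_order=None) -> tuple[pd.DataFrame, pd.Series]:
    """Validated wide matrix (one row per fish, one column per time)."""
    required = {"fish_id", "group", "test_time", "tdt20"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if table.duplicated(subset=["fish_id", "test_time"]).any():
        raise ValueError("duplicate (fish_id, test_time) rows")
    groups = table.groupby("fish_id")["group"].nunique()
    if (groups > 1).any():
        raise ValueError("a fish appears in more than one group")
    wide = table.pivot(index="fish_id", columns="test_time", values="tdt20")
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"unbalanced table: fish missing test times: {bad}; "
                         "apply the completeness filter upstream")
    if time_order is not None:
        if set(time_order) != set(wide.columns):
            raise ValueError("time_order does not match the test times present")
        wide = wide[list(time_order)]
    fish_group = table.drop_duplicates("fish_id").set_index("fish_id")["group"]
    return wide, fish_group.loc[wide.index]


def greenhouse_geisser_epsilon(cov: np.ndarray, k: int | None = None):
    """Greenhouse-Geisser epsilon from a covariance of the repeated measures.

    Computed from the double-centred covariance S~ = C S C (C the centering
    projector): epsilon = tr(S~)^2 / ((k-1) tr(S~ S~)), clipped to
    [1/(k-1), 1].  Returns ``(epsilon, warning)``; a numerically singular
    double-centred covariance yields the lower bound with ``warning=True``.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    k = S.shape[0] if k is None else k
    C = np.eye(k) - np.ones((k, k)) / k
    St = C @ S @ C
    lower = 1.0 / (k - 1)
    denom = (k - 1) * np.trace(St @ St)
    if denom <= 1e-12 * max(1.0, np.trace(St) ** 2) or np.trace(St) <= 0:
        return lower, True
    eps = float(np.trace(St) ** 2 / denom)
    return float(np.clip(eps, lower, 1.0)), False


def _within_group_covariance(wide: pd.DataFrame, fish_group: pd.Series) -> np.ndarray:
    """Pooled (weighted by df) within-group covariance of the k measures."""
    mats, dfs = [], []
    for g in fish_group.unique():
        block = wide.loc[fish_group == g].to_numpy()
        if len(block) >= 2:
            mats.append(np.cov(block, rowvar=False) * (len(block) - 1))
            dfs.append(len(block) - 1)
    if not mats:
        raise ValueError("need at least 2 subjects in some group")
    return np.sum(mats, axis=0) / np.sum(dfs)


def _marginal_means(wide: pd.DataFrame, fish_group: pd.Series) -> pd.DataFrame:
    rows = []
    for g in fish_group.unique():
        block = wide.loc[fish_group == g]
        for tt in wide.columns:
            col = block[tt]
            rows.append((g, tt, col.mean(),
                         col.std(ddof=1) / np.sqrt(len(col)) if len(col) > 1 else 0.0,
                         len(col)))
    return pd.DataFrame(rows, columns=["group", "test_time", "mean", "se", "n"])


def mixed_anova(table: pd.DataFrame, time_order=None) -> MixedAnovaResult:
    """2 x k mixed-design ANOVA on a balanced per-fish TDT20 table.

    Between effect (group) tested on (G-1, N-G) df; within effect (time)
    and the interaction on raw df ((k-1), (N-G)(k-1)) with Greenhouse-
    Geisser corrected dfs epsilon * raw.  Requires a complete (balanced)
    table — enforce completeness upstream.
    """
    wide, fish_group = _pivot(table, time_order)
    y = wide.to_numpy()
    N, k = y.shape
    group_labels = fish_group.unique()
    G = len(group_labels)
    if G < 2:
        raise ValueError("mixed ANOVA needs at least 2 groups")
    n_per_group = fish_group.value_counts()
    if (n_per_group < 2).any():
        raise ValueError("each group needs at least 2 fish")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    group_idx = {g: (fish_group == g).to_numpy() for g in group_labels}

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(sum(k * group_idx[g].sum() * (y[group_idx[g]].mean() - grand) ** 2
                         for g in group_labels))
    ss_subj = ss_between_subj - ss_group
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    ss_cells = float(sum(group_idx[g].sum() * (y[group_idx[g], t].mean() - grand) ** 2
                         for g in group_labels for t in range(k)))
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_between_subj - ss_time - ss_inter

    df_group, df_subj = G - 1, N - G
    df_time = k - 1
    df_inter = (G - 1) * (k - 1)
    df_resid = (N - G) * (k - 1)
    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0 or ms_subj <= 0:
        raise ValueError("degenerate data: zero residual variance")

    eps, eps_warn = greenhouse_geisser_epsilon(
        _within_group_covariance(wide, fish_group), k)

    def effect(name, ss, df_num, df_den, ms_err, within):
        F = (ss / df_num) / ms_err
        p_raw = float(sps.f.sf(F, df_num, df_den))
        if within:
            dn, dd = eps * df_num, eps * df_den
            return EffectResult(name, ss, df_num, df_den, float(F), p_raw,
                                gg_epsilon=eps, df_num_gg=dn, df_den_gg=dd,
                                p_gg=float(sps.f.sf(F, dn, dd)))
        return EffectResult(name, ss, df_num, df_den, float(F), p_raw)

    effects = {
        "group": effect("group", ss_group, df_group, df_subj, ms_subj, False),
        "time": effect("time", ss_time, df_time, df_resid, ms_resid, True),
        "group:time": effect("group:time", ss_inter, df_inter, df_resid,
                             ms_resid, True),
    }
    ss_table = {"group": ss_group, "subjects(group)": ss_subj, "time": ss_time,
                "group:time": ss_inter, "residual": ss_resid, "total": ss_total}
    return MixedAnovaResult(effects=effects, gg_epsilon=eps,
                            marginal_means=_marginal_means(wide, fish_group),
                            n_subjects=N, n_groups=G, n_times=k,
                            epsilon_warning=eps_warn, ss_table=ss_table)


def rm_anova_per_group(table: pd.DataFrame, time_order=None) -> MixedAnovaResult:
    """One-way repeated-measures ANOVA (time effect) for a single group.

    Raw df ((k-1), (n-1)(k-1)); Greenhouse-Geisser correction as in the
    mixed model.
    """
    if table["group"].nunique() != 1:
        raise ValueError("rm_anova_per_group expects exactly one group; "
                         "subset the table first")
    wide, fish_group = _pivot(table, time_order)
    y = wide.to_numpy()
    n, k = y.shape
    if n < 2:
        raise ValueError("need at least 2 fish")

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_subj = float(k * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(n * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_resid = ss_total - ss_subj - ss_time
    df_time, df_resid = k - 1, (n - 1) * (k - 1)
    ms_resid = ss_resid / df_resid
    if ms_resid <= 1e-300:
        raise ValueError("degenerate data: zero residual variance")

    cov = np.cov(y, rowvar=False)
    eps, eps_warn = greenhouse_geisser_epsilon(cov, k)
    F = (ss_time / df_time) / ms_resid
    dn, dd = eps * df_time, eps * df_resid
    eff = EffectResult("time", ss_time, df_time, df_resid, float(F),
                       float(sps.f.sf(F, df_time, df_resid)), gg_epsilon=eps,
                       df_num_gg=dn, df_den_gg=dd, p_gg=float(sps.f.sf(F, dn, dd)))
    ss_table = {"subjects": ss_subj, "time": ss_time, "residual": ss_resid,
                "total": ss_total}
    return MixedAnovaResult(effects={"time": eff}, gg_epsilon=eps,
                            marginal_means=_marginal_means(wide, fish_group),
                            n_subjects=n, n_groups=1, n_times=k,
                            epsilon_warning=eps_warn, ss_table=ss_table)


_CORRECTIONS = {"bonferroni": "bonferroni", "holm": "holm", "sidak": "sidak",
                "fdr_bh": "fdr_bh", "none": None}


def pairwise_times(table: pd.DataFrame, correction: str = "bonferroni",
                   time_order=None) -> PairwiseTable:
    """All pairwise time contrasts for one group, from paired differences.

    Each contrast is a paired t-test over fish; p-values adjusted by the
    configured method (Bonferroni default).
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; "
                         f"choose from {sorted(_CORRECTIONS)}")
    if table["group"].nunique() != 1:
        raise ValueError("pairwise_times expects a single-group table")
    wide, _ = _pivot(table, time_order)
    n = len(wide)
    rows = []
    for t_i, t_j in combinations(wide.columns, 2):
        diff = (wide[t_j] - wide[t_i]).to_numpy()
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1))
        se = sd / np.sqrt(n)
        if se == 0:
            t_stat, p = (0.0, 1.0) if mean == 0 else (np.inf, 0.0)
        else:
            t_stat = mean / se
            p = float(2 * sps.t.sf(abs(t_stat), n - 1))
        rows.append((t_i, t_j, mean, float(se), float(t_stat), p))
    frame = pd.DataFrame(rows, columns=["time_i", "time_j", "mean_diff",
                                        "se", "t", "p"])
    method = _CORRECTIONS[correction]
    if method is None:
        frame["p_adjusted"] = frame["p"]
    else:
        frame["p_adjusted"] = multipletests(frame["p"].to_numpy(),
                                            method=method)[1]
    return PairwiseTable(frame=frame, correction=correction)
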
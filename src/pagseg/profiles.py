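"""Per-column connectivity profiles to named targets and their comparison.

Whole-seed connectivity to each target is computed first and targets whose
mean connection probability falls below the removal floor (P < 3e-4) are
dropped — in the human study this is what eliminated the anterior cingulate
and paracingulate targets. Per-column profiles are the mean connection
probability over the column's retained voxels, and each column's *relative*
connectivity is its share of the four-column total for a target.

Across a cohort, columns are compared pairwise: per target with paired
t-tests (Wilcoxon available as a switch), Bonferroni-corrected over the six
column pairs, and per pair with a within-subject permutation test over the
whole target vector (random exchange of the two column labels inside each
subject, i.e. sign flips of the paired differences) in place of a classical
repeated-measures MANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import UNASSIGNED, ClusterResult
from .tracking import ConnectivityMatrix

__all__ = [
    "ColumnProfile",
    "total_seed_connectivity",
    "column_profiles",
    "profiles_to_frame",
    "pairwise_column_tests",
    "multivariate_permutation_test",
    "plot_radial_profiles",
]


@dataclass
class ColumnProfile:
    """Connection probabilities of one column to every retained target."""

    column: str
    target_probs: Dict[str, float]
    relative: Dict[str, float]
    n_voxels: int = 0


def total_seed_connectivity(
    cm: ConnectivityMatrix,
    prob_threshold: float = 0.0003,
) -> Tuple[Dict[str, float], List[str]]:
    """Mean whole-seed connection probability per target, plus removals.

    For each target: the mean over seed voxels of (samples reaching any voxel
    of the target) / n_samples. Targets with mean probability below
    ``prob_threshold`` are flagged for removal from profile analysis.
    """
    if not cm.target_names:
        raise ValueError("connectivity matrix carries no target counts")
    probs = cm.target_probabilities().mean(axis=0)
    table = {name: float(p) for name, p in zip(cm.target_names, probs)}
    removed = [name for name, p in table.items() if p < prob_threshold]
    return table, removed


def column_profiles(
    cluster_result: ClusterResult,
    cm: ConnectivityMatrix,
    retained_targets: Sequence[str],
) -> List[ColumnProfile]:
    """Mean and relative per-column connection probability to each target.

    Relative shares are normalized across columns per target and sum to one
    whenever any column connects. Empty columns (no retained voxels) are
    excluded with a warning record rather than imputed.
    """
    tprob = cm.target_probabilities()
    name_to_idx = {n: i for i, n in enumerate(cm.target_names)}
    cols = [
        (c, ident)
        for c, ident in sorted(cluster_result.column_identity.items())
        if ident != UNASSIGNED
    ]
    if not cols:
        return []

    means = np.zeros((len(cols), len(retained_targets)))
    n_vox = []
    kept_cols = []
    for c, ident in cols:
        sel = (cluster_result.labels == c) & cluster_result.retained
        if not sel.any():
            import warnings

            warnings.warn(f"column {ident!r} has no retained voxels; excluded")
            continue
        kept_cols.append((c, ident))
        row = [tprob[sel, name_to_idx[t]].mean() for t in retained_targets]
        means[len(kept_cols) - 1] = row
        n_vox.append(int(sel.sum()))
    means = means[: len(kept_cols)]

    totals = means.sum(axis=0)
    shares = np.divide(
        means, totals[None, :], out=np.zeros_like(means), where=totals[None, :] > 0
    )
    return [
        ColumnProfile(
            column=ident,
            target_probs={t: float(means[i, j]) for j, t in enumerate(retained_targets)},
            relative={t: float(shares[i, j]) for j, t in enumerate(retained_targets)},
            n_voxels=n_vox[i],
        )
        for i, (c, ident) in enumerate(kept_cols)
    ]


def profiles_to_frame(
    cohort_profiles: Sequence[Tuple[int, str, Sequence[ColumnProfile]]],
) -> pd.DataFrame:
    """Tidy frame (subject, side, column, target, prob, relative)."""
    rows = []
    for subject, side, profs in cohort_profiles:
        for p in profs:
            for t in p.target_probs:
                rows.append(
                    {
                        "subject": subject,
                        "side": side,
                        "column": p.column,
                        "target": t,
                        "prob": p.target_probs[t],
                        "relative": p.relative[t],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def multivariate_permutation_test(
    diffs: np.ndarray,
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> float:
    """Within-subject permutation test on paired multivariate differences.

    ``diffs`` is (n_subjects, n_targets): per-subject difference of the two
    columns' target-probability vectors. The statistic is the sum over
    targets of squared paired t statistics; the null distribution is built by
    random sign flips of whole subject rows (exchangeability of the two
    column labels within subject). Returns the permutation p-value with the
    add-one convention.
    """
    diffs = np.asarray(diffs, dtype=np.float64)
    n, _ = diffs.shape
    if n < 3:
        raise ValueError("at least 3 subjects are required")

    def statistic(d: np.ndarray) -> np.ndarray:
        m = d.mean(axis=-2)
        sd = d.std(axis=-2, ddof=1)
        se = sd / np.sqrt(n)
        t = np.divide(m, se, out=np.zeros_like(m), where=se > 0)
        return (t**2).sum(axis=-1)

    t_obs = statistic(diffs)
    rng = np.random.default_rng(rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n, 1))
    t_perm = statistic(signs * diffs[None, :, :])
    return float((1 + np.sum(t_perm >= t_obs - 1e-12)) / (1 + n_permutations))


def pairwise_column_tests(
    cohort: pd.DataFrame,
    n_permutations: int = 10_000,
    rng_seed: int = 0,
    method: str = "ttest",
    value_col: str = "prob",
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], float]]:
    """Column-pair comparisons across subjects, per target and multivariate.

    ``cohort`` is a tidy frame with columns subject, column, target and the
    value column; per (subject, column, target) values are averaged over
    sides first. Per-target paired tests (t-test by default, Wilcoxon with
    ``method='wilcoxon'``) are Bonferroni-corrected over the six column
    pairs. Each pair additionally gets a multivariate permutation p-value
    over the full target vector. Requires >= 3 subjects with complete data.
    """
    if method not in ("ttest", "wilcoxon"):
        raise ValueError("method must be 'ttest' or 'wilcoxon'")
    wide = (
        cohort.groupby(["subject", "column", "target"])[value_col]
        .mean()
        .unstack("target")
    )
    columns = sorted(wide.index.get_level_values("column").unique())
    targets = list(wide.columns)
    pairs = list(combinations(columns, 2))
    n_pairs = len(pairs)

    rows = []
    multivariate: Dict[Tuple[str, str], float] = {}
    for pi, (a, b) in enumerate(pairs):
        da = wide.xs(a, level="column")
        db = wide.xs(b, level="column")
        common = da.index.intersection(db.index)
        if len(common) < 3:
            raise ValueError(
                f"fewer than 3 subjects with data for columns {a!r} and {b!r}"
            )
        diffs = (da.loc[common] - db.loc[common]).to_numpy()
        for j, t in enumerate(targets):
            d = diffs[:, j]
            if method == "ttest":
                stat_p = stats.ttest_rel(d, np.zeros_like(d)).pvalue if d.std() > 0 else 1.0
            else:
                stat_p = stats.wilcoxon(d).pvalue if np.any(d != 0) else 1.0
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "target": t,
                    "p_raw": float(stat_p),
                    "p_bonferroni": float(min(1.0, stat_p * n_pairs)),
                }
            )
        multivariate[(a, b)] = multivariate_permutation_test(
            diffs, n_permutations=n_permutations, rng_seed=rng_seed + pi
        )
    return pd.DataFrame(rows), multivariate


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * n_comparisons)


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_radial_profiles(profiles: Sequence[ColumnProfile], out_path: str) -> None:
    """Radial (spider) diagram of relative connectivity per column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = list(profiles[0].relative.keys())
    angles = np.linspace(0, 2 * np.pi, len(targets), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for p in profiles:
        vals = [p.relative[t] for t in targets]
        ax.plot(np.concatenate([angles, angles[:1]]), vals + vals[:1], label=p.column)
        ax.fill(np.concatenate([angles, angles[:1]]), vals + vals[:1], alpha=0.1)
    ax.set_xticks(angles)
    ax.set_xticklabels(targets, fontsize=8)
    ax.set_title("Relative connectivity by column")
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1))
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
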
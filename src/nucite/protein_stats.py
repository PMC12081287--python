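"""Nucleus- and donor-level statistics on protein levels and compositions.

Nucleus-level percentile contrasts (e.g. reactive vs homeostatic
capillary clusters) use the pooled two-sample t-test with the pooled
Cohen's d, which satisfies the identity d = t * sqrt(1/n1 + 1/n2) — the
convention under which the printed (t, n1, n2, d) trios of the source
analyses are mutually consistent. Donor-level composition statistics
(proportion of each donor's nuclei per cluster) use one-way ANOVA with
Tukey HSD post hoc tests and Spearman rank correlation against donor
age. Protein-protein stoichiometry curves (e.g. TDP-43 vs NF-kB) are
equal-count binned means with a short running-mean smoother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_data import logger


def cohens_d_from_t(t_stat: float, n1: int, n2: int) -> float:
    """Pooled Cohen's d implied by a pooled two-sample t statistic."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    return float(t_stat) * np.sqrt(1.0 / n1 + 1.0 / n2)


@dataclass
class ContrastResult:
    """Pooled two-sample contrast between two nucleus groups."""

    group_labels: tuple
    n1: int
    n2: int
    mean1: float
    mean2: float
    t_stat: float
    p_value: float
    cohens_d: float

    def __post_init__(self):
        # internal consistency of the pooled formulas
        implied = cohens_d_from_t(self.t_stat, self.n1, self.n2)
        if not np.isclose(self.cohens_d, implied, atol=1e-10):
            raise AssertionError(
                f"pooled identity violated: d={self.cohens_d} vs "
                f"t*sqrt(1/n1+1/n2)={implied}"
            )


def percentile_contrast(
    values, group_mask_1, group_mask_2, labels=("group1", "group2")
) -> ContrastResult:
    """Unpaired pooled-variance t-test with pooled Cohen's d.

    ``values`` are per-nucleus protein levels (any scale); the two masks
    select the contrasted nucleus groups (e.g. percentile bins or
    clusters).
    """
    v = np.asarray(values, dtype=float)
    g1 = v[np.asarray(group_mask_1, dtype=bool)]
    g2 = v[np.asarray(group_mask_2, dtype=bool)]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 nuclei")
    sp2 = (
        (n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)
    ) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; contrast undefined")
    t, p = scipy.stats.ttest_ind(g1, g2, equal_var=True)
    d = (g1.mean() - g2.mean()) / np.sqrt(sp2)
    return ContrastResult(
        group_labels=tuple(labels),
        n1=n1,
        n2=n2,
        mean1=float(g1.mean()),
        mean2=float(g2.mean()),
        t_stat=float(t),
        p_value=float(p),
        cohens_d=float(d),
    )


# ---------------------------------------------------------------------------
# stoichiometry curves
# ---------------------------------------------------------------------------


@dataclass
class StoichiometryCurve:
    """Binned mean of one protein against another, lightly smoothed."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    smoothing_window: int


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean; the window truncates at the edges."""
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def stoichiometry_curve(
    nclr: pd.DataFrame,
    x_protein: str,
    y_protein: str,
    groups=None,
    n_bins: int = 20,
    smooth_window: int = 3,
) -> dict:
    """Equal-count binned y-vs-x protein curves, one per group.

    Nuclei are sorted by the x protein and split into ``n_bins``
    equal-count bins; within each bin the mean of both proteins is
    taken, then both the bin centers and bin means are smoothed with the
    same running mean (window ``smooth_window``) so exact linear
    relationships are preserved. Groups smaller than ``n_bins`` nuclei
    are skipped with a warning. Returns ``{group: StoichiometryCurve}``
    (a single ``"all"`` entry when ``groups`` is None).
    """
    for p in (x_protein, y_protein):
        if p not in nclr.columns:
            raise ValueError(f"protein {p!r} absent from nCLR columns")
    x = nclr[x_protein].to_numpy(dtype=float)
    y = nclr[y_protein].to_numpy(dtype=float)
    if groups is None:
        group_arr = np.array(["all"] * len(x))
    else:
        group_arr = np.asarray(groups)
    curves = {}
    for gname in pd.unique(group_arr):
        m = group_arr == gname
        if m.sum() < n_bins:
            warnings.warn(
                f"group {gname!r} has {int(m.sum())} nuclei < n_bins={n_bins}; "
                "skipped"
            )
            continue
        order = np.argsort(x[m], kind="stable")
        xs, ys = x[m][order], y[m][order]
        chunks = np.array_split(np.arange(len(xs)), n_bins)
        centers = np.array([xs[c].mean() for c in chunks])
        means = np.array([ys[c].mean() for c in chunks])
        counts = np.array([len(c) for c in chunks])
        curves[gname] = StoichiometryCurve(
            bin_centers=_running_mean(centers, smooth_window),
            bin_means=_running_mean(means, smooth_window),
            bin_counts=counts,
            smoothing_window=smooth_window,
        )
    return curves


# ---------------------------------------------------------------------------
# donor-level composition statistics
# ---------------------------------------------------------------------------


def group_anova_tukey(values, group_labels):
    """One-way ANOVA plus Tukey HSD pairwise table on donor-level units.

    Groups with a single unit are excluded with a warning. Returns
    ``(F, p, tukey DataFrame)`` where the table has k(k-1)/2 rows with
    columns group1, group2, meandiff, p_adj, lower, upper, reject.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    counts = pd.Series(g).value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"excluding groups with a single unit: {list(small)}")
        keep = ~pd.Series(g).isin(small).to_numpy()
        v, g = v[keep], g[keep]
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with >= 2 units")
    F, p = scipy.stats.f_oneway(*[v[g == lev] for lev in levels])
    res = pairwise_tukeyhsd(v, g)
    table = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return float(F), float(p), table


def correlate_age_proportions(
    donor_proportions: pd.DataFrame, donor_age: pd.Series
) -> pd.DataFrame:
    """Spearman rank correlation of per-donor cluster proportions vs age.

    One row per cluster with rho and the two-sided p-value; clusters
    with constant proportions get NaN and are flagged in the
    ``undefined`` column. Requires at least 4 donors.
    """
    common = donor_proportions.index.intersection(donor_age.index)
    if len(common) < 4:
        raise ValueError(f"need >= 4 donors, have {len(common)}")
    props = donor_proportions.loc[common]
    age = donor_age.loc[common].to_numpy(dtype=float)
    rows = []
    for cluster in props.columns:
        x = props[cluster].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("cluster %s has constant proportions; rho undefined",
                           cluster)
            rows.append({"cluster": cluster, "rho": np.nan, "p_value": np.nan,
                         "undefined": True})
            continue
        rho, p = scipy.stats.spearmanr(x, age)
        rows.append({"cluster": cluster, "rho": float(rho),
                     "p_value": float(p), "undefined": False})
    return pd.DataFrame(rows).set_index("cluster")
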
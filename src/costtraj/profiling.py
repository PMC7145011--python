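"""Profiling of latent trajectory groups and cross-model agreement.

Two jobs live here.  First, the descriptive comparison of patient- and
treatment-associated factors across latent groups: Kruskal-Wallis tests for
continuous covariates, Pearson chi-square for categorical ones, reported as
a group-by-covariate table with per-covariate p-values (no multiplicity
adjustment; significance flagged at p <= 0.05).  Second, the machinery for
comparing two trajectory fits — matching their groups by trajectory shape
and quantifying class-allocation agreement with (weighted) Cohen's kappa —
used when a model refit on a subgroup is compared with the full-cohort
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2_contingency, kruskal


@dataclass
class GroupProfileTable:
    """Table 2-style profile: one column per group, covariate rows."""

    table: pd.DataFrame
    tests: pd.DataFrame  # covariate, test, statistic, pvalue, significant
    group_sizes: np.ndarray

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True)


def profile_groups(patients: pd.DataFrame, labels: np.ndarray,
                   continuous: list[str], categorical: list[str],
                   group_names: list[str] | None = None,
                   alpha: float = 0.05) -> GroupProfileTable:
    """Compare covariate distributions across latent groups.

    Continuous covariates are summarised as mean (SD) per group and tested
    with Kruskal-Wallis; categorical covariates as n (%) per level and
    tested with Pearson's chi-square on the group-by-level contingency
    table.  Covariates constant across the cohort are skipped with a note.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if group_names is None:
        group_names = [f"G{g + 1}" for g in groups]
    sizes = np.array([(labels == g).sum() for g in groups])

    rows: dict[str, dict[str, str]] = {}
    tests = []

    def add_test(cov, name, stat, p):
        tests.append({"covariate": cov, "test": name, "statistic": stat,
                      "pvalue": p, "significant": (p <= alpha) if np.isfinite(p) else False})

    for cov in continuous:
        x = patients[cov].to_numpy(dtype=float)
        cells = {}
        samples = []
        for g, name in zip(groups, group_names):
            xi = x[labels == g]
            cells[name] = f"{xi.mean():.1f} ({xi.std(ddof=1):.1f})"
            samples.append(xi)
        rows[cov] = cells
        if np.unique(x).size < 2:
            add_test(cov, "skipped (constant)", np.nan, np.nan)
            continue
        stat, p = kruskal(*samples)
        add_test(cov, "kruskal-wallis", stat, p)

    for cov in categorical:
        x = patients[cov]
        levels = sorted(x.unique(), key=str)
        if len(levels) < 2:
            rows[cov] = {
                name: f"{(x[labels == g] == levels[0]).sum()} (100%)"
                for g, name in zip(groups, group_names)
            }
            add_test(cov, "skipped (constant)", np.nan, np.nan)
            continue
        contingency = np.array(
            [[(x[labels == g] == lev).sum() for lev in levels] for g in groups]
        )
        # plain Pearson statistic (no Yates continuity correction)
        stat, p, _, _ = chi2_contingency(contingency, correction=False)
        add_test(cov, "chi-square", stat, p)
        binary = set(levels) <= {0, 1, False, True}
        if binary:
            cells = {}
            for (g, name), n_g in zip(zip(groups, group_names), sizes):
                k = int((x[labels == g] == True).sum())  # noqa: E712
                cells[name] = f"{k} ({100 * k / n_g:.0f}%)"
            rows[cov] = cells
        else:
            for lev, counts in zip(levels, contingency.T):
                cells = {}
                for name, k, n_g in zip(group_names, counts, sizes):
                    cells[name] = f"{k} ({100 * k / n_g:.0f}%)"
                rows[f"{cov}: {lev}"] = cells

    table = pd.DataFrame(rows).T[list(group_names)]
    tests_df = pd.DataFrame(tests)
    table["pvalue"] = [
        tests_df.set_index("covariate")["pvalue"].get(str(r).split(":")[0], np.nan)
        for r in table.index
    ]
    return GroupProfileTable(table=table, tests=tests_df, group_sizes=sizes)


def match_classes(curves_a: np.ndarray, curves_b: np.ndarray) -> np.ndarray:
    """Optimally match groups of two fits by fitted mean trajectories.

    ``curves_*`` are (J, 12) fitted mean cost curves.  Returns ``mapping``
    such that group ``k`` of fit B corresponds to group ``mapping[k]`` of
    fit A, minimising the total over months of |curve_a - curve_b| across
    matched pairs (solved exactly via the assignment problem).  Using
    fitted curves rather than shared memberships keeps the matching defined
    even for disjoint patient sets.
    """
    A = np.asarray(curves_a, dtype=float)
    B = np.asarray(curves_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(
            f"fits must share the number of groups; got {A.shape[0]} and {B.shape[0]}")
    cost = np.abs(A[:, None, :] - B[None, :, :]).sum(axis=2)  # (Ja, Jb)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(B.shape[0], dtype=int)
    mapping[cols] = rows
    return mapping


def match_classes_bruteforce(curves_a: np.ndarray, curves_b: np.ndarray) -> np.ndarray:
    """Exhaustive-permutation reference for :func:`match_classes`."""
    A = np.asarray(curves_a, float)
    B = np.asarray(curves_b, float)
    J = A.shape[0]
    cost = np.abs(A[:, None, :] - B[None, :, :]).sum(axis=2)
    best, best_perm = np.inf, None
    for perm in permutations(range(J)):
        c = sum(cost[perm[k], k] for k in range(J))
        if c < best:
            best, best_perm = c, perm
    return np.array(best_perm)


@dataclass
class KappaResult:
    """Agreement between two labelings of the same patients."""

    mapping: np.ndarray
    agreement_matrix: np.ndarray
    kappa: float
    weight_scheme: str


def weighted_kappa(labels_a, labels_b, weight_scheme: str = "linear",
                   n_classes: int | None = None) -> float:
    """(Weighted) Cohen's kappa between two labelings.

    kappa_w = 1 - sum(w o) / sum(w e), with ``o`` the observed and ``e`` the
    chance-expected cell proportions of the confusion matrix and ``w``
    disagreement weights: |i-j| for ``linear``, (i-j)^2 for ``quadratic``,
    1[i != j] for ``unweighted``.  Labels must already sit on a common,
    meaningful ordering (here: groups ordered by decreasing mean fitted
    cost).  Returns NaN when either labeling uses a single class.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    J = int(max(a.max(), b.max())) + 1 if n_classes is None else n_classes
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    conf = np.zeros((J, J))
    np.add.at(conf, (a, b), 1.0)
    n = conf.sum()
    o = conf / n
    e = np.outer(conf.sum(axis=1), conf.sum(axis=0)) / n**2
    idx = np.arange(J)
    if weight_scheme == "linear":
        w = np.abs(idx[:, None] - idx[None, :]).astype(float)
    elif weight_scheme == "quadratic":
        w = (idx[:, None] - idx[None, :]) ** 2.0
    elif weight_scheme == "unweighted":
        w = (idx[:, None] != idx[None, :]).astype(float)
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    return float(1.0 - (w * o).sum() / (w * e).sum())


def class_agreement(labels_full, labels_sub, curves_full, curves_sub,
                    weight_scheme: str = "linear") -> KappaResult:
    """Match a subgroup refit to the full-cohort fit and measure agreement.

    Labels refer to the same (shared) patients in both fits; the subgroup
    model's groups are first aligned to the full model's by trajectory
    shape, then weighted kappa is computed on the aligned labels.
    """
    mapping = match_classes(curves_full, curves_sub)
    aligned = mapping[np.asarray(labels_sub, dtype=int)]
    a = np.asarray(labels_full, dtype=int)
    J = np.asarray(curves_full).shape[0]
    conf = np.zeros((J, J), dtype=int)
    np.add.at(conf, (a, aligned), 1)
    kappa = weighted_kappa(a, aligned, weight_scheme=weight_scheme, n_classes=J)
    return KappaResult(mapping=mapping, agreement_matrix=conf, kappa=kappa,
                       weight_scheme=weight_scheme)
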
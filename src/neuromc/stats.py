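"""Statistical comparison of MC_W across hierarchy levels over repeated runs.

Each simulation run yields one MC_W value per hierarchy level; runs are the
subjects of a fully repeated one-way design (level = within-subject factor).
The pipeline mirrors common practice for such designs: Shapiro--Wilk
normality screening per level group (alpha = 0.1, deliberately liberal so
deviations from normality are flagged rather than missed), a repeated-measures
ANOVA, and pairwise paired t-tests with Bonferroni correction, from which
groups of levels with indistinguishable means are formed by linking
non-significant pairs.

Greenhouse--Geisser corrected p-values are reported alongside the uncorrected
ones; sphericity violations inflate the uncorrected test, so both are shown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MCTable:
    """runs x levels matrix of MC_W values (bits), complete design."""

    values: np.ndarray
    levels: list[str]
    mode: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a runs x levels matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 runs")
        if self.values.shape[1] != len(self.levels):
            raise ValueError("level labels do not match the number of columns")
        if not np.isfinite(self.values).all():
            raise ValueError("missing cells: the design must be fully repeated")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "") -> "MCTable":
        return cls(df.to_numpy(), list(df.columns), mode)

    @classmethod
    def from_long(cls, df: pd.DataFrame, mode: str = "") -> "MCTable":
        """Build from long format with columns run, level, mc_bits."""
        wide = df.pivot(index="run", columns="level", values="mc_bits")
        return cls(wide.to_numpy(), list(wide.columns), mode)

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]


def normality_screen(table: MCTable, alpha: float = 0.1) -> pd.DataFrame:
    """Shapiro--Wilk test per level group.

    Groups with fewer than 3 runs or zero variance are reported as not
    testable.  Returns a frame with statistic, p, and pass/fail at ``alpha``.
    """
    rows = []
    for j, level in enumerate(table.levels):
        x = table.values[:, j]
        if len(x) < 3 or np.ptp(x) == 0.0:
            rows.append({"level": level, "statistic": np.nan, "p": np.nan,
                         "testable": False, "normal": False})
            continue
        stat, p = sps.shapiro(x)
        rows.append({"level": level, "statistic": stat, "p": p,
                     "testable": True, "normal": bool(p > alpha)})
    return pd.DataFrame(rows).set_index("level")


@dataclass
class AnovaResult:
    f: float
    df_level: float
    df_error: float
    p: float
    eps_gg: float
    p_gg: float
    zero_residual: bool = False


def rm_anova(table: MCTable) -> AnovaResult:
    """One-way repeated-measures ANOVA (runs as subjects, level as factor).

    F = MS_level / MS_(level x run residual).  Greenhouse--Geisser epsilon is
    computed from the double-centered covariance of the level columns.
    """
    x = table.values
    n, k = x.shape
    gm = x.mean()
    ss_level = n * ((x.mean(axis=0) - gm) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - gm) ** 2).sum()
    ss_total = ((x - gm) ** 2).sum()
    ss_err = ss_total - ss_level - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)

    # Greenhouse-Geisser epsilon
    s = np.cov(x, rowvar=False, bias=True)
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    sdc = c @ s @ c
    denom = (k - 1) * np.trace(sdc @ sdc)
    eps = (np.trace(sdc) ** 2 / denom) if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    if ss_err <= 1e-300 * max(ss_total, 1.0):
        if ss_level <= 1e-300 * max(ss_total, 1.0):
            return AnovaResult(0.0, df1, df2, 1.0, eps, 1.0, zero_residual=True)
        return AnovaResult(np.inf, df1, df2, np.nextafter(0, 1), eps,
                           np.nextafter(0, 1), zero_residual=True)
    f = (ss_level / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
    return AnovaResult(float(f), df1, df2, p, eps, p_gg)


@dataclass
class PosthocResult:
    """Bonferroni-adjusted pairwise paired t-tests and the resulting grouping."""

    p_adj: pd.DataFrame
    p_raw: pd.DataFrame
    groups: list[set[str]]
    alpha: float

    def same_group(self, a: str, b: str) -> bool:
        return any(a in grp and b in grp for grp in self.groups)


def posthoc_bonferroni(table: MCTable, alpha: float = 0.05) -> PosthocResult:
    """All pairwise paired t-tests, p multiplied by the number of pairs (capped at 1).

    Levels whose difference is not significant at ``alpha`` are linked; the
    connected components of these links are the reported groups of levels
    with similar means.
    """
    k = table.n_levels
    m = k * (k - 1) // 2
    praw = np.full((k, k), np.nan)
    padj = np.full((k, k), np.nan)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        praw[i, i] = 1.0
        padj[i, i] = 1.0
        for j in range(i + 1, k):
            d = table.values[:, i] - table.values[:, j]
            if np.ptp(d) == 0.0:
                p = 1.0 if np.allclose(d, 0) else np.nextafter(0, 1)
            else:
                p = float(sps.ttest_rel(table.values[:, i], table.values[:, j]).pvalue)
            praw[i, j] = praw[j, i] = p
            pa = min(1.0, m * p)
            padj[i, j] = padj[j, i] = pa
            if pa >= alpha:
                parent[find(i)] = find(j)

    comp: dict[int, set[str]] = {}
    for i in range(k):
        comp.setdefault(find(i), set()).add(table.levels[i])
    groups = sorted(comp.values(), key=lambda g: min(table.levels.index(x) for x in g))
    lab = table.levels
    return PosthocResult(pd.DataFrame(padj, index=lab, columns=lab),
                         pd.DataFrame(praw, index=lab, columns=lab),
                         groups, alpha)
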
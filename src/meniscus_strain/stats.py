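"""Nonparametric statistics battery for the strain cohort.

Strain data from the loading experiments are not normally distributed
(Shapiro-Wilk screen), so all group and location comparisons are
rank-based, mirroring the study protocol:

- Mann-Whitney U: mild vs severe degeneration, per side/region/
  direction/load.
- Friedman + post hoc paired Wilcoxon with step-down correction:
  meniscal locations within a group (AH vs PI vs PH, and the six
  inner/outer zone combinations).
- Paired Wilcoxon: anterior vs posterior root attachment.
- Kruskal-Wallis + corrected pairwise follow-up: the three load levels.

"Linear p-value Bonferroni correction" is read as Holm's step-down
(sequentially rejective) Bonferroni procedure — the common meaning of a
"linear" Bonferroni; plain Bonferroni is available by config. Exact
small-sample p-values (full enumeration) are used whenever group sizes
are at or below ``exact_threshold`` and the data are tie-free;
otherwise the usual normal / chi-square approximations with mid-ranks
and tie correction apply. Tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .phantom import region_level

__all__ = [
    "StatsConfig",
    "mann_whitney",
    "wilcoxon_signed",
    "friedman",
    "kruskal_wallis",
    "shapiro_wilk",
    "adjust_pvalues",
    "run_study_stats",
]


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    correction: str = "holm"  # or "bonferroni"
    exact_threshold: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("holm", "bonferroni"):
            raise ValueError("correction must be 'holm' or 'bonferroni'")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(a, b, alternative: str = "two-sided",
                 exact_threshold: int = 12) -> tuple[float, float]:
    """Mann-Whitney U test. Exact enumeration p when both groups are at
    most ``exact_threshold`` and tie-free, else normal approximation
    with tie correction and continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return len(a) * len(b) / 2.0, 1.0
    exact = len(a) <= exact_threshold and len(b) <= exact_threshold and not _has_ties(pooled)
    res = sps.mannwhitneyu(a, b, alternative=alternative,
                           method="exact" if exact else "asymptotic",
                           use_continuity=not exact)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed(x, y=None, alternative: str = "two-sided",
                    exact_threshold: int = 12) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on differences (``x`` alone) or
    pairs (``x``, ``y``). Zero differences are dropped before ranking;
    exact enumeration when the nonzero count is at most
    ``exact_threshold`` and the absolute differences are tie-free."""
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero — the test is undefined")
    exact = len(d) <= exact_threshold and not _has_ties(np.abs(d))
    res = sps.wilcoxon(d, alternative=alternative,
                       method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def friedman(matrix, n_permutations: int = 0, seed: int = 0) -> tuple[float, float]:
    """Friedman rank test on a block x treatment matrix, with mid-rank
    tie correction; chi-square p on k-1 df.

    The tie-corrected statistic is
    chi2_F = (k-1) [sum_j Rj^2 - n^2 k (k+1)^2 / 4]
             / [sum_ij r_ij^2 - n k (k+1)^2 / 4],
    which reduces to the textbook formula without ties. When
    ``n_permutations`` > 0 a within-block permutation p-value is
    returned instead of the chi-square approximation (seeded, for small
    block counts where the asymptotic p is unreliable).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    n, k = X.shape

    def statistic(M: np.ndarray) -> float:
        ranks = sps.rankdata(M, axis=1)
        Rj = ranks.sum(axis=0)
        num = (k - 1) * (np.sum(Rj ** 2) - n * n * k * (k + 1) ** 2 / 4.0)
        den = np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0
        if den <= 0:  # all blocks fully tied
            return 0.0
        return float(num / den)

    chi2 = statistic(X)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = np.take_along_axis(X, rng.permuted(np.tile(np.arange(k), (n, 1)), axis=1), axis=1)
            if statistic(perm) >= chi2 - 1e-12:
                count += 1
        return chi2, (count + 1) / (n_permutations + 1)
    p = float(sps.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return chi2, p


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across independent groups, tie-corrected,
    chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 0.0, 1.0  # scipy rejects the all-identical degenerate case
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(pvalues, scheme: str = "holm",
                   alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-comparison adjustment within one family.

    holm: step-down Bonferroni with monotone adjusted values;
    bonferroni: m * p capped at 1. Returns (adjusted, reject)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method=scheme)
    return adj, reject


# ---------------------------------------------------------------------------
# full study battery

_BODY_REGIONS = ("AH", "PI", "PH")


def _row(family, contrast, test, stat, p):
    return {"family": family, "contrast": contrast, "test": test,
            "statistic": stat, "p_raw": p}


def run_study_stats(table: pd.DataFrame, config: StatsConfig = StatsConfig()) -> pd.DataFrame:
    """Run the full nonparametric battery on a cohort table.

    ``table`` is zone-resolved (columns specimen, group, side, load,
    region, zone, direction, strain_pct). Returns one row per contrast
    with family, test, statistic, raw and adjusted p, and the decision
    at ``config.alpha``. Corrections are applied within the post hoc
    families (Wilcoxon after Friedman; pairwise load follow-ups after
    Kruskal-Wallis); omnibus and single-contrast families report raw
    p-values. Missing cells skip their contrast with a note row rather
    than aborting the battery.
    """
    reg = region_level(table)
    rows: list[dict] = []
    posthoc_families: dict[str, list[int]] = {}
    thr = config.exact_threshold
    groups = sorted(reg["group"].unique())
    sides = sorted(reg["side"].unique())
    loads = sorted(reg["load"].unique())
    regions = [r for r in ("ARA", "AH", "PI", "PH", "PRA") if r in set(reg["region"])]
    directions = sorted(reg["direction"].unique())

    # normality screen per direction (pooled strains)
    for direction in directions:
        v = reg.loc[reg["direction"] == direction, "strain_pct"].to_numpy()
        if 3 <= len(v) <= 5000 and len(np.unique(v)) > 1:
            W, p = shapiro_wilk(v)
            rows.append(_row("normality", f"{direction}", "shapiro_wilk", W, p))

    # mild vs severe per side/load/region/direction
    if len(groups) == 2:
        g0, g1 = groups
        for side in sides:
            for load in loads:
                for region in regions:
                    for direction in directions:
                        sub = reg[(reg["side"] == side) & (reg["load"] == load)
                                  & (reg["region"] == region) & (reg["direction"] == direction)]
                        a = sub.loc[sub["group"] == g0, "strain_pct"].to_numpy()
                        b = sub.loc[sub["group"] == g1, "strain_pct"].to_numpy()
                        if len(a) == 0 or len(b) == 0:
                            continue
                        U, p = mann_whitney(a, b, exact_threshold=thr)
                        rows.append(_row("group", f"{g0}_vs_{g1}|{side}|{load:g}BW|{region}|{direction}",
                                         "mann_whitney", U, p))

    def paired_matrix(sub: pd.DataFrame, key: str, levels) -> np.ndarray | None:
        wide = sub.pivot_table(index="specimen", columns=key, values="strain_pct")
        if not all(l in wide.columns for l in levels):
            return None
        wide = wide[list(levels)].dropna()
        return wide.to_numpy() if len(wide) >= 2 else None

    zone_tab = table.copy()
    zone_tab["loc"] = zone_tab["region"] + "_" + zone_tab["zone"].str[:3]

    # location contrasts within each group (Friedman + post hoc Wilcoxon)
    for group in groups:
        for side in sides:
            for load in loads:
                for direction in directions:
                    base = (reg["group"] == group) & (reg["side"] == side) \
                        & (reg["load"] == load) & (reg["direction"] == direction)
                    sub = reg[base]
                    for tag, frame, key, levels in (
                        ("regions", sub, "region", _BODY_REGIONS),
                        ("zones",
                         zone_tab[(zone_tab["group"] == group) & (zone_tab["side"] == side)
                                  & (zone_tab["load"] == load) & (zone_tab["direction"] == direction)
                                  & (zone_tab["region"].isin(_BODY_REGIONS))],
                         "loc",
                         tuple(f"{r}_{z}" for r in _BODY_REGIONS for z in ("inn", "out"))),
                    ):
                        M = paired_matrix(frame, key, levels)
                        if M is None:
                            continue
                        chi2, p = friedman(M)
                        ctx = f"{group}|{side}|{load:g}BW|{direction}|{tag}"
                        rows.append(_row("location_omnibus", ctx, "friedman", chi2, p))
                        if p <= config.alpha:
                            fam = f"location_posthoc:{ctx}"
                            for i in range(len(levels)):
                                for j in range(i + 1, len(levels)):
                                    try:
                                        W, pw = wilcoxon_signed(M[:, i], M[:, j], exact_threshold=thr)
                                    except ValueError:
                                        continue
                                    rows.append(_row("location_posthoc",
                                                     f"{ctx}|{levels[i]}_vs_{levels[j]}",
                                                     "wilcoxon", W, pw))
                                    posthoc_families.setdefault(fam, []).append(len(rows) - 1)

    # ARA vs PRA paired contrast
    for group in groups:
        for side in sides:
            for load in loads:
                for direction in directions:
                    sub = reg[(reg["group"] == group) & (reg["side"] == side)
                              & (reg["load"] == load) & (reg["direction"] == direction)
                              & (reg["region"].isin(["ARA", "PRA"]))]
                    M = paired_matrix(sub, "region", ("ARA", "PRA"))
                    if M is None:
                        continue
                    try:
                        W, p = wilcoxon_signed(M[:, 0], M[:, 1], exact_threshold=thr)
                    except ValueError:
                        continue
                    rows.append(_row("attachments", f"{group}|{side}|{load:g}BW|{direction}|ARA_vs_PRA",
                                     "wilcoxon", W, p))

    # load-level contrasts (Kruskal-Wallis omnibus + corrected pairwise)
    if len(loads) >= 2:
        for group in groups:
            for side in sides:
                for region in regions:
                    for direction in directions:
                        sub = reg[(reg["group"] == group) & (reg["side"] == side)
                                  & (reg["region"] == region) & (reg["direction"] == direction)]
                        samples = [sub.loc[sub["load"] == l, "strain_pct"].to_numpy() for l in loads]
                        if any(len(s) == 0 for s in samples):
                            continue
                        H, p = kruskal_wallis(samples)
                        ctx = f"{group}|{side}|{region}|{direction}"
                        rows.append(_row("load_omnibus", ctx, "kruskal_wallis", H, p))
                        if p <= config.alpha:
                            fam = f"load_posthoc:{ctx}"
                            for i in range(len(loads)):
                                for j in range(i + 1, len(loads)):
                                    U, pu = mann_whitney(samples[i], samples[j], exact_threshold=thr)
                                    rows.append(_row("load_posthoc",
                                                     f"{ctx}|{loads[i]:g}BW_vs_{loads[j]:g}BW",
                                                     "mann_whitney", U, pu))
                                    posthoc_families.setdefault(fam, []).append(len(rows) - 1)

    report = pd.DataFrame(rows)
    if report.empty:
        return pd.DataFrame(columns=["family", "contrast", "test", "statistic",
                                     "p_raw", "p_adj", "significant"])
    report["p_adj"] = report["p_raw"]
    for fam, idx in posthoc_families.items():
        adj, _ = adjust_pvalues(report.loc[idx, "p_raw"].to_numpy(),
                                scheme=config.correction, alpha=config.alpha)
        report.loc[idx, "p_adj"] = adj
    report["significant"] = report["p_adj"] <= config.alpha
    return report
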
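"""Descriptive analyses of organic-carbon-normalized sorption (KOC).

Normalizing Kd by the organic-carbon fraction (KOC = Kd / fOC) removes the
first-order soil effect so compound-intrinsic trends become visible: log KOC
grows with the fluorinated chain length within a subfamily, differs between
head groups, and correlates linearly with hydrophobicity (log KOW) across
subfamilies.  Compounds that fall far off that KOC-KOW line are candidates
for exclusion (see ``harmonize.flag_outliers``).

Group comparisons use Welch's ANOVA with Games-Howell pairwise tests
(heteroscedasticity-robust), summarized as compact letter displays:
groups sharing a letter are statistically indistinguishable at alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm

from .harmonize import SorptionEntry, koc_of
from .registry import CompoundRegistry

__all__ = ["koc_summary", "compare_groups", "koc_kow_regression", "RegressionResult"]

log = logging.getLogger(__name__)

#: Head-group labels by subfamily, for functional-group comparisons.
FUNCTIONAL_GROUPS = {
    "PFCA": "carboxylate",
    "PFECA": "carboxylate",
    "FOSAA": "carboxylate",
    "PFSA": "sulfonate",
    "PFAES": "sulfonate",
    "FTS": "telomer sulfonate",
    "FOSA": "sulfonamide",
    "FTOH": "telomer alcohol",
    "PFPA": "phosphonate",
    "PFPiA": "phosphinate",
    "cationic_zwitterionic": "cationic/zwitterionic",
}


def _log_koc_table(
    entries: Sequence[SorptionEntry], registry: CompoundRegistry
) -> pd.DataFrame:
    rows = []
    for e in entries:
        if e.soil.corg is None or e.soil.corg <= 0:
            continue
        c = registry.get(e.compound_id)
        rows.append({
            "compound_id": c.id,
            "subfamily": c.subfamily,
            "functional_group": FUNCTIONAL_GROUPS[c.subfamily],
            "n_fluorinated_carbons": c.n_fluorinated_carbons,
            "log_kow": c.log_kow,
            "log_koc": math.log10(koc_of(e)),
            "outlier": e.outlier,
        })
    return pd.DataFrame(rows)


def koc_summary(
    entries: Sequence[SorptionEntry],
    registry: CompoundRegistry,
    group_by: str = "subfamily",
) -> pd.DataFrame:
    """Mean, sample SD and n of log KOC per group.

    ``group_by`` is one of ``subfamily``, ``n_fluorinated_carbons`` or
    ``functional_group``; groups are ordered by mean chain length so
    chain-length trends read top to bottom.  Single-entry groups report SD
    as missing; empty groups are omitted (logged).
    """
    if group_by not in ("subfamily", "n_fluorinated_carbons", "functional_group"):
        raise ValueError(f"cannot group by {group_by!r}")
    df = _log_koc_table(entries, registry)
    if df.empty:
        raise ValueError("no entries with corg > 0")
    grouped = df.groupby(group_by)
    out = grouped.agg(
        mean_log_koc=("log_koc", "mean"),
        sd_log_koc=("log_koc", lambda v: v.std(ddof=1) if len(v) > 1 else np.nan),
        n=("log_koc", "size"),
        mean_chain_length=("n_fluorinated_carbons", "mean"),
    ).sort_values("mean_chain_length")
    present = set(grouped.groups)
    if group_by == "subfamily":
        for g in set(FUNCTIONAL_GROUPS) - present:
            log.info("group %r has no entries; omitted", g)
    return out.reset_index()


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


def koc_kow_regression(
    entries: Sequence[SorptionEntry],
    registry: CompoundRegistry,
    exclude_outliers: bool = True,
) -> RegressionResult:
    """OLS of per-compound mean log KOC on log KOW."""
    df = _log_koc_table(entries, registry)
    if exclude_outliers:
        df = df[~df["outlier"]]
    per_compound = (
        df.groupby("compound_id")
        .agg(log_koc=("log_koc", "mean"), log_kow=("log_kow", "first"))
        .sort_index()
    )
    if len(per_compound) < 3:
        raise ValueError("regression needs >= 3 compounds")
    if per_compound["log_kow"].std(ddof=0) == 0:
        raise ValueError("degenerate log KOW variance")
    x = sm.add_constant(per_compound["log_kow"].to_numpy())
    fit = sm.OLS(per_compound["log_koc"].to_numpy(), x).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        n=len(per_compound),
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Welch ANOVA + Games-Howell pairwise comparisons with letter subsets.

    Returns one row per group (ordered by mean) with columns ``mean``, ``sd``,
    ``n`` and ``letters``; groups sharing any letter are homogeneous at
    ``alpha``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if all(len(v) < 2 for v in groups.values()):
        raise ValueError("all groups are singletons; nothing to test")

    long = pd.DataFrame(
        [(name, val) for name, vals in groups.items() for val in vals],
        columns=["group", "value"],
    )
    names = sorted(groups, key=lambda g: float(np.mean(groups[g])))

    # pairwise non-significance graph (Games-Howell controls multiplicity)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    if long.groupby("group")["value"].var(ddof=1).fillna(0).sum() == 0:
        # all groups internally constant: identical means are homogeneous
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.mean(groups[a]) == np.mean(groups[b]):
                    graph.add_edge(a, b)
    else:
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        for _, row in gh.iterrows():
            p = row["pval"]
            if not np.isfinite(p) or p > alpha:
                graph.add_edge(row["A"], row["B"])

    # compact letter display via clique cover of the non-significance graph
    cliques = sorted(
        (sorted(c, key=names.index) for c in nx.find_cliques(graph)),
        key=lambda c: names.index(c[0]),
    )
    letters: dict[str, str] = {name: "" for name in names}
    symbol = iter("abcdefghijklmnopqrstuvwxyz")
    for clique in cliques:
        s = next(symbol)
        for member in clique:
            letters[member] += s

    return pd.DataFrame({
        "group": names,
        "mean": [float(np.mean(groups[g])) for g in names],
        "sd": [float(np.std(groups[g], ddof=1)) if len(groups[g]) > 1 else np.nan
               for g in names],
        "n": [len(groups[g]) for g in names],
        "letters": [letters[g] for g in names],
    })
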
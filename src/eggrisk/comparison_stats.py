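"""Descriptive summaries, multi-group comparisons and compliance screening.

Group comparisons follow the survey-statistics convention for trace
elements: one-way ANOVA per metal at alpha = 0.05, Tukey HSD pairwise
contrasts when the omnibus test is significant, with Shapiro-Wilk and
Levene screens reported (not enforced — a Kruskal-Wallis alternative is
available behind ``method="kruskal"``).

Compliance screening compares each metal's maximum observed concentration
against every configured maximum permitted level; a concentration exactly
at the limit passes (limits are maximum permitted levels), and a metal
without a configured limit is reported as such, never as a pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_io import ConcentrationRecord, RegulatoryLimit, records_to_frame
from .deterministic_risk import DomainError

__all__ = [
    "ComparisonResult",
    "RankResult",
    "summarize",
    "rank_metals",
    "compare_groups",
    "compliance_screen",
]

_GROUPINGS = ("area", "production_system", "mining_class")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-metal omnibus test plus pairwise contrasts for one grouping."""

    metal: str
    grouping: str
    anova_F: float
    anova_p: float
    pairwise: list[tuple[str, str, float, float]]  # (a, b, mean_diff b-a, adj p)
    significant: bool
    degenerate: bool = False
    method: str = "anova"
    shapiro_min_p: float = float("nan")
    levene_p: float = float("nan")


@dataclass(frozen=True)
class RankResult:
    """Metals of one area ordered by descending mean concentration."""

    area: str
    order: list[str]
    ties: list[tuple[str, str]]
    absent: list[str]


def summarize(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Per-(area, metal) mean, sd, min, max and n."""
    if not records:
        raise DomainError("no records to summarize")
    df = records_to_frame(list(records))
    out = (
        df.groupby(["area", "metal"], sort=True)["concentration"]
        .agg(mean="mean", sd="std", min="min", max="max", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)  # singleton cells
    return out


def rank_metals(
    records: Sequence[ConcentrationRecord],
    area: str,
    expected_metals: Sequence[str] | None = None,
) -> RankResult:
    """Order an area's metals by mean concentration, descending.

    Exact ties are broken alphabetically and flagged; metals from
    ``expected_metals`` missing in the area are listed as absent, not
    ranked.
    """
    df = records_to_frame(list(records))
    sub = df[df["area"] == area]
    if sub.empty:
        raise DomainError(f"no records for area {area!r}")
    means = sub.groupby("metal")["concentration"].mean()
    order = sorted(means.index, key=lambda m: (-means[m], m))
    ties = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if means[a] == means[b]
    ]
    absent = sorted(set(expected_metals or []) - set(means.index))
    return RankResult(area=area, order=order, ties=ties, absent=absent)


def compare_groups(
    records: Sequence[ConcentrationRecord],
    grouping: str,
    alpha: float = 0.05,
    method: str = "anova",
) -> list[ComparisonResult]:
    """One comparison per metal across the levels of ``grouping``.

    Requires >= 2 groups with >= 2 samples each per metal. Tukey HSD runs
    only when the omnibus test is significant. Groups that are all
    identical constants have no finite F and are reported as degenerate,
    never as significant.
    """
    if grouping not in _GROUPINGS:
        raise DomainError(f"grouping must be one of {_GROUPINGS}, got {grouping!r}")
    if method not in ("anova", "kruskal"):
        raise DomainError(f"method must be 'anova' or 'kruskal', got {method!r}")
    df = records_to_frame(list(records))
    results: list[ComparisonResult] = []
    for metal, sub in df.groupby("metal", sort=True):
        groups = {k: g["concentration"].to_numpy() for k, g in sub.groupby(grouping)}
        if len(groups) < 2:
            raise DomainError(
                f"metal {metal}: need >= 2 groups under {grouping!r}, got {len(groups)}"
            )
        small = [k for k, v in groups.items() if len(v) < 2]
        if small:
            raise DomainError(f"metal {metal}: groups with < 2 samples: {small}")
        values = list(groups.values())
        pooled = np.concatenate(values)
        if np.all(pooled == pooled[0]):
            results.append(
                ComparisonResult(
                    metal=metal, grouping=grouping, anova_F=float("nan"),
                    anova_p=float("nan"), pairwise=[], significant=False,
                    degenerate=True, method=method,
                )
            )
            continue
        if method == "anova":
            stat, p = sps.f_oneway(*values)
        else:
            stat, p = sps.kruskal(*values)
        shapiro_min_p = min(
            (sps.shapiro(v).pvalue for v in values if len(v) >= 3), default=float("nan")
        )
        levene_p = float(sps.levene(*values).pvalue)
        significant = bool(np.isfinite(p) and p < alpha)
        pairwise: list[tuple[str, str, float, float]] = []
        if significant and method == "anova":
            tk = pairwise_tukeyhsd(
                endog=sub["concentration"].to_numpy(),
                groups=sub[grouping].to_numpy(),
                alpha=alpha,
            )
            frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            pairwise = [
                (str(r.group1), str(r.group2), float(r.meandiff), float(r["p-adj"]))
                for _, r in frame.iterrows()
            ]
        results.append(
            ComparisonResult(
                metal=metal, grouping=grouping, anova_F=float(stat), anova_p=float(p),
                pairwise=pairwise, significant=significant, method=method,
                shapiro_min_p=float(shapiro_min_p), levene_p=levene_p,
            )
        )
    return results


def compliance_screen(
    records: Sequence[ConcentrationRecord], limits: Sequence[RegulatoryLimit]
) -> pd.DataFrame:
    """Max concentration per metal vs every configured limit.

    One row per (metal, authority); metals without any configured limit get
    a single ``no_limit_configured`` row. Verdicts: ``pass`` (max <= limit),
    ``fail`` (max > limit, with offending sample ids), ``no_limit_configured``.
    """
    df = records_to_frame(list(records))
    if df.empty:
        raise DomainError("no records to screen")
    by_metal = {m: g for m, g in df.groupby("metal")}
    limit_map: dict[str, list[RegulatoryLimit]] = {}
    for lim in limits:
        limit_map.setdefault(lim.metal, []).append(lim)

    rows = []
    for metal in sorted(by_metal):
        g = by_metal[metal]
        cmax = float(g["concentration"].max())
        configured = limit_map.get(metal, [])
        if not configured:
            rows.append((metal, "", float("nan"), cmax, "no_limit_configured", ""))
            continue
        for lim in sorted(configured, key=lambda l: l.authority):
            exceeding = g.loc[g["concentration"] > lim.limit, "sample_id"].tolist()
            verdict = "fail" if exceeding else "pass"
            rows.append((metal, lim.authority, lim.limit, cmax, verdict, ";".join(exceeding)))
    return pd.DataFrame(
        rows,
        columns=["metal", "authority", "limit", "max_concentration", "verdict", "exceeding_samples"],
    )
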
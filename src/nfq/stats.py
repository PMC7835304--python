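"""Group comparisons, clinical-score correlations, and the assembled
per-region results table.

Two-sided nonparametric tests throughout, alpha = 0.05: Mann-Whitney U for
EAE-vs-CTR contrasts (exact null distribution when the pooled sample is
small and tie-free, normal approximation with tie and continuity
correction otherwise) and tie-aware Spearman rank correlation for clinical
score and cross-modality associations, pooling both groups. Region-wise p
values are reported uncorrected (a Holm adjustment is available, off by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError
from .phantom import REGIONS_TESTED

__all__ = ["StatResult", "mann_whitney", "spearman", "build_results", "ResultsReport"]

#: Largest pooled sample for which the exact Mann-Whitney null is used.
EXACT_MW_LIMIT = 14
ALPHA = 0.05


@dataclass
class StatResult:
    statistic: float  # U for Mann-Whitney, rho for Spearman
    p_value: float
    n1: int
    n2: int
    method: str
    defined: bool = True


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a, b) -> StatResult:
    """Two-sided Mann-Whitney U test of group a vs group b.

    Exact p (full null enumeration over rank partitions) when
    n_a + n_b <= 14 and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction. The method
    actually used is recorded on the result.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both groups must be nonempty")
    exact = a.size + b.size <= EXACT_MW_LIMIT and not _has_ties(np.concatenate([a, b]))
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=int(a.size),
        n2=int(b.size),
        method="mann_whitney_exact" if exact else "mann_whitney_normal",
    )


def spearman(x, y) -> StatResult:
    """Tie-aware Spearman rank correlation; p from the t approximation.

    Constant input makes rho undefined — returned flagged (NaN), never a
    silent zero.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateDataError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(float("nan"), float("nan"), x.size, x.size,
                          "spearman", defined=False)
    rho, p = sps.spearmanr(x, y)
    return StatResult(float(rho), float(min(p, 1.0)), int(x.size), int(x.size), "spearman")


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


@dataclass
class ResultsReport:
    per_region: pd.DataFrame  # group summaries + Mann-Whitney per (region, metric)
    correlations: pd.DataFrame  # Spearman rho/p per (region, pair)
    summary_md: str


def _tidy_to_wide(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sel = table[table["metric"] == metric][["animal_id", "region", "value"]]
    return sel.pivot(index="animal_id", columns="region", values="value")


def build_results(
    suvr_table: pd.DataFrame,
    spio_table: pd.DataFrame,
    cohort: pd.DataFrame,
    regions=REGIONS_TESTED,
    holm: bool = False,
) -> ResultsReport:
    """Assemble the per-region results: group mean +/- SD, Mann-Whitney p,
    pooled clinical-score correlations and SUVR-vs-SPIO-Vol correlations.

    ``suvr_table``/``spio_table`` are tidy (animal_id, region, metric,
    value) frames carrying SUVR and SPIO_Vol_pct metrics; ``cohort`` has
    animal_id, group ('EAE'/'CTR') and cs columns. Correlations pool both
    groups. Significance is flagged at p < 0.05.
    """
    cohort = cohort.set_index("animal_id")
    metrics = {"SUVR": _tidy_to_wide(suvr_table, "SUVR"),
               "SPIO_Vol_pct": _tidy_to_wide(spio_table, "SPIO_Vol_pct")}
    for metric, wide in metrics.items():
        missing_animals = sorted(set(wide.index).symmetric_difference(cohort.index))
        if missing_animals:
            raise ValueError(
                f"{metric}: animals not shared with cohort table: {missing_animals}"
            )
        missing_regions = [r for r in regions if r not in wide.columns]
        if missing_regions:
            raise ValueError(f"{metric}: missing regions {missing_regions}")

    groups = cohort["group"]
    rows, corr_rows = [], []
    for metric, wide in metrics.items():
        wide = wide.loc[cohort.index]
        eae = wide[groups == "EAE"]
        ctr = wide[groups == "CTR"]
        for region in regions:
            row = {
                "region": region,
                "metric": metric,
                "eae_mean": float(eae[region].mean()) if len(eae) else float("nan"),
                "eae_sd": float(eae[region].std(ddof=1)) if len(eae) > 1 else float("nan"),
                "ctr_mean": float(ctr[region].mean()) if len(ctr) else float("nan"),
                "ctr_sd": float(ctr[region].std(ddof=1)) if len(ctr) > 1 else float("nan"),
                "n_eae": int(len(eae)),
                "n_ctr": int(len(ctr)),
            }
            if len(eae) and len(ctr):
                mw = mann_whitney(eae[region], ctr[region])
                row.update(U=mw.statistic, p=mw.p_value, test_method=mw.method)
            else:
                row.update(U=float("nan"), p=float("nan"), test_method="none")
            rows.append(row)
            cs = cohort["cs"].loc[wide.index]
            sp = spearman(wide[region], cs)
            corr_rows.append(
                {"region": region, "pair": f"CS~{metric}",
                 "rho": sp.statistic, "p": sp.p_value, "n": sp.n1}
            )
    suvr_wide = metrics["SUVR"].loc[cohort.index]
    spio_wide = metrics["SPIO_Vol_pct"].loc[cohort.index]
    for region in regions:
        sp = spearman(suvr_wide[region], spio_wide[region])
        corr_rows.append(
            {"region": region, "pair": "SUVR~SPIO_Vol_pct",
             "rho": sp.statistic, "p": sp.p_value, "n": sp.n1}
        )

    per_region = pd.DataFrame(rows)
    if holm:
        per_region["p_holm"] = _holm(per_region["p"].fillna(1.0).tolist())
        per_region["significant"] = per_region["p_holm"] < ALPHA
    else:
        per_region["significant"] = per_region["p"] < ALPHA
    correlations = pd.DataFrame(corr_rows)

    lines = ["# Per-region results", "",
             "| region | metric | EAE mean±SD | CTR mean±SD | p | sig |",
             "|---|---|---|---|---|---|"]
    for _, r in per_region.iterrows():
        lines.append(
            f"| {r.region} | {r.metric} | {r.eae_mean:.2f}±{r.eae_sd:.2f} "
            f"| {r.ctr_mean:.2f}±{r.ctr_sd:.2f} | {r.p:.4f} "
            f"| {'*' if r.significant else ''} |"
        )
    lines += ["", "# Pooled Spearman correlations", "",
              "| region | pair | rho | p |", "|---|---|---|---|"]
    for _, r in correlations.iterrows():
        lines.append(f"| {r.region} | {r.pair} | {r.rho:.3f} | {r.p:.4f} |")
    return ResultsReport(per_region=per_region, correlations=correlations,
                         summary_md="\n".join(lines) + "\n")
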
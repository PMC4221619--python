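"""Paired two-arm cohort comparison.

:class:`PairedPlanComparison` is the modelling object: built from a list of
paired patient cases, its :meth:`~PairedPlanComparison.fit` computes the
full metric battery (physical indices plus TCP/NTCP) for every plan, then
per-metric arm means, standard deviations and a two-sided Wilcoxon
matched-pair signed-rank p-value, returning a
:class:`PairedComparisonResults` whose ``summary()`` renders the familiar
"mean+/-SD | mean+/-SD | * or ~" comparison table per stage stratum.

The signed-rank test enumerates all 2^n sign assignments exactly for
n <= 15 informative pairs (midranks for tied magnitudes) and switches to
the tie-corrected normal approximation above, without continuity
correction.  Zero differences are dropped (classical Wilcoxon convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PatientCase, Plan
from .metrics import oar_metrics, target_metrics
from .radbio import FractionationScheme, ParamLibrary, ntcp_relative_seriality, tcp_poisson

__all__ = [
    "SignedRankResult",
    "signed_rank_test",
    "default_battery",
    "compute_plan_metrics",
    "PairedPlanComparison",
    "PairedComparisonResults",
    "summarize_cohort",
    "render_report",
]

ALPHA = 0.05
_EXACT_MAX_N = 15

#: target structure -> prescription dose (Gy)
TARGET_PRESCRIPTIONS = {"PTV70": 70.0, "PTV60": 60.0, "PTV54": 54.0}

#: default metric battery mirroring the clinical report schema.  Target
#: "max"/"min" rows are the D2%/D98% proxies; tcp/ntcp are percent-scale.
DEFAULT_BATTERY: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("PTV70", ("tcp", "mean", "d2pct", "d98pct", "v110pct", "v107pct",
               "v95pct", "cn", "hi")),
    ("PTV60", ("mean", "d2pct", "d98pct", "v95pct", "cn", "hi")),
    ("PTV54", ("mean", "v95pct")),
    ("brain_stem", ("ntcp", "d1pct", "d5pct")),
    ("spinal_cord", ("ntcp", "d1pct", "d5pct")),
    ("optic_nerve", ("ntcp", "d1pct", "d5pct")),
    ("optic_chiasma", ("ntcp", "d1pct", "d5pct")),
    ("eye_retina", ("ntcp", "mean")),
    ("lens", ("ntcp", "mean")),
    ("parotid", ("ntcp", "mean", "v30gy", "v40gy", "v50gy")),
)


def default_battery() -> list[tuple[str, tuple[str, ...]]]:
    return list(DEFAULT_BATTERY)


# -- Wilcoxon matched-pair signed-rank test ------------------------------


@dataclass(frozen=True)
class SignedRankResult:
    p_value: float
    statistic: float  # W+ (sum of ranks of positive differences)
    n_used: int       # informative (nonzero) pairs
    method: str       # "exact" | "approx" | "degenerate"
    all_zero: bool = False


@lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n inclusion patterns as a (2^n, n) 0/1 matrix."""
    idx = np.arange(2 ** n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating every sign assignment."""
    w_all = _sign_matrix(len(ranks)) @ ranks
    m = w_all.size
    tol = 1e-9
    lo = np.count_nonzero(w_all <= w_plus + tol) / m
    hi = np.count_nonzero(w_all >= w_plus - tol) / m
    return min(1.0, 2.0 * min(lo, hi))


def signed_rank_test(diffs: Sequence[float],
                     exact_max_n: int = _EXACT_MAX_N,
                     zero_tol: float = 0.0) -> SignedRankResult:
    """Two-sided Wilcoxon matched-pair signed-rank test on paired differences.

    Zero differences (|d| <= ``zero_tol``) are removed first; if every
    difference is zero the test is degenerate and p = 1 is returned with a
    warning flag.  With at most ``exact_max_n`` informative pairs the null
    distribution of W+ is enumerated exactly (valid with ties via
    midranks); beyond that the normal approximation with midrank tie
    correction and no continuity correction is used.
    """
    d = np.asarray(list(diffs), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    d = d[np.abs(d) > zero_tol]
    n = d.size
    if n == 0:
        return SignedRankResult(1.0, 0.0, 0, "degenerate", all_zero=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return SignedRankResult(_exact_p(ranks, w_plus), w_plus, n, "exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return SignedRankResult(1.0, w_plus, n, "degenerate", all_zero=False)
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SignedRankResult(min(p, 1.0), w_plus, n, "approx")


# -- per-plan metric battery ---------------------------------------------


def compute_plan_metrics(plan: Plan, params: ParamLibrary,
                         tcp_stage: str) -> dict[tuple[str, str], float]:
    """All per-structure metrics of one plan as a {(structure, metric): value} map.

    TCP (PTV70 only, staged parameter row) and NTCP values are reported on
    the percent scale to match the clinical tables; doses in Gy; V-metrics
    in percent of structure volume.
    """
    out: dict[tuple[str, str], float] = {}
    fx = plan.fractions
    for name, dvh in plan.dvhs.items():
        if name in TARGET_PRESCRIPTIONS:
            vals = target_metrics(dvh, TARGET_PRESCRIPTIONS[name],
                                  conformity=plan.conformity.get(name))
            if name == "PTV70":
                vals["tcp"] = 100.0 * tcp_poisson(dvh, params.tcp(tcp_stage), fx)
        else:
            vals = oar_metrics(dvh)
            if params.has_ntcp(name):
                vals["ntcp"] = 100.0 * ntcp_relative_seriality(
                    dvh, params.ntcp(name), fx)
        for metric, value in vals.items():
            out[(name, metric)] = float(value)
    return out


# -- model / results -----------------------------------------------------


class PairedPlanComparison:
    """Paired two-arm plan comparison model over a cohort of patient cases.

    Parameters
    ----------
    cases : list of PatientCase
        Paired cases; strata may be mixed and are summarised separately.
    battery : sequence of (structure, metrics) pairs, optional
        Which metrics to compare per structure (default: the clinical
        report schema).
    params : ParamLibrary, optional
        Dose-response parameter library (default: packaged values).
    arm_a, arm_b : str
        Arm labels; differences and table columns are ``arm_a`` vs ``arm_b``.
    alpha : float
        Significance threshold (flags at p <= alpha).
    """

    def __init__(self, cases: Sequence[PatientCase],
                 battery: Optional[Sequence[tuple[str, Sequence[str]]]] = None,
                 params: Optional[ParamLibrary] = None,
                 arm_a: str = "BBTP", arm_b: str = "DVTP",
                 alpha: float = ALPHA):
        if not cases:
            raise ValueError("need at least one patient case")
        for case in cases:
            for arm in (arm_a, arm_b):
                if arm not in case.arms:
                    raise ValueError(f"case {case.case_id} lacks arm {arm!r}")
        self.cases = list(cases)
        self.battery = list(battery) if battery is not None else default_battery()
        self.params = params if params is not None else ParamLibrary.default()
        self.arm_a, self.arm_b = arm_a, arm_b
        self.alpha = alpha

    def fit(self) -> "PairedComparisonResults":
        per_case: dict[str, list] = {}
        values: dict[str, dict[tuple[str, str], dict[str, list[float]]]] = {}
        skipped: list[str] = []
        for case in self.cases:
            stratum = case.stage_stratum
            metrics_by_arm = {
                arm: compute_plan_metrics(case.arms[arm], self.params,
                                          case.tcp_stage_key)
                for arm in (self.arm_a, self.arm_b)
            }
            store = values.setdefault(stratum, {})
            for structure, metric_names in self.battery:
                for metric in metric_names:
                    key = (structure, metric)
                    pair = [metrics_by_arm[arm].get(key)
                            for arm in (self.arm_a, self.arm_b)]
                    if any(v is None for v in pair):
                        skipped.append(
                            f"{case.case_id}: missing ({structure}, {metric})")
                        continue
                    slot = store.setdefault(key, {"a": [], "b": []})
                    slot["a"].append(pair[0])
                    slot["b"].append(pair[1])
        tables: dict[str, pd.DataFrame] = {}
        for stratum, store in values.items():
            rows = []
            for (structure, metric), slot in store.items():
                a = np.asarray(slot["a"])
                b = np.asarray(slot["b"])
                n = a.size
                row = {"structure": structure, "metric": metric, "n": n,
                       "mean_a": a.mean(), "sd_a": a.std(ddof=1) if n > 1 else 0.0,
                       "mean_b": b.mean(), "sd_b": b.std(ddof=1) if n > 1 else 0.0}
                if n >= 2:
                    # differences at float-rounding scale are not evidence
                    res = signed_rank_test(a - b, zero_tol=1e-9)
                    row["p_value"] = res.p_value
                    row["significant"] = res.p_value <= self.alpha
                else:
                    row["p_value"] = np.nan
                    row["significant"] = False
                rows.append(row)
            tables[stratum] = pd.DataFrame(rows)
        return PairedComparisonResults(self, tables, skipped)


@dataclass
class PairedComparisonResults:
    """Fitted paired-comparison tables, one per stage stratum."""

    model: PairedPlanComparison
    tables: dict[str, pd.DataFrame]
    skipped: list[str] = field(default_factory=list)

    def table(self, stratum: str) -> pd.DataFrame:
        return self.tables[stratum]

    def summary(self) -> str:
        chunks = []
        for stratum in sorted(self.tables):
            chunks.append(f"Stratum: {stratum} "
                          f"({self.model.arm_a} vs {self.model.arm_b}, "
                          f"Wilcoxon signed-rank, alpha={self.model.alpha:g})")
            chunks.append(render_report(self.tables[stratum],
                                        self.model.arm_a, self.model.arm_b))
        if self.skipped:
            chunks.append(f"skipped metric entries: {len(self.skipped)}")
        return "\n".join(chunks)

    def to_csv(self, stratum: str, path) -> None:
        self.tables[stratum].to_csv(path, index=False)

    def plot_metric(self, stratum: str, structure: str, metric: str, ax=None):
        """Paired per-case values of one metric, one line per patient."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        a, b = [], []
        for case in m.cases:
            if case.stage_stratum != stratum:
                continue
            va = compute_plan_metrics(case.arms[m.arm_a], m.params,
                                      case.tcp_stage_key).get((structure, metric))
            vb = compute_plan_metrics(case.arms[m.arm_b], m.params,
                                      case.tcp_stage_key).get((structure, metric))
            if va is not None and vb is not None:
                a.append(va)
                b.append(vb)
        for va, vb in zip(a, b):
            ax.plot([0, 1], [va, vb], "o-", color="0.5", alpha=0.7)
        ax.set_xticks([0, 1], [m.arm_a, m.arm_b])
        ax.set_ylabel(f"{structure} {metric}")
        return ax


def summarize_cohort(cases: Sequence[PatientCase],
                     battery: Optional[Sequence[tuple[str, Sequence[str]]]] = None,
                     params: Optional[ParamLibrary] = None,
                     arm_a: str = "BBTP", arm_b: str = "DVTP",
                     alpha: float = ALPHA) -> dict[str, pd.DataFrame]:
    """Per-stratum comparison tables (mean+/-SD per arm, p, significance)."""
    return PairedPlanComparison(cases, battery=battery, params=params,
                                arm_a=arm_a, arm_b=arm_b, alpha=alpha).fit().tables


def render_report(table: pd.DataFrame, arm_a: str = "BBTP",
                  arm_b: str = "DVTP") -> str:
    """Human-readable comparison table with * / ~ significance symbols."""
    header = (f"{'structure':<14}{'metric':<10}"
              f"{arm_a + ' mean±SD':>20}{arm_b + ' mean±SD':>20}"
              f"{'p':>10}  sig")
    lines = [header, "-" * len(header)]
    for _, r in table.iterrows():
        sig = "*" if r["significant"] else "~"
        p = "" if pd.isna(r["p_value"]) else f"{r['p_value']:.4f}"
        lines.append(
            f"{r['structure']:<14}{r['metric']:<10}"
            f"{f'{r.mean_a:.2f}±{r.sd_a:.2f}':>20}"
            f"{f'{r.mean_b:.2f}±{r.sd_b:.2f}':>20}"
            f"{p:>10}  {sig}")
    return "\n".join(lines)
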
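"""Pairwise hypothesis tests between modalities and the multi-index decision rule.

For every unordered pair of the six experimental modalities, each index
(H, PSk, TP, DFs) is tested for equality of means across participants with
an unequal-variance (Welch) t-test at α = 0.05, giving a binary decision
matrix per index per group.  The four matrices are then combined cell-wise
with a conservative majority rule: a modality pair is

* ``Reject``  when H0 is rejected for 3 or 4 indices,
* ``Neutral`` when exactly 2 indices reject,
* ``Accept``  when 0 or 1 reject.

Borderline tests (p within 0.005 of α) are flagged; an optional switch lets
borderline accepts count as rejects, which matters for one cell of the
bundled reference tables (see :func:`load_reference_decision_tables`).

:func:`robustness_battery` wraps the surrounding standard checks — omnibus
ANOVA/Friedman, pairwise Wilcoxon, Bonferroni-corrected pairwise t-tests and
four normality tests — into one structured report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .preprocess import MODALITIES

__all__ = [
    "TABLE_MODALITY_ORDER",
    "WelchResult",
    "DecisionMatrix",
    "CombinedDecisionMatrix",
    "welch_t_test",
    "pairwise_decision_matrix",
    "combine_decisions",
    "combined_matrix",
    "robustness_battery",
    "load_reference_decision_tables",
    "load_reference_combined",
]

#: Modality order used by the reference cohort's printed decision tables.
TABLE_MODALITY_ORDER = ("MED", "MM", "WORDS", "SENT", "IMG", "VDO")

INDEX_KINDS = ("H", "PSk", "TP", "DFs")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    reject: bool
    degenerate: bool = False
    borderline: bool = False


def welch_t_test(
    x, y, alpha: float = 0.05, borderline_margin: float = 0.005
) -> WelchResult:
    """Two-sided unequal-variance t-test with Satterthwaite degrees of freedom.

    Degenerate inputs (zero variance in both samples) yield p = 1 for equal
    means, or a flagged rejection for unequal means.  ``borderline`` marks
    |p - α| < ``borderline_margin``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return WelchResult(t=0.0, df=float(x.size + y.size - 2), p=1.0,
                               reject=False, degenerate=True)
        return WelchResult(t=math.inf, df=float(x.size + y.size - 2), p=0.0,
                           reject=True, degenerate=True)
    res = sstats.ttest_ind(x, y, equal_var=False)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return WelchResult(
        t=t, df=df, p=p, reject=bool(p < alpha),
        borderline=bool(abs(p - alpha) < borderline_margin),
    )


@dataclass
class DecisionMatrix:
    """Binary accept/reject matrix over modality pairs for one index and group."""

    index_kind: str
    group: str
    modalities: tuple[str, ...]
    decisions: np.ndarray  # int, -1 on the diagonal
    pvalues: np.ndarray  # NaN on the diagonal
    borderline: np.ndarray  # bool
    alpha: float = 0.05

    def decision(self, a: str, b: str) -> int:
        i, j = self.modalities.index(a), self.modalities.index(b)
        return int(self.decisions[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decisions, index=self.modalities,
                            columns=self.modalities)


def pairwise_decision_matrix(
    data: pd.DataFrame | dict,
    index_kind: str = "",
    group: str = "",
    alpha: float = 0.05,
    modalities: tuple[str, ...] = TABLE_MODALITY_ORDER,
) -> DecisionMatrix:
    """Test all unordered modality pairs on participant-level values.

    ``data`` maps modality -> per-participant values (dict), or is a frame
    with columns ``modality`` and ``value``.  Both triangles of the returned
    matrix are populated identically.
    """
    if isinstance(data, pd.DataFrame):
        samples = {m: g["value"].to_numpy() for m, g in data.groupby("modality")}
    else:
        samples = {m: np.asarray(v, dtype=float) for m, v in data.items()}
    missing = [m for m in modalities if m not in samples]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    for m in modalities:
        if len(samples[m]) < 2:
            raise ValueError(f"modality {m}: need at least 2 participants")

    k = len(modalities)
    dec = np.full((k, k), -1, dtype=int)
    pvals = np.full((k, k), np.nan)
    border = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        res = welch_t_test(samples[modalities[i]], samples[modalities[j]], alpha=alpha)
        dec[i, j] = dec[j, i] = int(res.reject)
        pvals[i, j] = pvals[j, i] = res.p
        border[i, j] = border[j, i] = res.borderline
    return DecisionMatrix(
        index_kind=index_kind, group=group, modalities=tuple(modalities),
        decisions=dec, pvalues=pvals, borderline=border, alpha=alpha,
    )


def combine_decisions(
    decisions,
    borderline: tuple[bool, ...] | None = None,
    borderline_as_reject: bool = False,
) -> str:
    """Collapse four per-index H0 decisions into Reject / Neutral / Accept.

    Rejecting 3-4 indices → Reject; exactly 2 → Neutral; 0-1 → Accept.
    With ``borderline_as_reject``, a borderline accept (p just above α)
    counts toward the rejection tally.
    """
    d = list(decisions)
    if len(d) != 4 or any(v not in (0, 1) for v in d):
        raise ValueError("expected exactly four binary decisions")
    if borderline_as_reject and borderline is not None:
        d = [1 if (v == 0 and bl) else v for v, bl in zip(d, borderline)]
    count = sum(d)
    if count >= 3:
        return "Reject"
    if count == 2:
        return "Neutral"
    return "Accept"


@dataclass
class CombinedDecisionMatrix:
    """Categorical modality x modality matrix from the four-index rule."""

    group: str
    modalities: tuple[str, ...]
    categories: np.ndarray  # object array of {Accept, Neutral, Reject}, "" diag
    rejection_counts: np.ndarray  # int, -1 diag

    def category(self, a: str, b: str) -> str:
        i, j = self.modalities.index(a), self.modalities.index(b)
        return str(self.categories[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.categories, index=self.modalities,
                            columns=self.modalities)


def combined_matrix(
    dms: dict[str, DecisionMatrix] | list[DecisionMatrix],
    borderline_as_reject: bool = False,
) -> CombinedDecisionMatrix:
    """Cell-wise combination of the four per-index decision matrices."""
    if isinstance(dms, dict):
        dms = [dms[k] for k in INDEX_KINDS]
    if len(dms) != 4:
        raise ValueError("need exactly four decision matrices (H, PSk, TP, DFs)")
    mods = dms[0].modalities
    group = dms[0].group
    for dm in dms[1:]:
        if dm.modalities != mods:
            raise ValueError("decision matrices have mismatched modality sets")
        if dm.group != group:
            raise ValueError("decision matrices have mismatched groups")

    k = len(mods)
    cats = np.full((k, k), "", dtype=object)
    counts = np.full((k, k), -1, dtype=int)
    for i, j in itertools.combinations(range(k), 2):
        dec = tuple(int(dm.decisions[i, j]) for dm in dms)
        bl = tuple(bool(dm.borderline[i, j]) for dm in dms)
        eff = [1 if (v == 0 and b and borderline_as_reject) else v
               for v, b in zip(dec, bl)]
        cats[i, j] = cats[j, i] = combine_decisions(
            dec, borderline=bl, borderline_as_reject=borderline_as_reject
        )
        counts[i, j] = counts[j, i] = sum(eff)
    return CombinedDecisionMatrix(
        group=group, modalities=mods, categories=cats, rejection_counts=counts
    )


# ---------------------------------------------------------------------------
# bundled reference tables (worked example for the combination rule)


def _reference_path(name: str):
    return resources.files("eegstates.data").joinpath(name)


def load_reference_decision_tables() -> dict[str, dict[str, DecisionMatrix]]:
    """Per-index binary decision tables of the reference 20-participant
    meditation cohort (11 meditators vs 9 non-meditators, six modalities).

    Returns ``{group: {index_kind: DecisionMatrix}}``.  Two cells carry a
    borderline flag (test p-value very close to α as published).  P-values
    themselves were not published, so the p-value matrices are NaN.
    """
    ref = _reference_path("reference_decision_tables.csv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path)
    mods = TABLE_MODALITY_ORDER
    k = len(mods)
    out: dict[str, dict[str, DecisionMatrix]] = {}
    for (group, kind), sub in table.groupby(["group", "index"]):
        dec = np.full((k, k), -1, dtype=int)
        border = np.zeros((k, k), dtype=bool)
        for _, row in sub.iterrows():
            i, j = mods.index(row["mod_a"]), mods.index(row["mod_b"])
            dec[i, j] = dec[j, i] = int(row["decision"])
            border[i, j] = border[j, i] = bool(row["borderline"])
        out.setdefault(group, {})[kind] = DecisionMatrix(
            index_kind=kind, group=group, modalities=mods, decisions=dec,
            pvalues=np.full((k, k), np.nan), borderline=border,
        )
    return out


def load_reference_combined() -> dict[str, pd.DataFrame]:
    """Published combined Reject/Neutral/Accept matrix of the reference
    cohort, as ``{group: long-format frame}`` with one row per pair."""
    ref = _reference_path("reference_combined_decisions.csv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path)
    return {g: sub.reset_index(drop=True) for g, sub in table.groupby("group")}


# ---------------------------------------------------------------------------
# robustness battery


def robustness_battery(data: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Standard-routine cross-checks of the modality effect on one index.

    ``data`` has columns participant, modality, value (participant-level
    summaries).  The report bundles: one-way and repeated-measures ANOVA,
    Friedman, pairwise Wilcoxon signed-rank, Bonferroni-adjusted pairwise
    Welch p-values, and Shapiro-Wilk / Anderson-Darling / D'Agostino K2 /
    Kolmogorov-Smirnov normality checks per modality.  Repeated-measures
    entries are marked unavailable when the design is unbalanced.
    """
    from statsmodels.stats.multitest import multipletests

    mods = sorted(data["modality"].unique())
    samples = {m: data.loc[data["modality"] == m, "value"].to_numpy() for m in mods}
    report: dict = {"alpha": alpha, "modalities": mods}

    f_stat, f_p = sstats.f_oneway(*[samples[m] for m in mods])
    report["anova_oneway"] = {"F": float(f_stat), "p": float(f_p)}

    wide = data.pivot_table(index="participant", columns="modality", values="value")
    balanced = not wide.isna().any().any()
    if balanced and len(mods) >= 3:
        fr_stat, fr_p = sstats.friedmanchisquare(*[wide[m].to_numpy() for m in mods])
        report["friedman"] = {"chi2": float(fr_stat), "p": float(fr_p)}
        try:
            from statsmodels.stats.anova import AnovaRM

            rm = AnovaRM(
                data, depvar="value", subject="participant", within=["modality"]
            ).fit()
            row = rm.anova_table.iloc[0]
            report["anova_rm"] = {"F": float(row["F Value"]),
                                  "p": float(row["Pr > F"])}
        except Exception as exc:  # pragma: no cover - statsmodels edge cases
            report["anova_rm"] = {"unavailable": str(exc)}
        wilcoxon = {}
        for a, b in itertools.combinations(mods, 2):
            try:
                w = sstats.wilcoxon(wide[a], wide[b])
                wilcoxon[f"{a}|{b}"] = {"W": float(w.statistic), "p": float(w.pvalue)}
            except ValueError as exc:  # all-zero differences
                wilcoxon[f"{a}|{b}"] = {"unavailable": str(exc)}
        report["wilcoxon_pairwise"] = wilcoxon
    else:
        note = "unbalanced repeated-measures design"
        report["friedman"] = {"unavailable": note}
        report["anova_rm"] = {"unavailable": note}
        report["wilcoxon_pairwise"] = {"unavailable": note}

    pairs = list(itertools.combinations(mods, 2))
    raw_p = [welch_t_test(samples[a], samples[b], alpha=alpha).p for a, b in pairs]
    rejected, adj_p, _, _ = multipletests(raw_p, alpha=alpha, method="bonferroni")
    report["bonferroni_pairwise"] = {
        f"{a}|{b}": {"p_raw": float(p), "p_adj": float(q), "reject": bool(r)}
        for (a, b), p, q, r in zip(pairs, raw_p, adj_p, rejected)
    }

    normality = {}
    for m in mods:
        v = samples[m]
        sh = sstats.shapiro(v)
        try:
            ad = sstats.anderson(v, dist="norm", method="interpolate")
            ad_entry = {
                "stat": float(ad.statistic),
                "p": float(ad.pvalue),
                "reject_5pct": bool(ad.pvalue < 0.05),
            }
        except TypeError:  # older scipy without the method/pvalue API
            ad = sstats.anderson(v, dist="norm")
            crit = ad.critical_values[list(ad.significance_level).index(5.0)]
            ad_entry = {
                "stat": float(ad.statistic),
                "reject_5pct": bool(ad.statistic > crit),
            }
        ks = sstats.kstest((v - v.mean()) / v.std(ddof=1), "norm")
        entry = {
            "shapiro_wilk": {"stat": float(sh.statistic), "p": float(sh.pvalue)},
            "anderson_darling": ad_entry,
            "kolmogorov_smirnov": {"stat": float(ks.statistic), "p": float(ks.pvalue)},
        }
        if len(v) >= 8:
            dk = sstats.normaltest(v)
            entry["dagostino_k2"] = {"stat": float(dk.statistic), "p": float(dk.pvalue)}
        else:
            entry["dagostino_k2"] = {"unavailable": "needs n >= 8"}
        normality[m] = entry
    report["normality"] = normality
    return report
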
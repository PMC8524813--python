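"""Differential H3K9me3 enrichment between groups or across stages.

Two-group mode (normal vs cancer cell lines): per-element Welch two-sample
t-test on the clamped log2 FC values; elements with unadjusted p < alpha form
the headline differential set (Bonferroni-adjusted significance is reported
alongside — with a broad histone mark and only handfuls of samples, family-
wise correction across thousands of elements is known to be very
conservative, so both sets are kept).

Stage mode (fetal development): per-element one-way ANOVA across stages with
tissues as replicates, Bonferroni correction across elements, Tukey HSD post
hoc (Tukey-Kramer for unequal stage sizes) on elements with adjusted
p < 0.01, and finally a biological-relevance filter: stage means of clamped
log2 FC are shifted by +1 and the larger of the two direction ratios must
reach 1.5.  The shift prevents near-zero means (e.g. 0.1 vs 0.01, both
practically FC 1) from registering as ten-fold differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import RepeatInstance
from .signal import EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialRecord",
    "FamilyEnrichment",
    "welch_test",
    "anova_oneway",
    "bonferroni",
    "tukey_hsd",
    "relevance_filter",
    "differential_two_group",
    "differential_stagewise",
    "family_overrepresentation",
]


@dataclass
class DifferentialRecord:
    """Per-element test result."""

    element_id: str
    test: str  # "welch" | "anova"
    statistic: float
    df: tuple
    p: float
    p_adj: float
    significant: bool
    significant_adj: bool = False
    group_means: dict = field(default_factory=dict)
    # (stage_a, stage_b, tukey_p, relevance_ratio, relevant)
    pairwise: list = field(default_factory=list)
    flags: list = field(default_factory=list)


@dataclass
class FamilyEnrichment:
    """Over-representation of one satellite family in the differential set."""

    family: str
    N: int  # all analyzed elements
    K: int  # family elements among N
    n: int  # differential elements
    k: int  # family elements among n
    fold: float  # (k/n)/(K/N)
    p: float  # upper-tail hypergeometric P(X >= k)


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Welch unequal-variance t-test: (t, Welch-Satterthwaite df, p).

    Degenerate conventions: both groups constant and equal -> (0, df, 1);
    both constant and different -> p = 0 (the caller flags this).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_test requires >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df_fallback = float(len(a) + len(b) - 2)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, df_fallback, 1.0
        return float("inf"), df_fallback, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_oneway(values: Sequence[float], labels: Sequence) -> tuple[float, int, int, float]:
    """One-way ANOVA: (F, df_between, df_within, p).

    Groups are the distinct labels.  All values identical -> (0, ., ., 1).
    Zero within-group variance with differing means -> F = inf, p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("anova_oneway requires >= 2 groups")
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("anova_oneway requires >= 1 group with >= 2 observations")
    dfb = len(groups) - 1
    dfw = len(values) - len(groups)
    if np.all(values == values[0]):
        return 0.0, dfb, dfw, 1.0
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        return float("inf"), dfb, dfw, 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), dfb, dfw, p


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), m defaulting to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def tukey_hsd(values: Sequence[float], labels: Sequence) -> list[tuple]:
    """All-pairs Tukey HSD p-values: [(label_a, label_b, p), ...].

    Uses the studentized-range distribution with the Tukey-Kramer adjustment
    for unequal group sizes.  Groups with < 2 observations participate (the
    pooled within-group variance carries the df); two identical groups give
    p = 1.  A label with zero observations never arises (labels define groups).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    groups = {g: values[labels == g] for g in uniq}
    n_total = len(values)
    k = len(uniq)
    dfw = n_total - k
    if dfw < 1:
        raise ValueError("Tukey HSD requires residual df >= 1")
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = ssw / dfw
    out = []
    for ga, gb in itertools.combinations(uniq, 2):
        a, b = groups[ga], groups[gb]
        if len(a) < 1 or len(b) < 1:
            out.append((ga, gb, float("nan")))
            continue
        if mse == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            q = abs(a.mean() - b.mean()) / se
            p = float(stats.studentized_range.sf(q, k, dfw))
        out.append((ga, gb, min(1.0, p)))
    return out


def relevance_filter(
    stage_means: Mapping, cutoff: float = 1.5
) -> list[tuple]:
    """Pairwise biological-relevance ratios on +1-shifted stage means.

    For each stage pair, ratio = max((ma+1)/(mb+1), (mb+1)/(ma+1)); the pair
    is relevant iff ratio >= cutoff (inclusive).  Symmetric in the two stages.
    Returns [(stage_a, stage_b, ratio, relevant), ...].
    """
    items = list(stage_means.items())
    out = []
    for (ga, ma), (gb, mb) in itertools.combinations(items, 2):
        ta, tb = ma + 1.0, mb + 1.0
        ratio = max(ta / tb, tb / ta)
        out.append((ga, gb, ratio, ratio >= cutoff))
    return out


def differential_two_group(
    matrix: EnrichmentMatrix,
    grouping: Mapping[str, str] | str = "group",
    alpha: float = 0.05,
) -> list[DifferentialRecord]:
    """Welch test per element between two sample groups.

    ``grouping`` is either a metadata column name or an explicit
    sample_id -> group mapping; it must define exactly two groups.
    Significance flags use the unadjusted p (the headline set); Bonferroni-
    adjusted significance is reported in the same record.  All-zero rows are
    tested and flagged ``all_zero``; zero-variance rows get the degenerate
    conventions of :func:`welch_test` and a ``degenerate`` flag when the
    constant means differ.
    """
    if isinstance(grouping, str):
        g = matrix.groups(grouping)
    else:
        g = pd.Series({s: grouping[s] for s in matrix.values.columns})
    names = list(pd.unique(g.loc[matrix.values.columns]))
    if len(names) != 2:
        raise ValueError(f"two-group mode needs exactly 2 groups, got {names}")
    ga, gb = names
    X = matrix.values
    A = X.loc[:, g.loc[X.columns] == ga].to_numpy()
    B = X.loc[:, g.loc[X.columns] == gb].to_numpy()
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    # vectorized Welch across rows; degenerate rows patched by convention
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        t = np.array(res.statistic, dtype=float)
        p = np.array(res.pvalue, dtype=float)
        df = np.array(res.df, dtype=float)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    ma = A.mean(axis=1)
    mb = B.mean(axis=1)
    const = (va == 0) & (vb == 0)
    eq = const & (ma == mb)
    ne = const & (ma != mb)
    t[eq], p[eq] = 0.0, 1.0
    t[ne], p[ne] = np.inf, 0.0
    df[const] = A.shape[1] + B.shape[1] - 2
    p_adj = bonferroni(p)

    records = []
    for i, eid in enumerate(X.index):
        flags = []
        if (A[i] == 0).all() and (B[i] == 0).all():
            flags.append("all_zero")
        if ne[i]:
            flags.append("degenerate")
        records.append(
            DifferentialRecord(
                element_id=eid,
                test="welch",
                statistic=float(t[i]),
                df=(float(df[i]),),
                p=float(p[i]),
                p_adj=float(p_adj[i]),
                significant=bool(p[i] < alpha),
                significant_adj=bool(p_adj[i] < alpha),
                group_means={ga: float(ma[i]), gb: float(mb[i])},
                flags=flags,
            )
        )
    return records


def differential_stagewise(
    matrix: EnrichmentMatrix,
    stage_labels: Mapping[str, str] | str = "stage",
    posthoc_alpha_adj: float = 0.01,
    tukey_alpha: float = 0.05,
    relevance_cutoff: float = 1.5,
) -> list[DifferentialRecord]:
    """ANOVA -> Bonferroni -> Tukey HSD -> relevance filter per element.

    An element is reported significant iff its Bonferroni-adjusted ANOVA p
    is < ``posthoc_alpha_adj`` and at least one stage pair is both
    Tukey-significant (p < ``tukey_alpha``) and relevant (+1-shifted stage-
    mean ratio >= ``relevance_cutoff``).
    """
    if isinstance(stage_labels, str):
        lab = matrix.groups(stage_labels)
    else:
        lab = pd.Series({s: stage_labels[s] for s in matrix.values.columns})
    lab = lab.loc[matrix.values.columns]
    stages = list(pd.unique(lab))
    if len(stages) < 2:
        raise ValueError("stagewise mode needs >= 2 stages")
    X = matrix.values.to_numpy()
    labels = lab.to_numpy()
    cols = [labels == s for s in stages]

    # vectorized one-way ANOVA across rows
    n = X.shape[1]
    k = len(stages)
    dfb, dfw = k - 1, n - k
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    means = np.empty((X.shape[0], k))
    for j, mask in enumerate(cols):
        gm = X[:, mask].mean(axis=1)
        means[:, j] = gm
        ssb += mask.sum() * (gm - grand) ** 2
        ssw += ((X[:, mask] - gm[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    all_const = np.isclose(ssb + ssw, 0.0)
    F[all_const], p[all_const] = 0.0, 1.0
    zero_within = (ssw == 0) & ~all_const
    F[zero_within], p[zero_within] = np.inf, 0.0
    p_adj = bonferroni(p)

    records = []
    for i, eid in enumerate(matrix.values.index):
        rec = DifferentialRecord(
            element_id=eid,
            test="anova",
            statistic=float(F[i]),
            df=(dfb, dfw),
            p=float(p[i]),
            p_adj=float(p_adj[i]),
            significant=False,
            significant_adj=bool(p_adj[i] < posthoc_alpha_adj),
            group_means={s: float(means[i, j]) for j, s in enumerate(stages)},
        )
        if rec.significant_adj:
            tk = {(a, b): tp for a, b, tp in tukey_hsd(X[i], labels)}
            rel = relevance_filter(rec.group_means, cutoff=relevance_cutoff)
            pairwise = []
            hit = False
            for ga, gb, ratio, relevant in rel:
                tp = tk.get((ga, gb), tk.get((gb, ga), float("nan")))
                tukey_sig = bool(tp < tukey_alpha)
                pairwise.append((ga, gb, float(tp), float(ratio), relevant))
                if tukey_sig and relevant:
                    hit = True
            rec.pairwise = pairwise
            rec.significant = hit
        records.append(rec)
    return records


def family_overrepresentation(
    all_instances: Sequence[RepeatInstance],
    differential_ids: Sequence[str],
) -> list[FamilyEnrichment]:
    """Hypergeometric over-representation of satellite families.

    For each family: fold = (k/n)/(K/N) and p = P(X >= k) with X
    hypergeometric(N, K, n), where N is the number of analyzed elements,
    K the family's elements, n the differential set size and k the family's
    elements within it.
    """
    ids = set(differential_ids)
    unknown = ids - {i.id for i in all_instances}
    if unknown:
        raise ValueError(f"differential ids not in instance set: {sorted(unknown)[:5]}")
    n = len(ids)
    if n == 0:
        return []
    N = len(all_instances)
    by_family: dict[str, list[RepeatInstance]] = {}
    for inst in all_instances:
        by_family.setdefault(inst.name, []).append(inst)
    out = []
    for family in sorted(by_family):
        members = by_family[family]
        K = len(members)
        k = sum(1 for m in members if m.id in ids)
        fold = (k / n) / (K / N)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        out.append(FamilyEnrichment(family=family, N=N, K=K, n=n, k=k,
                                    fold=float(fold), p=min(1.0, p)))
    return out


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Flatten differential records to the TSV output layout."""
    rows = []
    for r in records:
        best = None
        for pw in r.pairwise:
            if best is None or (pw[3], -pw[2]) > (best[3], -best[2]):
                best = pw
        rows.append(
            {
                "element_id": r.element_id,
                "test": r.test,
                "statistic": r.statistic,
                "df": "/".join(str(d) for d in r.df),
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "significant_adj": r.significant_adj,
                **{f"mean_{g}": m for g, m in r.group_means.items()},
                "best_pair": f"{best[0]}|{best[1]}" if best else "NA",
                "best_ratio": best[3] if best else np.nan,
                "flags": ",".join(r.flags) if r.flags else "",
            }
        )
    return pd.DataFrame(rows)
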
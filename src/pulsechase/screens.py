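"""Statistical screens: correlations, DEG filtering, ANOVA + LSD letters.

The screens reproduce the descriptive statistics a fruit-development
study reports around its sugar data:

* Pearson correlation matrices between sugar contents and the five
  sucrose-metabolism enzymes (SuSy-II, SPS, S-AI, B-AI, NI), starred
  with the conventional ``*`` (p < 0.05) / ``**`` (p < 0.01) marks;
* a ranking of genes by the Pearson correlation of their FPKM
  trajectory with the sucrose trajectory;
* filtering of differential-expression tables at FDR <= 0.05 and
  |log2 fold change| >= 1 (both boundaries inclusive), plus Venn-region
  counts across comparisons;
* one-way ANOVA with Fisher's LSD post hoc, summarized as a compact
  letter display (groups share a letter iff not significantly
  different).

Correlations pair observations at replicate level by default; pass
``stage_means=True`` to collapse replicates first.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ENZYMES",
    "pearson_with_p",
    "star_for_p",
    "enzyme_sugar_matrix",
    "gene_sucrose_screen",
    "deg_filter",
    "venn_overlap",
    "anova_lsd_letters",
    "lsd_pairwise",
    "shapiro_gate",
]

#: Canonical order of the sucrose-metabolism enzyme panel.
ENZYMES = ("SuSy_II", "SPS", "S_AI", "B_AI", "NI")

SUGAR_ROWS = ("soluble_sugar", "fructose", "glucose", "sucrose")


def star_for_p(p: float) -> str:
    """Significance stars: ``**`` iff p < 0.01, ``*`` iff 0.01 <= p < 0.05."""
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_p(x, y) -> tuple[float, float, str, int]:
    """Sample Pearson r with a two-sided p-value and star annotation.

    Pairs with a missing value in either series are dropped
    (pairwise-complete).  The p-value is the usual t transform with
    ``n - 2`` degrees of freedom.  Returns ``(r, p, star, n)``;
    ``(nan, nan, "", n)`` when fewer than 3 complete pairs remain or
    either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "", n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), star_for_p(float(p)), n


def _collapse_stage_means(df: pd.DataFrame, value_cols, keys=("organ", "month")) -> pd.DataFrame:
    return df.groupby(list(keys), as_index=False)[list(value_cols)].mean()


def enzyme_sugar_matrix(
    panels: pd.DataFrame,
    sugars: pd.DataFrame,
    stage_means: bool = False,
) -> dict[str, pd.DataFrame]:
    """Sugar x enzyme Pearson correlation matrix for each organ.

    Parameters
    ----------
    panels
        Enzyme activities, one row per organ x month x replicate with
        columns ``organ, month, replicate`` and one column per enzyme
        (``SuSy_II, SPS, S_AI, B_AI, NI``; missing assays may be absent
        or NaN, e.g. NI in peels).
    sugars
        Sugar contents, same keying, with columns
        ``soluble_sugar, fructose, glucose, sucrose``.
    stage_means
        Collapse replicates to per-month means before correlating.
        Default pairs at replicate level, which is what gives the
        printed significance levels enough degrees of freedom.

    Returns
    -------
    dict of organ -> DataFrame
        Long-format cells: ``sugar, enzyme, r, p, star, n``.  Enzyme
        columns with no usable cell for an organ are dropped; cells with
        fewer than 3 matched points or zero variance carry NaN r and a
        ``reason``.
    """
    enzyme_cols = [c for c in ENZYMES if c in panels.columns]
    sugar_cols = [c for c in SUGAR_ROWS if c in sugars.columns]
    if not enzyme_cols:
        raise ValueError("panels contain no recognized enzyme columns")
    if not sugar_cols:
        raise ValueError("sugars contain no recognized sugar columns")

    keys = ["organ", "month"] if stage_means else ["organ", "month", "replicate"]
    if stage_means:
        panels = _collapse_stage_means(panels, enzyme_cols)
        sugars = _collapse_stage_means(sugars, sugar_cols)
    merged = panels.merge(sugars, on=keys, how="inner")

    out: dict[str, pd.DataFrame] = {}
    for organ, sub in merged.groupby("organ", sort=False):
        rows = []
        for enzyme in enzyme_cols:
            if enzyme not in sub.columns or sub[enzyme].dropna().empty:
                continue  # assay absent for this organ; mirror a blank column
            for sugar in sugar_cols:
                r, p, star, n = pearson_with_p(sub[sugar], sub[enzyme])
                reason = ""
                if np.isnan(r):
                    reason = (
                        f"fewer than 3 matched points (n={n})"
                        if n < 3
                        else "zero variance"
                    )
                rows.append(
                    dict(sugar=sugar, enzyme=enzyme, r=r, p=p, star=star, n=n, reason=reason)
                )
        out[organ] = pd.DataFrame(rows)
    return out


def gene_sucrose_screen(
    expr: pd.DataFrame,
    sucrose_series: pd.DataFrame | Mapping[str, float],
    top_k: int | None = None,
    stage_means: bool = False,
) -> pd.DataFrame:
    """Rank genes by Pearson correlation of FPKM with sucrose content.

    Parameters
    ----------
    expr
        Long-format expression table: ``gene_id, stage, replicate, fpkm``.
    sucrose_series
        Either a mapping stage -> sucrose content (mg/g FW), applied to
        every replicate of that stage, or a DataFrame with columns
        ``stage, replicate, sucrose`` for replicate-resolved pairing.
    top_k
        Return only the ``top_k`` highest-r genes (all genes if None or
        larger than the gene count).
    stage_means
        Correlate per-stage mean FPKM against per-stage sucrose instead
        of replicate-level pairing.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_id, r, p, star, n`` sorted by descending r, ties
        broken by ``gene_id`` (lexicographic).  Zero-variance genes are
        excluded (logged).
    """
    required = {"gene_id", "stage", "replicate", "fpkm"}
    if not required.issubset(expr.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")

    if isinstance(sucrose_series, Mapping):
        suc = pd.DataFrame(
            [{"stage": s, "sucrose": v} for s, v in sucrose_series.items()]
        )
        expr = expr.merge(suc, on="stage", how="inner")
    else:
        on = ["stage"] if "replicate" not in sucrose_series.columns else ["stage", "replicate"]
        expr = expr.merge(sucrose_series, on=on, how="inner")

    if stage_means:
        expr = expr.groupby(["gene_id", "stage"], as_index=False)[["fpkm", "sucrose"]].mean()

    rows = []
    excluded = 0
    for gene_id, sub in expr.groupby("gene_id", sort=False):
        r, p, star, n = pearson_with_p(sub["fpkm"], sub["sucrose"])
        if np.isnan(r):
            excluded += 1
            logger.info("gene %s excluded from screen (zero variance or n<3)", gene_id)
            continue
        rows.append(dict(gene_id=gene_id, r=r, p=p, star=star, n=n))
    if excluded:
        logger.warning("%d genes excluded from the sucrose screen", excluded)

    out = pd.DataFrame(rows, columns=["gene_id", "r", "p", "star", "n"])
    out = out.sort_values(
        ["r", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out


def deg_filter(
    records: pd.DataFrame,
    fdr_max: float = 0.05,
    abs_log2fc_min: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a differential-expression table.

    A gene survives iff ``fdr <= fdr_max`` AND ``|log2fc| >=
    abs_log2fc_min`` — both boundaries inclusive.  Direction is the
    sign of ``log2fc``.

    Returns the surviving rows and ``{"up": ..., "down": ...}`` counts.
    """
    required = {"gene_id", "log2fc", "fdr"}
    if not required.issubset(records.columns):
        raise ValueError(f"DEG table needs columns {sorted(required)}")
    if records.empty:
        return records.copy(), {"up": 0, "down": 0}
    keep = (records["fdr"] <= fdr_max) & (records["log2fc"].abs() >= abs_log2fc_min)
    kept = records.loc[keep].copy()
    counts = {
        "up": int((kept["log2fc"] > 0).sum()),
        "down": int((kept["log2fc"] < 0).sum()),
    }
    return kept, counts


def venn_overlap(sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Counts for every exclusive Venn region of >= 2 gene sets.

    Keys are tuples of set labels; the value is the number of elements
    belonging to exactly those sets.  The region keyed by all labels is
    the common intersection.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = list(sets)
    assets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*assets.values())
    regions = {
        combo: 0
        for r in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, r)
    }
    for el in universe:
        membership = tuple(lbl for lbl in labels if el in assets[lbl])
        regions[membership] += 1
    return regions


def shapiro_gate(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> dict[str, float]:
    """Shapiro-Wilk normality pre-check; warns but never blocks.

    Returns per-group p-values (NaN when a group has < 3 values, the
    test's minimum).  Groups failing at ``alpha`` trigger a warning so
    the analyst can fall back to a nonparametric test if they care.
    """
    out = {}
    for label, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3 or np.ptp(vals) == 0:
            out[label] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.shapiro(vals).pvalue)
        out[label] = p
        if p < alpha:
            logger.warning(
                "group %r fails Shapiro-Wilk normality (p=%.3g); "
                "ANOVA/LSD proceed regardless",
                label,
                p,
            )
    return out


def lsd_pairwise(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[pd.DataFrame, float, float]:
    """All pairwise Fisher LSD tests with the pooled ANOVA error.

    Each pair is compared with a t statistic using the one-way ANOVA
    pooled mean squared error on ``N - k`` degrees of freedom (the
    classical unprotected LSD, as statistical packages implement it).

    Returns ``(pairs, mse, df_error)`` where ``pairs`` has columns
    ``a, b, t, p, significant``.  With zero pooled variance, pairs are
    significant iff their means differ at all.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for label in labels:
        v = np.asarray(groups[label], dtype=float)
        if v.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 replicates")
        arrays[label] = v
    ns = {k: v.size for k, v in arrays.items()}
    means = {k: float(v.mean()) for k, v in arrays.items()}
    N = sum(ns.values())
    k = len(labels)
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in arrays.values())
    df_err = N - k
    mse = sse / df_err

    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = means[a] - means[b]
        if mse == 0:
            sig = diff != 0
            t = float("inf") if sig else 0.0
            p = 0.0 if sig else 1.0
        else:
            se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), df_err)
            sig = p < alpha
        rows.append(dict(a=a, b=b, t=float(t), p=float(p), significant=bool(sig)))
    return pd.DataFrame(rows), mse, float(df_err)


def _insert_absorb(order: list[str], distinct: set[frozenset]) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb construction.

    ``order`` lists groups in the order letters should be assigned
    (descending mean); ``distinct`` holds the significantly different
    pairs.  Each letter is a column of mutually non-distinct groups;
    columns are split for every distinct pair and subsets absorbed, so
    two groups share a letter iff they are not significantly different.
    """
    columns: list[set[str]] = [set(order)]
    for pair in distinct:
        a, b = tuple(pair)
        new_columns = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = [
            c
            for i, c in enumerate(new_columns)
            if c and not any(i != j and c < d or (c == d and i > j) for j, d in enumerate(new_columns))
        ]
    # order columns by the first (highest-mean) group they contain
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in order}
    for idx, col in enumerate(columns):
        letter = alphabet[idx] if idx < 26 else f"z{idx}"
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def anova_lsd_letters(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> dict[str, str]:
    """One-way ANOVA + Fisher LSD compact letter display.

    Groups are labeled ``a``, ``b``, ... in descending-mean order; two
    groups share a letter iff the LSD test does not separate them at
    ``alpha``.  A Shapiro-Wilk normality pre-check logs warnings but
    never blocks the ANOVA.

    Parameters
    ----------
    groups
        Mapping of group label -> replicate values (each >= 2 values).
    alpha
        Pairwise significance level (default 0.05).

    Returns
    -------
    dict of label -> letter string.
    """
    shapiro_gate(groups, alpha)
    pairs, _, _ = lsd_pairwise(groups, alpha)
    means = {k: float(np.mean(np.asarray(v, dtype=float))) for k, v in groups.items()}
    order = sorted(groups, key=lambda g: (-means[g], g))
    distinct = {
        frozenset((row.a, row.b)) for row in pairs.itertuples() if row.significant
    }
    return _insert_absorb(order, distinct)
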
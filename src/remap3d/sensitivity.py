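"""Drug-sensitivity genomics: cell-line classification, per-gene tests,
fold changes, rank-based FDR, gene selection, and over-representation.

Cell lines are labelled from the activity area of their dose-response
profile: sensitive (>= 1.95), resistant (<= 1.3), intermediate in between.
For each gene a classical pooled-variance two-sample Student t-test compares
log2 expression between the sensitive and resistant groups (intermediate
lines are excluded).  The fold change is the ratio of group mean log2
levels, sign-flipped toward the larger group:

    FC = E_S / E_R   if E_S > E_R
    FC = -E_R / E_S  if E_S < E_R        (FC = 1 at a tie)

and the FDR-adjusted q-value follows the rank formula q = (p / rank) * N
over N tests (ascending p ranks, ties averaged).  Note this is the
first-step Benjamini-Hochberg quantity *without* the step-up monotonicity
enforcement — q-values here need not be monotone in p; see the methods note.
Genes with q below a cut-off (default 1e-3) are split into sensitivity
(positive fold change) and resistance (negative fold change) sets, which
feed a hypergeometric over-representation analysis against annotated gene
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SensitivityLabels",
    "classify_cell_lines",
    "gene_t_test",
    "fold_change",
    "q_values",
    "gene_statistics",
    "select_genes",
    "overrepresentation",
    "SENSITIVE_MIN_AA",
    "RESISTANT_MAX_AA",
    "Q_VALUE_CUT",
]

logger = logging.getLogger(__name__)

SENSITIVE_MIN_AA = 1.95
RESISTANT_MAX_AA = 1.3
Q_VALUE_CUT = 1.0e-3


@dataclass
class SensitivityLabels:
    """Per-cell-line sensitivity label and the activity area behind it."""

    labels: dict[str, str] = field(default_factory=dict)
    activity_area: dict[str, float] = field(default_factory=dict)

    def group(self, label: str) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == label]

    def __getitem__(self, cell_line: str) -> str:
        return self.labels[cell_line]


def classify_cell_lines(
    activity_areas: Mapping[str, float],
    sensitive_min: float = SENSITIVE_MIN_AA,
    resistant_max: float = RESISTANT_MAX_AA,
) -> SensitivityLabels:
    """Label cell lines by activity area.

    sensitive: AA >= ``sensitive_min``; resistant: AA <= ``resistant_max``;
    intermediate: the open interval between (boundaries inclusive on the
    sensitive/resistant sides).
    """
    if sensitive_min <= resistant_max:
        raise ValueError("sensitive_min must exceed resistant_max")
    out = SensitivityLabels()
    for cell, aa in activity_areas.items():
        if not np.isfinite(aa):
            raise ValueError(f"non-finite activity area for {cell!r}")
        if aa >= sensitive_min:
            lab = "sensitive"
        elif aa <= resistant_max:
            lab = "resistant"
        else:
            lab = "intermediate"
        out.labels[cell] = lab
        out.activity_area[cell] = float(aa)
    return out


def gene_t_test(expr: pd.DataFrame, labels: SensitivityLabels) -> pd.DataFrame:
    """Pooled-variance two-sided Student t-test per gene (rows of ``expr``).

    ``expr`` holds log2 expression, genes x cell lines; columns are matched
    against the labels and intermediate lines are dropped.  Degenerate
    genes with zero pooled variance get t = +/-inf, p = 0 when the group
    means differ and t = 0, p = 1 when they coincide.
    """
    s_cols = [c for c in expr.columns if labels.labels.get(c) == "sensitive"]
    r_cols = [c for c in expr.columns if labels.labels.get(c) == "resistant"]
    for name, cols in (("sensitive", s_cols), ("resistant", r_cols)):
        if len(cols) < 2:
            raise ValueError(f"{name} group has {len(cols)} cell lines; need >= 2")
    xs = expr[s_cols].to_numpy(dtype=float)
    xr = expr[r_cols].to_numpy(dtype=float)
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", category=RuntimeWarning)
        t, p = stats.ttest_ind(xs, xr, axis=1, equal_var=True)
        diff = xs.mean(axis=1) - xr.mean(axis=1)
        bad = ~np.isfinite(t)
        # zero pooled variance: infinite separation unless the means also agree
        t = np.where(bad & (diff == 0), 0.0, t)
        p = np.where(bad & (diff == 0), 1.0, p)
        t = np.where(bad & (diff != 0), np.sign(diff) * np.inf, t)
        p = np.where(bad & (diff != 0), 0.0, p)
    return pd.DataFrame({"t": t, "p": p}, index=expr.index)


def fold_change(mean_sensitive: float, mean_resistant: float) -> float:
    """Ratio-of-means fold change on the log2 scale, signed toward the
    larger group; 1.0 at a tie.  Raises when the applicable denominator is
    not positive (flag such genes upstream rather than reporting a value).
    """
    es, er = float(mean_sensitive), float(mean_resistant)
    if es == er:
        return 1.0
    if es > er:
        if er <= 0:
            raise ZeroDivisionError(f"fold change undefined: E_R = {er} <= 0")
        return es / er
    if es <= 0:
        raise ZeroDivisionError(f"fold change undefined: E_S = {es} <= 0")
    return -er / es


def q_values(p_values: Iterable[float]) -> np.ndarray:
    """Rank-based FDR adjustment q_i = (p_i / rank_i) * N.

    Ranks are ascending ranks of p with ties sharing the mean rank.  The
    adjustment is order-free: permuting the input permutes the output the
    same way.  No step-up monotonicity is applied.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) & (p != 0)) or np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    ranks = stats.rankdata(p, method="average")
    return p / ranks * p.size


def gene_statistics(
    expr: pd.DataFrame, labels: SensitivityLabels
) -> pd.DataFrame:
    """Full per-gene statistics table: t, p, fold_change, q, direction.

    Genes whose fold change is undefined (non-positive mean in the
    applicable denominator) get ``fold_change = NaN`` and ``flagged=True``.
    """
    tt = gene_t_test(expr, labels)
    s_cols = [c for c in expr.columns if labels.labels.get(c) == "sensitive"]
    r_cols = [c for c in expr.columns if labels.labels.get(c) == "resistant"]
    es = expr[s_cols].mean(axis=1)
    er = expr[r_cols].mean(axis=1)
    fc = np.empty(len(expr))
    flagged = np.zeros(len(expr), dtype=bool)
    for k, (a, b) in enumerate(zip(es.to_numpy(), er.to_numpy())):
        try:
            fc[k] = fold_change(a, b)
        except ZeroDivisionError:
            fc[k] = np.nan
            flagged[k] = True
    out = tt.copy()
    out["fold_change"] = fc
    out["q"] = q_values(out["p"])
    out["direction"] = np.where(fc >= 1.0, "sensitivity", "resistance")
    out.loc[flagged, "direction"] = "undefined"
    out["flagged"] = flagged
    return out


def select_genes(
    stats_table: pd.DataFrame, q_cut: float = Q_VALUE_CUT
) -> tuple[list[str], list[str]]:
    """Split genes with q < ``q_cut`` (strict) by fold-change sign.

    Positive fold change -> sensitivity list (overexpressed in sensitive
    lines); negative -> resistance list.
    """
    keep = stats_table["q"] < q_cut
    if "flagged" in stats_table.columns:
        keep &= ~stats_table["flagged"]
    hits = stats_table[keep]
    sens = hits.index[hits["fold_change"] > 0].tolist()
    resist = hits.index[hits["fold_change"] < 0].tolist()
    return sens, resist


def overrepresentation(
    selected: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    max_terms_for_bonferroni: Optional[int] = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` genes per term.

    For a term with K annotated genes in a universe of N, and k of the n
    selected genes annotated, the p-value is the upper hypergeometric tail
    P(X >= k) and the fold enrichment is (k/n) / (K/N).  Bonferroni
    multiplies by the number of tested terms (capped at 1); the Benjamini
    column applies the rank-based q-value formula.  Terms with no universe
    genes are skipped (logged).
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, genes in annotation.items():
        members = set(genes) & universe
        K = len(members)
        if K == 0:
            logger.info("term %r has no genes in the universe; skipped", term)
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        fe = (k / n) / (K / N) if n else 0.0
        rows.append((term, k, K, p, fe))
    if not rows:
        return pd.DataFrame(
            columns=["overlap", "term_size", "p", "fold_enrichment", "bonferroni", "benjamini"]
        )
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p", "fold_enrichment"])
    df = df.set_index("term")
    m = max_terms_for_bonferroni or len(df)
    df["bonferroni"] = np.minimum(1.0, df["p"] * m)
    df["benjamini"] = q_values(df["p"])
    return df.sort_values("p")
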
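"""Gene-set level transcriptome comparison statistics.

Works on tiling-array style signal tables: per-sample signals are scaled to
a common mean of 500, gene sets (e.g. the AbrB regulon, central-metabolism
genes, amino-acid / purine / pyrimidine biosynthesis genes) are compared
between conditions with a one-sided Mann-Whitney U test, and per-gene
differential expression is classified either by the volcano rule
(|log2 FC| >= 1 and P < 0.05) or by a plain 1.5-fold-change cutoff.

Genes annotated to both the central-metabolism set and the AbrB regulon are
excluded from both sets' tests, since their assignment is ambiguous.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, ttest_ind

__all__ = [
    "ExpressionTable",
    "DEResult",
    "normalize_signals",
    "gene_set_shift_test",
    "mann_whitney_one_sided",
    "classify_de",
    "classify_fold_cutoff",
    "set_summary",
    "volcano_table",
    "TARGET_MEAN",
]

TARGET_MEAN = 500.0  # per-sample signal average after normalization
EXACT_LIMIT = 16  # exact Mann-Whitney enumeration up to m + n of this


@dataclass
class ExpressionTable:
    """Gene x sample signal matrix with condition labels and gene sets."""

    signals: pd.DataFrame  # index: gene ids; columns: sample ids
    conditions: dict[str, str]  # sample id -> condition
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.signals.to_numpy() < 0).any():
            raise ValueError("signals must be nonnegative")
        missing = set(self.signals.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.signals.columns if self.conditions[s] == condition]

    def excluded_genes(self, set_a: str = "cmp", set_b: str = "abrb") -> set[str]:
        """Genes in both the central-metabolism and AbrB sets (dropped from
        either set's statistics)."""
        if set_a not in self.gene_sets or set_b not in self.gene_sets:
            return set()
        return self.gene_sets[set_a] & self.gene_sets[set_b]

    def set_members(self, set_id: str, apply_exclusion: bool = True) -> list[str]:
        members = self.gene_sets[set_id] & set(self.signals.index)
        if apply_exclusion and set_id in ("cmp", "abrb"):
            members -= self.excluded_genes()
        return sorted(members)


def normalize_signals(table: ExpressionTable,
                      target: float = TARGET_MEAN) -> ExpressionTable:
    """Scale every sample so its mean signal equals ``target`` exactly."""
    means = table.signals.mean(axis=0)
    if (means <= 0).any():
        bad = means.index[means <= 0].tolist()
        raise ValueError(f"cannot normalize all-zero sample(s): {bad}")
    scaled = table.signals / means * target
    return ExpressionTable(scaled, dict(table.conditions),
                           {k: set(v) for k, v in table.gene_sets.items()})


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group b (count of (a_i, b_j) pairs with b_j > a_i,
    ties counting one half)."""
    ranks = rankdata(np.concatenate([a, b]))
    rb = ranks[len(a):].sum()
    return float(rb - len(b) * (len(b) + 1) / 2.0)


def mann_whitney_one_sided(a, b, alternative: str = "greater") -> float:
    """One-sided Mann-Whitney U p-value for H1: b shifted relative to a.

    ``alternative='greater'`` tests whether b tends to exceed a.  For small
    samples (m + n <= 16) the p-value is the exact inclusive tail
    probability P(U >= u_obs) enumerated over all C(m+n, n) group
    assignments of the pooled values (midranks for ties); larger samples use
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if alternative == "less":
        return mann_whitney_one_sided(b, a, "greater")
    if alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    m, n = len(a), len(b)
    if m + n <= EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)  # midranks; fixed across reassignments
        offset = n * (n + 1) / 2.0
        u_obs = _u_statistic(a, b)
        count = 0
        total = 0
        for comb in itertools.combinations(range(m + n), n):
            u = ranks[list(comb)].sum() - offset
            count += u >= u_obs - 1e-12
            total += 1
        return count / total
    res = mannwhitneyu(b, a, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def gene_set_shift_test(set_values_a, set_values_b,
                        direction: str = "greater") -> float:
    """One-sided shift test between a gene set's signals in two conditions.

    ``direction='greater'`` asks whether condition b's signals are higher;
    ``'less'`` whether they are lower.
    """
    return mann_whitney_one_sided(set_values_a, set_values_b,
                                  alternative=direction)


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fc: float
    p_value: float
    de_class: str  # 'up' | 'down' | 'ns'


def classify_de(log2fc: float, p: float) -> str:
    """Volcano-plot DE rule: up if log2 FC >= 1 and P < 0.05, down if
    log2 FC <= -1 and P < 0.05, else ns.

    The downregulation threshold is -1 (the symmetric counterpart of +1);
    a printed form of this rule stating "<= 1" is treated as a typo.
    """
    if not (math.isfinite(log2fc) and math.isfinite(p)):
        raise ValueError("log2 fold change and p-value must be finite")
    if p < 0.05:
        if log2fc >= 1.0:
            return "up"
        if log2fc <= -1.0:
            return "down"
    return "ns"


def classify_fold_cutoff(fc_linear: float, cutoff: float = 1.5) -> str:
    """Plain fold-change rule: up if FC >= cutoff, down if FC <= 1/cutoff."""
    if fc_linear <= 0 or not math.isfinite(fc_linear):
        raise ValueError("fold change must be positive and finite")
    if fc_linear >= cutoff:
        return "up"
    if fc_linear <= 1.0 / cutoff:
        return "down"
    return "ns"


def volcano_table(
    table: ExpressionTable,
    condition_a: str,
    condition_b: str,
    *,
    pseudo: float = 1.0,
) -> list[DEResult]:
    """Per-gene log2 FC (b over a) and p-value with volcano classification.

    P-values come from a two-sample t-test on log2 signals across
    replicates (a plain substitute for moderated-variance pipelines; no
    empirical-Bayes shrinkage is applied — flagged here so downstream
    consumers know the provenance of the p-values).
    """
    sa = table.samples_of(condition_a)
    sb = table.samples_of(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    la = np.log2(table.signals[sa].to_numpy() + pseudo)
    lb = np.log2(table.signals[sb].to_numpy() + pseudo)
    fc = lb.mean(axis=1) - la.mean(axis=1)
    pvals = ttest_ind(lb, la, axis=1).pvalue
    out = []
    for gene, f, p in zip(table.signals.index, fc, pvals):
        p = float(p) if np.isfinite(p) else 1.0
        out.append(DEResult(str(gene), float(f), p, classify_de(float(f), p)))
    return out


def set_summary(
    table: ExpressionTable,
    set_id: str,
    condition_a: str,
    condition_b: str,
    *,
    direction: str = "greater",
    pseudo: float = 1.0,
) -> dict:
    """Box-plot statistics and up/down fractions for one gene set.

    Log2 mean signals per gene and condition; quartiles use linear
    interpolation.  The Mann-Whitney direction must be stated explicitly:
    'greater' tests whether condition b is higher.  Returns the number of
    dual-membership genes excluded.
    """
    members = table.set_members(set_id)
    if not members:
        raise ValueError(f"gene set {set_id!r} is empty after exclusions")
    sa = table.samples_of(condition_a)
    sb = table.samples_of(condition_b)
    la = np.log2(table.signals.loc[members, sa].mean(axis=1).to_numpy() + pseudo)
    lb = np.log2(table.signals.loc[members, sb].mean(axis=1).to_numpy() + pseudo)

    def box(x: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"min": float(x.min()), "q1": float(q1), "median": float(med),
                "q3": float(q3), "max": float(x.max())}

    p = gene_set_shift_test(la, lb, direction=direction)
    de = {g: r for r in volcano_table(table, condition_a, condition_b,
                                      pseudo=pseudo)
          for g in [r.gene_id] if g in set(members)}
    n_up = sum(r.de_class == "up" for r in de.values())
    n_down = sum(r.de_class == "down" for r in de.values())
    return {
        "set_id": set_id,
        "n_genes": len(members),
        "n_excluded": len(table.excluded_genes())
        if set_id in ("cmp", "abrb") else 0,
        "box_a": box(la),
        "box_b": box(lb),
        "median_shift": float(np.median(lb) - np.median(la)),
        "mann_whitney_p": p,
        "fraction_up": n_up / len(members),
        "fraction_down": n_down / len(members),
    }


def read_expression_tsv(signals_path, sets_path=None,
                        conditions: dict[str, str] | None = None) -> ExpressionTable:
    """Signals TSV: gene_id then one column per sample; gene-set TSV:
    two columns (gene_id, set_id)."""
    df = pd.read_csv(signals_path, sep="\t", index_col=0)
    gene_sets: dict[str, set[str]] = {}
    if sets_path is not None:
        sets_df = pd.read_csv(sets_path, sep="\t")
        for _, row in sets_df.iterrows():
            gene_sets.setdefault(str(row.iloc[1]), set()).add(str(row.iloc[0]))
    if conditions is None:
        conditions = {c: c.rsplit("_", 1)[0] for c in df.columns}
    return ExpressionTable(df, conditions, gene_sets)
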
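"""Downstream analyses on differentially methylated gene sets.

Early/mid/continuous response classification via configurable set algebra,
hypergeometric term enrichment with a dual-correction consensus flag,
relative expression from Ct tables (2^-ddCt), expression outcome testing and
the methylation/expression agreement call.
"""

from __future__ import annotations

import ast
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseClass",
    "EnrichmentResult",
    "AgreementRecord",
    "classify_response",
    "enrich_terms",
    "delta_delta_ct",
    "test_expression",
    "agreement",
    "DEFAULT_RESPONSE_RULE",
]

METH_OUTCOMES = ("De-methylation", "Methylation", "N.S.")
EXPR_OUTCOMES = ("Up-regulation", "Down-regulation", "N.S.")

#: Default set algebra over the three pairwise comparisons. Evaluated in
#: order; later expressions may reference earlier class names.
DEFAULT_RESPONSE_RULE: dict[str, str] = {
    "early": "T30_vs_T0 - T90_vs_T0",
    "mid": "(T90_vs_T0 & T90_vs_T30) - T30_vs_T0",
    "continuous": "T90_vs_T0 - early - mid",
}


@dataclass
class ResponseClass:
    early: frozenset[str]
    mid: frozenset[str]
    continuous: frozenset[str]
    directions: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.early & self.mid or self.early & self.continuous or self.mid & self.continuous:
            raise ValueError("response classes must be pairwise disjoint")


_ALLOWED_OPS = (ast.Sub, ast.BitAnd, ast.BitOr, ast.BitXor)


def _eval_set_expr(expr: str, env: Mapping[str, frozenset[str]]) -> frozenset[str]:
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"malformed set expression {expr!r}: {exc.msg}") from None

    def ev(node: ast.AST) -> frozenset[str]:
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Name):
            if node.id not in env:
                raise ValueError(f"unknown name {node.id!r} in set expression {expr!r}")
            return env[node.id]
        if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_OPS):
            left, right = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.BitAnd):
                return left & right
            if isinstance(node.op, ast.BitOr):
                return left | right
            return left ^ right
        raise ValueError(
            f"set expression {expr!r} may only use names and the operators - & | ^"
        )

    return ev(tree)


def classify_response(
    genes_by_comparison: Mapping[str, Mapping[str, str]],
    rule: Mapping[str, str] | None = None,
) -> ResponseClass:
    """Split genes into early/mid/continuous response classes.

    ``genes_by_comparison`` maps comparison name (e.g. ``T30_vs_T0``) to a
    gene → direction mapping. The rule is a dict of set expressions over the
    comparison names (and previously defined class names), evaluated in
    order. Per-gene directions are taken from the first comparison (in rule
    order of mention: early from the T30 contrast, mid/continuous from the
    T90-vs-baseline contrast when available).
    """
    rule = dict(DEFAULT_RESPONSE_RULE if rule is None else rule)
    env: dict[str, frozenset[str]] = {
        name: frozenset(genes) for name, genes in genes_by_comparison.items()
    }
    classes: dict[str, frozenset[str]] = {}
    for cls_name, expr in rule.items():
        classes[cls_name] = _eval_set_expr(expr, env)
        env[cls_name] = classes[cls_name]
    for required in ("early", "mid", "continuous"):
        classes.setdefault(required, frozenset())

    def lookup_direction(gene: str, preferred: Sequence[str]) -> str:
        for comp in preferred:
            if comp in genes_by_comparison and gene in genes_by_comparison[comp]:
                return genes_by_comparison[comp][gene]
        for comp in genes_by_comparison.values():
            if gene in comp:
                return comp[gene]
        return "unknown"

    ordered = sorted(genes_by_comparison)
    preference = {
        "early": [c for c in ordered if c.startswith("T30")] + ordered,
        "mid": [c for c in ordered if c.endswith("T0") and not c.startswith("T30")] + ordered,
        "continuous": [c for c in ordered if c.endswith("T0") and not c.startswith("T30")] + ordered,
    }
    directions = {
        cls: {g: lookup_direction(g, preference.get(cls, ordered)) for g in genes}
        for cls, genes in classes.items()
    }
    return ResponseClass(
        early=classes["early"],
        mid=classes["mid"],
        continuous=classes["continuous"],
        directions=directions,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # selected genes carrying the term
    K: int  # background genes carrying the term
    n: int  # selected-set size
    N: int  # background size
    p: float  # hypergeometric upper tail P(X >= k)
    q_bh: float
    p_bonferroni: float
    consensus_significant: bool


def enrich_terms(
    selected: set[str],
    background: set[str],
    term_map: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of terms in ``selected``.

    Every term annotating at least one background gene is tested with the
    upper-tail hypergeometric probability P(X >= k). BH and Bonferroni are
    applied across terms; ``consensus_significant`` requires both corrected
    values below ``alpha``. Results are sorted by raw p.
    """
    from .dmp import adjust_fdr

    offenders = set(selected) - set(background)
    if offenders:
        raise ValueError(f"selected genes outside background: {sorted(offenders)}")
    terms: dict[str, set[str]] = {}
    for gene, gene_terms in term_map.items():
        if gene not in background:
            continue
        for t in gene_terms:
            terms.setdefault(t, set()).add(gene)
    if not any(gene in term_map for gene in selected):
        raise ValueError("term map covers no selected gene")
    N, n = len(background), len(selected)
    names = sorted(terms)
    ks = np.array([len(terms[t] & selected) for t in names])
    Ks = np.array([len(terms[t]) for t in names])
    pvals = stats.hypergeom.sf(ks - 1, N, Ks, n)
    pvals = np.clip(pvals, 0.0, 1.0)
    qvals = adjust_fdr(pvals)
    bonf = np.minimum(pvals * len(names), 1.0)
    results = [
        EnrichmentResult(
            term_id=t,
            k=int(k),
            K=int(K),
            n=n,
            N=N,
            p=float(p),
            q_bh=float(q),
            p_bonferroni=float(b),
            consensus_significant=bool(q < alpha and b < alpha),
        )
        for t, k, K, p, q, b in zip(names, ks, Ks, pvals, qvals, bonf)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def delta_delta_ct(
    ct_table: pd.DataFrame,
    calibrator_timepoint: str = "T0",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Expects columns gene, bulk, timepoint, ct_target and two reference-gene
    columns (any columns starting with ``ct_`` other than ``ct_target``).
    dCt = ct_target − mean(reference Cts); ddCt subtracts the gene's mean
    calibrator dCt, so the calibrator group's geometric-mean fold change is 1.
    Rows with missing reference Cts are skipped with a warning.
    """
    ref_cols = [c for c in ct_table.columns if c.startswith("ct_") and c != "ct_target"]
    if len(ref_cols) < 2:
        raise ValueError("need at least two reference-gene Ct columns (ct_*)")
    df = ct_table.copy()
    bad = df[ref_cols].isna().any(axis=1) | df["ct_target"].isna()
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} row(s) with missing Ct values", stacklevel=2)
        df = df[~bad]
    df["delta_ct"] = df["ct_target"] - df[ref_cols].mean(axis=1)
    out = []
    for gene, sub in df.groupby("gene", sort=True):
        cal = sub.loc[sub["timepoint"] == calibrator_timepoint, "delta_ct"]
        if cal.empty:
            raise ValueError(f"gene {gene}: no calibrator ({calibrator_timepoint}) rows")
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - cal.mean()
        sub["rel_expr"] = np.power(2.0, -sub["delta_delta_ct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _pairwise_name(late: str, early: str) -> str:
    return f"{late}_vs_{early}"


def test_expression(
    rel_expr: pd.DataFrame,
    alpha: float = 0.05,
    timepoint_order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Per-comparison expression outcome for one gene.

    One-way ANOVA on log2 relative expression across timepoints; if the
    omnibus p < alpha, Welch pairwise t-tests with Holm correction decide
    each comparison, signed by the difference of group means (late > early →
    Up-regulation). Otherwise every comparison is N.S. Identical groups
    (zero between-group variance) are N.S.
    """
    if timepoint_order is None:
        timepoint_order = sorted(rel_expr["timepoint"].unique())
    groups = {
        tp: np.log2(rel_expr.loc[rel_expr["timepoint"] == tp, "rel_expr"].to_numpy())
        for tp in timepoint_order
    }
    for tp, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"timepoint {tp}: need >= 2 replicates")
    pairs = [
        (late, early)
        for i, early in enumerate(timepoint_order)
        for late in timepoint_order[i + 1 :]
    ]
    outcomes = {_pairwise_name(l, e): "N.S." for l, e in pairs}
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        return outcomes
    with np.errstate(invalid="ignore"):
        anova = stats.f_oneway(*arrays)
    if not np.isfinite(anova.pvalue) or anova.pvalue >= alpha:
        return outcomes
    raw = []
    for late, early in pairs:
        a, b = groups[late], groups[early]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and np.mean(a) == np.mean(b):
            raw.append(1.0)
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        raw.append(float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)
    # Holm step-down
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(running, 1.0)
    for (late, early), p_adj in zip(pairs, adj):
        if p_adj < alpha:
            sign = np.mean(groups[late]) - np.mean(groups[early])
            if sign > 0:
                outcomes[_pairwise_name(late, early)] = "Up-regulation"
            elif sign < 0:
                outcomes[_pairwise_name(late, early)] = "Down-regulation"
    return outcomes


def load_validation_outcomes() -> pd.DataFrame:
    """Packaged RT-qPCR vs methylation outcome table used for validation.

    Columns: gene, comparison, meth_outcome, expr_outcome, agreement (empty
    string when either outcome was not statistically supported).
    """
    from importlib import resources

    with resources.files("methcut.data").joinpath("validation_outcomes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    return df


@dataclass(frozen=True)
class AgreementRecord:
    gene: str
    comparison: str
    meth_outcome: str
    expr_outcome: str
    agreement: str  # "Yes" | "No" | "" (blank when either side is N.S.)


def agreement(
    gene: str,
    comparison: str,
    meth_outcome: str,
    expr_outcome: str,
) -> AgreementRecord:
    """Agreement between methylation and expression outcomes.

    Blank unless both outcomes are statistically supported; ``Yes`` for the
    canonical inverse relationship (De-methylation with Up-regulation, or
    Methylation with Down-regulation), ``No`` otherwise.
    """
    if meth_outcome not in METH_OUTCOMES:
        raise ValueError(f"unknown methylation outcome {meth_outcome!r}")
    if expr_outcome not in EXPR_OUTCOMES:
        raise ValueError(f"unknown expression outcome {expr_outcome!r}")
    if meth_outcome == "N.S." or expr_outcome == "N.S.":
        verdict = ""
    elif (meth_outcome, expr_outcome) in (
        ("De-methylation", "Up-regulation"),
        ("Methylation", "Down-regulation"),
    ):
        verdict = "Yes"
    else:
        verdict = "No"
    return AgreementRecord(gene, comparison, meth_outcome, expr_outcome, verdict)
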
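"""Expression-binned subtype-incidence correlation screen.

For each candidate gene (mouse ids mapped one-to-one to human orthologues),
patients are ranked by that gene's expression and split into k equal cohorts
(k = 10 for all patients, k = 6 for BRCA1-mutant subsets); the TNBC
proportion of each cohort is computed, and a Spearman rank correlation
between cohort index and proportion quantifies whether TNBC incidence rises
or falls with expression. Genes significant with the same direction in two
independent databases form the cross-database consensus. Generic contingency
proportions with Wilson intervals round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError, DataError


def map_orthologues(
    mouse_genes, mapping: list[tuple[str, str]] | pd.DataFrame
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Map mouse gene ids to human orthologues.

    Only one-to-one pairs are kept: mouse genes mapping to several human
    genes, and human genes receiving several mouse genes, are dropped and
    logged. Returns ``(mapping, dropped)`` where dropped is a list of
    (gene, reason) pairs.
    """
    if isinstance(mapping, pd.DataFrame):
        pairs = list(mapping.itertuples(index=False, name=None))
    else:
        pairs = list(mapping)
    if not pairs:
        raise DataError("empty orthologue mapping table")
    mouse_to = {}
    human_from = {}
    many_mouse, many_human = set(), set()
    for m, h in pairs:
        if m in mouse_to and mouse_to[m] != h:
            many_mouse.add(m)
        mouse_to.setdefault(m, h)
        if h in human_from and human_from[h] != m:
            many_human.add(h)
        human_from.setdefault(h, m)
    out, dropped = {}, []
    for g in mouse_genes:
        if g not in mouse_to:
            dropped.append((g, "unmapped"))
        elif g in many_mouse:
            dropped.append((g, "one_to_many"))
        elif mouse_to[g] in many_human:
            dropped.append((g, "many_to_one"))
        else:
            out[g] = mouse_to[g]
    return out, dropped


def rank_and_bin(values: pd.Series, k: int) -> pd.Series:
    """Assign each patient to one of ``k`` contiguous expression cohorts.

    Patients are sorted ascending by expression with ties broken by stable
    patient-id order; cohort sizes differ by at most one, with the first
    ``n mod k`` cohorts (lowest expression) receiving the extra patient.
    Returns a Series patient_id -> cohort index 1..k.
    """
    n = len(values)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if n < k:
        raise ConfigError(f"cannot split {n} patients into {k} cohorts")
    order = values.reset_index()
    order.columns = ["patient_id", "value"]
    order = order.sort_values(["value", "patient_id"], kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    return pd.Series(labels, index=order["patient_id"], name="cohort")


def cohort_incidence(assignment: pd.Series, labels: pd.Series) -> np.ndarray:
    """Per-cohort positive-label proportion, in cohort-index order."""
    labels = labels.reindex(assignment.index)
    if labels.isna().any():
        raise DataError("every patient must carry a label")
    k = int(assignment.max())
    out = np.empty(k)
    for j in range(1, k + 1):
        members = labels[assignment == j]
        if members.empty:
            raise DataError(f"cohort {j} is empty")
        out[j - 1] = float(members.astype(bool).mean())
    return out


def _spearman_r(x_ranks: np.ndarray, y: np.ndarray) -> float:
    y_ranks = stats.rankdata(y, method="average")
    if np.all(y_ranks == y_ranks[0]):
        return 0.0
    return float(np.corrcoef(x_ranks, y_ranks)[0, 1])


def correlate_expression_incidence(
    proportions, alpha: float = 0.05, method: str = "spearman",
    exact_max_k: int = 8,
) -> tuple[float, float, str]:
    """Correlation between cohort index and cohort incidence.

    Spearman by default (tied proportions receive average ranks); the
    two-sided p-value is an exact permutation enumeration over all k!
    orderings when k <= ``exact_max_k``, and the t-approximation otherwise.
    Pearson is available with ``method='pearson'``. Constant proportions
    yield (0.0, 1.0, 'none'). Direction is the sign of R when p < alpha.
    """
    pi = np.asarray(proportions, dtype=float)
    k = pi.size
    if k < 4:
        raise ConfigError("need at least 4 cohorts")
    if np.all(pi == pi[0]):
        return 0.0, 1.0, "none"
    idx = np.arange(1, k + 1, dtype=float)
    if method == "pearson":
        r, p = stats.pearsonr(idx, pi)
        r, p = float(r), float(p)
    elif method == "spearman":
        x_ranks = idx  # already ranks
        r = _spearman_r(x_ranks, pi)
        if k <= exact_max_k:
            y_ranks = stats.rankdata(pi, method="average")
            obs = abs(r)
            count = 0
            # permuting the proportions is equivalent to permuting their ranks
            perms = np.array(list(permutations(y_ranks)))
            sx = x_ranks - x_ranks.mean()
            sy = perms - perms.mean(axis=1, keepdims=True)
            num = sy @ sx
            den = np.sqrt((sx @ sx) * (sy * sy).sum(axis=1))
            rs = num / den
            count = int(np.sum(np.abs(rs) >= obs - 1e-12))
            p = count / factorial(k)
        else:
            p = float(stats.spearmanr(x_ranks, pi).pvalue)
    else:
        raise ConfigError(f"unknown method {method!r}")
    if p < alpha:
        direction = "positive" if r > 0 else "negative"
    else:
        direction = "none"
    return float(r), float(p), direction


def screen_genes(
    table: pd.DataFrame,
    genes: list[str],
    k: int = 10,
    label_column: str = "tnbc",
    brca1_only: bool = False,
    alpha: float = 0.05,
    method: str = "spearman",
) -> pd.DataFrame:
    """Run the binned-cohort incidence screen for every gene.

    ``table`` is a patient-per-row frame with clinical columns (``tnbc``,
    ``brca1_mutant``, ...) and one expression column per gene (the layout
    :func:`sbscreen.simulate.simulate_patient_cohort` produces).
    """
    if brca1_only:
        if "brca1_mutant" not in table.columns:
            raise DataError("no brca1_mutant column for --brca1-only")
        table = table[table["brca1_mutant"].astype(bool)]
    if label_column not in table.columns:
        raise DataError(f"missing label column {label_column!r}")
    rows = []
    for gene in genes:
        if gene not in table.columns:
            raise DataError(f"no expression column for gene {gene!r}")
        assign = rank_and_bin(table[gene], k)
        pi = cohort_incidence(assign, table[label_column])
        r, p, direction = correlate_expression_incidence(pi, alpha, method)
        rows.append({"gene": gene, "k": k, "R": r, "p": p,
                     "direction": direction,
                     **{f"pi_{j + 1}": pi[j] for j in range(k)}})
    return pd.DataFrame(rows)


@dataclass
class ConsensusResult:
    gene: str
    direction: str
    p_db1: float
    p_db2: float


def cross_db_consensus(
    results_db1: pd.DataFrame, results_db2: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes significant with the same direction in both databases."""
    need = {"gene", "p", "direction"}
    for df in (results_db1, results_db2):
        if not need <= set(df.columns):
            raise DataError(f"result tables need columns {sorted(need)}")
    merged = results_db1.merge(results_db2, on="gene", suffixes=("_db1", "_db2"))
    mask = (
        (merged["p_db1"] < alpha)
        & (merged["p_db2"] < alpha)
        & (merged["direction_db1"] == merged["direction_db2"])
        & (merged["direction_db1"] != "none")
    )
    out = merged.loc[mask, ["gene", "direction_db1", "p_db1", "p_db2",
                            "R_db1", "R_db2"]].copy()
    return out.rename(columns={"direction_db1": "direction"}).reset_index(drop=True)


def incidence_summary(n_pos: int, n_total: int) -> dict[str, float]:
    """Proportion as a percentage with its 95% Wilson interval."""
    if n_total < 1 or not 0 <= n_pos <= n_total:
        raise ConfigError("need 0 <= n_pos <= n_total and n_total >= 1")
    lo, hi = proportion_confint(n_pos, n_total, alpha=0.05, method="wilson")
    return {
        "percent": 100.0 * n_pos / n_total,
        "ci_low": 100.0 * float(lo),
        "ci_high": 100.0 * float(hi),
        "n_pos": n_pos,
        "n_total": n_total,
    }
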
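"""Common insertion site (CIS) discovery over gene-centric windows.

Each gene is scored over its extended region (gene body plus 3 kb upstream,
strand-aware) against a uniform-insertion Poisson null: with N total
insertions across an effective genome of length L, the expected count in a
window of w bp is lambda = N*w/L and the CIS p-value is the Poisson upper
tail P(X >= k). Genes with p below the significance cut-off are retained;
Benjamini-Hochberg q-values are additionally reported. The recurrence filter
then keeps genes hit in at least a minimum fraction of tumours in *both*
transposon strains — the guard against donor-chromosome local-hopping
artefacts, which inflate insertion density (and hence raw p-values) on the
donor chromosome of one strain but rarely recur across both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .genes import GeneCatalog, UPSTREAM_WINDOW
from .simulate import DEFAULT_DONOR_CHROMS


def poisson_cis_pvalue(k: int, w: float, n_total: int, genome_length: float) -> float:
    """Poisson upper-tail CIS p-value: P(X >= k) with X ~ Poisson(N*w/L).

    Returns 1.0 when k == 0. Raises ``ConfigError`` on invalid geometry
    (w > L) or negative inputs.
    """
    if w < 0 or n_total < 0 or k < 0 or genome_length <= 0:
        raise ConfigError("k, w, N must be >= 0 and L > 0")
    if w > genome_length:
        raise ConfigError("window longer than effective genome")
    if k == 0:
        return 1.0
    lam = n_total * w / genome_length
    return float(stats.poisson.sf(k - 1, lam))


@dataclass
class CandidateSet:
    """Genes surviving the CIS significance and recurrence filters for one
    Cre group, with per-gene frequency over all tumours of the group."""

    group: str
    genes: list[str]
    frequency: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def gene_cis_scan(
    insertions: pd.DataFrame,
    catalog: GeneCatalog,
    alpha: float = 0.05,
    upstream: int = UPSTREAM_WINDOW,
    exclude_donor: bool = False,
    donor_chroms: dict[str, str] | None = None,
    tumour_totals: dict[str, int] | None = None,
    genome_length: float | None = None,
) -> pd.DataFrame:
    """Score every catalog gene over its extended region.

    Returns one row per gene with p < ``alpha``: columns gene_id, chrom,
    region_start, region_end, k (insertion count), t (distinct tumours),
    one ``f_<strain>`` tumour-fraction column per strain present, frequency
    (t over all tumours), p and BH q (adjusted over *all* genes scanned).
    A site overlapping two genes' extended regions counts for both.

    ``exclude_donor`` drops, per strain, insertions on that strain's donor
    chromosome before scanning (off by default: all insertion sites are
    assessed, the recurrence filter handles hopping bias). ``tumour_totals``
    supplies per-strain tumour counts when tumours without insertions exist.
    """
    if genome_length is None:
        genome_length = catalog.genome_length
    if not genome_length:
        raise ConfigError("effective genome length unknown; supply genome_length")
    cols = {"chrom", "pos", "tumour_id", "strain"}
    if insertions.empty:
        ins = pd.DataFrame(columns=sorted(cols))
    else:
        missing = cols - set(insertions.columns)
        if missing:
            raise DataError(f"insertion table lacks columns {sorted(missing)}")
        ins = insertions
    if exclude_donor and not ins.empty:
        donors = donor_chroms or DEFAULT_DONOR_CHROMS
        drop = pd.Series(False, index=ins.index)
        for strain, donor in donors.items():
            drop |= (ins["strain"].astype(str) == strain) & (ins["chrom"] == donor)
        ins = ins[~drop]

    strains = sorted(ins["strain"].astype(str).unique()) if not ins.empty else []
    if tumour_totals is None:
        tumour_totals = {
            s: int(ins.loc[ins["strain"].astype(str) == s, "tumour_id"].nunique())
            for s in strains
        }
    else:
        strains = sorted(set(strains) | set(tumour_totals))
    n_all_tumours = sum(tumour_totals.values())
    n_total = int(len(ins))

    rows = []
    for gene in catalog:
        lo, hi = gene.extended_region(upstream)
        if ins.empty:
            sub = ins
        else:
            sub = ins[(ins["chrom"] == gene.chrom)
                      & (ins["pos"] >= lo) & (ins["pos"] <= hi)]
        k = int(len(sub))
        w = hi - lo + 1
        p = poisson_cis_pvalue(k, w, n_total, genome_length)
        row = {"gene_id": gene.gene_id, "chrom": gene.chrom,
               "region_start": lo, "region_end": hi, "k": k,
               "t": int(sub["tumour_id"].nunique()) if k else 0, "p": p}
        for s in strains:
            tot = tumour_totals.get(s, 0)
            hit = int(sub.loc[sub["strain"].astype(str) == s, "tumour_id"].nunique()) if k else 0
            row[f"f_{s}"] = hit / tot if tot else np.nan
        row["frequency"] = row["t"] / n_all_tumours if n_all_tumours else np.nan
        rows.append(row)
    scan = pd.DataFrame(rows)
    if scan.empty:
        return scan
    scan["q"] = stats.false_discovery_control(scan["p"].to_numpy(), method="bh")
    out = scan[scan["p"] < alpha].reset_index(drop=True)
    return out


def recurrence_filter(
    gene_cis: pd.DataFrame, theta: float = 0.05, group: str = ""
) -> CandidateSet:
    """Keep genes hit in at least ``theta`` of tumours in every strain
    (boundary fractions equal to theta are kept)."""
    if gene_cis.empty:
        return CandidateSet(group=group, genes=[])
    fcols = [c for c in gene_cis.columns if c.startswith("f_")]
    if not fcols:
        raise DataError("gene_cis table lacks per-strain fraction columns")
    if gene_cis[fcols].isna().any().any():
        raise DataError(
            "a strain has zero tumours in this group: per-strain fraction undefined"
        )
    mask = (gene_cis[fcols] >= theta).all(axis=1)
    kept = gene_cis[mask].sort_values("frequency", ascending=False)
    return CandidateSet(
        group=group,
        genes=list(kept["gene_id"]),
        frequency=dict(zip(kept["gene_id"], kept["frequency"])),
    )


def combine_groups(set_a, set_b) -> dict[str, list[str]]:
    """Union / intersection / exclusives of two candidate gene sets.

    Accepts CandidateSets or plain iterables of gene ids. The exclusives
    partition the union: |union| = |A| + |B| - |A n B|.
    """
    a = set(set_a.genes if isinstance(set_a, CandidateSet) else set_a)
    b = set(set_b.genes if isinstance(set_b, CandidateSet) else set_b)
    return {
        "union": sorted(a | b),
        "intersection": sorted(a & b),
        "only_a": sorted(a - b),
        "only_b": sorted(b - a),
    }


def oncoplot_matrix(
    genes, insertions: pd.DataFrame, catalog: GeneCatalog,
    upstream: int = UPSTREAM_WINDOW,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x tumour binary presence matrix plus per-gene frequency.

    Rows (genes) are ordered by descending frequency over all tumours in the
    insertion table; row sums equal per-gene tumour counts.
    """
    gene_ids = list(genes.genes if isinstance(genes, CandidateSet) else genes)
    tumours = sorted(insertions["tumour_id"].unique()) if not insertions.empty else []
    mat = pd.DataFrame(0, index=gene_ids, columns=tumours, dtype=int)
    for gid in gene_ids:
        gene = catalog[gid]
        lo, hi = gene.extended_region(upstream)
        if insertions.empty:
            continue
        sub = insertions[(insertions["chrom"] == gene.chrom)
                         & (insertions["pos"] >= lo) & (insertions["pos"] <= hi)]
        mat.loc[gid, sub["tumour_id"].unique()] = 1
    freq = mat.sum(axis=1) / len(tumours) if tumours else mat.sum(axis=1) * np.nan
    order = freq.sort_values(ascending=False, kind="stable").index
    return mat.loc[order], freq.loc[order].rename("frequency")
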
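"""Oncogene / tumour-suppressor classification from insertion patterns.

A transposon carrying a strong internal promoter activates a gene when it
inserts in the gene's transcriptional direction (sense) at a recurrent
hotspot, producing an overexpressed (often truncated) transcript; dispersed,
orientation-unbiased insertions instead disrupt the gene through the
transposon's polyadenylation signal. Two statistics capture this:

* the **sense fraction** of a gene's insertions with an exact two-sided
  binomial test against 0.5;
* a **cluster score**: the maximum fraction of insertions contained in any
  sliding window spanning a fixed fraction (default 0.2) of the gene's
  annotation region.

A gene is called ONCOGENE when sense bias is significant and insertions are
clustered; TSG when there is no sense bias (or an antisense bias); AMBIGUOUS
on conflict or when fewer than five insertions are available.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigError
from .genes import GeneCatalog, UPSTREAM_WINDOW


@dataclass
class OrientationProfile:
    gene_id: str
    n_sense: int
    n_antisense: int
    f_sense: float
    p_binom: float


@dataclass
class DriverCall:
    gene_id: str
    n_total: int
    f_sense: float
    p_binom: float
    cluster_score: float
    driver_class: str  # ONCOGENE | TSG | AMBIGUOUS
    evidence: str


def sense_fraction(n_sense: int, n_total: int) -> tuple[float, float]:
    """Sense fraction and exact two-sided binomial p-value against 0.5.

    The two-sided p sums the probabilities of all outcomes no more likely
    than the observed one (scipy's exact method).
    """
    if n_total < 1 or not 0 <= n_sense <= n_total:
        raise ConfigError("need 0 <= n_sense <= n_total and n_total >= 1")
    f = n_sense / n_total
    p = stats.binomtest(n_sense, n_total, 0.5).pvalue
    return f, float(p)


def cluster_score(
    positions: Sequence[int],
    region: tuple[int, int],
    window_frac: float = 0.2,
) -> float:
    """Maximum fraction of insertions inside any window of width
    ``window_frac`` x region length.

    The maximising window can always be anchored at an insertion position, so
    the exhaustive scan runs over windows ``[p, p + W)`` for each insertion
    position p (W = window_frac x region length).
    """
    if not len(positions):
        raise ConfigError("cluster_score requires at least one position")
    lo, hi = region
    if hi < lo:
        raise ConfigError("invalid region")
    if not 0 < window_frac <= 1:
        raise ConfigError("window_frac must be in (0,1]")
    pos = sorted(positions)
    if pos[0] < lo or pos[-1] > hi:
        raise ConfigError("positions outside region")
    width = window_frac * (hi - lo + 1)
    best = 0
    for p in pos:
        j = bisect.bisect_left(pos, p + width)
        i = bisect.bisect_left(pos, p)
        best = max(best, j - i)
    return best / len(pos)


def classify_driver(
    profile: OrientationProfile,
    cluster: float,
    alpha: float = 0.05,
    cluster_threshold: float = 0.5,
    min_insertions: int = 5,
) -> DriverCall:
    """Apply the documented classification rule.

    ONCOGENE iff f_sense > 0.5 AND p_binom < alpha AND cluster >= threshold;
    TSG iff p_binom >= alpha OR f_sense < 0.5 (given enough insertions);
    AMBIGUOUS below ``min_insertions`` or when the rules conflict (e.g.
    significant sense bias without clustering).
    """
    n = profile.n_sense + profile.n_antisense
    f, p = profile.f_sense, profile.p_binom
    if n < min_insertions:
        cls, why = "AMBIGUOUS", f"only {n} insertions (< {min_insertions})"
    elif f > 0.5 and p < alpha and cluster >= cluster_threshold:
        cls = "ONCOGENE"
        why = (f"sense bias {f:.3f} (p={p:.2g}) with clustered insertions "
               f"(score {cluster:.3f})")
    elif p >= alpha or f < 0.5:
        cls = "TSG"
        why = (f"no sense bias (f={f:.3f}, p={p:.2g})" if p >= alpha
               else f"antisense bias (f={f:.3f}, p={p:.2g})")
    else:
        cls = "AMBIGUOUS"
        why = (f"sense bias (f={f:.3f}, p={p:.2g}) but dispersed insertions "
               f"(score {cluster:.3f})")
    return DriverCall(profile.gene_id, n, f, p, cluster, cls, why)


def classify_genes(
    genes,
    insertions: pd.DataFrame,
    catalog: GeneCatalog,
    upstream: int = UPSTREAM_WINDOW,
    alpha: float = 0.05,
    window_frac: float = 0.2,
    cluster_threshold: float = 0.5,
    min_insertions: int = 5,
) -> pd.DataFrame:
    """Classify each gene from the insertion table.

    The denominator for the sense fraction and the cluster score is all
    insertions in the gene's extended annotation region. Returns one row per
    gene with the profile statistics and the driver class.
    """
    from .cis import CandidateSet  # local import to avoid cycle

    gene_ids = list(genes.genes if isinstance(genes, CandidateSet) else genes)
    rows = []
    for gid in gene_ids:
        gene = catalog[gid]
        lo, hi = gene.extended_region(upstream)
        sub = insertions[(insertions["chrom"] == gene.chrom)
                         & (insertions["pos"] >= lo) & (insertions["pos"] <= hi)]
        n = len(sub)
        if n == 0:
            rows.append({"gene_id": gid, "n_total": 0, "n_sense": 0,
                         "f_sense": float("nan"), "p_binom": float("nan"),
                         "cluster_score": float("nan"),
                         "driver_class": "AMBIGUOUS",
                         "evidence": "no insertions"})
            continue
        n_sense = int((sub["transposon_orient"] == gene.strand).sum())
        f, p = sense_fraction(n_sense, n)
        cs = cluster_score(sub["pos"].tolist(), (lo, hi), window_frac)
        call = classify_driver(
            OrientationProfile(gid, n_sense, n - n_sense, f, p),
            cs, alpha, cluster_threshold, min_insertions,
        )
        rows.append({"gene_id": gid, "n_total": n, "n_sense": n_sense,
                     "f_sense": f, "p_binom": p, "cluster_score": cs,
                     "driver_class": call.driver_class,
                     "evidence": call.evidence})
    return pd.DataFrame(rows)
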
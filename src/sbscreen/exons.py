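"""Exon-level expression normalisation and activation-breakpoint detection.

A transposon inserted inside a gene and pointing in its transcriptional
direction drives a truncated transcript from its internal promoter: exons
downstream of the insertion are overexpressed in trapped tumours while
upstream exons stay at baseline. After normalising each exon's read count by
library size and exon length (e_i = c_i / (T * l_i), an RPKM-like quantity up
to a constant), the breakpoint is the exon index maximising the separation of
mean log-ratios (trapped over control) between the downstream and upstream
segments; a call is reported only when the implied fold change passes a gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


@dataclass
class BreakpointCall:
    gene_id: str
    breakpoint: int | None  # 1-based exon index from which expression steps up
    fold: float  # downstream/upstream ratio of trapped vs control, at the argmax
    score: float  # mean log-ratio separation at the argmax


def normalize_exon_counts(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    exon_lengths: pd.Series | None = None,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Normalise per-exon counts: e_i = scale * c_i / (T * l_i).

    ``counts`` has exons as rows and samples as columns; an ``exon_length``
    column is used (and dropped) when ``exon_lengths`` is not given.
    ``lib_sizes`` defaults to per-sample column totals. Set ``scale=1e9`` for
    RPKM-like readability; invariances, not absolute scale, are the contract.
    """
    counts = counts.copy()
    if exon_lengths is None:
        if "exon_length" not in counts.columns:
            raise DataError("exon lengths required (column 'exon_length' or argument)")
        exon_lengths = counts.pop("exon_length")
    lengths = pd.Series(exon_lengths, index=counts.index).astype(float)
    if (lengths <= 0).any():
        raise DataError("exon lengths must be positive")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = pd.Series(lib_sizes, index=counts.columns).astype(float)
    if (lib <= 0).any():
        raise DataError("zero library size")
    return scale * counts.div(lib, axis=1).div(lengths, axis=0)


def detect_breakpoint(
    trapped: pd.DataFrame,
    control: pd.DataFrame,
    eps: float = 1e-8,
    min_fold: float = 2.0,
    gene_id: str = "",
) -> BreakpointCall:
    """Two-segment mean-shift breakpoint on normalised exon profiles.

    For exon i, r_i = log((mean trapped e_i + eps)/(mean control e_i + eps));
    the breakpoint b* maximises mean(r_{i>=b}) - mean(r_{i<b}) over b = 2..n
    (an exhaustive scan). The call is reported only when the implied fold
    exp(separation) >= ``min_fold``; otherwise ``breakpoint`` is None and the
    best fold is still returned.

    ``trapped`` and ``control`` are samples-as-columns normalised profiles
    with a common exon index; mismatched exon structures raise ``DataError``.
    """
    if trapped.shape[0] != control.shape[0] or not trapped.index.equals(control.index):
        raise DataError("trapped and control profiles have mismatched exon structure")
    if trapped.shape[1] < 1 or control.shape[1] < 1:
        raise DataError("at least one profile per group required")
    n = trapped.shape[0]
    if n < 2:
        raise DataError("need at least two exons")
    if eps <= 0:
        raise ConfigError("eps must be positive")
    mt = trapped.mean(axis=1).to_numpy(dtype=float)
    mc = control.mean(axis=1).to_numpy(dtype=float)
    r = np.log((mt + eps) / (mc + eps))
    cum = np.concatenate([[0.0], np.cumsum(r)])
    best_b, best_sep = None, -np.inf
    for b in range(2, n + 1):  # 1-based: upstream = exons 1..b-1
        up = cum[b - 1] / (b - 1)
        down = (cum[n] - cum[b - 1]) / (n - b + 1)
        sep = down - up
        if sep > best_sep:
            best_b, best_sep = b, sep
    fold = float(np.exp(best_sep))
    exon_index = trapped.index.to_list()
    b_label = int(exon_index[best_b - 1])
    if fold >= min_fold:
        return BreakpointCall(gene_id, b_label, fold, float(best_sep))
    return BreakpointCall(gene_id, None, fold, float(best_sep))
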
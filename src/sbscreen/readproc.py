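"""Splinkerette junction-read processing.

Raw junction reads are trimmed (transposon IRDR end located as a prefix, the
splinkerette linker located downstream, both within a mismatch tolerance),
located against a reference by exact 25-nt seed plus bounded-mismatch
verification, and deduplicated into non-redundant insertion sites.

Filtering rules:

* reads without a valid transposon end are rejected (``no_transposon``);
* reads without a downstream linker are rejected (``no_adapter``);
* genomic segments shorter than 20 nt after trimming are rejected
  (``too_short``);
* seeds hitting two or more reference loci are rejected (``ambiguous_map``);
* best hits with four or more mismatches are rejected
  (``too_many_mismatches``).

Coordinates are 1-based; an insertion site is reported at the T of its TA
junction. Real pre-mapped data can bypass trimming/location entirely through
the TSV interface in :mod:`sbscreen.io`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .adapters import IRDR_L, IRDR_R, LINKER, ORIENTATION, revcomp
from .errors import DataError

REJECT_REASONS = ("no_transposon", "no_adapter", "too_short",
                  "ambiguous_map", "too_many_mismatches")


@dataclass
class AdapterConfig:
    """Trimming/location parameters.

    ``mismatch_tolerance`` is the allowed mismatch fraction for adapter and
    IRDR matching (a common trimmer default of 10%); ``max_mismatches`` is
    the bounded full-segment mismatch count for location (3, matching the
    screen's alignment criterion); ``min_genomic_length`` enforces the
    minimum post-trim segment length of 20 nt.
    """

    irdr_l: str = IRDR_L
    irdr_r: str = IRDR_R
    linker: str = LINKER
    mismatch_tolerance: float = 0.10
    min_genomic_length: int = 20
    seed_length: int = 25
    max_mismatches: int = 3
    min_linker_overlap: int = 8


@dataclass
class TrimmedRead:
    read_id: str
    genomic_seq: str = ""
    irdr_end: str | None = None  # 'L' or 'R'
    reject_reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


@dataclass(frozen=True)
class InsertionSite:
    chrom: str
    pos: int  # 1-based T of the TA junction
    transposon_orient: str
    tumour_id: str
    strain: str
    cre: str
    support: int = 1


def _mismatches(a: str, b: str, limit: int | None = None) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if limit is not None and m > limit:
                return m
    return m


def trim_read(read_id: str, seq: str, config: AdapterConfig | None = None) -> TrimmedRead:
    """Locate the transposon end as a read prefix and the linker downstream;
    return the intervening genomic segment or a rejection with reason."""
    cfg = config or AdapterConfig()
    seq = seq.upper()
    best_end, best_len = None, 0
    for end, irdr in (("L", cfg.irdr_l), ("R", cfg.irdr_r)):
        if len(seq) < len(irdr):
            continue
        tol = int(len(irdr) * cfg.mismatch_tolerance)
        if _mismatches(seq[: len(irdr)], irdr, tol) <= tol:
            if best_end is not None:  # both ends match: ambiguous chemistry
                return TrimmedRead(read_id, reject_reason="no_transposon")
            best_end, best_len = end, len(irdr)
    if best_end is None:
        return TrimmedRead(read_id, reject_reason="no_transposon")
    rest = seq[best_len:]

    linker_at = None
    for off in range(len(rest)):
        overlap = min(len(cfg.linker), len(rest) - off)
        if overlap < cfg.min_linker_overlap:
            break
        tol = int(overlap * cfg.mismatch_tolerance)
        if _mismatches(rest[off : off + overlap], cfg.linker[:overlap], tol) <= tol:
            linker_at = off
            break
    if linker_at is None:
        return TrimmedRead(read_id, reject_reason="no_adapter")
    genomic = rest[:linker_at]
    if len(genomic) < cfg.min_genomic_length:
        return TrimmedRead(read_id, reject_reason="too_short")
    return TrimmedRead(read_id, genomic_seq=genomic, irdr_end=best_end)


class Reference:
    """Small in-memory reference supporting exact seed lookup on both strands."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise DataError("empty reference")
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    def seed_hits(self, seed: str, max_hits: int = 2) -> list[tuple[str, int, str]]:
        """All occurrences of ``seed`` as (chrom, 0-based index, strand),
        where strand '-' means the seed matches the reverse complement
        (i.e. the read aligns to the minus strand). Stops after ``max_hits``."""
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(seed)
        for chrom, seq in self.sequences.items():
            for query, strand in ((seed, "+"), (rc, "-")):
                start = 0
                while len(hits) < max_hits:
                    idx = seq.find(query, start)
                    if idx < 0:
                        break
                    hits.append((chrom, idx, strand))
                    start = idx + 1
                if len(hits) >= max_hits:
                    return hits
        return hits


def locate_insertion(
    trimmed: TrimmedRead,
    reference: Reference,
    config: AdapterConfig | None = None,
    tumour_id: str = "NA",
    strain: str = "NA",
    cre: str = "NA",
) -> tuple[InsertionSite | None, str | None]:
    """Locate one trimmed read; returns ``(site, None)`` on success or
    ``(None, reject_reason)``.

    The first ``seed_length`` nt must match the reference exactly and
    uniquely; the full genomic segment may then differ by at most
    ``max_mismatches`` substitutions. The site is reported at the TA adjacent
    to the IRDR junction (the first two read bases) and the transposon
    orientation follows the fixed (IRDR end, strand) convention table.
    """
    cfg = config or AdapterConfig()
    if not trimmed.accepted:
        return None, trimmed.reject_reason
    g = trimmed.genomic_seq
    if len(g) < cfg.seed_length:
        return None, "too_short"
    seed = g[: cfg.seed_length]
    hits = reference.seed_hits(seed, max_hits=2)
    if len(hits) >= 2:
        return None, "ambiguous_map"
    if not hits:
        return None, "too_many_mismatches"
    chrom, idx, strand = hits[0]
    seq = reference.sequences[chrom]
    if strand == "+":
        ref_seg = seq[idx : idx + len(g)]
        pos = idx + 1  # read base 0 is the T of the TA
    else:
        # read base 0 pairs with the genome base at idx + seed_length - 1 (0-based),
        # which is the A of the TA; the T sits one base to its left.
        a0 = idx + cfg.seed_length - 1
        lo = max(0, a0 - len(g) + 1)
        ref_seg = revcomp(seq[lo : a0 + 1])
        pos = a0  # 1-based position of the T (= 0-based a0 - 1, +1)
    if pos < 1:
        return None, "too_many_mismatches"
    if _mismatches(g, ref_seg, cfg.max_mismatches) > cfg.max_mismatches or len(
        ref_seg
    ) < len(g):
        return None, "too_many_mismatches"
    orient = ORIENTATION[(trimmed.irdr_end, strand)]
    return InsertionSite(chrom, pos, orient, tumour_id, strain, cre), None


def parse_read_id(read_id: str) -> tuple[str, str, str]:
    """Recover (tumour_id, strain, cre) metadata from a simulated read id of
    the form ``tumour|strain|cre|serial``; unknown layouts map to NA."""
    parts = read_id.split("|")
    if len(parts) >= 3:
        return parts[0], parts[1], parts[2]
    return "NA", "NA", "NA"


def process_reads(
    reads: Iterable[tuple[str, str]],
    reference: Reference,
    config: AdapterConfig | None = None,
) -> tuple[pd.DataFrame, Counter]:
    """Trim, locate and dedupe a stream of ``(read_id, sequence)`` pairs.

    Returns the deduplicated insertion table and a Counter of per-stage
    outcomes (``accepted`` plus one entry per rejection reason); counts sum
    to the number of input reads.
    """
    cfg = config or AdapterConfig()
    raw_sites: list[InsertionSite] = []
    tally: Counter = Counter()
    for read_id, seq in reads:
        tr = trim_read(read_id, seq, cfg)
        if not tr.accepted:
            tally[tr.reject_reason] += 1
            continue
        tumour, strain, cre = parse_read_id(read_id)
        site, reason = locate_insertion(tr, reference, cfg, tumour, strain, cre)
        if site is None:
            tally[reason] += 1
        else:
            tally["accepted"] += 1
            raw_sites.append(site)
    return dedupe_sites(raw_sites), tally


def sites_to_frame(sites: Iterable[InsertionSite]) -> pd.DataFrame:
    cols = ["chrom", "pos", "transposon_orient", "tumour_id", "strain", "cre",
            "support"]
    rows = [(s.chrom, s.pos, s.transposon_orient, s.tumour_id, s.strain,
             s.cre, s.support) for s in sites]
    return pd.DataFrame(rows, columns=cols)


def dedupe_sites(sites, merge_window: int = 0) -> pd.DataFrame:
    """Collapse raw sites identical in (chrom, pos, orientation, tumour) into
    one record with ``support`` = read count. Sites from different tumours are
    never merged. ``merge_window`` > 0 additionally merges sites within that
    many bp of a more-supported site in the same tumour/orientation."""
    df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    if df.empty:
        return df.copy()
    keys = ["chrom", "pos", "transposon_orient", "tumour_id", "strain", "cre"]
    out = df.groupby(keys, as_index=False, sort=True)["support"].sum()
    if merge_window > 0:
        merged = []
        group_keys = ["chrom", "transposon_orient", "tumour_id", "strain", "cre"]
        for _, grp in out.groupby(group_keys, sort=True):
            grp = grp.sort_values("support", ascending=False)
            kept: list[pd.Series] = []
            for _, row in grp.iterrows():
                for k in kept:
                    if abs(k["pos"] - row["pos"]) <= merge_window:
                        k["support"] += row["support"]
                        break
                else:
                    kept.append(row.copy())
            merged.extend(kept)
        out = pd.DataFrame(merged).reset_index(drop=True)
    return out.sort_values(["strain", "cre", "tumour_id", "chrom", "pos"]).reset_index(
        drop=True
    )
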
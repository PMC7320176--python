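"""Gene models and catalogs.

A :class:`GeneModel` is a gene span with strand and exon structure; exons are
numbered 1..n in *transcription* order (so exon 1 of a minus-strand gene lies
at the highest genomic coordinates). Coordinates are 1-based inclusive
throughout, GTF-style.

The annotation window used for common-insertion-site calling is the gene body
extended 3 kb upstream of the transcription start site, strand-aware:
``(start-3000, end)`` for a plus-strand gene and ``(start, end+3000)`` for a
minus-strand gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .errors import ConfigError, DataError

UPSTREAM_WINDOW = 3000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive
    end: int
    exons: tuple[tuple[int, int], ...]  # transcription order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"{self.gene_id}: strand must be '+' or '-'")
        if not 1 <= self.start <= self.end:
            raise DataError(f"{self.gene_id}: invalid span [{self.start},{self.end}]")
        if not self.exons:
            raise DataError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise DataError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
        # strictly ordered & non-overlapping along the transcription direction
        genomic = self.exons if self.strand == "+" else self.exons[::-1]
        prev_end = None
        for s, e in genomic:
            if prev_end is not None and s <= prev_end:
                raise DataError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def extended_region(self, upstream: int = UPSTREAM_WINDOW) -> tuple[int, int]:
        """Gene body plus ``upstream`` bp before the TSS (clamped to >= 1)."""
        if self.strand == "+":
            return max(1, self.start - upstream), self.end
        return self.start, self.end + upstream

    def hotspot_span(self, exon_from: int, exon_to: int) -> tuple[int, int]:
        """Genomic span covering exons ``exon_from..exon_to`` (1-based,
        transcription order), introns included."""
        if not 1 <= exon_from <= exon_to <= self.n_exons:
            raise ConfigError(
                f"{self.gene_id}: hotspot exons ({exon_from},{exon_to}) out of range"
            )
        chosen = self.exons[exon_from - 1 : exon_to]
        lo = min(s for s, _ in chosen)
        hi = max(e for _, e in chosen)
        return lo, hi

    def exon_of_position(self, pos: int) -> int | None:
        """1-based exon number containing ``pos``, or None if intronic."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None


@dataclass
class GeneCatalog:
    """An ordered collection of non-overlapping gene models plus the sizes of
    the chromosomes they live on."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise DataError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def validate(self) -> None:
        """Check chromosome consistency and pairwise non-overlap per chrom."""
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self:
            if self.chrom_lengths and g.chrom not in self.chrom_lengths:
                raise DataError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if self.chrom_lengths and g.end > self.chrom_lengths[g.chrom]:
                raise DataError(f"{g.gene_id}: extends past end of {g.chrom}")
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                if b.start <= a.end:
                    raise DataError(f"genes {a.gene_id} and {b.gene_id} overlap")

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if self.chrom_lengths:
                sizes = ",".join(f"{c}:{n}" for c, n in self.chrom_lengths.items())
                fh.write(f"#chrom_lengths={sizes}\n")
            fh.write("gene_id\tchrom\tstrand\tstart\tend\texon_starts\texon_ends\n")
            for g in self:
                starts = ",".join(str(s) for s, _ in g.exons)
                ends = ",".join(str(e) for _, e in g.exons)
                fh.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}"
                    f"\t{starts}\t{ends}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        path = Path(path)
        cat = cls()
        with path.open() as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#chrom_lengths="):
                    for item in line.split("=", 1)[1].split(","):
                        c, n = item.split(":")
                        cat.chrom_lengths[c] = int(n)
                    continue
                if line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True  # column header
                    continue
                f = line.split("\t")
                if len(f) != 7:
                    raise DataError(f"{path}: malformed catalog line: {line!r}")
                exons = tuple(
                    (int(s), int(e))
                    for s, e in zip(f[5].split(","), f[6].split(","))
                )
                cat.add(GeneModel(f[0], f[1], f[2], int(f[3]), int(f[4]), exons))
        cat.validate()
        return cat


def read_orthologue_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (mouse_id, human_id) TSV; header optional."""
    pairs: list[tuple[str, str]] = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise DataError(f"{path}: malformed orthologue line: {line!r}")
            if i == 0 and f[0].lower() in {"mouse", "mouse_id", "mouse_gene"}:
                continue
            pairs.append((f[0], f[1]))
    return pairs
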
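"""Synthetic data generation for every pipeline stage.

The generators emulate the statistical structure the downstream analysis
assumes, so every stage is testable without any external downloads:

* gene catalogs packed onto synthetic chromosomes (:func:`make_gene_catalog`);
* tumour insertion profiles with Poisson background, a donor-chromosome
  local-hopping excess, and planted drivers — oncogene-like (tight positional
  hotspot, sense-orientation bias) or tumour-suppressor-like (dispersed over
  the gene, orientation-unbiased) (:func:`simulate_screen`);
* splinkerette junction reads: transposon IRDR end + genomic flank starting
  at the TA junction + linker, with substitution errors and contaminant reads
  (:func:`emit_reads`);
* per-exon count profiles with a step increase downstream of a trapped exon
  (:func:`simulate_exon_counts`);
* patient cohorts in which triple-negative (TNBC) probability depends, or
  not, on a gene's expression percentile through a logit-linear link
  (:func:`simulate_patient_cohort`).

All generators require an explicit integer seed and are deterministic under
it. Screen simulation returns a ground-truth sidecar table alongside the
insertion table, so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adapters import IRDR_L, IRDR_R, LINKER, ORIENTATION_INVERSE, revcomp
from .errors import ConfigError, DataError
from .genes import GeneCatalog, GeneModel

STRAINS = ("12740", "12775")
CRE_LINES = ("WAP", "MMTV")

#: Mouse-like chromosome sizes (bp) used for coordinate-only screens. Nineteen
#: autosomes plus X, summing to ~2.53 Gb, so that genome-wide insertion rates
#: and per-gene window expectations are on the scale of a real mouse screen.
MOUSE_LIKE_CHROMS: dict[str, int] = {
    **{f"chr{i}": n for i, n in enumerate(
        [195_000_000, 182_000_000, 160_000_000, 157_000_000, 152_000_000,
         150_000_000, 145_000_000, 129_000_000, 124_000_000, 131_000_000,
         122_000_000, 120_000_000, 120_000_000, 125_000_000, 104_000_000,
         98_000_000, 95_000_000, 91_000_000, 61_000_000], start=1)},
    "chrX": 171_000_000,
}

#: Donor concatemer chromosomes of the two transposon lines.
DEFAULT_DONOR_CHROMS: dict[str, str] = {"12740": "chr9", "12775": "chr12"}


def _require_seed(seed) -> int:
    if seed is None:
        raise ConfigError("an explicit integer seed is required (reproducibility)")
    return int(seed)


# --------------------------------------------------------------------------
# genomes and catalogs
# --------------------------------------------------------------------------

def random_genome(
    chrom_lengths: Mapping[str, int], seed: int, gc: float = 0.42
) -> dict[str, str]:
    """Random nucleotide sequence per chromosome at the given GC content."""
    seed = _require_seed(seed)
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for chrom, n in chrom_lengths.items():
        if n <= 0:
            raise ConfigError(f"chromosome {chrom} has non-positive length")
        idx = rng.choice(4, size=int(n), p=p)
        genome[chrom] = np.frombuffer(b"ACGT", dtype="S1")[idx].tobytes().decode()
    return genome


@dataclass
class CatalogConfig:
    chrom_lengths: Mapping[str, int]
    n_genes: int
    gene_length: int = 10_000
    n_exons: int = 10
    exonic_fraction: float = 0.5
    min_gap: int = 4_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.gene_length <= 0 or self.n_exons < 1:
            raise ConfigError("n_genes >= 0, gene_length > 0, n_exons >= 1 required")
        if not 0 < self.exonic_fraction <= 1:
            raise ConfigError("exonic_fraction must be in (0,1]")
        for c, n in self.chrom_lengths.items():
            if n <= 0:
                raise ConfigError(f"chromosome {c} has non-positive length")


def _split_lengths(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        return np.array([total])
    if total < parts:
        raise ConfigError("cannot split length into that many positive parts")
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False)) + 1
    return np.diff(np.concatenate([[0], cuts, [total]]))


def make_gene_catalog(config: CatalogConfig) -> GeneCatalog:
    """Pack non-overlapping gene models with valid exon structure onto the
    configured chromosomes. Deterministic under the seed."""
    seed = _require_seed(config.seed)
    rng = np.random.default_rng(seed)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)

    # spread genes over chromosomes proportionally to length
    n_per = np.floor(lengths / lengths.sum() * config.n_genes).astype(int)
    for i in np.argsort(-lengths)[: config.n_genes - n_per.sum()]:
        n_per[i] += 1

    cat = GeneCatalog(chrom_lengths=dict(config.chrom_lengths))
    gid = 0
    for ci, chrom in enumerate(chroms):
        count = int(n_per[ci])
        if count == 0:
            continue
        L = int(lengths[ci])
        need = count * (config.gene_length + config.min_gap)
        if need > L:
            raise ConfigError(
                f"cannot pack {count} genes of {config.gene_length} bp "
                f"(+{config.min_gap} bp gaps) onto {chrom} ({L} bp)"
            )
        free = L - need
        gaps = rng.multinomial(free, np.ones(count + 1) / (count + 1))
        pos = 1
        for k in range(count):
            pos += int(gaps[k]) + config.min_gap
            start, end = pos, pos + config.gene_length - 1
            pos = end + 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            cat.add(_make_gene(f"gene{gid:03d}", chrom, strand, start, end,
                               config.n_exons, config.exonic_fraction, rng))
    cat.validate()
    return cat


def _make_gene(gene_id, chrom, strand, start, end, n_exons, exonic_fraction, rng):
    span = end - start + 1
    exonic = max(n_exons, int(round(span * exonic_fraction)))
    intronic = span - exonic
    if n_exons == 1 or intronic < n_exons - 1:
        exon_sizes = _split_lengths(span, n_exons, rng)
        intron_sizes = np.zeros(0, dtype=int)
        if n_exons > 1:  # degenerate: no room for introns -> abutting illegal
            raise ConfigError(f"{gene_id}: gene too short for {n_exons} exons")
    else:
        exon_sizes = _split_lengths(exonic, n_exons, rng)
        intron_sizes = _split_lengths(intronic, n_exons - 1, rng)
    exons_genomic = []
    pos = start
    for i in range(n_exons):
        exons_genomic.append((pos, pos + int(exon_sizes[i]) - 1))
        pos += int(exon_sizes[i])
        if i < n_exons - 1:
            pos += int(intron_sizes[i])
    exons = tuple(exons_genomic if strand == "+" else exons_genomic[::-1])
    return GeneModel(gene_id, chrom, strand, start, end, exons)


# --------------------------------------------------------------------------
# screen simulation
# --------------------------------------------------------------------------

@dataclass
class DriverSpec:
    """A planted driver gene.

    ONCOGENE drivers require a positional hotspot (an inclusive exon range in
    transcription order) and a sense probability > 0.5; TSG drivers use the
    whole gene span and sense probability exactly 0.5.
    """

    gene_id: str
    driver_class: str  # ONCOGENE | TSG
    penetrance: Mapping[str, float] | float = 0.2
    hotspot: tuple[int, int] | None = None
    sense_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.driver_class not in ("ONCOGENE", "TSG"):
            raise ConfigError(f"{self.gene_id}: class must be ONCOGENE or TSG")
        if self.driver_class == "ONCOGENE":
            if self.hotspot is None or not self.sense_prob > 0.5:
                raise ConfigError(
                    f"{self.gene_id}: ONCOGENE requires a hotspot and sense_prob > 0.5"
                )
        else:
            if self.hotspot is not None or self.sense_prob != 0.5:
                raise ConfigError(
                    f"{self.gene_id}: TSG uses the whole span and sense_prob = 0.5"
                )
        if not 0 <= self.sense_prob <= 1:
            raise ConfigError(f"{self.gene_id}: sense_prob must be in [0,1]")

    def penetrance_for(self, strain: str) -> float:
        p = self.penetrance[strain] if isinstance(self.penetrance, Mapping) else self.penetrance
        if not 0 <= p <= 1:
            raise ConfigError(f"{self.gene_id}: penetrance must be in [0,1]")
        return float(p)


@dataclass
class ScreenConfig:
    """Study design of a simulated screen.

    ``n_tumours`` maps (strain, cre) -> tumour count, e.g.
    ``{("12740","WAP"): 50, ("12775","WAP"): 50}``. ``background_rate`` is the
    expected number of background insertions per tumour; the donor chromosome
    of each strain receives ``hopping_factor``-times higher insertion density
    (renormalised), modelling local hopping of the transposon around its
    concatemer.
    """

    n_tumours: Mapping[tuple[str, str], int]
    background_rate: float = 50.0
    donor_chrom: Mapping[str, str] | str | None = None
    hopping_factor: float = 3.0
    drivers: Sequence[DriverSpec] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        for key, n in self.n_tumours.items():
            if n < 0:
                raise ConfigError(f"negative tumour count for {key}")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if self.hopping_factor < 1:
            raise ConfigError("hopping_factor must be >= 1")

    def donor_for(self, strain: str) -> str | None:
        if self.donor_chrom is None:
            return None
        if isinstance(self.donor_chrom, str):
            return self.donor_chrom
        return self.donor_chrom.get(strain)


INSERTION_COLUMNS = ["chrom", "pos", "transposon_orient", "tumour_id",
                     "strain", "cre", "support"]


def _ta_positions(seq: str) -> np.ndarray:
    """1-based positions of the T of every TA dinucleotide in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = (arr[:-1] == ord("T")) & (arr[1:] == ord("A"))
    return np.nonzero(mask)[0] + 1


def simulate_screen(
    catalog: GeneCatalog,
    config: ScreenConfig,
    genome: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one screen; returns ``(insertions, truth)``.

    ``insertions`` has columns chrom, pos, transposon_orient, tumour_id,
    strain, cre, support (deduplicated); ``truth`` records each planted driver
    insertion (tumour_id, gene_id, driver_class, chrom, pos,
    transposon_orient, sense).

    When ``genome`` is given, every position falls on a TA dinucleotide (the
    transposon's integration site preference); coordinate-only screens place
    insertions at arbitrary integer positions, which keeps genome-scale
    simulations fast.
    """
    seed = _require_seed(config.seed)
    rng = np.random.default_rng(seed)
    for d in config.drivers:
        if d.gene_id not in catalog:
            raise ConfigError(f"driver gene {d.gene_id} not in catalog")
    chroms = list(catalog.chrom_lengths)
    if not chroms:
        raise ConfigError("catalog carries no chromosome lengths")
    lengths = np.array([catalog.chrom_lengths[c] for c in chroms], dtype=float)

    ta_index: dict[str, np.ndarray] = {}
    if genome is not None:
        for c in chroms:
            if c not in genome:
                raise DataError(f"genome lacks chromosome {c}")
            ta_index[c] = _ta_positions(genome[c])
            if ta_index[c].size == 0:
                raise DataError(f"chromosome {c} contains no TA site")

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for (strain, cre), n_tum in sorted(config.n_tumours.items()):
        if strain not in STRAINS or cre not in CRE_LINES:
            raise ConfigError(f"unknown strain/cre group ({strain},{cre})")
        donor = config.donor_for(strain)
        weights = lengths.copy()
        if donor is not None:
            if donor not in catalog.chrom_lengths:
                raise ConfigError(f"donor chromosome {donor} not in catalog")
            weights[chroms.index(donor)] *= config.hopping_factor
        weights /= weights.sum()
        for t in range(n_tum):
            tumour_id = f"{strain}-{cre}-T{t + 1:04d}"
            n_bg = rng.poisson(config.background_rate)
            if n_bg:
                ci = rng.choice(len(chroms), size=n_bg, p=weights)
                orients = np.where(rng.random(n_bg) < 0.5, "+", "-")
                for j in range(n_bg):
                    chrom = chroms[ci[j]]
                    if genome is None:
                        pos = int(rng.integers(1, catalog.chrom_lengths[chrom]))
                    else:
                        pos = int(ta_index[chrom][rng.integers(ta_index[chrom].size)])
                    rows.append((chrom, pos, orients[j], tumour_id, strain, cre, 1))
            for d in config.drivers:
                if rng.random() >= d.penetrance_for(strain):
                    continue
                gene = catalog[d.gene_id]
                lo, hi = (gene.hotspot_span(*d.hotspot) if d.hotspot
                          else (gene.start, gene.end))
                if genome is None:
                    pos = int(rng.integers(lo, hi + 1))
                else:
                    tas = ta_index[gene.chrom]
                    sel = tas[(tas >= lo) & (tas <= hi)]
                    if sel.size == 0:
                        raise DataError(
                            f"{d.gene_id}: no TA site inside planted region"
                        )
                    pos = int(sel[rng.integers(sel.size)])
                sense = rng.random() < d.sense_prob
                orient = gene.strand if sense else ("-" if gene.strand == "+" else "+")
                rows.append((gene.chrom, pos, orient, tumour_id, strain, cre, 1))
                truth_rows.append((tumour_id, d.gene_id, d.driver_class,
                                   gene.chrom, pos, orient, sense))

    insertions = pd.DataFrame(rows, columns=INSERTION_COLUMNS)
    if not insertions.empty:
        insertions = (
            insertions.groupby(INSERTION_COLUMNS[:-1], as_index=False, sort=True)
            ["support"].sum()
        )
        insertions = insertions.sort_values(
            ["strain", "cre", "tumour_id", "chrom", "pos"]
        ).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=["tumour_id", "gene_id", "driver_class", "chrom", "pos",
                 "transposon_orient", "sense"],
    )
    return insertions, truth


# --------------------------------------------------------------------------
# junction reads
# --------------------------------------------------------------------------

@dataclass
class ReadConfig:
    irdr_l: str = IRDR_L
    irdr_r: str = IRDR_R
    linker: str = LINKER
    read_length: int = 150
    flank_length: int = 70
    reads_per_site: int = 3
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1 or not 0 <= self.contaminant_fraction <= 1:
            raise ConfigError("error_rate in [0,1), contaminant_fraction in [0,1]")
        if self.flank_length < 20:
            raise ConfigError("flank_length must be >= 20 (post-trim length rule)")
        if self.read_length < len(self.irdr_l) + self.flank_length:
            raise ConfigError("read_length too short for IRDR + flank")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(choices.size)]
    return arr.tobytes().decode()


def emit_reads(
    insertions: pd.DataFrame,
    genome: Mapping[str, str],
    config: ReadConfig,
) -> list[tuple[str, str]]:
    """Generate junction reads ``(read_id, sequence)`` for every insertion.

    Each read is IRDR end + genomic flank beginning at the TA junction +
    linker, truncated to ``read_length``. The IRDR end and mapped strand are
    drawn uniformly from the two pairings consistent with the insertion's
    transposon orientation. Read ids embed tumour metadata as
    ``tumour|strain|cre|serial`` so the locator can restore them.

    Raises ``DataError`` if any insertion is not at a TA in the reference
    (model violation).
    """
    seed = _require_seed(config.seed)
    rng = np.random.default_rng(seed)
    ends = {"L": config.irdr_l, "R": config.irdr_r}
    reads: list[tuple[str, str]] = []
    serial = 0
    for row in insertions.itertuples(index=False):
        seq = genome.get(row.chrom)
        if seq is None:
            raise DataError(f"genome lacks chromosome {row.chrom}")
        pos = int(row.pos)  # 1-based T of the TA
        if seq[pos - 1 : pos + 1] != "TA":
            raise DataError(
                f"insertion {row.chrom}:{pos} is not at a TA dinucleotide"
            )
        pairs = ORIENTATION_INVERSE[row.transposon_orient]
        for _ in range(config.reads_per_site * int(row.support)):
            serial += 1
            irdr_end, strand = pairs[rng.integers(2)]
            if strand == "+":
                flank = seq[pos - 1 : pos - 1 + config.flank_length]
            else:
                lo = max(0, pos + 1 - config.flank_length)
                flank = revcomp(seq[lo : pos + 1])
            read = (ends[irdr_end] + flank + config.linker)[: config.read_length]
            read = _add_errors(read, config.error_rate, rng)
            rid = f"{row.tumour_id}|{row.strain}|{row.cre}|{serial}"
            reads.append((rid, read))
    if config.contaminant_fraction > 0 and reads:
        n_contam = int(round(
            len(reads) * config.contaminant_fraction / (1 - config.contaminant_fraction)
        ))
        for i in range(n_contam):
            junk = _BASES[rng.integers(4, size=config.read_length)].tobytes().decode()
            reads.append((f"contam|NA|NA|{i + 1}", junk))
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    return reads


# --------------------------------------------------------------------------
# exon counts
# --------------------------------------------------------------------------

def simulate_exon_counts(
    exon_lengths: Sequence[int],
    breakpoint_exon: int,
    fold: float,
    depth: float,
    n_trapped: int,
    n_control: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-exon read counts with a step increase downstream of an insertion.

    Counts are Poisson(depth x exon_length x mu) with mu = 1 for control
    samples and for trapped samples upstream of the breakpoint, and
    mu = ``fold`` for exons >= ``breakpoint_exon`` in trapped samples.
    ``depth`` is in expected reads per exonic bp at mu = 1.

    Returns ``(counts, groups)``: counts indexed by exon number 1..n with an
    ``exon_length`` column followed by one column per sample; groups maps
    sample name -> 'trapped' | 'control'.
    """
    seed = _require_seed(seed)
    lengths = np.asarray(exon_lengths, dtype=float)
    n = lengths.size
    if n == 0 or np.any(lengths <= 0):
        raise ConfigError("exon_lengths must be positive")
    if not 1 <= breakpoint_exon <= n:
        raise ConfigError("breakpoint_exon out of range")
    if fold < 1:
        raise ConfigError("fold must be >= 1")
    if n_trapped < 1 or n_control < 1:
        raise ConfigError("at least one sample per group required")
    rng = np.random.default_rng(seed)
    mu_control = depth * lengths
    mu_trapped = mu_control.copy()
    mu_trapped[breakpoint_exon - 1 :] *= fold
    data = {"exon_length": lengths.astype(int)}
    groups = {}
    for i in range(n_trapped):
        name = f"trapped_{i + 1}"
        data[name] = rng.poisson(mu_trapped)
        groups[name] = "trapped"
    for i in range(n_control):
        name = f"control_{i + 1}"
        data[name] = rng.poisson(mu_control)
        groups[name] = "control"
    counts = pd.DataFrame(data, index=pd.RangeIndex(1, n + 1, name="exon"))
    return counts, pd.Series(groups, name="group")


# --------------------------------------------------------------------------
# patient cohorts
# --------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_patient_cohort(
    n: int,
    gene_effects: Mapping[str, float],
    n_null_genes: int = 0,
    base_tnbc_rate: float = 0.15,
    brca1_mutant_rate: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a breast-cancer patient cohort table.

    ``gene_effects`` maps gene -> slope of the logit-linear link
    ``logit P(TNBC) = logit(base_tnbc_rate) + slope * (percentile - 0.5)``
    where percentile is the patient's expression percentile for that gene
    (0..1). Effect genes contribute additively on the logit scale; null genes
    (``n_null_genes`` extra genes named null0001..) are independent of labels.

    TNBC status implies ER, PR and HER2 all negative; non-TNBC patients
    receive a uniformly random receptor combination with at least one
    positive. Basal-type status is correlated with TNBC; the BRCA1-mutant
    flag is independent.
    """
    seed = _require_seed(seed)
    if not 0 <= base_tnbc_rate <= 1:
        raise ConfigError("base_tnbc_rate must be in [0,1]")
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(gene_effects) + [f"null{i + 1:04d}" for i in range(n_null_genes)]
    expr = pd.DataFrame(
        rng.normal(size=(n, len(genes))),
        columns=genes,
        index=[f"P{i + 1:05d}" for i in range(n)],
    )
    logit_p = np.full(n, _logit(base_tnbc_rate) if 0 < base_tnbc_rate < 1 else
                      (-np.inf if base_tnbc_rate == 0 else np.inf))
    for gene, slope in gene_effects.items():
        pct = expr[gene].rank(method="average").to_numpy() - 1
        pct = pct / max(n - 1, 1)
        logit_p = logit_p + slope * (pct - 0.5)
    with np.errstate(over="ignore"):
        p_tnbc = 1.0 / (1.0 + np.exp(-logit_p))
    tnbc = rng.random(n) < p_tnbc
    # receptor status: TNBC == triple negative by construction
    er = np.empty(n, dtype=object)
    pr = np.empty(n, dtype=object)
    her2 = np.empty(n, dtype=object)
    combos = [(e, p, h) for e in ("pos", "neg") for p in ("pos", "neg")
              for h in ("pos", "neg") if (e, p, h) != ("neg", "neg", "neg")]
    pick = rng.integers(len(combos), size=n)
    for i in range(n):
        if tnbc[i]:
            er[i] = pr[i] = her2[i] = "neg"
        else:
            er[i], pr[i], her2[i] = combos[pick[i]]
    basal = np.where(tnbc, rng.random(n) < 0.8, rng.random(n) < 0.15)
    brca1 = rng.random(n) < brca1_mutant_rate
    clinical = pd.DataFrame(
        {"er": er, "pr": pr, "her2": her2, "tnbc": tnbc,
         "basal": basal, "brca1_mutant": brca1},
        index=expr.index,
    )
    return pd.concat([clinical, expr], axis=1).rename_axis("patient_id")
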
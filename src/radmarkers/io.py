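"""Readers and writers for the pipeline's external formats.

The pipeline exchanges four plain-text formats: FASTA contig sets (one per
parental genotype), a restricted VCF-like tab-separated variant table carrying
the caller metrics the hard filters consume, a tab-separated marker report,
and a YAML configuration file.  All external coordinates are 1-based
inclusive (marker-community convention); any 0-based arithmetic happens
internally and is converted at this boundary.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("radmarkers")

_VALID_BASES = frozenset("ACGTN")
_VALID_ALLELE = frozenset("ACGT")


def configure_logging(verbosity: int = 0) -> None:
    """Route pipeline logging to stderr; verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


class FormatError(ValueError):
    """An input file violates the documented dialect."""


class ConfigError(ValueError):
    """A configuration value violates its constraints."""


@dataclass(frozen=True)
class Contig:
    """A named parental sequence; the substrate every marker is located on."""

    id: str
    sequence: str
    genotype: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path, genotype: str = "") -> list[Contig]:
    """Parse a FASTA file into Contigs (uppercased, DNA-only, order preserved)."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has a zero-length sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(id=rec.id, sequence=seq, genotype=genotype))
    return contigs


def write_fasta(contigs, path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class VariantRecord:
    """One caller-style site with the metrics the hard filters evaluate.

    ``ad_ref``/``ad_alt`` are read depths supporting the reference and
    alternate allele; ``MQ0`` counts mapping-quality-zero reads.
    """

    contig_id: str
    pos: int                     # 1-based position on the contig
    ref: str
    alt: str
    DP: int
    MQ: float
    MQ0: int
    QUAL: float
    ad_ref: int
    ad_alt: int

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"{self.contig_id}:{self.pos}: pos must be >= 1")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _VALID_ALLELE:
                raise FormatError(
                    f"{self.contig_id}:{self.pos}: bad {name} allele {allele!r}"
                )
        if self.ref == self.alt:
            raise FormatError(f"{self.contig_id}:{self.pos}: ref == alt")
        if len(self.ref) > 1 and len(self.alt) > 1 and len(self.ref) == len(self.alt):
            raise FormatError(
                f"{self.contig_id}:{self.pos}: multi-base substitutions unsupported"
            )
        if self.ad_ref < 0 or self.ad_alt < 0:
            raise FormatError(f"{self.contig_id}:{self.pos}: negative allele depth")
        if self.DP < self.ad_ref + self.ad_alt:
            raise FormatError(
                f"{self.contig_id}:{self.pos}: DP={self.DP} < "
                f"AD_ref+AD_alt={self.ad_ref + self.ad_alt}"
            )

    @property
    def vtype(self) -> str:
        """SNP, INS or DEL, inferred from allele lengths."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive span occupied by the reference allele."""
        return self.pos, self.pos + len(self.ref) - 1


VARIANT_COLUMNS = [
    "contig", "pos", "ref", "alt", "DP", "MQ", "MQ0", "QUAL", "AD_ref", "AD_alt",
]


def read_variant_table(path) -> list[VariantRecord]:
    """Parse the tab-separated variant dialect (header line required)."""
    records: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != VARIANT_COLUMNS:
            expected = "\t".join(VARIANT_COLUMNS)
            raise FormatError(
                f"{path}: expected header {expected!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(VARIANT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(VARIANT_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                rec = VariantRecord(
                    contig_id=parts[0],
                    pos=int(parts[1]),
                    ref=parts[2].upper(),
                    alt=parts[3].upper(),
                    DP=int(parts[4]),
                    MQ=float(parts[5]),
                    MQ0=int(parts[6]),
                    QUAL=float(parts[7]),
                    ad_ref=int(parts[8]),
                    ad_alt=int(parts[9]),
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_variant_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.contig_id}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.DP}\t{r.MQ:g}\t"
                f"{r.MQ0}\t{r.QUAL:g}\t{r.ad_ref}\t{r.ad_alt}\n"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_SSR_MINIMA = {2: 7, 3: 5, 4: 4, 5: 3, 6: 3, 7: 3, 8: 3}


@dataclass
class PrimerConstraints:
    """Hard bounds and optima for the deterministic primer picker."""

    len_min: int = 18
    len_opt: int = 20
    len_max: int = 24
    tm_opt: float = 57.0
    gc_min: float = 40.0
    gc_opt: float = 50.0
    gc_max: float = 60.0
    product_min: int = 100
    product_max: int = 500       # singleton regions
    product_opt: int = 300
    clustered_product_max: int = 800   # strict: product < this for clusters


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the published defaults."""

    ssr_minima: dict = field(default_factory=lambda: dict(DEFAULT_SSR_MINIMA))
    compound_gap: int = 500          # max interrupting bases inside a compound SSR
    flank_min: int = 20              # minimum usable flank on each side (bp)
    flank_max: int = 200             # flank length cap used for anchoring (bp)
    anchor_evalue: float = 1e-5      # cross-genotype flank anchoring cutoff
    redundancy_matched_min: int = 50   # matched bases vs the known-marker db
    redundancy_evalue: float = 10.0    # permissive search cutoff for the db scan
    cluster_dist: int = 500          # markers closer than this share a region
    geometry_window: int = 50        # allowed inter-flank gap disagreement (bp)
    maf_hom: float = 0.10
    maf_het: float = 0.25
    snp_min_depth: int = 8
    primer: PrimerConstraints = field(default_factory=PrimerConstraints)
    seed: int = 0

    def validate(self) -> None:
        if not self.ssr_minima:
            raise ConfigError("ssr_minima is empty")
        for k, v in self.ssr_minima.items():
            if not (2 <= int(k) <= 8) or int(v) < 1:
                raise ConfigError(f"bad SSR minimum {k!r}: {v!r}")
        positives = {
            "compound_gap": self.compound_gap,
            "flank_min": self.flank_min,
            "flank_max": self.flank_max,
            "anchor_evalue": self.anchor_evalue,
            "redundancy_matched_min": self.redundancy_matched_min,
            "cluster_dist": self.cluster_dist,
            "maf_hom": self.maf_hom,
            "maf_het": self.maf_het,
            "snp_min_depth": self.snp_min_depth,
        }
        for name, val in positives.items():
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val!r}")
        if self.maf_hom >= self.maf_het:
            raise ConfigError(
                f"maf_hom ({self.maf_hom}) must be below maf_het ({self.maf_het})"
            )
        if self.flank_min > self.flank_max:
            raise ConfigError("flank_min > flank_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        primer = PrimerConstraints(**data.pop("primer", {}))
        minima = data.pop("ssr_minima", None)
        cfg = cls(primer=primer, **data)
        if minima is not None:
            cfg.ssr_minima = {int(k): int(v) for k, v in minima.items()}
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# marker report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "marker_id", "genotype", "kind", "contig", "start", "end",
    "status", "partner", "insilico_polymorphic", "redundant", "primer_status",
]


def write_marker_report(markers, stats: dict, path) -> None:
    """Write the deterministic TSV report: a summary block then a marker table.

    ``markers`` is a sequence of dicts keyed by REPORT_COLUMNS; rows are sorted
    by (genotype, contig, start, marker_id) so identical inputs always produce
    byte-identical files.
    """
    rows = sorted(
        markers,
        key=lambda m: (
            str(m.get("genotype", "")),
            str(m.get("contig", "")),
            int(m.get("start", 0)),
            str(m.get("marker_id", "")),
        ),
    )
    with open(path, "w") as fh:
        for key in sorted(stats):
            fh.write(f"# {key}\t{stats[key]}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for m in rows:
            fh.write("\t".join(str(m.get(c, "")) for c in REPORT_COLUMNS) + "\n")
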
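"""Species-specific SNP-corrected reference genomes.

Bisulfite treatment converts unmethylated C to T, so a genuine C>T SNP in a
focal species (or G>A on the reverse strand) is indistinguishable from a
methylation signal when its reads are mapped against the base reference.
The fix is to substitute exactly those two substitution classes into the
reference before mapping/counting, one corrected genome per species.  All
other SNP classes are left untouched: they do not confound bisulfite
conversion and substituting them would change non-cytosine context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

__all__ = [
    "SnpRecord",
    "SubstitutionReport",
    "read_snps_vcf",
    "build_snp_corrected_reference",
    "write_fasta",
    "read_fasta",
]


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic single-base substitution. ``position`` is 1-based (VCF)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    species: str


@dataclass
class SubstitutionReport:
    """Counts of applied and skipped records per substitution class."""

    species: str
    applied_c_to_t: int = 0
    applied_g_to_a: int = 0
    skipped_non_bisulfite: int = 0
    skipped_malformed: int = 0
    per_class: dict = field(default_factory=dict)

    @property
    def applied(self) -> int:
        return self.applied_c_to_t + self.applied_g_to_a

    @property
    def skipped(self) -> int:
        return self.skipped_non_bisulfite + self.skipped_malformed

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [
            ("applied_C>T", self.applied_c_to_t),
            ("applied_G>A", self.applied_g_to_a),
            ("skipped_non_bisulfite", self.skipped_non_bisulfite),
            ("skipped_malformed", self.skipped_malformed),
        ]
        rows += sorted((f"class_{k}", v) for k, v in self.per_class.items())
        return rows


def read_snps_vcf(
    path: str | Path,
    species: str | None = None,
    info_key: str = "SPECIES",
) -> list[SnpRecord]:
    """Read SNPs from a VCF, selecting records for one species.

    Species membership is taken from a comma-separated INFO tag
    (``info_key``, default ``SPECIES``); if the tag is absent and the VCF
    has a sample column named after the species, a non-reference genotype in
    that column selects the record instead.  ``species=None`` returns every
    record once per species label found.
    """
    import pysam

    records: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multiallelic or missing alt: skipped upstream of substitution
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            labels: list[str] = []
            if info_key in rec.info:
                raw = rec.info[info_key]
                if isinstance(raw, (tuple, list)):
                    raw = ",".join(str(r) for r in raw)
                labels = [s for s in str(raw).split(",") if s]
            elif sample_names:
                for name in sample_names:
                    gt = rec.samples[name].get("GT")
                    if gt and any(a not in (None, 0) for a in gt):
                        labels.append(name)
            for label in labels:
                if species is None or label == species:
                    records.append(SnpRecord(rec.chrom, rec.pos, ref, alt, label))
    return records


def build_snp_corrected_reference(
    genome: dict[str, str],
    snps: list[SnpRecord],
    species: str,
) -> tuple[dict[str, str], SubstitutionReport]:
    """Substitute the bisulfite-confounded SNPs of one species into a genome.

    Only records with (ref=C, alt=T) or (ref=G, alt=A) are applied; every
    other position, including other SNP classes, stays unchanged, so contig
    names and lengths are preserved and the operation is idempotent.

    Raises ``ValueError`` when a record's ref allele disagrees with the
    genome, naming contig and position.
    """
    arrays = {name: bytearray(seq.upper(), "ascii") for name, seq in genome.items()}
    report = SubstitutionReport(species=species)
    for snp in snps:
        if snp.species != species:
            continue
        ref = snp.ref_allele.upper()
        alt = snp.alt_allele.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            log.warning("skipping non-SNV record at %s:%d (%s>%s)", snp.contig, snp.position, ref, alt)
            report.skipped_malformed += 1
            continue
        if snp.contig not in arrays:
            raise ValueError(f"SNP contig {snp.contig!r} absent from genome")
        seq = arrays[snp.contig]
        idx = snp.position - 1
        if idx < 0 or idx >= len(seq):
            raise ValueError(f"SNP position out of bounds at {snp.contig}:{snp.position}")
        current = chr(seq[idx])
        cls = f"{ref}>{alt}"
        report.per_class[cls] = report.per_class.get(cls, 0) + 1
        if current != ref and not (current == alt and cls in ("C>T", "G>A")):
            # idempotence: a site already carrying the substituted alt is fine
            raise ValueError(
                f"ref allele mismatch at {snp.contig}:{snp.position}: "
                f"genome has {current}, record says {ref}"
            )
        if cls == "C>T":
            seq[idx] = ord("T")
            report.applied_c_to_t += 1
        elif cls == "G>A":
            seq[idx] = ord("A")
            report.applied_g_to_a += 1
        else:
            report.skipped_non_bisulfite += 1
    corrected = {name: arr.decode("ascii") for name, arr in arrays.items()}
    return corrected, report


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence mapping."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line width (default 60)."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_substitution_report(report: SubstitutionReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        for key, value in report.to_rows():
            fh.write(f"{key}\t{value}\n")
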
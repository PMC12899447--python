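"""Reading/writing genome FASTA, GFF3 annotations and target-locus tables.

Coordinates are 1-based inclusive throughout (GFF convention). Nucleotide
sequences are held uppercase over the alphabet {A, C, G, T, N}; any other
IUPAC ambiguity symbol is mapped to N on load (SSR runs must not cross
ambiguous bases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LOCUS_TABLE_COLUMNS = [
    "locus_id",
    "gene_label",
    "contig",
    "start",
    "end",
    "strand",
    "pathogen_tag",
    "family_tag",
]


@dataclass
class ContigSet:
    """A set of named contig sequences (uppercase, ACGTN alphabet)."""

    entries: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.entries.items()}

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.entries

    def __getitem__(self, contig_id: str) -> str:
        return self.entries[contig_id]

    def fetch(self, contig_id: str, start: int, end: int) -> str:
        """Return the subsequence [start, end] (1-based inclusive)."""
        seq = self.entries[contig_id]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"region {contig_id}:{start}-{end} outside contig bounds (len {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass
class LocusAnnotation:
    """A target gene locus with optional exon sub-structure."""

    locus_id: str
    gene_label: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    pathogen_tag: str = ""
    family_tag: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"locus {self.locus_id}: invalid coordinates {self.start}-{self.end}"
            )
        for es, ee in self.exons:
            if es < self.start or ee > self.end or es > ee:
                raise ValueError(
                    f"locus {self.locus_id}: exon ({es},{ee}) outside gene body"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnalysisRegion:
    """A locus plus flanking sequence, trimmed to contig bounds."""

    contig_id: str
    start: int
    end: int
    locus_id: str
    flank: int = 5000

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sanitize(seq: str, contig_id: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        n_bad = sum(seq.count(b) for b in bad)
        logger.warning(
            "contig %s: %d non-ACGTN symbols (%s) mapped to N",
            contig_id,
            n_bad,
            ",".join(sorted(bad)),
        )
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def load_contigs(path: str | Path) -> ContigSet:
    """Load a nucleotide FASTA into a :class:`ContigSet`.

    Sequences are uppercased; ambiguity codes other than N are mapped to N
    with a logged warning. Duplicate contig ids and empty files are errors.
    """
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise ValueError(f"duplicate contig id in {path}: {rec.id}")
        entries[rec.id] = _sanitize(str(rec.seq), rec.id)
    if not entries:
        raise ValueError(f"no FASTA records found in {path}")
    return ContigSet(entries)


def write_contigs(contigs: ContigSet, path: str | Path, width: int = 70) -> None:
    """Write a ContigSet as FASTA."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.entries.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def load_protein_fasta(path: str | Path) -> dict[str, str]:
    """Load an amino-acid FASTA as a plain id → sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate protein id in {path}: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def _gff_db(gff_path: str | Path):
    import gffutils

    return gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def load_loci(
    gff_path: str | Path,
    targets: Sequence[str],
    locus_meta: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[list[LocusAnnotation], list[str]]:
    """Extract target gene loci (with exons) from a GFF3 file.

    Parameters
    ----------
    gff_path:
        GFF3 with ``gene`` features and exon children linked via Parent.
    targets:
        Gene IDs or Name attributes to retain. Targets with no match are
        returned in the ``missing`` report (second element), not fatal.
    locus_meta:
        Optional per-target mapping supplying ``pathogen_tag``/``family_tag``.

    Returns
    -------
    (loci, missing_targets)
    """
    if not targets:
        logger.warning("load_loci called with an empty target list")
        return [], []
    db = _gff_db(gff_path)
    wanted = set(targets)
    found: dict[str, LocusAnnotation] = {}
    for gene in db.features_of_type("gene"):
        names = {gene.id, *gene.attributes.get("Name", [])}
        match = wanted & names
        if not match:
            continue
        target = sorted(match)[0]
        exons: list[tuple[int, int]] = []
        for child in db.children(gene.id, featuretype="exon", order_by="start"):
            exons.append((child.start, child.end))
        # exons from multiple isoforms may repeat; keep unique, sorted
        exons = sorted(set(exons))
        meta = dict(locus_meta.get(target, {})) if locus_meta else {}
        found[target] = LocusAnnotation(
            locus_id=gene.id,
            gene_label=gene.attributes.get("Name", [gene.id])[0],
            contig_id=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=exons,
            pathogen_tag=meta.get("pathogen_tag", ""),
            family_tag=meta.get("family_tag", ""),
        )
    missing = sorted(wanted - set(found))
    if missing:
        logger.warning("targets without a GFF match: %s", ", ".join(missing))
    return [found[t] for t in targets if t in found], missing


def protein_to_gene_map(gff_path: str | Path) -> dict[str, str]:
    """Map protein ids to gene ids via gene→mRNA→CDS attribute chains."""
    db = _gff_db(gff_path)
    mapping: dict[str, str] = {}
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene.id, featuretype="mRNA"):
            for cds in db.children(mrna.id, featuretype="CDS"):
                for pid in cds.attributes.get("protein_id", []):
                    mapping[pid] = gene.id
    return mapping


def load_locus_table(path: str | Path) -> list[LocusAnnotation]:
    """Read the target-locus TSV (locus_id, gene_label, contig, start, end,
    strand, pathogen_tag, family_tag) into LocusAnnotation records."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing_cols = set(LOCUS_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"locus table {path} missing columns: {sorted(missing_cols)}")
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            LocusAnnotation(
                locus_id=row.locus_id,
                gene_label=row.gene_label,
                contig_id=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                pathogen_tag=row.pathogen_tag,
                family_tag=row.family_tag,
            )
        )
    return loci


def write_locus_table(loci: Iterable[LocusAnnotation], path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id,
            "gene_label": l.gene_label,
            "contig": l.contig_id,
            "start": l.start,
            "end": l.end,
            "strand": l.strand,
            "pathogen_tag": l.pathogen_tag,
            "family_tag": l.family_tag,
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def extract_region(
    contigs: ContigSet, locus: LocusAnnotation, flank: int = 5000
) -> tuple[AnalysisRegion, str]:
    """Extract the locus ± flank subsequence, trimmed to contig bounds.

    Returns the trimmed :class:`AnalysisRegion` and its sequence; the
    sequence length always equals ``end - start + 1``.
    """
    if locus.contig_id not in contigs:
        raise KeyError(f"locus {locus.locus_id}: unknown contig {locus.contig_id}")
    contig_len = contigs.lengths[locus.contig_id]
    if locus.end > contig_len:
        raise ValueError(
            f"locus {locus.locus_id} ({locus.start}-{locus.end}) outside contig "
            f"{locus.contig_id} (len {contig_len})"
        )
    start = max(1, locus.start - flank)
    end = min(contig_len, locus.end + flank)
    region = AnalysisRegion(locus.contig_id, start, end, locus.locus_id, flank)
    return region, contigs.fetch(locus.contig_id, start, end)
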
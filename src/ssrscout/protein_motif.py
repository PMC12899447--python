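"""Proteome-wide exact amino-acid motif screening for family discovery.

Conserved family motifs (e.g. the WRKY domain signature WRKYGQK) are
matched as exact substrings over the proteome; motif-bearing proteins are
mapped back to their genomic loci through GFF ID/Parent chains, and
positional motif atlases summarize where in the protein each family's
motifs occur. Motif strings are a required configuration input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import LocusAnnotation, protein_to_gene_map

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    family_tag: str
    motif: str
    position: int  # 1-based start within the protein
    count_in_protein: int


def scan_proteome(
    proteome: Mapping[str, str], motifs: Mapping[str, Sequence[str]]
) -> list[MotifHit]:
    """All exact (overlap-allowed) motif occurrences across the proteome.

    ``motifs`` maps family tag → motif strings (X is a literal residue,
    not a wildcard). Empty motifs are an error.
    """
    hits = []
    for family, patterns in motifs.items():
        for motif in patterns:
            if not motif:
                raise ValueError(f"family {family}: empty motif")
            bad = set(motif.upper()) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"family {family}: motif {motif} has non-amino-acid symbols {bad}"
                )
            pattern = re.compile(f"(?={re.escape(motif.upper())})")
            for pid, seq in proteome.items():
                positions = [m.start() + 1 for m in pattern.finditer(seq)]
                for pos in positions:
                    hits.append(MotifHit(pid, family, motif, pos, len(positions)))
    return hits


def family_proteins(hits: Sequence[MotifHit]) -> dict[str, list[str]]:
    """Deduplicated protein ids per family."""
    out: dict[str, set[str]] = {}
    for h in hits:
        out.setdefault(h.family_tag, set()).add(h.protein_id)
    return {fam: sorted(pids) for fam, pids in out.items()}


def hits_to_loci(
    hits: Sequence[MotifHit],
    gff_path,
    loci_by_id: Mapping[str, LocusAnnotation] | None = None,
    pathogen_tag: str = "Exobasidium vexans",
) -> tuple[list[LocusAnnotation], list[str]]:
    """Map motif-bearing proteins back to gene loci (one per gene).

    Isoforms of the same gene collapse to a single family-tagged locus;
    proteins with no GFF linkage are returned in the unmapped report.
    Returns (loci, unmapped_protein_ids).
    """
    p2g = protein_to_gene_map(gff_path)
    if loci_by_id is None:
        from .genome_io import load_loci

        all_genes = sorted(set(p2g.values()))
        found, _ = load_loci(gff_path, all_genes)
        loci_by_id = {l.locus_id: l for l in found}
    unmapped = []
    genes: dict[str, str] = {}  # gene_id -> family
    for h in hits:
        gene = p2g.get(h.protein_id)
        if gene is None or gene not in loci_by_id:
            unmapped.append(h.protein_id)
            continue
        genes.setdefault(gene, h.family_tag)
    if unmapped:
        logger.warning("%d motif hits had no GFF linkage", len(set(unmapped)))
    loci = []
    for gene_id in sorted(genes):
        base = loci_by_id[gene_id]
        loci.append(
            LocusAnnotation(
                locus_id=base.locus_id,
                gene_label=base.gene_label,
                contig_id=base.contig_id,
                start=base.start,
                end=base.end,
                strand=base.strand,
                exons=list(base.exons),
                pathogen_tag=base.pathogen_tag or pathogen_tag,
                family_tag=genes[gene_id],
            )
        )
    return loci, sorted(set(unmapped))


def motif_atlas(
    hits: Sequence[MotifHit],
    protein_lengths: Mapping[str, int],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-family histogram of motif positions normalized to protein length.

    Each hit contributes its start position divided by the protein length
    (a value in (0, 1]); totals per family equal the hit counts.
    """
    rows = []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    by_family: dict[str, list[float]] = {}
    for h in hits:
        length = protein_lengths[h.protein_id]
        by_family.setdefault(h.family_tag, []).append(h.position / length)
    for fam in sorted(by_family):
        vals = np.array(by_family[fam])
        counts, _ = np.histogram(vals, bins=edges)
        # np.histogram's last bin is closed; values are in (0, 1] so all land
        for i in range(n_bins):
            rows.append(
                {
                    "family_tag": fam,
                    "bin_low": edges[i],
                    "bin_high": edges[i + 1],
                    "n_hits": int(counts[i]),
                }
            )
    return pd.DataFrame(rows, columns=["family_tag", "bin_low", "bin_high", "n_hits"])
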
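"""Exact-match electronic PCR across genome assemblies and PIC scoring.

Primer binding sites are exact string matches (no mismatches, ambiguity
codes never match); both orientation combinations — forward primer with
the reverse primer's reverse complement, and vice versa — are screened,
and every upstream/downstream site pairing spanning at most 1000 bp
yields a predicted amplicon. Polymorphism across genomes is summarized
with Botstein's polymorphic information content computed from the
multiset of observed amplicon lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import ContigSet, reverse_complement
from .primer_design import PrimerPair

MAX_AMPLICON = 1000


@dataclass(frozen=True)
class AmpliconHit:
    primer_id: str
    genome_label: str
    contig_id: str
    start: int
    end: int
    orientation: str  # "F/rc(R)" or "R/rc(F)"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PICResult:
    primer_id: str
    allele_sizes: list[int]
    n_genomes_amplified: int
    pic: float


def _occurrences(seq: str, probe: str) -> list[int]:
    """All (overlapping) exact occurrences, 1-based starts."""
    out = []
    i = seq.find(probe)
    while i != -1:
        out.append(i + 1)
        i = seq.find(probe, i + 1)
    return out


def find_sites(genome: ContigSet, probe: str) -> list[tuple[str, int, str]]:
    """Exact binding sites of a primer on both strands.

    Returns (contig, 1-based start of the plus-strand footprint, strand):
    '+' where the probe itself occurs, '-' where its reverse complement
    occurs. Probes containing N never match.
    """
    probe = probe.upper()
    if set(probe) - set("ACGT"):  # Ns and ambiguity codes never match
        return []
    sites = []
    rc = reverse_complement(probe)
    for cid, seq in genome.entries.items():
        for s in _occurrences(seq, probe):
            sites.append((cid, s, "+"))
        for s in _occurrences(seq, rc):
            sites.append((cid, s, "-"))
    return sites


def enumerate_amplicons(
    genome: ContigSet,
    pair: PrimerPair,
    max_len: int = MAX_AMPLICON,
    genome_label: str = "",
) -> list[AmpliconHit]:
    """All predicted products of a primer pair on one genome.

    For each orientation combination, every plus-strand site of the
    upstream primer is paired with every downstream occurrence of the
    other primer's reverse complement; products run from the upstream 5'
    base to the downstream footprint's last base and are capped at
    ``max_len``. A pair may therefore yield many amplicons.
    """
    hits = []
    combos = (
        (pair.forward, pair.reverse, "F/rc(R)"),
        (pair.reverse, pair.forward, "R/rc(F)"),
    )
    for p1, p2, label in combos:
        p1 = p1.upper()
        rc2 = reverse_complement(p2.upper())
        for cid, seq in genome.entries.items():
            up = _occurrences(seq, p1)
            down = _occurrences(seq, rc2)
            if not up or not down:
                continue
            down_arr = np.array(down)
            for s1 in up:
                # downstream sites at/after the upstream 5' base
                for s2 in down_arr[down_arr >= s1]:
                    end = int(s2) + len(rc2) - 1
                    length = end - s1 + 1
                    if length <= max_len:
                        hits.append(
                            AmpliconHit(pair.primer_id, genome_label, cid, s1, end, label)
                        )
    return hits


def pic(allele_sizes: Sequence[int]) -> float:
    """Botstein polymorphic information content of an allele multiset.

    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j², with frequencies taken from
    the observations; 0 when a single distinct allele is observed, NaN for
    an empty multiset.
    """
    if len(allele_sizes) == 0:
        return float("nan")
    _, counts = np.unique(np.asarray(allele_sizes), return_counts=True)
    p = counts / counts.sum()
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


def multigenome_summary(
    hits_by_genome: Mapping[str, Sequence[AmpliconHit]],
    primer_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-primer cross-genome summary table.

    One row per primer: genomes amplified, per-genome amplicon counts,
    pooled allele sizes (one observation per amplicon), PIC, and a
    multi-product flag (some genome yields more than one amplicon).
    """
    by_primer: dict[str, dict[str, list[AmpliconHit]]] = {}
    for genome, hits in hits_by_genome.items():
        for h in hits:
            by_primer.setdefault(h.primer_id, {}).setdefault(genome, []).append(h)
    if primer_ids is None:
        primer_ids = sorted(by_primer)
    rows = []
    for pid in primer_ids:
        per_genome = by_primer.get(pid, {})
        sizes = [h.length for hits in per_genome.values() for h in hits]
        rows.append(
            {
                "primer_id": pid,
                "n_genomes_amplified": len(per_genome),
                "n_amplicons": len(sizes),
                "amplicons_per_genome": {g: len(v) for g, v in sorted(per_genome.items())},
                "allele_sizes": sorted(sizes),
                "n_distinct_alleles": len(set(sizes)),
                "pic": pic(sizes) if sizes else float("nan"),
                "multi_product": any(len(v) > 1 for v in per_genome.values()),
            }
        )
    return pd.DataFrame(rows)


def virtual_gel(
    hits_by_genome: Mapping[str, Sequence[AmpliconHit]]
) -> pd.DataFrame:
    """Size-sorted band table emulating a virtual agarose gel.

    Co-migrating bands (identical size for the same primer and genome)
    are collapsed with a multiplicity count.
    """
    rows: dict[tuple[str, str, int], int] = {}
    for genome, hits in hits_by_genome.items():
        for h in hits:
            key = (h.primer_id, genome, h.length)
            rows[key] = rows.get(key, 0) + 1
    table = pd.DataFrame(
        [
            {"primer_id": p, "genome": g, "size": s, "multiplicity": m}
            for (p, g, s), m in rows.items()
        ],
        columns=["primer_id", "genome", "size", "multiplicity"],
    )
    return table.sort_values(["primer_id", "genome", "size"]).reset_index(drop=True)


def plot_virtual_gel(band_table: pd.DataFrame, path=None):  # pragma: no cover
    """Render the band table as a gel-like scatter (one lane per primer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, band_table["primer_id"].nunique() * 0.4), 5))
    lanes = {p: i for i, p in enumerate(sorted(band_table["primer_id"].unique()))}
    for row in band_table.itertuples(index=False):
        ax.hlines(row.size, lanes[row.primer_id] - 0.3, lanes[row.primer_id] + 0.3)
    ax.set_xticks(list(lanes.values()), list(lanes), rotation=90, fontsize=6)
    ax.set_ylabel("product size (bp)")
    ax.invert_yaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
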
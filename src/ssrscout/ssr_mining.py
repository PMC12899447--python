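"""Perfect tandem-repeat (SSR) detection, motif lengths 2-6 bp.

A run is reported when a primitive motif of length k occurs in tandem at
least threshold(k) times: >=8 copies for dinucleotides, >=5 for tri-,
>=4 for tetra-, >=3 for penta- and hexanucleotides. Runs are maximal in
the per-base sense (not extendable by one more base continuing the
periodicity), truncated to whole motif copies, never cross N, and each
underlying repeat tract is reported once, at its minimal period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genome_io import ContigSet, LocusAnnotation, extract_region

MIN_MOTIF = 2
MAX_MOTIF = 6
REPEAT_THRESHOLDS = {2: 8, 3: 5, 4: 4, 5: 3, 6: 3}

CATALOGUE_COLUMNS = [
    "ssr_id",
    "locus_id",
    "contig",
    "start",
    "end",
    "motif",
    "k",
    "repeats",
    "strand",
    "distance_to_locus",
]


def repeat_threshold(k: int) -> int:
    """Minimum tandem copy number for a motif of length ``k`` (2-6 bp)."""
    try:
        return REPEAT_THRESHOLDS[k]
    except KeyError:
        raise ValueError(f"motif length {k} outside supported range [2, 6]") from None


@dataclass(order=True)
class SSRRecord:
    """One detected tandem repeat, in absolute 1-based genome coordinates."""

    contig_id: str
    start: int
    end: int
    motif: str
    k: int
    repeats: int
    ssr_id: str = field(default="", compare=False)
    locus_id: str = field(default="", compare=False)
    strand: str = field(default="+", compare=False)
    distance_to_locus: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.k * self.repeats:
            raise ValueError(
                f"SSR span {self.start}-{self.end} inconsistent with "
                f"{self.repeats} x {self.k}-mer {self.motif}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def key(self) -> tuple:
        return (self.contig_id, self.start, self.end, self.motif, self.k, self.repeats)


def is_primitive(motif: str) -> bool:
    """True when the motif is not itself a tandem repeat of a shorter motif."""
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def detect_ssrs(
    seq: str,
    region_offset: int = 0,
    contig_id: str = "",
    locus_id: str = "",
    strand: str = "+",
) -> list[SSRRecord]:
    """Scan an uppercase sequence for threshold-passing tandem repeats.

    ``region_offset`` shifts reported coordinates to absolute genome
    positions (offset = region start - 1). Runs never span N; a tract is
    reported once at its minimal period (an AT run is not re-reported as
    ATAT), and per-base maximality suppresses rotated sub-runs.
    """
    n = len(seq)
    records: list[SSRRecord] = []
    for k in range(MIN_MOTIF, MAX_MOTIF + 1):
        thr = REPEAT_THRESHOLDS[k]
        min_len = k * thr
        i = 0
        while i + min_len <= n:
            motif = seq[i : i + k]
            if "N" in motif or not is_primitive(motif):
                i += 1
                continue
            # per-base left maximality: extendable iff seq[i-1] continues
            # the periodicity (N never matches anything)
            if i > 0 and seq[i - 1] != "N" and seq[i - 1] == seq[i - 1 + k]:
                i += 1
                continue
            j = i + k
            while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
                j += 1
            copies = (j - i) // k
            if copies >= thr:
                start = i + 1 + region_offset
                end = i + k * copies + region_offset
                records.append(
                    SSRRecord(
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        motif=motif,
                        k=k,
                        repeats=copies,
                        locus_id=locus_id,
                        strand=strand,
                    )
                )
            # any start inside (i, j-k] is left-extendable; skip ahead
            i = max(i + 1, j - k + 1)
    records.sort()
    return records


def mine_locus(
    contigs: ContigSet, locus: LocusAnnotation, flank: int = 5000
) -> list[SSRRecord]:
    """Mine SSRs in the locus ± flank analysis region.

    Records are tagged with the owning locus id, the locus strand, and the
    minimum gap to the gene body (0 when the SSR overlaps it).
    """
    from .candidate_selection import locus_distance

    region, seq = extract_region(contigs, locus, flank)
    records = detect_ssrs(
        seq,
        region_offset=region.start - 1,
        contig_id=region.contig_id,
        locus_id=locus.locus_id,
        strand=locus.strand,
    )
    out = []
    for idx, rec in enumerate(records, start=1):
        out.append(
            replace(
                rec,
                ssr_id=f"{locus.locus_id}.ssr{idx:03d}",
                distance_to_locus=locus_distance(rec, locus),
            )
        )
    return out


def catalogue_frame(records: Iterable[SSRRecord]) -> pd.DataFrame:
    """Tabulate SSR records in the catalogue TSV layout."""
    rows = [
        {
            "ssr_id": r.ssr_id,
            "locus_id": r.locus_id,
            "contig": r.contig_id,
            "start": r.start,
            "end": r.end,
            "motif": r.motif,
            "k": r.k,
            "repeats": r.repeats,
            "strand": r.strand,
            "distance_to_locus": r.distance_to_locus,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)


def write_catalogue(records: Iterable[SSRRecord], path: str | Path) -> None:
    catalogue_frame(records).to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> list[SSRRecord]:
    df = pd.read_csv(path, sep="\t", comment="#").fillna({"strand": "+"})
    return [
        SSRRecord(
            contig_id=str(row.contig),
            start=int(row.start),
            end=int(row.end),
            motif=str(row.motif),
            k=int(row.k),
            repeats=int(row.repeats),
            ssr_id=str(row.ssr_id),
            locus_id=str(row.locus_id),
            strand=str(row.strand),
            distance_to_locus=int(row.distance_to_locus),
        )
        for row in df.itertuples(index=False)
    ]
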
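"""Hotspot-restricted SSR candidate ranking, panel filters and summaries.

Candidate selection is hierarchical: SSRs overlapping 99%-level hotspot
regions are used; a locus yielding none falls back to its 95%-level
regions. Ranking is by repeat count (descending), then distance to the
gene (ascending), then genomic start (ascending, for determinism), capped
at 100 candidates per locus. Before the final panel a structural filter
keeps 2-4 bp motifs with >= 8 copies and 5-6 bp motifs with >= 4 copies;
at most five markers per locus enter the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import LocusAnnotation
from .hotspot_stats import HotspotRegion
from .ssr_mining import SSRRecord

RANK_CAP = 100
PANEL_CAP = 5
STRUCTURAL_MIN_REPEATS = {2: 8, 3: 8, 4: 8, 5: 4, 6: 4}

REGION_LABELS = (
    "exonic",
    "intronic",
    "promoter_upstream",
    "downstream",
    "distal_intergenic",
)


@dataclass
class RankedCandidate:
    ssr: SSRRecord
    rank: int
    hotspot: HotspotRegion | None
    selected: bool = False


def locus_distance(ssr: SSRRecord, locus: LocusAnnotation) -> int:
    """Minimum gap (bp) between the SSR interval and the gene body.

    0 when the intervals overlap; requires both on the same contig.
    """
    if ssr.contig_id != locus.contig_id:
        raise ValueError(
            f"SSR on {ssr.contig_id} vs locus {locus.locus_id} on {locus.contig_id}"
        )
    if ssr.end < locus.start:
        return locus.start - ssr.end
    if ssr.start > locus.end:
        return ssr.start - locus.end
    return 0


def _overlaps(ssr: SSRRecord, region: HotspotRegion) -> bool:
    return ssr.contig_id == region.contig_id and not (
        ssr.end < region.start or ssr.start > region.end
    )


def filter_to_hotspots(
    ssrs: Sequence[SSRRecord],
    hotspots99: Sequence[HotspotRegion],
    hotspots95: Sequence[HotspotRegion] = (),
) -> list[tuple[SSRRecord, HotspotRegion]]:
    """Keep SSRs overlapping a hotspot, 99%-level first with 95% fallback.

    Returns (ssr, hotspot) pairs. When at least one SSR overlaps a
    99%-level region only those are kept; otherwise the 95%-level regions
    are tried so low-SSR loci are not excluded outright.
    """
    for regions in (hotspots99, hotspots95):
        kept = []
        for ssr in ssrs:
            hit = next((h for h in regions if _overlaps(ssr, h)), None)
            if hit is not None:
                kept.append((ssr, hit))
        if kept:
            return kept
    return []


def rank_candidates(
    ssrs: Sequence[SSRRecord],
    locus: LocusAnnotation | None = None,
    cap: int = RANK_CAP,
    hotspots: Mapping[tuple, HotspotRegion] | None = None,
) -> list[RankedCandidate]:
    """Rank a locus's candidates by (repeats desc, distance asc, start asc).

    ``distance_to_locus`` on the records is used when ``locus`` is None.
    At most ``cap`` candidates are returned.
    """
    def dist(s: SSRRecord) -> int:
        return locus_distance(s, locus) if locus is not None else s.distance_to_locus

    ordered = sorted(ssrs, key=lambda s: (-s.repeats, dist(s), s.start))
    out = []
    for i, ssr in enumerate(ordered[:cap], start=1):
        hs = hotspots.get(ssr.key()) if hotspots else None
        out.append(RankedCandidate(ssr, i, hs))
    return out


def structural_filter(ssrs: Iterable[SSRRecord]) -> list[SSRRecord]:
    """Panel-stage repeat-count filter: >=8 copies for 2-4 bp motifs,
    >=4 copies for 5-6 bp motifs (stricter than the mining thresholds)."""
    return [s for s in ssrs if s.repeats >= STRUCTURAL_MIN_REPEATS[s.k]]


def build_final_panel(
    ranked_by_locus: Mapping[str, Sequence[RankedCandidate]],
    panel_cap: int = PANEL_CAP,
) -> dict[str, list[RankedCandidate]]:
    """Top ``panel_cap`` candidates per locus, marked selected.

    Inputs are expected to be hotspot-restricted and structurally filtered
    already; ranking order within each locus is preserved.
    """
    panel: dict[str, list[RankedCandidate]] = {}
    for locus_id, ranked in ranked_by_locus.items():
        chosen = list(ranked)[:panel_cap]
        for c in chosen:
            c.selected = True
        panel[locus_id] = chosen
    return panel


def classify_region(
    ssr: SSRRecord, locus: LocusAnnotation, flank: int = 5000
) -> str:
    """Assign one genomic-context label to an SSR relative to its locus.

    exonic (overlaps an exon) > intronic (inside the gene body) >
    promoter_upstream / downstream (strand-aware, within the flank) >
    distal_intergenic.
    """
    if any(not (ssr.end < es or ssr.start > ee) for es, ee in locus.exons):
        return "exonic"
    if not (ssr.end < locus.start or ssr.start > locus.end):
        return "intronic"
    d = locus_distance(ssr, locus)
    genomically_left = ssr.end < locus.start
    five_prime = genomically_left if locus.strand == "+" else not genomically_left
    if d <= flank:
        return "promoter_upstream" if five_prime else "downstream"
    return "distal_intergenic"


def panel_frame(
    panel: Mapping[str, Sequence[RankedCandidate]],
    loci: Mapping[str, LocusAnnotation],
    flank: int = 5000,
) -> pd.DataFrame:
    """Final-panel table: locus metadata, SSR structure, genomic context,
    hotspot level and max z."""
    rows = []
    for locus_id, cands in panel.items():
        locus = loci[locus_id]
        for c in cands:
            rows.append(
                {
                    "locus_id": locus_id,
                    "gene_label": locus.gene_label,
                    "pathogen_tag": locus.pathogen_tag,
                    "family_tag": locus.family_tag,
                    "contig": c.ssr.contig_id,
                    "start": c.ssr.start,
                    "end": c.ssr.end,
                    "ssr_id": c.ssr.ssr_id,
                    "motif": c.ssr.motif,
                    "k": c.ssr.k,
                    "repeats": c.ssr.repeats,
                    "strand": c.ssr.strand,
                    "distance": locus_distance(c.ssr, locus),
                    "region_class": classify_region(c.ssr, locus, flank),
                    "hotspot_level": c.hotspot.level if c.hotspot else pd.NA,
                    "max_z": c.hotspot.max_z if c.hotspot else np.nan,
                }
            )
    return pd.DataFrame(rows)


def panel_summaries(panel: pd.DataFrame) -> dict[str, pd.DataFrame | dict]:
    """Summary statistics over a final-panel table.

    Returns per-motif-class counts and max-z stats, per-gene repeat
    distributions, strand proportions, locus-distance statistics, region
    class counts, and the Pearson/Spearman correlation between repeat
    number and max z (NA when either vector is constant).
    """
    if panel.empty:
        raise ValueError("panel is empty")
    motif_class = panel.groupby("k").agg(
        n=("ssr_id", "size"),
        mean_max_z=("max_z", "mean"),
        median_max_z=("max_z", "median"),
    )
    per_gene = panel.groupby("gene_label").agg(
        n=("ssr_id", "size"),
        mean_repeats=("repeats", "mean"),
        median_repeats=("repeats", "median"),
    )
    strand = panel["strand"].value_counts(normalize=True).to_dict()
    dist = panel["distance"]
    distance_stats = {
        "mean": float(dist.mean()),
        "median": float(dist.median()),
        "sd": float(dist.std(ddof=1)) if len(dist) > 1 else float("nan"),
        "min": int(dist.min()),
        "max": int(dist.max()),
    }
    region_counts = panel["region_class"].value_counts().to_dict()
    x = panel["repeats"].to_numpy(dtype=float)
    y = panel["max_z"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    return {
        "motif_class": motif_class,
        "per_gene": per_gene,
        "strand_proportions": strand,
        "distance_stats": distance_stats,
        "region_class_counts": region_counts,
        "correlations": {"pearson": pearson, "spearman": spearman},
    }
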
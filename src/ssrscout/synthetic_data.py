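"""Synthetic genomes, annotations, cultivars and proteomes with ground truth.

The generator emulates the structure the pipeline assumes: multi-contig
nucleotide assemblies carrying annotated genes with exon/intron structure,
perfect SSR arrays planted at controlled positions (clustered to form
density hotspots or scattered as background), derived "cultivar" genomes
whose planted arrays are expanded/contracted by repeat-count jitter on top
of background SNPs, and proteomes carrying planted conserved family
motifs. Every emitted dataset comes with a truth table holding exact
coordinates and allele sizes, and all generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import AnalysisRegion, ContigSet, LocusAnnotation
from .ssr_mining import is_primitive

BASES = np.array(list("ACGT"))

PLACEMENTS = (
    "intron", "exon_adjacent", "upstream", "downstream", "distal", "cluster", "cluster2"
)


@dataclass
class PlantSSR:
    """One SSR array to plant: where (locus + placement class) and what."""

    locus_id: str
    placement: str
    motif: str
    repeats: int

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement class {self.placement}")
        if not (2 <= len(self.motif) <= 6) or not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif} must be a primitive 2-6mer")
        if self.repeats < 2:
            raise ValueError("repeats must be >= 2")

    @property
    def length(self) -> int:
        return len(self.motif) * self.repeats


@dataclass
class SyntheticSpec:
    n_contigs: int = 3
    contig_length: int = 100_000
    n_genes: int = 9
    gene_length: tuple[int, int] = (2000, 3500)
    exons_per_gene: int = 3
    gc: float = 0.5
    flank: int = 5000
    ssr_plants: list[PlantSSR] = field(default_factory=list)
    family_tags: tuple[str, ...] = ("WRKY", "PRX", "NAC", "LRR", "CHI")
    pathogen_tags: tuple[str, ...] = (
        "Exobasidium vexans",
        "Empoasca onukii",
        "Ectropis obliqua",
    )

    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(1, self.n_genes + 1)]


@dataclass
class TruthTable:
    genes: pd.DataFrame
    ssrs: pd.DataFrame  # ssr_id, locus_id, placement, contig, start, end, motif, k, repeats
    motif_carriers: pd.DataFrame | None = None
    cultivars: dict[str, pd.DataFrame] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    gcp = gc / 2
    return rng.choice(BASES, size=n, p=[at, gcp, gcp, at])


def _write_run(seq: np.ndarray, start0: int, motif: str, repeats: int,
               rng: np.random.Generator) -> None:
    """Write motif*repeats at 0-based start0, breaking periodicity at both
    boundaries so the planted copy number is exact."""
    k = len(motif)
    run = np.array(list(motif * repeats))
    end0 = start0 + len(run) - 1
    if start0 < 0 or end0 >= len(seq):
        raise ValueError("planted run outside contig bounds")
    seq[start0 : end0 + 1] = run
    if start0 > 0 and seq[start0 - 1] == motif[k - 1]:
        seq[start0 - 1] = rng.choice([b for b in "ACGT" if b != motif[k - 1]])
    if end0 + 1 < len(seq) and seq[end0 + 1] == motif[0]:
        seq[end0 + 1] = rng.choice([b for b in "ACGT" if b != motif[0]])


def _gene_layout(spec: SyntheticSpec, rng: np.random.Generator) -> list[LocusAnnotation]:
    ids = spec.gene_ids()
    per_contig: dict[str, list[str]] = {}
    for i, gid in enumerate(ids):
        per_contig.setdefault(f"contig{(i % spec.n_contigs) + 1}", []).append(gid)
    genes = []
    max_len = spec.gene_length[1]
    for contig, gids in per_contig.items():
        slot = spec.contig_length // len(gids)
        if slot < max_len + 2 * spec.flank + 2000:
            raise ValueError(
                f"infeasible packing: slot {slot} bp cannot hold a gene of "
                f"{max_len} bp plus {spec.flank} bp flanks ({gids[0]}...)"
            )
        for j, gid in enumerate(gids):
            glen = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            start = j * slot + spec.flank + 1000 + int(rng.integers(0, 500))
            end = start + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _exon_layout(start, end, spec.exons_per_gene)
            idx = int(gid[1:]) - 1
            genes.append(
                LocusAnnotation(
                    locus_id=gid,
                    gene_label=f"Cs{gid.upper()}",
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    pathogen_tag=spec.pathogen_tags[idx % len(spec.pathogen_tags)],
                    family_tag=spec.family_tags[idx % len(spec.family_tags)],
                )
            )
    return sorted(genes, key=lambda g: g.locus_id)


def _exon_layout(start: int, end: int, n_exons: int) -> list[tuple[int, int]]:
    glen = end - start + 1
    if n_exons <= 1:
        return [(start, end)]
    exon_len = max(50, glen // (2 * n_exons))
    intron_len = (glen - n_exons * exon_len) // (n_exons - 1)
    exons = []
    pos = start
    for i in range(n_exons):
        es = pos
        ee = es + exon_len - 1 if i < n_exons - 1 else end
        exons.append((es, min(ee, end)))
        pos = ee + 1 + intron_len
    return exons


def _placement_interval(
    gene: LocusAnnotation, placement: str, length: int, flank: int
) -> tuple[int, int]:
    """Genomic interval (1-based, inclusive) of admissible run starts."""
    margin = 25
    if placement in ("cluster", "cluster2"):
        lo, hi = clustered_placement_interval(gene, flank, secondary=placement == "cluster2")
        return lo, hi - length + 1
    if placement == "intron":
        introns = [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:])
            if s2 - e1 - 1 >= length + 2 * margin
        ]
        if not introns:
            raise ValueError(f"gene {gene.locus_id}: no intron can hold {length} bp")
        s, e = introns[len(introns) // 2]
        return s + margin, e - margin - length + 1
    if placement == "exon_adjacent":
        (_, e1), (s2, _) = gene.exons[0], gene.exons[1]
        lo = e1 + 6
        hi = min(e1 + 150, s2 - margin) - length + 1
        if hi < lo:
            raise ValueError(f"gene {gene.locus_id}: first intron too small")
        return lo, hi
    left = placement == "upstream" if gene.strand == "+" else placement == "downstream"
    if placement in ("upstream", "downstream"):
        if left:
            return gene.start - flank + 400, gene.start - 400 - length
        return gene.end + 400, gene.end + flank - 400 - length
    if placement == "distal":
        return max(2, gene.start - flank - 1800), gene.start - flank - 300 - length
    raise ValueError(placement)


def generate_reference(
    spec: SyntheticSpec, seed: int
) -> tuple[ContigSet, list[LocusAnnotation], TruthTable]:
    """Simulate the reference assembly: i.i.d. background sequence,
    annotated genes, and planted SSR arrays written verbatim at recorded
    coordinates. Deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    genes = _gene_layout(spec, rng)
    by_id = {g.locus_id: g for g in genes}
    seqs = {
        f"contig{i + 1}": _random_sequence(rng, spec.contig_length, spec.gc)
        for i in range(spec.n_contigs)
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    rows = []
    for n, plant in enumerate(spec.ssr_plants, start=1):
        gene = by_id.get(plant.locus_id)
        if gene is None:
            raise ValueError(f"plant references unknown locus {plant.locus_id}")
        lo, hi = _placement_interval(gene, plant.placement, plant.length, spec.flank)
        if hi < lo:
            raise ValueError(
                f"plant {n} ({plant.placement} at {plant.locus_id}) does not fit"
            )
        start = _find_free_start(rng, occupied[gene.contig_id], lo, hi, plant.length)
        if start is None:
            raise ValueError(
                f"plant {n} ({plant.placement} at {plant.locus_id}): no free position"
            )
        _write_run(seqs[gene.contig_id], start - 1, plant.motif, plant.repeats, rng)
        occupied[gene.contig_id].append((start - 10, start + plant.length + 9))
        rows.append(
            {
                "ssr_id": f"planted{n:04d}",
                "locus_id": plant.locus_id,
                "placement": plant.placement,
                "contig": gene.contig_id,
                "start": start,
                "end": start + plant.length - 1,
                "motif": plant.motif,
                "k": len(plant.motif),
                "repeats": plant.repeats,
            }
        )
    contigs = ContigSet({c: "".join(s) for c, s in seqs.items()})
    gene_rows = pd.DataFrame(
        [
            {
                "locus_id": g.locus_id,
                "gene_label": g.gene_label,
                "contig": g.contig_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "pathogen_tag": g.pathogen_tag,
                "family_tag": g.family_tag,
            }
            for g in genes
        ]
    )
    truth = TruthTable(genes=gene_rows, ssrs=pd.DataFrame(rows))
    return contigs, genes, truth


def _find_free_start(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    lo: int,
    hi: int,
    length: int,
    tries: int = 200,
) -> int | None:
    for _ in range(tries):
        start = int(rng.integers(lo, hi + 1))
        end = start + length - 1
        if all(e < start - 5 or s > end + 5 for s, e in occupied):
            return start
    return None


def write_gff(genes: Sequence[LocusAnnotation], path: str | Path) -> None:
    """Emit genes as GFF3 with mRNA, exon and CDS children (protein ids
    follow the <gene>.p1 convention)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.locus_id};Name={g.gene_label}"
            fh.write(
                f"{g.contig_id}\tsynth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.locus_id}.t1"
            fh.write(
                f"{g.contig_id}\tsynth\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.locus_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig_id}\tsynth\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    f"{g.contig_id}\tsynth\tCDS\t{es}\t{ee}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna};protein_id={g.locus_id}.p1\n"
                )


def plant_hotspot(
    region: AnalysisRegion,
    base_rate: float,
    fold: float,
    target_window: int | None = None,
    window: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[int], tuple[int, int]]:
    """Draw SSR start positions with one locally elevated window.

    Counts per non-overlapping ``window``-bp tile are Poisson(base_rate),
    except the target tile at Poisson(fold * base_rate); positions are
    uniform within their tile. fold = 1 gives the uniform null. Returns
    (starts, target tile interval).
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tiles = []
    start = region.start
    while start <= region.end:
        tiles.append((start, min(start + window - 1, region.end)))
        start += window
    if target_window is None:
        target_window = int(rng.integers(0, len(tiles)))
    starts: list[int] = []
    for i, (ws, we) in enumerate(tiles):
        lam = base_rate * (fold if i == target_window else 1.0)
        n = int(rng.poisson(lam))
        starts.extend(int(p) for p in rng.integers(ws, we + 1, size=n))
    return sorted(starts), tiles[target_window]


def derive_cultivar(
    contigs: ContigSet,
    truth: TruthTable,
    seed: int,
    repeat_deltas: Mapping[int, float] | None = None,
    snp_rate: float = 1e-4,
    exclusion_margin: int = 250,
) -> tuple[ContigSet, pd.DataFrame]:
    """Derive a cultivar genome: jitter planted repeat counts, add SNPs.

    ``repeat_deltas`` maps copy-number change → probability (default an
    even mix of −2..+2). Background SNPs are substituted at ``snp_rate``
    per base, never within ``exclusion_margin`` bp of a planted array, so
    primer footprints around planted SSRs stay exact. Returns the new
    assembly and a per-SSR truth delta (new coordinates, repeats and
    allele length).
    """
    rng = np.random.default_rng(seed)
    if repeat_deltas is None:
        repeat_deltas = {-2: 0.2, -1: 0.2, 0: 0.2, 1: 0.2, 2: 0.2}
    delta_vals = np.array(list(repeat_deltas))
    delta_p = np.array([repeat_deltas[d] for d in delta_vals])
    delta_p = delta_p / delta_p.sum()

    new_entries: dict[str, str] = {}
    rows = []
    for cid, seq in contigs.entries.items():
        plants = truth.ssrs[truth.ssrs["contig"] == cid].sort_values("start")
        pieces = []
        cursor = 0  # 0-based position in the reference
        shift = 0
        keep_free: list[tuple[int, int]] = []  # 0-based exclusion intervals (new coords)
        for row in plants.itertuples(index=False):
            delta = int(rng.choice(delta_vals, p=delta_p))
            new_repeats = max(1, row.repeats + delta)
            pieces.append(seq[cursor : row.start - 1])
            pieces.append(row.motif * new_repeats)
            new_start = row.start + shift
            new_len = len(row.motif) * new_repeats
            rows.append(
                {
                    "ssr_id": row.ssr_id,
                    "contig": cid,
                    "ref_start": row.start,
                    "new_start": new_start,
                    "new_end": new_start + new_len - 1,
                    "ref_repeats": row.repeats,
                    "new_repeats": new_repeats,
                    "delta": new_repeats - row.repeats,
                    "allele_length": new_len,
                }
            )
            keep_free.append(
                (new_start - 1 - exclusion_margin, new_start + new_len - 1 + exclusion_margin)
            )
            cursor = row.end
            shift += new_len - (row.end - row.start + 1)
        pieces.append(seq[cursor:])
        arr = np.array(list("".join(pieces)))
        allowed = np.ones(len(arr), dtype=bool)
        for s, e in keep_free:
            allowed[max(0, s) : e + 1] = False
        allowed &= arr != "N"
        mask = (rng.random(len(arr)) < snp_rate) & allowed
        for pos in np.flatnonzero(mask):
            arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
        new_entries[cid] = "".join(arr)
    return ContigSet(new_entries), pd.DataFrame(rows)


def generate_proteome(
    genes: Sequence[LocusAnnotation],
    motif_plants: Mapping[str, tuple[str, Sequence[str]]],
    seed: int,
    length_range: tuple[int, int] = (150, 400),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random proteome (one <gene>.p1 protein per gene) with planted motifs.

    ``motif_plants`` maps family tag → (motif string, locus ids carrying
    it). Returns (proteome, carriers truth table with planted positions).
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    proteome: dict[str, str] = {}
    for g in genes:
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        proteome[f"{g.locus_id}.p1"] = "".join(rng.choice(aa, size=n))
    rows = []
    for family, (motif, locus_ids) in motif_plants.items():
        for gid in locus_ids:
            pid = f"{gid}.p1"
            if pid not in proteome:
                raise ValueError(f"motif plant references unknown gene {gid}")
            seq = list(proteome[pid])
            pos = int(rng.integers(10, len(seq) - len(motif) - 10))
            seq[pos : pos + len(motif)] = list(motif)
            proteome[pid] = "".join(seq)
            rows.append(
                {
                    "protein_id": pid,
                    "locus_id": gid,
                    "family_tag": family,
                    "motif": motif,
                    "position": pos + 1,
                }
            )
    carriers = pd.DataFrame(
        rows, columns=["protein_id", "locus_id", "family_tag", "motif", "position"]
    )
    return proteome, carriers


# ---------------------------------------------------------------------------
# Ready-made study: plants chosen so every pipeline stage has signal


CLUSTER_MOTIFS = ["AC", "AG", "AT", "AAG", "AAT", "ACAT"]
SCATTER_MOTIFS = ["AC", "AG", "CT", "AAC", "AGG", "AATC", "AACTG", "AACGTC"]


def study_spec(
    seed: int,
    n_contigs: int = 3,
    n_genes: int = 9,
    cluster_size: int = 8,
    n_scatter: int = 6,
    cluster2_size: int = 4,
) -> SyntheticSpec:
    """A spec whose planted SSRs give each gene a clustered hotspot
    (``cluster_size`` high-copy arrays inside one 900-bp span upstream of
    the gene), a weaker secondary cluster downstream (often reaching only
    the 95% threshold) plus scattered background arrays across the
    analysis region."""
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(n_contigs=n_contigs, n_genes=n_genes)
    plants: list[PlantSSR] = []
    # one exon_adjacent at most per gene: its admissible window is narrow
    scatter_classes = ["intron", "upstream", "downstream", "exon_adjacent", "intron", "downstream"]
    for gid in spec.gene_ids():
        for _ in range(cluster_size):
            motif = CLUSTER_MOTIFS[int(rng.integers(0, len(CLUSTER_MOTIFS)))]
            reps = int(rng.integers(8, 13)) if len(motif) <= 4 else int(rng.integers(4, 8))
            plants.append(PlantSSR(gid, "cluster", motif, reps))
        for _ in range(cluster2_size):
            motif = CLUSTER_MOTIFS[int(rng.integers(0, len(CLUSTER_MOTIFS)))]
            reps = int(rng.integers(8, 13)) if len(motif) <= 4 else int(rng.integers(4, 8))
            plants.append(PlantSSR(gid, "cluster2", motif, reps))
        for j in range(n_scatter):
            motif = SCATTER_MOTIFS[int(rng.integers(0, len(SCATTER_MOTIFS)))]
            if len(motif) <= 2:
                reps = int(rng.integers(8, 11))
            elif len(motif) <= 4:
                reps = int(rng.integers(5, 9))
            else:
                reps = int(rng.integers(3, 6))
            placement = scatter_classes[j % len(scatter_classes)]
            plants.append(PlantSSR(gid, placement, motif, reps))
    spec.ssr_plants = plants
    return spec


def clustered_placement_interval(
    gene: LocusAnnotation, flank: int, secondary: bool = False
) -> tuple[int, int]:
    """900-bp span used for hotspot clusters (fits inside a single 1-kb
    analysis window when the flank is untrimmed); the primary cluster sits
    upstream of the gene, the weaker secondary one downstream."""
    if secondary:
        return gene.end + 601, gene.end + 1500
    return gene.start - 1500, gene.start - 601


def generate_study(
    seed: int, **spec_kwargs
) -> tuple[ContigSet, list[LocusAnnotation], TruthTable]:
    """Reference assembly for :func:`study_spec`."""
    return generate_reference(study_spec(seed, **spec_kwargs), seed)


def synthetic_labeled_family(
    n_loci: int,
    per_locus: int,
    seed: int,
    family_tag: str = "WRKY",
    informative: bool = True,
):
    """Labeled SSR sets with a constructed class signal, for RF tests.

    Positives carry systematically higher repeat counts and window z than
    negatives when ``informative``; with ``informative=False`` features are
    exchangeable between classes (label-permutation sanity check).
    """
    from .ml_prioritization import LabeledSSR, featurize
    from .ssr_mining import SSRRecord

    rng = np.random.default_rng(seed)
    items = []
    counter = 0
    for li in range(n_loci):
        locus_id = f"L{li:03d}"
        for _ in range(per_locus):
            positive = rng.random() < 0.5
            if informative and positive:
                repeats = int(rng.integers(10, 16))
                z = float(rng.normal(3.0, 0.4))
            elif informative:
                repeats = int(rng.integers(4, 8))
                z = float(rng.normal(0.5, 0.4))
            else:
                repeats = int(rng.integers(4, 16))
                z = float(rng.normal(1.5, 1.0))
            k = int(rng.integers(2, 7))
            motif = "".join(rng.choice(BASES, size=k))
            counter += 1
            start = 1000 + counter * 200
            ssr = SSRRecord(
                contig_id="contig1",
                start=start,
                end=start + k * repeats - 1,
                motif=motif,
                k=k,
                repeats=repeats,
                ssr_id=f"s{counter:04d}",
                locus_id=locus_id,
                distance_to_locus=int(rng.integers(0, 4500)),
            )
            item = LabeledSSR(ssr, family_tag, "positive" if positive else "negative")
            featurize(item, window_z=z)
            items.append(item)
    return items
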
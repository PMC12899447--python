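"""End-to-end orchestration: mine → density/Z → permutation → hotspots →
select/filter → (optional RF per family) → panel → primers → e-PCR → PIC.

Every run is deterministic given (inputs, config, seed); per-locus
permutation streams are derived from the run seed and the locus index.
Stage outputs are TSV/JSON files in the run directory, each carrying a
header comment with the package version, seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidate_selection import (
    RankedCandidate,
    build_final_panel,
    filter_to_hotspots,
    panel_frame,
    panel_summaries,
    rank_candidates,
    structural_filter,
)
from .genome_io import ContigSet, load_contigs, load_locus_table
from .hotspot_stats import locus_hotspots
from .insilico_pcr import enumerate_amplicons, multigenome_summary, virtual_gel
from .ml_prioritization import (
    ablation_compare,
    baseline_select,
    featurize,
    label_family_ssrs,
    ml_select,
    train_rf,
)
from .primer_design import PrimerConstraints, design_for_ssrs
from .ssr_mining import mine_locus, read_catalogue, write_catalogue

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reference_fasta: str = ""
    locus_table: str = ""
    gff: str | None = None
    motif_yaml: str | None = None
    cultivar_fastas: dict[str, str] = field(default_factory=dict)
    flank: int = 5000
    window_size: int = 1000
    offsets: tuple[int, ...] = (0, 500)
    B: int = 1000
    levels: tuple[int, ...] = (95, 99)
    rank_cap: int = 100
    panel_cap: int = 5
    prob_cutoff: float = 0.70
    primer_flank: int = 200
    primer_min_size: int = 18
    primer_max_size: int = 25
    primer_min_tm: float = 50.0
    primer_max_tm: float = 65.0
    primer_min_gc: float = 35.0
    primer_max_gc: float = 65.0
    product_min: int = 100
    product_max: int = 400
    epcr_max_len: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("offsets", "levels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def primer_constraints(self) -> PrimerConstraints:
        return PrimerConstraints(
            min_size=self.primer_min_size,
            max_size=self.primer_max_size,
            min_tm=self.primer_min_tm,
            max_tm=self.primer_max_tm,
            min_gc=self.primer_min_gc,
            max_gc=self.primer_max_gc,
            product_range=(self.product_min, self.product_max),
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.md5(blob).hexdigest()[:10]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ssrscout {__version__} seed={config.seed} config={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, outdir: str | Path, resume: bool = False) -> dict:
    """Run every stage, returning a summary dict of key counts and paths.

    With ``resume=True`` the SSR catalogue is reloaded from a previous run
    directory instead of being re-mined.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.B < 100:
        logger.warning("B=%d is small; permutation thresholds will be coarse", config.B)

    contigs = load_contigs(config.reference_fasta)
    loci = load_locus_table(config.locus_table)
    loci_by_id = {l.locus_id: l for l in loci}
    if config.gff:
        from .genome_io import load_loci

        gff_loci, _ = load_loci(config.gff, [l.locus_id for l in loci])
        for gl in gff_loci:
            if gl.locus_id in loci_by_id:
                loci_by_id[gl.locus_id].exons = gl.exons

    # --- stage: mine -------------------------------------------------------
    cat_path = out / "ssr_catalogue.tsv"
    if resume and cat_path.exists():
        records = read_catalogue(cat_path)
        ssrs_by_locus = {}
        for r in records:
            ssrs_by_locus.setdefault(r.locus_id, []).append(r)
        logger.info("resume: reloaded %d SSRs from %s", len(records), cat_path)
    else:
        ssrs_by_locus = {
            l.locus_id: mine_locus(contigs, l, config.flank) for l in loci
        }
        all_records = [r for recs in ssrs_by_locus.values() for r in recs]
        write_catalogue(all_records, cat_path)

    # --- stage: density / permutation / hotspots ---------------------------
    from .genome_io import extract_region

    hotspot_rows = []
    profiles = {}
    calls_by_locus = {}
    for i, locus in enumerate(loci):
        region, _ = extract_region(contigs, locus, config.flank)
        rng = np.random.default_rng([config.seed, i])
        profile, null, calls = locus_hotspots(
            ssrs_by_locus.get(locus.locus_id, []),
            region,
            window_size=config.window_size,
            offsets=config.offsets,
            B=config.B,
            seed=rng,
        )
        profiles[locus.locus_id] = profile
        calls_by_locus[locus.locus_id] = calls
        if null is None:
            continue
        for level in config.levels:
            for h in calls.get(level, []):
                hotspot_rows.append(
                    {
                        "locus_id": h.locus_id,
                        "contig": h.contig_id,
                        "start": h.start,
                        "end": h.end,
                        "level": h.level,
                        "n_windows": h.n_windows,
                        "max_z": h.max_z,
                        "q95": null.thresholds[95],
                        "q99": null.thresholds[99],
                        "seed": config.seed,
                        "B": config.B,
                    }
                )
    hotspot_df = pd.DataFrame(
        hotspot_rows,
        columns=[
            "locus_id", "contig", "start", "end", "level", "n_windows",
            "max_z", "q95", "q99", "seed", "B",
        ],
    )
    _write_table(hotspot_df, out / "hotspots.tsv", config)

    # --- stage: hotspot-restricted selection & panel -----------------------
    ranked_by_locus: dict[str, list[RankedCandidate]] = {}
    for locus in loci:
        calls = calls_by_locus[locus.locus_id]
        pairs = filter_to_hotspots(
            ssrs_by_locus.get(locus.locus_id, []), calls.get(99, []), calls.get(95, [])
        )
        if not pairs:
            continue
        hotspot_of = {s.key(): h for s, h in pairs}
        kept = structural_filter([s for s, _ in pairs])
        ranked = rank_candidates(kept, locus, cap=config.rank_cap, hotspots=hotspot_of)
        if ranked:
            ranked_by_locus[locus.locus_id] = ranked
    panel = build_final_panel(ranked_by_locus, panel_cap=config.panel_cap)
    panel_df = panel_frame(panel, loci_by_id, flank=config.flank)
    _write_table(panel_df, out / "final_panel.tsv", config)
    if not panel_df.empty:
        summaries = panel_summaries(panel_df)
        with open(out / "panel_summary.json", "w") as fh:
            json.dump(
                {
                    "distance_stats": summaries["distance_stats"],
                    "region_class_counts": summaries["region_class_counts"],
                    "strand_proportions": summaries["strand_proportions"],
                    "correlations": summaries["correlations"],
                },
                fh,
                indent=2,
                default=float,
            )

    # --- stage: per-family random forest (optional) ------------------------
    ablation: dict[str, dict] = {}
    families = sorted({l.family_tag for l in loci if l.family_tag})
    for fam in families:
        fam_loci = [l for l in loci if l.family_tag == fam]
        fam_ssrs = [s for l in fam_loci for s in ssrs_by_locus.get(l.locus_id, [])]
        h99 = [h for l in fam_loci for h in calls_by_locus[l.locus_id].get(99, [])]
        h95 = [h for l in fam_loci for h in calls_by_locus[l.locus_id].get(95, [])]
        labeled = label_family_ssrs(fam_ssrs, fam, h95, h99)
        for item in labeled:
            featurize(item, profile=profiles.get(item.ssr.locus_id))
        model = train_rf(labeled, seed=config.seed)
        if model is None:
            logger.info("family %s: RF skipped, heuristic path only", fam)
            continue
        ml_sel = ml_select(labeled, prob_cutoff=config.prob_cutoff, panel_cap=config.panel_cap)
        base_sel = baseline_select(labeled, panel_cap=config.panel_cap)
        ml_res, base_res, uplift = ablation_compare(ml_sel, base_sel)
        ablation[fam] = {
            "heldout_accuracy": model.heldout_accuracy,
            "importances": model.importances,
            "ml": {"n_selected": ml_res.n_selected, "n_positive": ml_res.n_positive,
                   "positive_rate": ml_res.positive_rate},
            "baseline": {"n_selected": base_res.n_selected, "n_positive": base_res.n_positive,
                         "positive_rate": base_res.positive_rate},
            "uplift": uplift,
            "hyperparameters": {"n_trees": 1000, "mtry": 3, "probability": True},
            "seed": config.seed,
        }
    with open(out / "ablation.json", "w") as fh:
        json.dump(ablation, fh, indent=2, default=float)

    # --- stage: primers ----------------------------------------------------
    panel_ssrs = [c.ssr for cands in panel.values() for c in cands]
    pairs = design_for_ssrs(
        contigs, panel_ssrs, config.primer_constraints(), flank=config.primer_flank
    )
    primer_df = pd.DataFrame(
        [
            {
                "primer_id": p.primer_id,
                "ssr_id": p.target_ssr_id,
                "forward": p.forward,
                "reverse": p.reverse,
                "tm_f": round(p.tm_f, 2),
                "tm_r": round(p.tm_r, 2),
                "gc_f": round(p.gc_f, 1),
                "gc_r": round(p.gc_r, 1),
                "expected_product": p.expected_product,
                "penalty": round(p.penalty, 3),
            }
            for p in pairs
        ],
        columns=[
            "primer_id", "ssr_id", "forward", "reverse", "tm_f", "tm_r",
            "gc_f", "gc_r", "expected_product", "penalty",
        ],
    )
    _write_table(primer_df, out / "primers.tsv", config)

    # --- stage: in silico PCR + PIC ----------------------------------------
    genomes: dict[str, ContigSet] = {"reference": contigs}
    for label, path in config.cultivar_fastas.items():
        genomes[label] = load_contigs(path)
    hits_by_genome = {}
    hit_rows = []
    for label, genome in genomes.items():
        hits = []
        for pair in pairs:
            hits.extend(
                enumerate_amplicons(genome, pair, config.epcr_max_len, genome_label=label)
            )
        hits_by_genome[label] = hits
        for h in hits:
            hit_rows.append(
                {
                    "primer_id": h.primer_id,
                    "genome": label,
                    "contig": h.contig_id,
                    "start": h.start,
                    "end": h.end,
                    "length": h.length,
                    "orientation": h.orientation,
                }
            )
    _write_table(
        pd.DataFrame(
            hit_rows,
            columns=["primer_id", "genome", "contig", "start", "end", "length", "orientation"],
        ),
        out / "epcr_hits.tsv",
        config,
    )
    summary = multigenome_summary(hits_by_genome, [p.primer_id for p in pairs])
    if not summary.empty:
        flat = summary.copy()
        flat["amplicons_per_genome"] = flat["amplicons_per_genome"].map(json.dumps)
        flat["allele_sizes"] = flat["allele_sizes"].map(lambda v: ",".join(map(str, v)))
        _write_table(flat, out / "pic_summary.tsv", config)
    _write_table(virtual_gel(hits_by_genome), out / "virtual_gel.tsv", config)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_loci": len(loci),
        "n_ssrs_mined": int(sum(len(v) for v in ssrs_by_locus.values())),
        "n_hotspot_regions": int(len(hotspot_df)),
        "n_loci_in_panel": int(len(panel)),
        "n_panel_ssrs": int(len(panel_df)),
        "n_primer_pairs": int(len(pairs)),
        "n_polymorphic_primers": int((summary["pic"] > 0).sum()) if not summary.empty else 0,
        "families_with_rf": sorted(ablation),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
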
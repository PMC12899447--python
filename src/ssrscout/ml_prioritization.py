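"""Random-forest prioritization of hotspot SSRs and its ablation analysis.

Within each protein family (CHI, LRR, NAC, WRKY, PRX, ...), SSRs that
overlap a 99%-level hotspot form the positive class and SSRs inside a
hotspot that never reaches the 99% level form the negative class; SSRs
outside all hotspots are excluded. A 1000-tree random forest (three
variables per split, probability output, impurity importances) is fit on a
stratified 70/30 split and scored on every family SSR. The ML selection
keeps, per locus, the top five candidates with prob_pos >= 0.70 ordered by
(probability desc, repeats desc, distance asc); the heuristic baseline
ranks by (repeats desc, distance asc) alone. The ablation metric is the
positive rate among selected candidates and the uplift is the ML rate
minus the baseline rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .candidate_selection import STRUCTURAL_MIN_REPEATS
from .hotspot_stats import DensityProfile, HotspotRegion
from .ssr_mining import SSRRecord

logger = logging.getLogger(__name__)

N_TREES = 1000
MTRY = 3
PROB_CUTOFF = 0.70
PANEL_CAP = 5
MIN_CLASS_SIZE = 10

FEATURE_NAMES = [
    "k",
    "repeats",
    "length",
    "distance",
    "motif_gc",
    "window_z",
    "z_missing",
    "strand",
]


@dataclass
class LabeledSSR:
    ssr: SSRRecord
    family_tag: str
    label: str  # "positive" | "negative"
    features: dict[str, float] = field(default_factory=dict)
    prob_pos: float | None = None


@dataclass
class AblationResult:
    strategy: str
    n_selected: int
    n_positive: int
    positive_rate: float
    per_locus_rates: dict[str, float] = field(default_factory=dict)


def _overlaps_any(ssr: SSRRecord, regions: Sequence[HotspotRegion]) -> bool:
    return any(
        ssr.contig_id == r.contig_id and not (ssr.end < r.start or ssr.start > r.end)
        for r in regions
    )


def label_family_ssrs(
    ssrs: Sequence[SSRRecord],
    family_tag: str,
    hotspots95: Sequence[HotspotRegion],
    hotspots99: Sequence[HotspotRegion],
) -> list[LabeledSSR]:
    """Label family SSRs positive/negative by hotspot overlap.

    positive: overlaps a 99%-level region; negative: overlaps a hotspot
    (95%-level) but no 99%-level one; outside all hotspots: excluded.
    """
    labeled = []
    for ssr in ssrs:
        if _overlaps_any(ssr, hotspots99):
            labeled.append(LabeledSSR(ssr, family_tag, "positive"))
        elif _overlaps_any(ssr, hotspots95):
            labeled.append(LabeledSSR(ssr, family_tag, "negative"))
    classes = {l.label for l in labeled}
    if labeled and len(classes) < 2:
        logger.warning(
            "family %s has a single class (%s); RF training will be skipped",
            family_tag,
            classes.pop(),
        )
    return labeled


def featurize(
    item: LabeledSSR,
    profile: DensityProfile | None = None,
    window_z: float | None = None,
) -> dict[str, float]:
    """Default numeric feature vector for one SSR.

    window_z is the maximum observed z among windows containing the SSR
    start (0 with a mask flag when z is undefined for the locus).
    """
    ssr = item.ssr
    z = window_z
    if z is None and profile is not None and profile.z is not None:
        zs = [
            float(profile.z[i])
            for i, w in enumerate(profile.grid.windows)
            if w.start <= ssr.start <= w.end
        ]
        z = max(zs) if zs else None
    gc = (ssr.motif.count("G") + ssr.motif.count("C")) / len(ssr.motif)
    feats = {
        "k": float(ssr.k),
        "repeats": float(ssr.repeats),
        "length": float(ssr.k * ssr.repeats),
        "distance": float(ssr.distance_to_locus),
        "motif_gc": gc,
        "window_z": float(z) if z is not None else 0.0,
        "z_missing": 0.0 if z is not None else 1.0,
        "strand": 1.0 if ssr.strand == "+" else 0.0,
    }
    item.features = feats
    return feats


@dataclass
class RFModel:
    model: RandomForestClassifier
    feature_names: list[str]
    heldout_accuracy: float
    importances: dict[str, float]
    seed: int


def train_rf(
    labeled: Sequence[LabeledSSR], seed: int = 0, min_class_size: int = MIN_CLASS_SIZE
) -> RFModel | None:
    """Fit the family random forest on a stratified 70/30 split.

    Returns None (skip signal) when a class is missing or too small.
    After fitting, prob_pos is written onto *every* labeled SSR, training
    items included (scores on training items are optimistically biased;
    selection uses them the same way for all candidates).
    """
    y = np.array([1 if l.label == "positive" else 0 for l in labeled])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos < min_class_size or n_neg < min_class_size:
        logger.warning(
            "RF skipped: class sizes pos=%d neg=%d below %d", n_pos, n_neg, min_class_size
        )
        return None
    for item in labeled:
        if not item.features:
            featurize(item)
    names = list(labeled[0].features)
    X = np.array([[l.features[f] for f in names] for l in labeled])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.30, stratify=y, random_state=seed
    )
    rf = RandomForestClassifier(
        n_estimators=N_TREES,
        max_features=MTRY,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X_tr, y_tr)
    acc = float((rf.predict(X_te) == y_te).mean())
    importances = dict(zip(names, rf.feature_importances_.tolist()))
    pos_col = list(rf.classes_).index(1)
    probs = rf.predict_proba(X)[:, pos_col]
    for item, p in zip(labeled, probs):
        item.prob_pos = float(p)
    logger.info("RF held-out accuracy %.3f (pos=%d neg=%d)", acc, n_pos, n_neg)
    return RFModel(rf, names, acc, importances, seed)


def _passes_structural(ssr: SSRRecord) -> bool:
    return ssr.repeats >= STRUCTURAL_MIN_REPEATS[ssr.k]


def ml_select(
    scored: Sequence[LabeledSSR],
    prob_cutoff: float = PROB_CUTOFF,
    panel_cap: int = PANEL_CAP,
    apply_structural: bool = True,
) -> list[LabeledSSR]:
    """Per-locus top-``panel_cap`` by (prob_pos desc, repeats desc,
    distance asc), restricted to prob_pos >= cutoff (structural filter
    applied first)."""
    pool = [
        s
        for s in scored
        if s.prob_pos is not None
        and s.prob_pos >= prob_cutoff
        and (not apply_structural or _passes_structural(s.ssr))
    ]
    by_locus: dict[str, list[LabeledSSR]] = {}
    for s in pool:
        by_locus.setdefault(s.ssr.locus_id, []).append(s)
    selected = []
    for locus_id in sorted(by_locus):
        ranked = sorted(
            by_locus[locus_id],
            key=lambda s: (-s.prob_pos, -s.ssr.repeats, s.ssr.distance_to_locus, s.ssr.start),
        )
        selected.extend(ranked[:panel_cap])
    return selected


def baseline_select(
    candidates: Sequence[LabeledSSR],
    panel_cap: int = PANEL_CAP,
    apply_structural: bool = True,
) -> list[LabeledSSR]:
    """Heuristic per-locus top-``panel_cap`` by (repeats desc, distance asc)."""
    pool = [
        s for s in candidates if not apply_structural or _passes_structural(s.ssr)
    ]
    by_locus: dict[str, list[LabeledSSR]] = {}
    for s in pool:
        by_locus.setdefault(s.ssr.locus_id, []).append(s)
    selected = []
    for locus_id in sorted(by_locus):
        ranked = sorted(
            by_locus[locus_id],
            key=lambda s: (-s.ssr.repeats, s.ssr.distance_to_locus, s.ssr.start),
        )
        selected.extend(ranked[:panel_cap])
    return selected


def positive_rate(n_positive: int, n_selected: int) -> float:
    """Fraction of selected candidates that are hotspot-positive."""
    if n_selected < 1:
        return float("nan")
    if not 0 <= n_positive <= n_selected:
        raise ValueError("n_positive must lie in [0, n_selected]")
    return n_positive / n_selected


def _result(strategy: str, selection: Sequence[LabeledSSR]) -> AblationResult:
    n_sel = len(selection)
    n_pos = sum(1 for s in selection if s.label == "positive")
    per_locus: dict[str, list[int]] = {}
    for s in selection:
        per_locus.setdefault(s.ssr.locus_id, []).append(1 if s.label == "positive" else 0)
    rates = {loc: sum(v) / len(v) for loc, v in per_locus.items()}
    return AblationResult(strategy, n_sel, n_pos, positive_rate(n_pos, n_sel), rates)


def ablation_compare(
    ml_selection: Sequence[LabeledSSR], baseline_selection: Sequence[LabeledSSR]
) -> tuple[AblationResult, AblationResult, float]:
    """Overall and per-locus positive rates for both strategies, plus the
    uplift (ml overall rate − baseline overall rate)."""
    ml_res = _result("ml", ml_selection)
    base_res = _result("baseline", baseline_selection)
    uplift = ml_res.positive_rate - base_res.positive_rate
    return ml_res, base_res, uplift
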
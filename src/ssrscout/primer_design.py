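"""SSR-flanking primer design and constraint validation.

Templates are the SSR ± 200 bp; pairs must satisfy length 18-25 nt,
melting temperature 50-65 °C, GC content 35-65 % and an expected product
of 100-400 bp spanning the repeat tract. Candidate primers are enumerated
exhaustively over both flanks, scored with a primer3-style penalty
(deviation from 60 °C and 20 nt, pair Tm difference), and the
lowest-penalty compliant pair is returned. Tm uses Biopython's
nearest-neighbor model by default (Wallace rule available via config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp, gc_fraction

from .genome_io import ContigSet, reverse_complement
from .ssr_mining import SSRRecord

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 200
MIN_USABLE_FLANK = 50


@dataclass(frozen=True)
class PrimerConstraints:
    min_size: int = 18
    max_size: int = 25
    min_tm: float = 50.0
    max_tm: float = 65.0
    min_gc: float = 35.0
    max_gc: float = 65.0
    product_range: tuple[int, int] = (100, 400)
    tm_method: str = "nn"  # "nn" (nearest-neighbor) or "wallace"
    opt_size: int = 20
    opt_tm: float = 60.0

    def tm(self, seq: str) -> float:
        if self.tm_method == "wallace":
            return float(MeltingTemp.Tm_Wallace(seq))
        return float(MeltingTemp.Tm_NN(seq))


@dataclass
class PrimerPair:
    primer_id: str
    forward: str
    reverse: str  # 5'->3' on the opposite strand
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    expected_product: int
    target_ssr_id: str = ""
    penalty: float = 0.0
    # template-local 1-based coordinates of the binding footprints
    forward_start: int = 0
    reverse_end: int = 0


def extract_template(
    contigs: ContigSet, ssr: SSRRecord, flank: int = DEFAULT_FLANK
) -> tuple[str, tuple[int, int]] | None:
    """SSR ± flank template and the repeat interval in template-local
    coordinates (1-based). Returns None (logged) when less than 50 bp of
    usable flank remains on either side after trimming to the contig."""
    contig_len = contigs.lengths.get(ssr.contig_id)
    if contig_len is None:
        raise KeyError(f"SSR {ssr.ssr_id}: unknown contig {ssr.contig_id}")
    if ssr.start < 1 or ssr.end > contig_len:
        raise ValueError(f"SSR {ssr.ssr_id} outside contig {ssr.contig_id}")
    t_start = max(1, ssr.start - flank)
    t_end = min(contig_len, ssr.end + flank)
    left = ssr.start - t_start
    right = t_end - ssr.end
    if left < MIN_USABLE_FLANK or right < MIN_USABLE_FLANK:
        logger.warning(
            "SSR %s skipped: usable flank %d/%d bp < %d",
            ssr.ssr_id,
            left,
            right,
            MIN_USABLE_FLANK,
        )
        return None
    template = contigs.fetch(ssr.contig_id, t_start, t_end)
    target = (ssr.start - t_start + 1, ssr.end - t_start + 1)
    return template, target


def _primer_penalty(seq: str, tm: float, c: PrimerConstraints) -> float:
    return abs(tm - c.opt_tm) + 0.5 * abs(len(seq) - c.opt_size)


def _candidates(
    template: str, lo: int, hi: int, c: PrimerConstraints, reverse: bool, limit: int = 60
):
    """Compliant single-primer candidates binding within template[lo:hi]
    (0-based slice bounds), best-penalty first."""
    found = []
    for size in range(c.min_size, c.max_size + 1):
        for s in range(lo, hi - size + 1):
            sub = template[s : s + size]
            if "N" in sub:
                continue
            seq = reverse_complement(sub) if reverse else sub
            gc = 100.0 * gc_fraction(seq)
            if not (c.min_gc <= gc <= c.max_gc):
                continue
            tm = c.tm(seq)
            if not (c.min_tm <= tm <= c.max_tm):
                continue
            found.append((_primer_penalty(seq, tm, c), s, size, seq, tm, gc))
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    return found[:limit]


def design_pair(
    template: str,
    target: tuple[int, int],
    constraints: PrimerConstraints | None = None,
    primer_id: str = "",
    target_ssr_id: str = "",
) -> PrimerPair | None:
    """Lowest-penalty compliant primer pair whose product spans the target.

    Forward primers are enumerated upstream of the target, reverse primers
    (reverse-complemented) downstream; None when no compliant pair exists.
    """
    c = constraints or PrimerConstraints()
    t_start, t_end = target  # 1-based inclusive
    fwd = _candidates(template, 0, t_start - 1, c, reverse=False)
    rev = _candidates(template, t_end, len(template), c, reverse=True)
    best: tuple[float, PrimerPair] | None = None
    lo, hi = c.product_range
    for pf, fs, flen, fseq, ftm, fgc in fwd:
        for pr, rs, rlen, rseq, rtm, rgc in rev:
            product = (rs + rlen) - fs  # template span, bp
            if not (lo <= product <= hi):
                continue
            penalty = pf + pr + abs(ftm - rtm)
            if best is None or penalty < best[0]:
                best = (
                    penalty,
                    PrimerPair(
                        primer_id=primer_id,
                        forward=fseq,
                        reverse=rseq,
                        tm_f=ftm,
                        tm_r=rtm,
                        gc_f=fgc,
                        gc_r=rgc,
                        expected_product=product,
                        target_ssr_id=target_ssr_id,
                        penalty=penalty,
                        forward_start=fs + 1,
                        reverse_end=rs + rlen,
                    ),
                )
    return best[1] if best else None


def validate_pair(
    pair: PrimerPair, constraints: PrimerConstraints | None = None
) -> list[str]:
    """Check a pair against the design constraints; returns violations
    (empty list = valid). GC is recomputed exactly; Tm with the configured
    method."""
    c = constraints or PrimerConstraints()
    violations = []
    for name, seq in (("forward", pair.forward), ("reverse", pair.reverse)):
        if not (c.min_size <= len(seq) <= c.max_size):
            comparator = "<" if len(seq) < c.min_size else ">"
            bound = c.min_size if len(seq) < c.min_size else c.max_size
            violations.append(f"{name}: length {comparator} {bound}")
        gc = 100.0 * gc_fraction(seq)
        if not (c.min_gc <= gc <= c.max_gc):
            violations.append(f"{name}: GC {gc:.1f}% outside [{c.min_gc}, {c.max_gc}]")
        tm = c.tm(seq)
        if not (c.min_tm <= tm <= c.max_tm):
            violations.append(f"{name}: Tm {tm:.1f}C outside [{c.min_tm}, {c.max_tm}]")
    lo, hi = c.product_range
    if not (lo <= pair.expected_product <= hi):
        violations.append(f"product {pair.expected_product} bp outside [{lo}, {hi}]")
    return violations


def design_for_ssrs(
    contigs: ContigSet,
    ssrs,
    constraints: PrimerConstraints | None = None,
    flank: int = DEFAULT_FLANK,
    id_prefix: str = "AE",
) -> list[PrimerPair]:
    """Design one pair per SSR (skipping infeasible templates)."""
    pairs = []
    for i, ssr in enumerate(ssrs, start=1):
        tpl = extract_template(contigs, ssr, flank)
        if tpl is None:
            continue
        template, target = tpl
        pair = design_pair(
            template,
            target,
            constraints,
            primer_id=f"{id_prefix}{i:03d}",
            target_ssr_id=ssr.ssr_id,
        )
        if pair is not None:
            pairs.append(pair)
    return pairs
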
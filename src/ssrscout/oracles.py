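"""Independent brute-force reference implementations used for validation.

These deliberately naive routines recompute, by exhaustive enumeration,
quantities the optimized modules produce, so the two routes can be compared
on the same inputs. They are slow and must never replace the main
implementations.
"""

from __future__ import annotations

from .genome_io import ContigSet, reverse_complement
from .ssr_mining import (
    MAX_MOTIF,
    MIN_MOTIF,
    REPEAT_THRESHOLDS,
    SSRRecord,
    is_primitive,
)


def enumerate_ssrs_bruteforce(
    seq: str, region_offset: int = 0, contig_id: str = ""
) -> list[SSRRecord]:
    """Exhaustively enumerate every (start, k) pair and keep maximal,
    threshold-passing, minimal-period tandem runs.

    Same mathematical rule as :func:`ssrscout.ssr_mining.detect_ssrs`
    (per-base maximality, whole-copy truncation, N breaks runs), derived by
    direct per-start string comparison rather than run scanning.
    """
    n = len(seq)
    records = []
    for k in range(MIN_MOTIF, MAX_MOTIF + 1):
        thr = REPEAT_THRESHOLDS[k]
        for s in range(0, n - k * thr + 1):
            motif = seq[s : s + k]
            if "N" in motif or not is_primitive(motif):
                continue
            # left extendable by one base continuing the period?
            if s > 0 and seq[s - 1] != "N" and seq[s - 1] == seq[s + k - 1]:
                continue
            copies = 1
            while seq[s : s + (copies + 1) * k] == motif * (copies + 1):
                copies += 1
            if copies >= thr:
                records.append(
                    SSRRecord(
                        contig_id=contig_id,
                        start=s + 1 + region_offset,
                        end=s + k * copies + region_offset,
                        motif=motif,
                        k=k,
                        repeats=copies,
                    )
                )
    records.sort()
    return records


def find_sites_naive(genome: ContigSet, probe: str) -> list[tuple[str, int, str]]:
    """Character-by-character scan for exact probe / reverse-complement hits."""
    probe = probe.upper()
    rc = reverse_complement(probe)
    m = len(probe)
    sites = []
    for cid, seq in genome.entries.items():
        for s in range(len(seq) - m + 1):
            window = seq[s : s + m]
            if window == probe:
                sites.append((cid, s + 1, "+"))
            if window == rc:
                sites.append((cid, s + 1, "-"))
    return sites


def enumerate_amplicons_naive(
    genome: ContigSet, forward: str, reverse: str, max_len: int = 1000
) -> set[tuple[str, int, int, str]]:
    """Exhaustive pairwise-site amplicon enumeration.

    For both primer orientation combinations, pairs every plus-strand site
    of the upstream primer with every site of the downstream primer's
    reverse complement, keeping products whose downstream site starts at or
    after the upstream site and whose span is <= ``max_len``.

    Returns {(contig, start, end, orientation)}.
    """
    hits: set[tuple[str, int, int, str]] = set()
    for p1, p2, label in ((forward, reverse, "F/rc(R)"), (reverse, forward, "R/rc(F)")):
        p1 = p1.upper()
        rc2 = reverse_complement(p2.upper())
        for cid, seq in genome.entries.items():
            up = [
                s + 1
                for s in range(len(seq) - len(p1) + 1)
                if seq[s : s + len(p1)] == p1
            ]
            down = [
                s + 1
                for s in range(len(seq) - len(rc2) + 1)
                if seq[s : s + len(rc2)] == rc2
            ]
            for s1 in up:
                for s2 in down:
                    if s2 < s1:
                        continue
                    end = s2 + len(rc2) - 1
                    length = end - s1 + 1
                    if 0 < length <= max_len:
                        hits.add((cid, s1, end, label))
    return hits


def scan_motif_naive(protein: str, motif: str) -> list[int]:
    """Sliding character comparison for exact motif occurrences (1-based)."""
    return [
        i + 1
        for i in range(len(protein) - len(motif) + 1)
        if protein[i : i + len(motif)] == motif
    ]


def min_interval_distance_naive(
    a: tuple[int, int], b: tuple[int, int]
) -> int:
    """Per-base minimum distance between two inclusive integer intervals."""
    best = None
    for x in range(a[0], a[1] + 1):
        for y in range(b[0], b[1] + 1):
            d = abs(x - y)
            if best is None or d < best:
                best = d
    return int(best)


def merge_intervals_naive(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval union via a per-base coverage mask (bookended runs merge)."""
    if not intervals:
        return []
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    mask = [False] * (hi - lo + 1)
    for s, e in intervals:
        for i in range(s, e + 1):
            mask[i - lo] = True
    merged = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            merged.append((lo + i, lo + j))
            i = j + 1
        else:
            i += 1
    return merged
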
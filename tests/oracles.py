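"""Independent brute-force reference implementations.

These deliberately use the simplest possible all-pairs logic, sharing no
code path with the package's sorted/merged implementations, so agreement
on randomized instances is meaningful evidence of correctness.
"""

from __future__ import annotations

from hervlink.core import GenomicInterval
from hervlink.parclip import Peak


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def brute_intersect(A, B, min_overlap_bp=1):
    flags = []
    pairs = []
    for i, a in enumerate(A):
        hit = False
        for j, b in enumerate(B):
            if overlap_bp(a, b) >= min_overlap_bp:
                hit = True
                pairs.append((i, j))
        flags.append(hit)
    return flags, sorted(pairs)


def brute_stringent(rep1, rep2, clusters, rpkm_cutoff=10.0):
    out = []
    for p in rep1:
        in_rep2 = any(overlap_bp(p.interval, q.interval) >= 1 for q in rep2)
        in_clust = any(overlap_bp(p.interval, c.interval) >= 1 for c in clusters)
        if in_rep2 and in_clust and p.rpkm > rpkm_cutoff:
            out.append(p.interval.id)
    return out


def brute_family_fraction(peaks: list[Peak], repeats):
    fams = {r.family for r in repeats}
    out = {}
    for fam in fams:
        members = [r.interval for r in repeats if r.family == fam]
        n = sum(
            1
            for p in peaks
            if any(overlap_bp(p.interval, m) >= 1 for m in members)
        )
        out[fam] = n / len(peaks)
    return out


def brute_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return float("inf")
    if overlap_bp(a, b) > 0:
        return 0.0
    return float(max(0, max(a.start, b.start) - min(a.end, b.end)))


def brute_count_within(enhancers, features, window_bp):
    n = 0
    for f in features:
        if any(brute_distance(f.interval, e) <= window_bp for e in enhancers):
            n += 1
    return n
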
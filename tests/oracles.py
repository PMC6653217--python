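"""Independent brute-force oracles shared by the super-enhancer tests."""


def brute_force_stitch(peaks, stitch_bp):
    """O(n^2) repeated pairwise merge until fixpoint."""
    regions = [
        [p.interval.chrom, p.interval.start, p.interval.end, float(p.tag_count), 1]
        for p in peaks
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= stitch_bp:
                    regions[i] = [a[0], min(a[1], b[1]), max(a[2], b[2]),
                                  a[3] + b[3], a[4] + b[4]]
                    del regions[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((tuple(r) for r in regions), key=lambda r: (r[0], r[1]))


def brute_force_cutoff(signals):
    """Exhaustive scan over every one-rank secant of the scaled curve."""
    s = sorted(signals)
    n = len(s)
    if s[-1] == s[0]:
        return float("inf")
    for i in range(n - 1):
        x0, x1 = i / (n - 1), (i + 1) / (n - 1)
        y0 = (s[i] - s[0]) / (s[-1] - s[0])
        y1 = (s[i + 1] - s[0]) / (s[-1] - s[0])
        if (y1 - y0) / (x1 - x0) > 1 + 1e-12:
            return s[i]
    return float("inf")
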
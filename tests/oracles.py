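"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library's own code paths: ORF enumeration by
scanning every ATG..stop span, clustering via a memoized recursive LCS, and
SNP calling by a plain-text per-column pileup counter.
"""
import functools

from bivirome._codons import STOP_CODONS, revcomp


def brute_force_orfs(contig, min_codons):
    """All maximal ATG..stop spans plus ATG..edge open ranges, six frames."""
    out = set()
    L = len(contig)
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        for frame in range(3):
            codons = [(p, seq[p:p + 3]) for p in range(frame, len(seq) - 2, 3)]
            stops = [p for p, c in codons if c in STOP_CODONS]
            atgs = [p for p, c in codons if c == "ATG"]
            prev_stop = -1
            for stop in stops:
                starts = [a for a in atgs if prev_stop < a < stop]
                if starts:
                    a = min(starts)
                    if (stop - a) // 3 >= min_codons:
                        s, e = a, stop + 3
                        if strand == "-":
                            s, e = L - e, L - s
                        out.add((strand, s, e, True))
                prev_stop = stop
            open_starts = [a for a in atgs if a > (stops[-1] if stops else -1)]
            if open_starts:
                a = min(open_starts)
                end = a + 3 * ((len(seq) - a) // 3)
                if (end - a) // 3 >= min_codons:
                    s, e = a, end
                    if strand == "-":
                        s, e = L - e, L - s
                    out.add((strand, s, e, False))
    return out


def _lcs(a, b):
    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 or j == 0:
            return 0
        if a[i - 1] == b[j - 1]:
            return rec(i - 1, j - 1) + 1
        return max(rec(i - 1, j), rec(i, j - 1))
    out = rec(len(a), len(b))
    rec.cache_clear()
    return out


def brute_force_clusters(seqs, threshold):
    """Greedy longest-first cluster count with recursive-LCS identity."""
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    reps = []
    for i in order:
        for r in reps:
            ident = _lcs(seqs[i], seqs[r]) / min(len(seqs[i]), len(seqs[r]))
            if ident >= threshold:
                break
        else:
            reps.append(i)
    return len(reps)


def brute_force_calls(sam_text, reference, min_freq=0.01, min_cov=50,
                      min_count=5, min_context_q=30.0):
    """Per-column pileup counting over plain SAM text (full-match CIGARs)."""
    L = len(reference)
    counts, qsum = {}, {}
    cov = [0] * L
    for line in sam_text.splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        if int(f[1]) & 0x904:  # unmapped/secondary/supplementary
            continue
        start = int(f[3]) - 1
        seq, quals = f[9], f[10]
        assert f[5] == f"{len(seq)}M"
        for off, base in enumerate(seq):
            rpos = start + off
            cov[rpos] += 1
            counts[(rpos, base)] = counts.get((rpos, base), 0) + 1
            lo, hi = max(0, off - 2), min(len(seq) - 1, off + 2)
            ctx = [ord(q) - 33 for q in quals[lo:hi + 1]]
            qsum[(rpos, base)] = qsum.get((rpos, base), 0.0) + \
                sum(ctx) / len(ctx)
    out = set()
    for (rpos, base), n in counts.items():
        if base == reference[rpos] or cov[rpos] < min_cov or n < min_count:
            continue
        if n / cov[rpos] < min_freq or qsum[(rpos, base)] / n < min_context_q:
            continue
        out.add((rpos, base, cov[rpos], n))
    return out
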
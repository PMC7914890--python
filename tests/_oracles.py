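"""Independent brute-force oracles used by the test suite only."""
from __future__ import annotations

from stablefrag.cluster import endpoint_distance


def oracle_overlap_cluster(products, tolerance):
    """Exhaustive greedy-max enumeration for overlap clustering: at every
    round, rescan every unrepresented product's coverage from scratch."""
    unrep = list(range(len(products)))
    reps = []
    while unrep:
        best, best_key, best_cov = None, None, None
        for i in unrep:
            cov = [
                j for j in unrep
                if endpoint_distance(products[i], products[j]) <= tolerance
            ]
            key = (
                -len(cov),
                -products[i].total_count,
                products[i].chrom,
                products[i].start0,
                products[i].end0,
                products[i].strand,
            )
            if best is None or key < best_key:
                best, best_key, best_cov = i, key, cov
        reps.append((best, tuple(sorted(best_cov))))
        unrep = [j for j in unrep if j not in best_cov]
    return reps
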
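"""Independent reference implementations used only as test oracles.

Deliberately written as plain, direct enumerations — no shared code with
the package — so agreement between the two is evidence of correctness, not
of common ancestry.
"""

from itertools import groupby

import numpy as np

MB = 1_000_000


# ---------------------------------------------------------------------------
# scar counting by direct maximal-run enumeration


def oracle_loh(rows, loh_min_len=15 * MB, bridge=3 * MB, exclude_whole=True):
    """rows: sorted (start, end, n_major, n_minor) for ONE chromosome."""
    lo_cov = min(r[0] for r in rows)
    hi_cov = max(r[1] for r in rows)
    count = 0
    runs = []
    # label each segment; build runs left to right
    labels = []
    for s, e, ma, mi in rows:
        if mi == 0 and ma >= 1:
            labels.append("L")
        elif ma == 0 and mi == 0:
            labels.append("H")
        else:
            labels.append("N")
    i = 0
    n = len(rows)
    while i < n:
        if labels[i] != "L":
            i += 1
            continue
        j = i
        last_l = i
        while j + 1 < n:
            gap = rows[j + 1][0] - rows[j][1]
            if gap >= bridge or labels[j + 1] == "N":
                break
            j += 1
            if labels[j] == "L":
                last_l = j
        length = sum(rows[k][1] - rows[k][0] for k in range(i, last_l + 1) if labels[k] == "L")
        runs.append((rows[i][0], rows[last_l][1], length))
        i = j + 1
    for start, end, length in runs:
        whole = start <= lo_cov and end >= hi_cov
        if length > loh_min_len and not (whole and exclude_whole):
            count += 1
    return count


def oracle_lst(rows, cen, lst_min=10 * MB, smooth=3 * MB):
    """rows for one chromosome; cen = (centromere_start, centromere_end)."""
    count = 0
    for arm_lo, arm_hi in ((0, cen[0]), (cen[1], 10**12)):
        segs = []
        for s, e, ma, mi in rows:
            cs, ce = max(s, arm_lo), min(e, arm_hi)
            if cs < ce:
                segs.append([cs, ce, (ma, mi)])
        while True:
            short = [k for k, sg in enumerate(segs) if sg[1] - sg[0] < smooth]
            if not short:
                break
            k = min(short, key=lambda q: (segs[q][1] - segs[q][0], q))
            segs.pop(k)
            if 0 < k < len(segs) and segs[k - 1][2] == segs[k][2]:
                segs[k - 1][1] = segs[k][1]
                segs.pop(k)
        for a, b in zip(segs, segs[1:]):
            if (
                a[2] != b[2]
                and a[1] - a[0] >= lst_min
                and b[1] - b[0] >= lst_min
                and b[0] - a[1] < smooth
            ):
                count += 1
    return count


def oracle_tai(rows, cen, tai_min_len=0, exclude_whole=True):
    lo_cov = min(r[0] for r in rows)
    hi_cov = max(r[1] for r in rows)
    count = 0
    for imb, grp in groupby(rows, key=lambda r: r[2] != r[3]):
        grp = list(grp)
        if not imb:
            continue
        start, end = grp[0][0], grp[-1][1]
        touches = start <= lo_cov or end >= hi_cov
        whole = start <= lo_cov and end >= hi_cov
        crosses = start < cen[0] and end > cen[1]
        if (
            touches
            and not crosses
            and end - start >= tai_min_len
            and not (whole and exclude_whole)
        ):
            count += 1
    return count


def oracle_scar_counts(profile_rows, genome, **kw):
    """profile_rows: DataFrame-like rows over possibly many chromosomes."""
    loh = lst = tai = 0
    by_chrom: dict[str, list] = {}
    for r in profile_rows:
        by_chrom.setdefault(r[0], []).append(tuple(r[1:]))
    for chrom, rows in by_chrom.items():
        rows = sorted(rows)
        c = genome.chromosome(chrom)
        cen = (c.centromere_start, c.centromere_end)
        loh += oracle_loh(rows)
        lst += oracle_lst(rows, cen)
        tai += oracle_tai(rows, cen)
    return loh, lst, tai


# ---------------------------------------------------------------------------
# segmentation by exhaustive enumeration


def _seg_cost(logr, mbaf, informative, i, j, wr, wb):
    r = logr[i:j]
    cost = wr * float(np.sum((r - r.mean()) ** 2))
    m = mbaf[i:j][informative[i:j]]
    if len(m) > 0:
        cost += wb * float(np.sum((m - m.mean()) ** 2))
    return cost


def enumerate_breakpoints(logr, mbaf, informative, penalty, min_len, wr, wb):
    """Enumerate every admissible breakpoint placement recursively.

    Partial placements are abandoned once they already exceed the best
    complete placement (all cost terms are non-negative, so this prunes
    without losing exactness).  Returns (best_cost, best_bps).
    """
    n = len(logr)
    best_cost = float("inf")
    best_bps: list[int] = []

    def rec(i, bps, cost):
        nonlocal best_cost, best_bps
        if cost >= best_cost:
            return
        for j in range(i + min_len, n + 1):
            if j != n and n - j < min_len:
                continue
            c = cost + _seg_cost(logr, mbaf, informative, i, j, wr, wb)
            if j == n:
                if c < best_cost - 1e-12:
                    best_cost, best_bps = c, list(bps)
            else:
                rec(j, bps + [j], c + penalty)

    rec(0, [], 0.0)
    return best_cost, best_bps
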
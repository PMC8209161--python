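"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available —
plain-Python dynamic programming, exhaustive pair enumeration, row-by-row
scans — without touching the package's optimised implementations.
"""

from __future__ import annotations

MATCH = 1
MISMATCH = -1
GAP = -2


def oracle_align_identity(read: str, ref: str, cpg_cols: set[int]):
    """Plain-Python semi-global alignment identity and per-CpG bases.

    Free end gaps on both sequences; T against reference C at a CpG column
    scores as a match.  Identity = matching columns / alignment columns with
    end-gap columns excluded.  Tie-breaking: diagonal, then vertical, then
    horizontal; the end cell is the first maximum of the last row, replaced
    by the last column's first maximum only if strictly better.
    """
    n, m = len(read), len(ref)

    def score(i: int, j: int) -> int:
        q, r = read[i], ref[j]
        if q == r or (j in cpg_cols and r == "C" and q == "T"):
            return MATCH
        return MISMATCH

    S = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i][j] = max(
                S[i - 1][j - 1] + score(i - 1, j - 1),
                S[i - 1][j] + GAP,
                S[i][j - 1] + GAP,
            )

    end_i, end_j = n, max(range(m + 1), key=lambda j: S[n][j])
    best = S[end_i][end_j]
    ci = max(range(n + 1), key=lambda i: S[i][m])
    if S[ci][m] > best:
        end_i, end_j, best = ci, m, S[ci][m]

    i, j = end_i, end_j
    matches = columns = 0
    aligned: dict[int, str] = {}
    while i > 0 and j > 0:
        s = S[i][j]
        if s == S[i - 1][j - 1] + score(i - 1, j - 1):
            aligned[j - 1] = read[i - 1]
            matches += int(score(i - 1, j - 1) == MATCH)
            columns += 1
            i, j = i - 1, j - 1
        elif s == S[i - 1][j] + GAP:
            columns += 1
            i -= 1
        else:
            aligned[j - 1] = "-"
            columns += 1
            j -= 1
    identity = matches / columns if columns else 0.0
    return identity, aligned


def oracle_auc(case_scores, control_scores) -> float:
    """Exhaustive pairwise concordance: ties count one half."""
    total = conc = 0.0
    for x in case_scores:
        for y in control_scores:
            total += 1
            if x > y:
                conc += 1
            elif x == y:
                conc += 0.5
    return conc / total


def oracle_single_linkage(positions: list[int], max_gap: int) -> list[list[int]]:
    """Brute-force single-linkage clustering of 1-D points at ``max_gap``:
    repeatedly merge the closest pair of clusters while the minimum
    inter-cluster distance is within the cutoff."""
    clusters = [[p] for p in sorted(positions)]
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(abs(x - y) for x in clusters[a] for y in clusters[b])
                if d <= max_gap:
                    clusters[a] = sorted(clusters[a] + clusters[b])
                    del clusters[b]
                    merged = True
                    break
            if merged:
                break
    return sorted(clusters)


def oracle_select_cpgs(beta_matrix, tumour_threshold, normal_threshold,
                       min_tumour_fraction, center=0.5) -> list[str]:
    """Row-by-row re-application of the two selection inequalities."""
    import math

    selected = []
    tum_cols = [i for i, g in enumerate(beta_matrix.group_labels) if g == "tumour"]
    groups = {}
    for i, g in enumerate(beta_matrix.group_labels):
        if g != "tumour":
            groups.setdefault(g, []).append(i)
    for r, cid in enumerate(beta_matrix.cpg_ids):
        vals = [beta_matrix.values[r, c] for c in tum_cols]
        obs = [v for v in vals if not math.isnan(v)]
        if not obs:
            continue
        frac = sum(1 for v in obs if v - center > tumour_threshold) / len(obs)
        if frac < min_tumour_fraction:
            continue
        ok = True
        for cols in groups.values():
            gvals = [
                beta_matrix.values[r, c]
                for c in cols
                if not math.isnan(beta_matrix.values[r, c])
            ]
            if not gvals or sum(gvals) / len(gvals) - center >= normal_threshold:
                ok = False
                break
        if ok:
            selected.append(cid)
    return selected
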
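"""Independent brute-force reference implementations used as test oracles.

Each oracle is deliberately naive (quadratic scans, explicit recursion)
and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np

_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def brute_force_overlaps(a, b):
    """All (i, j) pairs of overlapping 1-based closed intervals, O(n*m)."""
    pairs = []
    for i, (ca, sa, ea) in enumerate(a):
        for j, (cb, sb, eb) in enumerate(b):
            if ca == cb and sa <= eb and sb <= ea:
                pairs.append((i, j))
    return sorted(pairs)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_orfs(seq: str, min_aa: int, both_strands: bool = True):
    """Six-frame maximal ATG->stop scan by explicit per-position checks.

    Returns a set of (strand, frame, start, end, peptide, partial) tuples
    with start/end 1-based closed in sense orientation.
    """
    seq = seq.upper()
    out = set()
    strands = [("sense", seq)]
    if both_strands:
        strands.append(("antisense", _revcomp(seq)))
    for strand, s in strands:
        n = len(s)
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            # maximality: no earlier translatable in-frame ATG in this stretch
            maximal = True
            j = i - 3
            while j >= 0:
                c = s[j:j + 3]
                aa = _TABLE.get(c)
                if aa is None or aa == "*":
                    break
                if c == "ATG":
                    maximal = False
                    break
                j -= 3
            if not maximal:
                continue
            pep = ["M"]
            k = i + 3
            stopped = False
            broken = False
            while k + 3 <= n:
                aa = _TABLE.get(s[k:k + 3])
                if aa is None:
                    broken = True
                    break
                if aa == "*":
                    stopped = True
                    break
                pep.append(aa)
                k += 3
            if broken or len(pep) < min_aa:
                continue
            end0 = k + 2 if stopped else i + 3 * len(pep) - 1
            if strand == "sense":
                start, end = i + 1, end0 + 1
            else:
                start, end = n - end0, n - i
            out.add((strand, i % 3, start, end, "".join(pep), not stopped))
    return out


def naive_average_linkage(dist: np.ndarray):
    """Average-linkage agglomeration from a square distance matrix.

    Returns (merges, leaf_order) where merges is a list of
    (leaf_frozenset, height) in merge order and leaf_order is the
    dendrogram leaf sequence (lower-id subtree first at every node).
    """
    n = dist.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        members[next_id] = members[i] | members[j]
        children[next_id] = (i, j)
        merges.append((members[next_id], h))
        active -= {i, j}
        for k in sorted(active):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            ni, nj = len(members[i]), len(members[j])
            d[(k, next_id)] = (ni * d.pop(a) + nj * d.pop(b)) / (ni + nj)
        d.pop((i, j))
        active.add(next_id)
        next_id += 1

    def leaves(c: int):
        if c < n:
            return [c]
        a, b = children[c]
        return leaves(a) + leaves(b)

    return merges, leaves(next_id - 1)


def prosite_match(pattern: str, peptide: str) -> bool:
    """Direct recursive matcher for Prosite-style patterns (no regex)."""
    elems = []
    for part in pattern.strip().rstrip(".").split("-"):
        part = part.strip()
        if part.startswith("<") and part != "<":
            elems.append(("<", 1, 1))
            part = part[1:]
        tail = None
        if part.endswith(">") and part != ">":
            tail = (">", 1, 1)
            part = part[:-1]
        lo = hi = 1
        if "(" in part:
            body, rep = part.split("(", 1)
            rep = rep.rstrip(")")
            if "," in rep:
                lo, hi = (int(x) for x in rep.split(","))
            else:
                lo = hi = int(rep)
        else:
            body = part
        elems.append((body, lo, hi))
        if tail is not None:
            elems.append(tail)

    def elem_ok(body: str, ch: str) -> bool:
        if body == "x":
            return True
        if body.startswith("["):
            return ch in body[1:-1]
        if body.startswith("{"):
            return ch not in body[1:-1]
        return ch == body

    def rec(ei: int, pos: int) -> bool:
        if ei == len(elems):
            return True
        body, lo, hi = elems[ei]
        if body == "<":
            return pos == 0 and rec(ei + 1, pos)
        if body == ">":
            return pos == len(peptide) and rec(ei + 1, pos)
        for take in range(lo, hi + 1):
            if pos + take > len(peptide):
                break
            if all(elem_ok(body, peptide[pos + t]) for t in range(take)):
                if rec(ei + 1, pos + take):
                    return True
            else:
                break
        return False

    return any(rec(0, start) for start in range(len(peptide) + 1))
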
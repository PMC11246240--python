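"""Independent reference implementations used only to check the package:
a brute-force NG86 pathway-enumeration calculator and an exhaustive
collinear-chain search. Deliberately naive and cache-free."""

from itertools import permutations
from math import log

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_force_ng86(seq1: str, seq2: str):
    """(ka, ks, s_sites, n_sites, saturated) by direct enumeration."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    cods1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    cods2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]

    def sites(codon):
        syn = tot = 0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut in STOPS:
                    continue
                tot += 1
                syn += _aa(mut) == _aa(codon)
        return 3.0 * syn / tot

    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for c1, c2 in zip(cods1, cods2):
        if c1 in STOPS or c2 in STOPS:
            continue
        s1, s2 = sites(c1), sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += ((3 - s1) + (3 - s2)) / 2
        positions = [i for i in range(3) if c1[i] != c2[i]]
        if not positions:
            continue
        path_syn, path_non, n_paths = 0.0, 0.0, 0
        for order in permutations(positions):
            cur, syn, non, valid = c1, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in STOPS:
                    valid = False
                    break
                if _aa(cur) == _aa(nxt):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            if valid:
                path_syn += syn
                path_non += non
                n_paths += 1
        if n_paths:
            sd += path_syn / n_paths
            nd += path_non / n_paths

    def jc(p):
        arg = 1 - 4 * p / 3
        if arg <= 0:
            return float("nan"), True
        return -0.75 * log(arg), False

    ks, sat_s = jc(sd / s_sites if s_sites else 0.0)
    ka, sat_n = jc(nd / n_sites if n_sites else 0.0)
    return ka, ks, s_sites, n_sites, sat_s or sat_n


def exhaustive_best_chain(matches, max_gap, orientation="parallel"):
    """Length of the longest valid collinear chain, by depth-first search
    over every chain. Feasible for len(matches) <= ~15."""
    pts = sorted({(m.rank_a, m.rank_b) for m in matches})
    sign = 1 if orientation == "parallel" else -1

    def extend(i):
        best = 1
        ai, bi = pts[i]
        for j in range(i + 1, len(pts)):
            aj, bj = pts[j]
            if 0 < aj - ai <= max_gap and 0 < sign * (bj - bi) <= max_gap:
                best = max(best, 1 + extend(j))
        return best

    return max((extend(i) for i in range(len(pts))), default=0)
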
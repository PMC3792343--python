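"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on raw strings and first principles only: no
LoxSite/Molecule machinery, no parts assembly, no shared surgery code.
"""

from __future__ import annotations

import functools
import itertools

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# -- lox geometry from first principles -------------------------------------

WT_LEFT = "ATAACTTCGTATA"
MUT_LEFT = "TACCGTTCGTATA"
WT_RIGHT = "TATACGAAGTTAT"
MUT_RIGHT = "TATACGAACGGTA"
LINKERS = {
    "P": "ATGTATGC",
    "511": "ATGTATAC",
    "FAS": "TACCTTTC",
    "m2": "AGAAACCA",
    "2272": "AAGTATCC",
    "N": "GTATACCT",
}
_LINKER_CLASS = {v: k for k, v in LINKERS.items()}


def find_sites(seq: str) -> list[dict]:
    """Scan a raw string for lox sites by linker match on either strand."""
    sites = []
    for i in range(len(seq) - 33):
        k = seq[i + 13 : i + 21]
        if k in _LINKER_CLASS:
            cls, fwd = _LINKER_CLASS[k], True
        elif rc(k) in _LINKER_CLASS:
            cls, fwd = _LINKER_CLASS[rc(k)], False
        else:
            continue
        gl, gr = seq[i : i + 13], seq[i + 21 : i + 34]
        # site-frame arms
        sl, sr = (gl, gr) if fwd else (rc(gr), rc(gl))
        lm = sl == MUT_LEFT
        rm = sr == MUT_RIGHT
        if sl not in (WT_LEFT, MUT_LEFT) or sr not in (WT_RIGHT, MUT_RIGHT):
            continue
        sites.append(
            {"pos": i, "cls": cls, "fwd": fwd, "gl": gl, "gk": k, "gr": gr,
             "active": not (lm and rm)}
        )
    return sites


def _canon_circ(s: str) -> str:
    rots = [s[i:] + s[:i] for i in range(len(s))]
    t = rc(s)
    rots += [t[i:] + t[:i] for i in range(len(t))]
    return min(rots)


def canon(molecules: tuple[tuple[str, bool], ...]) -> tuple:
    """Canonical key of a multiset of (sequence, circular) molecules."""
    out = []
    for seq, circular in molecules:
        out.append(("c", _canon_circ(seq)) if circular else ("l", min(seq, rc(seq))))
    return tuple(sorted(out))


def _splice_events(mols: tuple[tuple[str, bool], ...]):
    """All single Cre events by raw string splicing."""
    found = [(mi, s) for mi, (seq, circ) in enumerate(mols) for s in find_sites(seq)]
    succs = []
    for (mi, a), (mj, b) in itertools.combinations(found, 2):
        if a["cls"] != b["cls"] or not (a["active"] and b["active"]):
            continue
        if mi == mj:
            seq, circ = mols[mi]
            if b["pos"] < a["pos"]:
                a, b = b, a
            i, j = a["pos"], b["pos"]
            rest = [m for k, m in enumerate(mols) if k != mi]
            if a["fwd"] == b["fwd"]:
                chrom = seq[:i] + a["gl"] + a["gk"] + b["gr"] + seq[j + 34 :]
                circle = b["gl"] + b["gk"] + a["gr"] + seq[i + 34 : j]
                succs.append(tuple(rest + [(chrom, circ), (circle, True)]))
            else:
                j1 = a["gl"] + rc(b["gk"]) + rc(b["gl"])
                j2 = rc(a["gr"]) + rc(a["gk"]) + b["gr"]
                prod = seq[:i] + j1 + rc(seq[i + 34 : j]) + j2 + seq[j + 34 :]
                succs.append(tuple(rest + [(prod, circ)]))
        else:
            (sa, ca), (sb, cb) = mols[mi], mols[mj]
            if not (ca and cb):
                continue
            # rotate both so each site sits at position 0, forward
            if not a["fwd"]:
                sa = rc(sa)
                a = next(s for s in find_sites(sa) if s["fwd"] and s["cls"] == b["cls"]
                         and s["pos"] == len(sa) - a["pos"] - 34)
            if not b["fwd"]:
                sb = rc(sb)
                b = next(s for s in find_sites(sb) if s["fwd"] and s["cls"] == a["cls"]
                         and s["pos"] == len(sb) - b["pos"] - 34)
            ra = sa[a["pos"] :] + sa[: a["pos"]]  # starts with site a
            rb = sb[b["pos"] :] + sb[: b["pos"]]
            fused = (
                a["gl"] + a["gk"] + b["gr"] + rb[34:] + b["gl"] + b["gk"] + a["gr"] + ra[34:]
            )
            rest = [m for k, m in enumerate(mols) if k not in (mi, mj)]
            succs.append(tuple(rest + [(fused, True)]))
    return succs


def closure_oracle(mols: tuple[tuple[str, bool], ...], max_states: int = 5000):
    """Reachable canonical states, edges, and terminal-SCC partition."""
    start = canon(mols)
    states = {start: mols}
    edges = set()
    frontier = [start]
    while frontier:
        nxt = []
        for key in frontier:
            for succ in _splice_events(states[key]):
                skey = canon(succ)
                edges.add((key, skey))
                if skey not in states:
                    states[skey] = succ
                    nxt.append(skey)
                    if len(states) > max_states:
                        raise RuntimeError("oracle state bound exceeded")
        frontier = nxt

    # Tarjan-free SCC via Kosaraju on the small graph
    adj, radj = {}, {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        radj.setdefault(v, []).append(u)
    order, seen = [], set()

    def dfs(u, graph, acc):
        stack = [u]
        while stack:
            node = stack[-1]
            if node not in seen:
                seen.add(node)
            pushed = False
            for w in graph.get(node, []):
                if w not in seen:
                    stack.append(w)
                    pushed = True
                    break
            if not pushed:
                stack.pop()
                acc.append(node)

    for u in states:
        if u not in seen:
            dfs(u, adj, order)
    seen = set()
    sccs = []
    for u in reversed(order):
        if u not in seen:
            comp: list = []
            dfs(u, radj, comp)
            sccs.append(frozenset(comp))
    terminal_sccs = [
        comp
        for comp in sccs
        if all(v in comp for u in comp for v in adj.get(u, []))
    ]
    return states, edges, terminal_sccs


# -- PCR by window enumeration ----------------------------------------------


def pcr_oracle(seq: str, circular: bool, fwd: str, rev: str, max_product: int):
    """Products defined as windows that begin with one primer and end with
    the reverse complement of the other."""
    L = len(seq)
    ext = seq + seq[: min(max_product, L)] if circular else seq
    prods = set()
    for a, b in ((fwd, rev), (rev, fwd)):
        tail = rc(b)
        for s in range(L):
            if ext[s : s + len(a)] != a:
                continue
            for size in range(max(len(a), len(b)), min(max_product, len(ext) - s, L) + 1):
                if ext[s + size - len(tail) : s + size] == tail:
                    prods.add((s, s + size, size))
    return sorted(prods)


# -- Nussinov pair count by plain recursion ---------------------------------

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def nussinov_count(rna: str) -> int:
    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= 3:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - 3):
            if (rna[k], rna[j]) in _PAIRS:
                left = rec(i, k - 1) if k > i else 0
                best = max(best, left + 1 + rec(k + 1, j - 1))
        return best

    return rec(0, len(rna) - 1)


# -- windowed regression ----------------------------------------------------


def window_r2_oracle(t: np.ndarray, y: np.ndarray, center: int, half: int = 3) -> float:
    sl = slice(center - half, center + half + 1)
    tt, yy = t[sl], y[sl]
    if np.allclose(yy, yy[0]):
        return 0.0
    coeffs = np.polyfit(tt, yy, 1)
    fit = np.polyval(coeffs, tt)
    ss_res = float(np.sum((yy - fit) ** 2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def slope_oracle(t: np.ndarray, y: np.ndarray) -> float:
    n = len(t)
    sx, sy = t.sum(), y.sum()
    sxx, sxy = (t * t).sum(), (t * y).sum()
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)
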
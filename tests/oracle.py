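"""Independent brute-force reference implementations for the tests.

Everything here is deliberately naive: plain dynamic-programming edit
distance (no edlib), exhaustive enumeration of frames, spans and germline
pairings. The production code must agree with these on small instances.
"""

from __future__ import annotations

from cdr3kit.germline import CODON_TO_AA, J_ANCHOR, revcomp

MIN_CONTEXT = 5
MAX_ED = 1
MIN_LEN, MAX_LEN = 4, 30


def dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def translate(nt: str) -> str:
    return "".join(CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


def frames(nt: str):
    for oriented in (nt, revcomp(nt)):
        for f in range(3):
            yield translate(oriented[f:]), oriented, f


def v_match(aa: str, x: int, v_x: str, v_y: str):
    """Best (distance, context) V evidence at span start x, or None."""
    results = []
    prefix = aa[:x]
    w = min(len(prefix), len(v_x))
    if w >= MIN_CONTEXT:
        d = dp_levenshtein(prefix[-w:], v_x[-w:])
        if d <= MAX_ED:
            results.append((d, w))
    pre = min(x, len(v_x))
    inner = min(len(aa) - x - 1, len(v_y))
    if pre + inner >= MIN_CONTEXT:
        d = dp_levenshtein(
            aa[x - pre : x + 1 + inner], v_x[len(v_x) - pre :] + "C" + v_y[:inner]
        )
        if d <= MAX_ED:
            results.append((d, pre + inner))
    if not results:
        return None
    best_d = min(r[0] for r in results)
    return best_d, max(r[1] for r in results if r[0] == best_d)


def j_match(aa: str, x: int, y: int, j_x: str, j_y: str):
    results = []
    suffix = aa[y + 1 :]
    w = min(len(suffix), len(j_y))
    if w >= MIN_CONTEXT:
        d = dp_levenshtein(suffix[:w], j_y[:w])
        if d <= MAX_ED:
            results.append((d, w))
    inner = min(len(j_x), y - x - 1)
    post = min(len(aa) - 1 - y, len(j_y))
    if inner + post >= MIN_CONTEXT:
        d = dp_levenshtein(
            aa[y - inner : y + 1 + post],
            j_x[len(j_x) - inner :] + aa[y] + j_y[:post],
        )
        if d <= MAX_ED:
            results.append((d, inner + post))
    if not results:
        return None
    best_d = min(r[0] for r in results)
    return best_d, max(r[1] for r in results if r[0] == best_d)


def oracle_best_candidate(nt: str, index):
    """Exhaustive (frame, span, V, J) search mirroring stage-1 admission.

    Returns (chain, core_aa, v_ids, j_ids) of the winning span or None.
    """
    best = None
    for aa, oriented, f in frames(nt):
        for chain in index.chains:
            v_rows = [
                (seg.id, sp.pre_anchor, sp.post_anchor)
                for seg, sp in zip(index.v_segments[chain], index.v_splits[chain])
            ]
            j_rows = [
                (seg.id, sp.pre_anchor, sp.post_anchor)
                for seg, sp in zip(index.j_segments[chain], index.j_splits[chain])
            ]
            terminal = J_ANCHOR[chain]
            for x in range(len(aa)):
                if aa[x] != "C":
                    continue
                for y in range(x + MIN_LEN - 1, min(x + MAX_LEN, len(aa))):
                    if aa[y] != terminal or "*" in aa[x : y + 1]:
                        continue
                    v_evs = {gid: v_match(aa, x, vx, vy) for gid, vx, vy in v_rows}
                    v_evs = {g: e for g, e in v_evs.items() if e}
                    j_evs = {gid: j_match(aa, x, y, jx, jy) for gid, jx, jy in j_rows}
                    j_evs = {g: e for g, e in j_evs.items() if e}
                    if not v_evs or not j_evs:
                        continue
                    vd = min(e[0] for e in v_evs.values())
                    jd = min(e[0] for e in j_evs.values())
                    v_ids = sorted(g for g, e in v_evs.items() if e[0] == vd)
                    j_ids = sorted(g for g, e in j_evs.items() if e[0] == jd)
                    ctx = max(e[1] for e in v_evs.values() if e[0] == vd) + max(
                        e[1] for e in j_evs.values() if e[0] == jd
                    )
                    core = aa[x : y + 1]
                    cand = (ctx, core, chain, v_ids, j_ids)
                    if best is None or (cand[0], _inv(cand[1])) > (best[0], _inv(best[1])):
                        best = cand
    if best is None:
        return None
    return best[2], best[1], best[3], best[4]


class _inv(str):
    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
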
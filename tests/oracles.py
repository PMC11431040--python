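"""Independent brute-force oracles used by the structure tests.

Deliberately naive (quadratic matching, set scans) so they share no code
path with the production classifier.
"""
from __future__ import annotations


def enumerate_balanced(max_len: int):
    """All dot-bracket strings over {., (, )} of length 1..max_len."""

    def rec(prefix: str, open_count: int, remaining: int):
        if remaining == 0:
            if open_count == 0:
                yield prefix
            return
        yield from rec(prefix + ".", open_count, remaining - 1)
        yield from rec(prefix + "(", open_count + 1, remaining - 1)
        if open_count > 0:
            yield from rec(prefix + ")", open_count - 1, remaining - 1)

    for n in range(1, max_len + 1):
        yield from rec("", 0, n)


def oracle_pairs(db: str) -> list[tuple[int, int]]:
    """Repeated innermost '(...)' elimination (no stack)."""
    work = list(db)
    pairs = []
    changed = True
    while changed:
        changed = False
        for i, ch in enumerate(work):
            if ch != "(":
                continue
            for j in range(i + 1, len(work)):
                if work[j] == "(":
                    break
                if work[j] == ")":
                    pairs.append((i + 1, j + 1))
                    work[i] = work[j] = "*"
                    changed = True
                    break
            if changed:
                break
    return sorted(pairs)


def oracle_labels(db: str) -> list[str]:
    """Brute-force loop decomposition from first principles."""
    n = len(db)
    pairs = oracle_pairs(db)
    paired = {i for ij in pairs for i in ij}
    labels = []
    for k in range(1, n + 1):
        if k in paired:
            partner = next(j if i == k else i for i, j in pairs if k in (i, j))
            labels.append("stem_5prime" if k < partner else "stem_3prime")
            continue
        enclosing = [(i, j) for i, j in pairs if i < k < j]
        if not enclosing:
            labels.append("exterior")
            continue
        a, b = min(enclosing, key=lambda p: p[1] - p[0])
        inside = [(i, j) for i, j in pairs if a < i and j < b]
        children = [
            (i, j)
            for i, j in inside
            if not any(x < i and j < y for x, y in inside)
        ]
        if not children:
            labels.append("hairpin_loop")
        elif len(children) >= 2:
            labels.append("multiloop")
        else:
            (c, d), = children
            side5 = any(
                a < u < c and u not in paired for u in range(a + 1, c)
            )
            side3 = any(
                d < u < b and u not in paired for u in range(d + 1, b)
            )
            labels.append("internal_loop" if side5 and side3 else "bulge")
    return labels
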
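"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written as naive, column-by-column Python,
sharing no code with the package: a literal column-walk event caller, a
literal sliding-mean, the textbook chi-squared formula and an exhaustive
hypergeometric enumeration for the two-sided Fisher test.
"""

from __future__ import annotations

from math import comb


def column_walk_events(seqs: list[str], upstream: int, downstream: int) -> list[list[int]]:
    """Naive per-column event caller.

    ``seqs`` are aligned strings, reference first, whose ungapped reference
    spans exactly ``upstream + downstream`` bases (TSS base = first
    downstream base).  Returns a (window length x n_other_species) matrix of
    event classes: 0 none, 1 base change, 2 indel.  Indels override base
    changes at the same position; an insertion run is one indel at the offset
    of the nearest 5' reference base (clamped to the first base).
    """
    ref = seqs[0].upper()
    length = upstream + downstream

    # per-column window index of the anchoring reference base
    anchors: list[int] = []
    seen = 0
    for ch in ref:
        if ch != "-":
            anchors.append(seen)
            seen += 1
        else:
            anchors.append(max(seen - 1, 0))
    assert seen == length, "reference must span the window exactly"

    out = []
    for sp in seqs[1:]:
        sp = sp.upper()
        classes = [0] * length
        for col, (rc, sc) in enumerate(zip(ref, sp)):
            idx = anchors[col]
            if rc != "-":
                if sc == "-":
                    classes[idx] = 2
                elif sc != rc and classes[idx] != 2:
                    classes[idx] = 1
            elif sc != "-":  # insertion column
                classes[idx] = 2
        out.append(classes)
    # transpose to window x species
    return [list(row) for row in zip(*out)]


def sliding_mean(values: list[float], window_size: int) -> list[float]:
    """Centered mean with truncation at the ends, literal loops."""
    half = window_size // 2
    out = []
    for i in range(len(values)):
        chunk = values[max(0, i - half) : i + half + 1]
        out.append(sum(chunk) / len(chunk))
    return out


def chi2_textbook(table) -> float:
    """Pearson chi-squared, literal sum of (O-E)^2 / E."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (table[i][j] - e) ** 2 / e
    return stat


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums P(X = x) over all tables with the observed margins whose probability
    does not exceed the observed one (with the conventional tiny relative
    fudge for float ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)
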
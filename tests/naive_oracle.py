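"""First-principles reference implementations used only by the test suite.

Everything here is written independently of the package internals: plain
character comparison, explicit enumeration with itertools, no imports from
surreg. The scanner oracle enumerates every offset x spacer realization x
orientation, keeps matches within the edit budget, collapses alternative
alignments of one (offset, pattern) site by the documented preference order,
and applies nesting suppression — all from the written rules, not from the
scanner's code.
"""

from __future__ import annotations

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


PATTERNS = {
    "short": (("GTT", "AAC"), (3,)),
    "long": (("GTT", "AAC", "GTT"), (3, 5)),
}
BUDGETS = {"short": 1, "long": 2}


def _block_mismatches(text: str, blocks, spacers) -> int:
    pos = 0
    mism = 0
    for i, block in enumerate(blocks):
        for a, b in zip(text[pos : pos + len(block)], block):
            if a != b:
                mism += 1
        pos += len(block)
        if i < len(spacers):
            pos += spacers[i]
    return mism


def naive_scan(
    seq: str,
    *,
    budgets: dict | None = None,
    flex: int = 1,
    nesting: bool = True,
) -> set[tuple]:
    """All motif sites as (offset, pattern, genomic_spacers, cost, label).

    One tuple per (offset, pattern) site: among every in-budget alignment
    (spacer realization x orientation) the best by (cost, block mismatches,
    total spacer deviation, genomic spacer vector) is kept. Labels: exact
    short sites match both orientations ("forward_and_reverse"); otherwise
    the cheaper orientation, forward on ties.
    """
    budgets = dict(BUDGETS if budgets is None else budgets)
    sites: dict[tuple, list] = {}
    for name, (blocks, canon) in PATTERNS.items():
        budget = budgets[name]
        block_len = sum(len(b) for b in blocks)
        for reading in itertools.product(
            *[range(max(0, c - flex), c + flex + 1) for c in canon]
        ):
            dev = sum(abs(r - c) for r, c in zip(reading, canon))
            if dev > budget:
                continue
            span = block_len + sum(reading)
            for off in range(len(seq) - span + 1):
                window = seq[off : off + span]
                for orient in ("forward", "reverse"):
                    text = window if orient == "forward" else naive_revcomp(window)
                    mism = _block_mismatches(text, blocks, reading)
                    cost = mism + dev
                    if cost > budget:
                        continue
                    g = (
                        tuple(reversed(reading))
                        if orient == "reverse"
                        else tuple(reading)
                    )
                    sites.setdefault((off, name), []).append(
                        (cost, mism, dev, g, orient, span)
                    )
    results = set()
    long_prefixes: set[tuple[int, int]] = set()
    chosen: dict[tuple, tuple] = {}
    for (off, name), alignments in sites.items():
        # Orientation pairs at the same geometry merge before ranking:
        # label is decided per geometry, then the best geometry wins.
        by_geom: dict[tuple, dict] = {}
        for cost, mism, dev, g, orient, span in alignments:
            by_geom.setdefault(g, {})[orient] = (cost, mism, dev, span)
        ranked = []
        for g, orients in by_geom.items():
            fwd = orients.get("forward")
            rev = orients.get("reverse")
            if name == "short" and fwd is not None and fwd[0] == 0:
                label, best = "forward_and_reverse", fwd
            elif rev is None or (fwd is not None and fwd[0] <= rev[0]):
                label, best = "forward", fwd
            else:
                label, best = "reverse", rev
            cost, mism, dev, span = best
            ranked.append(((cost, mism, dev, g), label, span))
        (cost, mism, dev, g), label, span = min(ranked)
        chosen[(off, name)] = (g, cost, label, span)
    for (off, name), (g, cost, label, span) in chosen.items():
        if name != "long":
            continue
        # reading-order first spacer bounds the embedded short footprint
        reading = tuple(reversed(g)) if label == "reverse" else g
        prefix_len = 3 + reading[0] + 3
        if label == "reverse":
            long_prefixes.add((off + span - prefix_len, off + span - 1))
        else:
            long_prefixes.add((off, off + prefix_len - 1))
    for (off, name), (g, cost, label, span) in chosen.items():
        if (
            nesting
            and name == "short"
            and (off, off + span - 1) in long_prefixes
        ):
            continue
        results.add((off, name, g, cost, label))
    return results


def naive_upstream(genome: str, start: int, end: int, strand: str, window: int) -> str:
    """Base-by-base upstream extraction oracle (1-based inclusive coords)."""
    out = []
    if strand == "forward":
        for p in range(start - window, start):
            if 1 <= p <= len(genome):
                out.append(genome[p - 1])
    else:
        for p in range(end + window, end, -1):
            if 1 <= p <= len(genome):
                out.append(_COMP[genome[p - 1]])
    return "".join(out)
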
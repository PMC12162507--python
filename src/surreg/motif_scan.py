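"""Block-and-spacer SurR motif compilation, scanning and reporting.

The SurR binding consensus is a gapped pattern: fixed base triplets separated
by spacers of unconstrained content. Two patterns are scanned by default:

* short  ``GTTn3AAC``       (9 bp canonical span; self-reverse-complementary)
* long   ``GTTn3AACn5GTT``  (17 bp canonical span)

A variant occurrence may deviate from the canonical pattern by block mismatches
and/or spacer-length shifts. The total *edit cost* of a hit is
``mismatch_count + sum(|spacer deviation|)`` and must not exceed the pattern's
edit budget (default: short 1, long 2; spacer flexibility +/-1 per spacer).
These budgets admit every variant class observed upstream of the
T. barophilus energy-metabolism clusters (1-mismatch short, 2-mismatch long,
2-spacer-shift long) and nothing more degenerate.

Because the exact short pattern is its own reverse complement, every exact
short occurrence matches both orientations and is labelled
``forward_and_reverse``; inexact hits report the cheaper orientation, ties
going to forward.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import poisson

from .sequence_io import (
    ClusterDef,
    Feature,
    GenomeRecord,
    PromoterRegion,
    extract_upstream,
    feature_index,
    resolve_cluster,
    reverse_complement,
)

__all__ = [
    "MotifPattern",
    "MotifHit",
    "ClusterRow",
    "ScanReport",
    "PatternSpecError",
    "compile_pattern",
    "default_patterns",
    "match_at",
    "scan_region",
    "resolve_nesting",
    "label_strand",
    "render_annotation",
    "promoter_report",
    "genome_scan",
    "write_bed",
    "expected_random_hits",
    "SHORT_SPEC",
    "LONG_SPEC",
    "ALT_SHORT_SPEC",
]

SHORT_SPEC = "GTTn3AAC"
LONG_SPEC = "GTTn3AACn5GTT"
#: Alternative short consensus sometimes quoted for Thermococcales; not
#: scanned by default but compilable on request.
ALT_SHORT_SPEC = "GTTn3ATC"

_SPEC_RE = re.compile(r"^([ACGT]+)((?:n[1-9][0-9]*[ACGT]+)+)$")
_PART_RE = re.compile(r"n([1-9][0-9]*)([ACGT]+)")

DEFAULT_EDIT_BUDGETS = {"short": 1, "long": 2}


class PatternSpecError(ValueError):
    """Raised for a malformed block-and-spacer pattern specification."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled block-and-spacer consensus."""

    name: str
    blocks: tuple[str, ...]
    spacer_lens: tuple[int, ...]
    spacer_flex: int = 1
    edit_budget: int = 1

    def __post_init__(self) -> None:
        if len(self.spacer_lens) != len(self.blocks) - 1:
            raise PatternSpecError("need exactly one spacer between consecutive blocks")
        if self.edit_budget < 0 or self.spacer_flex < 0:
            raise PatternSpecError("edit_budget and spacer_flex must be >= 0")

    @property
    def block_len(self) -> int:
        return sum(len(b) for b in self.blocks)

    def span(self, spacers: Sequence[int] | None = None) -> int:
        spacers = self.spacer_lens if spacers is None else spacers
        return self.block_len + sum(spacers)

    def spacer_vectors(self) -> list[tuple[int, ...]]:
        """All realized spacer-length vectors within the flex window (reading order)."""
        ranges = [
            range(max(0, c - self.spacer_flex), c + self.spacer_flex + 1)
            for c in self.spacer_lens
        ]
        return [tuple(v) for v in itertools.product(*ranges)]

    def genomic_spacer_vectors(self) -> list[tuple[int, ...]]:
        """Spacer vectors in genomic left-to-right order, either orientation.

        A reverse-orientation occurrence lays its spacers down in reversed
        order along the genome, so the genomic enumeration is the union of
        the reading-order flex window and its reversal.
        """
        vectors = set(self.spacer_vectors())
        vectors.update(tuple(reversed(v)) for v in self.spacer_vectors())
        return sorted(vectors)

    @property
    def canonical_string(self) -> str:
        parts = [self.blocks[0]]
        for k, block in zip(self.spacer_lens, self.blocks[1:]):
            parts.append(f"n{k}{block}")
        return "".join(parts)


def compile_pattern(
    spec_string: str,
    name: str | None = None,
    *,
    edit_budget: int | None = None,
    spacer_flex: int = 1,
) -> MotifPattern:
    """Compile a ``BLOCK(nK BLOCK)*`` specification into a :class:`MotifPattern`.

    The name defaults to "short" for 2-block and "long" for 3-block patterns.
    """
    m = _SPEC_RE.match(spec_string)
    if not m:
        raise PatternSpecError(
            f"malformed pattern spec {spec_string!r} "
            "(expected e.g. 'GTTn3AAC' with at least two blocks)"
        )
    blocks = [m.group(1)]
    spacers: list[int] = []
    for k, block in _PART_RE.findall(m.group(2)):
        spacers.append(int(k))
        blocks.append(block)
    if name is None:
        name = {2: "short", 3: "long"}.get(len(blocks), f"{len(blocks)}-block")
    if edit_budget is None:
        edit_budget = DEFAULT_EDIT_BUDGETS.get(name, 1)
    return MotifPattern(
        name=name,
        blocks=tuple(blocks),
        spacer_lens=tuple(spacers),
        spacer_flex=spacer_flex,
        edit_budget=edit_budget,
    )


def default_patterns(
    *,
    short_budget: int = 1,
    long_budget: int = 2,
    spacer_flex: int = 1,
) -> tuple[MotifPattern, MotifPattern]:
    return (
        compile_pattern(SHORT_SPEC, "short", edit_budget=short_budget, spacer_flex=spacer_flex),
        compile_pattern(LONG_SPEC, "long", edit_budget=long_budget, spacer_flex=spacer_flex),
    )


@dataclass(frozen=True)
class Match:
    """Outcome of matching a pattern at one offset with fixed spacers."""

    mismatch_count: int
    spacer_devs: tuple[int, ...]
    edit_cost: int
    matched_blocks: tuple[str, ...]


def match_at(
    seq: str,
    offset: int,
    pattern: MotifPattern,
    realized_spacers: Sequence[int],
) -> Match | None:
    """Match ``pattern`` reading forward from ``offset`` with the given spacers.

    Mismatches are Hamming distance over block positions only; spacer content
    is unconstrained. Returns None (not an error) when the total edit cost
    exceeds the pattern's budget, when a spacer lies outside the flex window,
    or when the window does not fit.
    """
    devs = tuple(r - c for r, c in zip(realized_spacers, pattern.spacer_lens))
    if any(abs(d) > pattern.spacer_flex for d in devs):
        return None
    spacer_cost = sum(abs(d) for d in devs)
    if spacer_cost > pattern.edit_budget:
        return None
    span = pattern.span(realized_spacers)
    if offset < 0 or offset + span > len(seq):
        return None
    mismatches = 0
    matched: list[str] = []
    pos = offset
    for i, block in enumerate(pattern.blocks):
        observed = seq[pos : pos + len(block)]
        mismatches += sum(1 for a, b in zip(observed, block) if a != b)
        if mismatches + spacer_cost > pattern.edit_budget:
            return None
        matched.append(observed)
        pos += len(block)
        if i < len(realized_spacers):
            pos += realized_spacers[i]
    return Match(
        mismatch_count=mismatches,
        spacer_devs=devs,
        edit_cost=mismatches + spacer_cost,
        matched_blocks=tuple(matched),
    )


@dataclass(frozen=True)
class MotifHit:
    """A located, scored, strand-labelled motif occurrence.

    ``region_offset`` is the 0-based offset of the hit's first base within the
    scanned region; ``realized_spacers`` are in the motif's own reading order
    (for reverse-orientation hits this is the reverse of the genomic
    left-to-right spacer order). ``upstream_distance`` counts the bases
    strictly between the hit edge nearest the start codon and the start
    codon's first base, and is None when the scanned sequence is not a
    promoter window.
    """

    pattern_name: str
    region_offset: int
    span: int
    strand_label: str  # "forward" | "reverse" | "forward_and_reverse"
    mismatch_count: int
    spacer_devs: tuple[int, ...]
    realized_spacers: tuple[int, ...]
    edit_cost: int
    matched_blocks: tuple[str, ...]
    upstream_distance: int | None = None
    contig_id: str | None = None
    genome_start: int | None = None  # 1-based inclusive
    genome_end: int | None = None
    genome_strand: str | None = None

    @property
    def exact(self) -> bool:
        return self.edit_cost == 0

    @property
    def annotation(self) -> str:
        return render_annotation(self)

    @property
    def genomic_spacers(self) -> tuple[int, ...]:
        """Spacer lengths in genomic left-to-right order within the region."""
        if self.strand_label == "reverse":
            return tuple(reversed(self.realized_spacers))
        return self.realized_spacers

    def key(self) -> tuple:
        """Deduplication identity: span position, pattern, realized geometry."""
        return (self.region_offset, self.pattern_name, self.genomic_spacers)


def label_strand(
    pattern: MotifPattern,
    forward: Match | None,
    reverse: Match | None,
) -> tuple[str, Match]:
    """Choose the reported orientation for a (forward, reverse) match pair.

    Exact short hits are labelled ``forward_and_reverse``: the canonical short
    pattern equals its own reverse complement, so every exact instance matches
    both orientations. Otherwise the cheaper orientation wins; ties go to
    forward.
    """
    if forward is None and reverse is None:
        raise ValueError("hit must match in at least one orientation")
    if (
        pattern.name == "short"
        and forward is not None
        and forward.edit_cost == 0
    ):
        return "forward_and_reverse", forward
    if reverse is None or (forward is not None and forward.edit_cost <= reverse.edit_cost):
        return "forward", forward  # type: ignore[return-value]
    return "reverse", reverse


def render_annotation(hit: MotifHit) -> str:
    """Render a hit the way site tables print it, e.g. ``Long with mutation: GTTn3AATn5GTT``.

    Blocks are printed as matched; spacers as ``nK`` with the realized K (in
    the motif's reading order). The mutation qualifier is plural only for two
    or more block mismatches — a spacer shift reads as a single "mutation"
    however many units it costs.
    """
    parts = [hit.matched_blocks[0]]
    for k, block in zip(hit.realized_spacers, hit.matched_blocks[1:]):
        parts.append(f"n{k}{block}")
    body = "".join(parts)
    prefix = hit.pattern_name.capitalize()
    if hit.edit_cost == 0:
        return prefix
    word = "mutations" if hit.mismatch_count >= 2 else "mutation"
    return f"{prefix} with {word}: {body}"


def scan_region(
    region: str | PromoterRegion,
    patterns: Sequence[MotifPattern] | None = None,
    *,
    is_promoter: bool = True,
    nesting: bool = True,
    collapse: bool = True,
) -> list[MotifHit]:
    """Find all motif occurrences in a region, both orientations, within budget.

    Every offset x realized-spacer combination x orientation is tested. All
    realizations sharing (offset, pattern) describe one physical site under
    alternative alignments, so they collapse to the best-scoring one: lowest
    edit cost, then fewest block mismatches (a spacer shift is geometrically
    benign, so ``GTTn2AACn6GTT`` at cost 2 beats a 2-mismatch canonical-spacing
    reading of the same site), then smallest total spacer deviation. Short
    hits nested as the leading two blocks of a long hit are suppressed (see
    :func:`resolve_nesting`). When ``is_promoter`` is true the region is taken
    to end immediately before a start codon and upstream distances are filled
    in; hits are then sorted by upstream distance (ascending), otherwise by
    offset. ``collapse=False`` keeps every alignment as its own hit (one per
    offset x pattern x genomic spacer vector), which is the representation
    under which strand symmetry is exact; the collapsed site report groups
    alignments by their start, which reflection maps onto their ends.
    """
    if isinstance(region, PromoterRegion):
        seq = region.sequence
    else:
        seq = str(region).upper()
    if patterns is None:
        patterns = default_patterns()
    n = len(seq)
    hits: list[MotifHit] = []
    for pattern in patterns:
        seen: dict = {}
        for spacers in pattern.genomic_spacer_vectors():
            span = pattern.span(spacers)
            if span > n:
                continue
            rev_spacers = tuple(reversed(spacers))
            for offset in range(n - span + 1):
                fwd = match_at(seq, offset, pattern, spacers)
                window = seq[offset : offset + span]
                rev = match_at(reverse_complement(window), 0, pattern, rev_spacers)
                if fwd is None and rev is None:
                    continue
                label, chosen = label_strand(pattern, fwd, rev)
                hit = MotifHit(
                    pattern_name=pattern.name,
                    region_offset=offset,
                    span=span,
                    strand_label=label,
                    mismatch_count=chosen.mismatch_count,
                    spacer_devs=chosen.spacer_devs,
                    realized_spacers=(
                        rev_spacers if label == "reverse" else spacers
                    ),
                    edit_cost=chosen.edit_cost,
                    matched_blocks=chosen.matched_blocks,
                    upstream_distance=(n - offset - span) if is_promoter else None,
                )
                key = offset if collapse else (offset, spacers)
                prev = seen.get(key)
                if prev is None or _alignment_rank(hit) < _alignment_rank(prev):
                    seen[key] = hit
        hits.extend(seen.values())
    if nesting:
        hits = resolve_nesting(hits)
    if is_promoter:
        hits.sort(key=lambda h: (h.upstream_distance, h.pattern_name, h.genomic_spacers))
    else:
        hits.sort(key=lambda h: (h.region_offset, h.pattern_name, h.genomic_spacers))
    return hits


def _alignment_rank(hit: MotifHit) -> tuple:
    """Collapse preference among alternative alignments of one site."""
    return (
        hit.edit_cost,
        hit.mismatch_count,
        sum(abs(d) for d in hit.spacer_devs),
        hit.genomic_spacers,
    )


def _long_prefix_span(hit: MotifHit) -> tuple[int, int] | None:
    """Genomic (start, end) offsets of a long hit's leading two-block prefix."""
    if hit.pattern_name != "long":
        return None
    s1 = hit.realized_spacers[0]  # reading-order first spacer
    b1 = len(hit.matched_blocks[0])
    b2 = len(hit.matched_blocks[1])
    prefix_len = b1 + s1 + b2
    if hit.strand_label == "reverse":
        end = hit.region_offset + hit.span - 1
        return (end - prefix_len + 1, end)
    return (hit.region_offset, hit.region_offset + prefix_len - 1)


def resolve_nesting(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Suppress short hits that are the embedded prefix of a long hit.

    The long pattern's leading two blocks with their spacer are themselves a
    short-pattern instance; counting both would double-report a single bound
    site. A short hit is dropped iff its span coincides with the leading
    two-block footprint of some long hit (in that hit's reading orientation).
    All other hits, including overlapping distinct-start hits, are retained.
    """
    prefixes = {
        span for h in hits if (span := _long_prefix_span(h)) is not None
    }
    out: list[MotifHit] = []
    for h in hits:
        if h.pattern_name == "short":
            span = (h.region_offset, h.region_offset + h.span - 1)
            if span in prefixes:
                continue
        out.append(h)
    return out


def expected_random_hits(
    patterns: Sequence[MotifPattern], region_len: int
) -> float:
    """Expected hit count on i.i.d. uniform {A,C,G,T} background.

    Per offset, orientation and spacer realization, a pattern with ``k`` block
    positions and residual mismatch budget ``b`` matches with probability
    ``sum_{m<=b} C(k,m) 3^m / 4^k``. Overlap between events is ignored, which
    is adequate for a flagging threshold.
    """
    total = 0.0
    for p in patterns:
        k = p.block_len
        for spacers in p.spacer_vectors():
            span = p.span(spacers)
            n_offsets = max(0, region_len - span + 1)
            budget = p.edit_budget - sum(
                abs(r - c) for r, c in zip(spacers, p.spacer_lens)
            )
            if budget < 0:
                continue
            prob = sum(
                math.comb(k, m) * 3**m for m in range(budget + 1)
            ) / 4**k
            total += 2 * n_offsets * prob
    return total


def _flag_threshold(patterns: Sequence[MotifPattern], region_len: int) -> int:
    lam = expected_random_hits(patterns, region_len)
    return int(poisson.ppf(0.99, lam))


@dataclass
class ClusterRow:
    """One report row: a cluster, its first CDS, and the hits found upstream."""

    cluster: ClusterDef
    feature: Feature
    hits: list[MotifHit]
    background_flag: bool = False

    @property
    def occurrence_count(self) -> int:
        return len(self.hits)


@dataclass
class ScanReport:
    rows: list[ClusterRow]

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "cluster",
            "locus_tag",
            "first_cds",
            "occurrence_count",
            "upstream_distance",
            "annotation",
            "strand",
            "background_flag",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                base = [
                    row.cluster.name,
                    f"{row.cluster.first_cds_locus} ({row.cluster.read_direction})",
                    row.feature.locus_tag,
                    str(row.occurrence_count),
                ]
                if not row.hits:
                    fh.write(
                        "\t".join(base + [".", ".", ".", str(row.background_flag)])
                        + "\n"
                    )
                for hit in row.hits:
                    fh.write(
                        "\t".join(
                            base
                            + [
                                f"{hit.upstream_distance} bp",
                                hit.annotation,
                                _strand_display(hit.strand_label),
                                str(row.background_flag),
                            ]
                        )
                        + "\n"
                    )


def _strand_display(label: str) -> str:
    return {
        "forward": "Forward",
        "reverse": "Reverse",
        "forward_and_reverse": "Forward/reverse",
    }[label]


def _map_hit_to_genome(
    hit: MotifHit, feature: Feature, region_len: int
) -> MotifHit:
    """Attach 1-based genomic coordinates to a promoter-region hit."""
    p, L = hit.region_offset, hit.span
    if feature.strand == "forward":
        gstart = feature.start - region_len + p
        gend = gstart + L - 1
        flip = False
    else:
        gend = feature.end + region_len - p
        gstart = gend - L + 1
        flip = True
    if hit.strand_label == "forward_and_reverse":
        gstrand = "forward_and_reverse"
    else:
        motif_on_coding_fwd = hit.strand_label == "forward"
        gstrand = (
            "reverse" if (motif_on_coding_fwd == flip) else "forward"
        )
    return replace(
        hit,
        contig_id=feature.contig_id,
        genome_start=gstart,
        genome_end=gend,
        genome_strand=gstrand,
    )


def promoter_report(
    genome: GenomeRecord,
    features: Sequence[Feature],
    clusters: Sequence[ClusterDef],
    patterns: Sequence[MotifPattern] | None = None,
    *,
    window_len: int | Mapping[str, int] = 300,
    alias: Mapping[str, str] | None = None,
    flag_background: bool = True,
) -> ScanReport:
    """Scan every cluster's promoter and tabulate occurrences per cluster.

    Rows mirror the published site-table shape: occurrence count plus one line
    per hit (upstream distance, annotation, strand), hits sorted by ascending
    upstream distance. ``window_len`` may be a single length or a per-cluster
    mapping (cluster name -> bp). Regions whose hit count exceeds the 99th
    percentile of the analytic Poisson background expectation are flagged
    (flags never alter counts); random sequence matches the degenerate short
    pattern often enough that an unflagged high count would be suspect.
    """
    if patterns is None:
        patterns = default_patterns()
    index = feature_index(features, alias)
    rows: list[ClusterRow] = []
    for cluster in clusters:
        feat = resolve_cluster(cluster, index, alias)
        win = (
            window_len.get(cluster.name, 300)
            if isinstance(window_len, Mapping)
            else window_len
        )
        region = extract_upstream(genome, feat, win, cluster)
        hits = scan_region(region, patterns)
        hits = [
            _map_hit_to_genome(h, feat, len(region.sequence)) for h in hits
        ]
        flag = flag_background and len(hits) > _flag_threshold(
            patterns, len(region.sequence)
        )
        rows.append(ClusterRow(cluster=cluster, feature=feat, hits=hits, background_flag=flag))
    return ScanReport(rows=rows)


def genome_scan(
    genome: GenomeRecord,
    patterns: Sequence[MotifPattern] | None = None,
) -> list[MotifHit]:
    """Scan a whole contig (both strands) and return coordinate-sorted hits."""
    hits = scan_region(genome.sequence, patterns, is_promoter=False, nesting=False)
    out = []
    for h in hits:
        gstart = h.region_offset + 1
        out.append(
            replace(
                h,
                contig_id=genome.id,
                genome_start=gstart,
                genome_end=gstart + h.span - 1,
                genome_strand=h.strand_label,
            )
        )
    out.sort(key=lambda h: (h.genome_start, h.pattern_name, h.genomic_spacers))
    return out


_BED_STRAND = {"forward": "+", "reverse": "-", "forward_and_reverse": "."}


def write_bed(
    hits: Iterable[MotifHit],
    path: str | Path,
    patterns: Sequence[MotifPattern] | None = None,
) -> None:
    """Write hits as BED6 (0-based half-open; score = budget - edit cost)."""
    budgets = {
        p.name: p.edit_budget for p in (patterns or default_patterns())
    }
    with open(path, "w") as fh:
        for h in hits:
            if h.genome_start is None:
                raise ValueError("hit lacks genomic coordinates; run genome_scan")
            score = budgets.get(h.pattern_name, 0) - h.edit_cost
            fh.write(
                "\t".join(
                    [
                        h.contig_id or ".",
                        str(h.genome_start - 1),
                        str(h.genome_end),
                        h.annotation.replace(" ", "_"),
                        str(score),
                        _BED_STRAND[h.genome_strand or h.strand_label],
                    ]
                )
                + "\n"
            )
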
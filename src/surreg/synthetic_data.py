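"""Synthetic fixtures with machine-readable ground truth.

Every generator here emulates one input class of the analysis pipeline:

* promoters and genomes with SurR motif variants planted at known upstream
  distances on backgrounds *verified* hit-free at the scanner's budgets;
* exponential growth curves with multiplicative (lognormal) counting noise;
* qPCR Ct tables with planted expression ratios.

Each fixture is paired with a :class:`SyntheticTruth` record sufficient to
recompute the expected analysis output without re-running the generator, and
is bit-reproducible from (seed, parameters).

Backgrounds are uniform i.i.d. {A,C,G,T}: the scanner's budgets make random
matches common enough that only scan-and-repair verification (rescan, then
re-randomize the unconstrained bases under any unplanted occurrence until
none remain) guarantees clean counts; genome-like composition would add
nothing to that guarantee.

Overlapping plants are permitted when, after resolving base conflicts at
shared block positions, every plant still scores within its pattern's edit
budget. The T. barophilus site tables contain such pairs (long sites 8 bp
apart upstream of the Mrp-Mbh1 and Mrp-Mbs clusters), whose footprints
overlap by 9 bp; the conflict resolution charges the unavoidable extra
mismatches to the affected plants and records the realized costs in the
truth sidecar.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .growth_kinetics import Condition, GrowthCurve
from .motif_scan import (
    MotifPattern,
    compile_pattern,
    default_patterns,
    scan_region,
)
from .sequence_io import (
    ClusterDef,
    Feature,
    GenomeRecord,
    reverse_complement,
)

__all__ = [
    "Plant",
    "PromoterPlan",
    "SyntheticTruth",
    "PlanError",
    "build_promoter",
    "build_genome",
    "simulate_growth",
    "simulate_growth_table",
    "simulate_ct",
    "SURR_SITE_PLANS",
    "SURR_SITE_GENE_LAYOUT",
]

_BASES = np.array(list("ACGT"))


class PlanError(ValueError):
    """Raised when a promoter plan cannot be realized."""


@dataclass(frozen=True)
class Plant:
    """One motif variant to plant: its literal string, distance, orientation."""

    variant: str  # e.g. "GTTn3AATn5GTT" — blocks as they should read
    upstream_distance: int  # bases between proximal motif edge and start codon
    orientation: str  # "forward" | "reverse" (relative to the region)

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.upstream_distance < 0:
            raise ValueError("upstream_distance must be >= 0")


@dataclass(frozen=True)
class PromoterPlan:
    """A promoter to synthesize: plants on a verified hit-free background."""

    cluster_name: str
    plants: tuple[Plant, ...]
    window_len: int = 300


@dataclass
class SyntheticTruth:
    """Planted parameters paired with a fixture; JSON-serializable."""

    kind: str
    seed: int | None
    params: dict
    planted: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "seed": self.seed,
                    "params": self.params,
                    "planted": self.planted,
                },
                fh,
                indent=2,
                default=_jsonable,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# promoter / genome construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Placement:
    """A plant resolved to absolute region offsets."""

    plant: Plant
    pattern: MotifPattern
    offset: int
    span: int
    reading_spacers: tuple[int, ...]
    # genomic-oriented templates: position -> base
    variant_demands: dict[int, str]
    canonical_demands: dict[int, str]
    spacer_cost: int

    @property
    def genomic_spacers(self) -> tuple[int, ...]:
        if self.plant.orientation == "reverse":
            return tuple(reversed(self.reading_spacers))
        return self.reading_spacers


def _parse_variant(variant: str, patterns: Mapping[str, MotifPattern]):
    parsed = compile_pattern(variant, name="_variant", edit_budget=0)
    name = {2: "short", 3: "long"}.get(len(parsed.blocks))
    if name is None or name not in patterns:
        raise PlanError(f"variant {variant!r} matches no scanned pattern")
    pattern = patterns[name]
    if tuple(len(b) for b in parsed.blocks) != tuple(
        len(b) for b in pattern.blocks
    ):
        raise PlanError(f"variant {variant!r}: block lengths differ from {name}")
    return pattern, parsed.blocks, parsed.spacer_lens


def _layout(blocks: Sequence[str], spacers: Sequence[int]) -> list[tuple[int, str]]:
    """(relative position, base) for every block base, reading order."""
    out = []
    pos = 0
    for i, block in enumerate(blocks):
        for j, base in enumerate(block):
            out.append((pos + j, base))
        pos += len(block)
        if i < len(spacers):
            pos += spacers[i]
    return out


def _place(plant: Plant, window_len: int, patterns: Mapping[str, MotifPattern]) -> _Placement:
    pattern, blocks, spacers = _parse_variant(plant.variant, patterns)
    devs = [r - c for r, c in zip(spacers, pattern.spacer_lens)]
    if any(abs(d) > pattern.spacer_flex for d in devs):
        raise PlanError(
            f"variant {plant.variant!r}: spacer lengths outside flex window"
        )
    span = sum(len(b) for b in blocks) + sum(spacers)
    offset = window_len - plant.upstream_distance - span
    if offset < 0:
        raise PlanError(
            f"plant {plant.variant!r} at {plant.upstream_distance} bp does not "
            f"fit in a {window_len} bp window"
        )
    var_rel = _layout(blocks, spacers)
    canon_rel = _layout(pattern.blocks, spacers)
    if plant.orientation == "reverse":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        var_rel = [(span - 1 - p, comp[b]) for p, b in var_rel]
        canon_rel = [(span - 1 - p, comp[b]) for p, b in canon_rel]
    return _Placement(
        plant=plant,
        pattern=pattern,
        offset=offset,
        span=span,
        reading_spacers=tuple(spacers),
        variant_demands={offset + p: b for p, b in var_rel},
        canonical_demands={offset + p: b for p, b in canon_rel},
        spacer_cost=sum(abs(d) for d in devs),
    )


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _genomic_block_demands(
    pattern: MotifPattern, offset: int, genomic_spacers: Sequence[int], orientation: str
) -> list[tuple[int, str]] | None:
    """(position, required base) pairs for one candidate occurrence.

    Returns None when the orientation's reading-order spacers fall outside
    the pattern's flex window (the occurrence cannot exist).
    """
    reading = (
        tuple(reversed(genomic_spacers))
        if orientation == "reverse"
        else tuple(genomic_spacers)
    )
    if any(
        abs(r - c) > pattern.spacer_flex
        for r, c in zip(reading, pattern.spacer_lens)
    ):
        return None
    rel = _layout(pattern.blocks, reading)
    if orientation == "reverse":
        span = pattern.span(reading)
        rel = [(span - 1 - p, _COMP[b]) for p, b in rel]
    return [(offset + p, b) for p, b in rel]


def _suppressed_prefix_sites(placements: Sequence[_Placement]) -> set[tuple]:
    """(offset, "short") sites hidden by nesting resolution under planted longs."""
    sites = set()
    for pl in placements:
        if pl.pattern.name != "long":
            continue
        s1 = pl.reading_spacers[0]
        prefix_len = len(pl.pattern.blocks[0]) + s1 + len(pl.pattern.blocks[1])
        if pl.plant.orientation == "reverse":
            start = pl.offset + pl.span - prefix_len
        else:
            start = pl.offset
        sites.add((start, "short"))
    return sites


def _unavoidable_extras(
    assignment: Mapping[int, str],
    patterns: Mapping[str, MotifPattern],
    window_len: int,
    placements: Sequence[_Placement],
) -> list[tuple]:
    """Occurrences the fixed plant bases imply no matter how free bases fall.

    A candidate alignment is unavoidable when its fixed-position mismatches
    plus its free block positions (which repair can at best turn into
    mismatches) plus its spacer-shift cost still fit the edit budget. Such an
    alignment is harmless when it shares a site (offset, pattern) with a
    plant that outranks it even in that worst case — the scanner collapses
    alternative alignments of one site to the best-ranked one — or when it is
    a short site nesting-suppressed under a planted long. Anything else would
    corrupt the occurrence count, so the conflict assignment producing it
    must be rejected.
    """
    planted_rank: dict[tuple, tuple] = {}
    for pl in placements:
        mism = sum(
            1
            for pos, canon_base in pl.canonical_demands.items()
            if assignment[pos] != canon_base
        )
        planted_rank[(pl.offset, pl.pattern.name)] = (
            mism + pl.spacer_cost,
            mism,
            pl.spacer_cost,
        )
    suppressed = _suppressed_prefix_sites(placements)
    extras = []
    for pattern in patterns.values():
        for g in pattern.genomic_spacer_vectors():
            span = pattern.span(g)
            for offset in range(window_len - span + 1):
                site = (offset, pattern.name)
                if site in suppressed and pattern.name == "short":
                    continue
                for orient in ("forward", "reverse"):
                    demands = _genomic_block_demands(pattern, offset, g, orient)
                    if demands is None:
                        continue
                    reading = tuple(reversed(g)) if orient == "reverse" else g
                    spacer_cost = sum(
                        abs(r - c)
                        for r, c in zip(reading, pattern.spacer_lens)
                    )
                    mism_fixed = n_free = 0
                    for pos, base in demands:
                        if pos in assignment:
                            mism_fixed += assignment[pos] != base
                        else:
                            n_free += 1
                    worst_cost = mism_fixed + n_free + spacer_cost
                    if worst_cost > pattern.edit_budget:
                        continue
                    worst_rank = (worst_cost, mism_fixed + n_free, spacer_cost)
                    if site in planted_rank:
                        # Repair can steer free bases so the plant's own
                        # alignment wins the collapse unless this alignment
                        # outranks it even at worst case.
                        if worst_rank >= planted_rank[site]:
                            continue
                    extras.append((offset, pattern.name, g, orient, worst_cost))
    return extras


def _resolve_conflicts(
    placements: Sequence[_Placement],
    patterns: Mapping[str, MotifPattern],
    window_len: int,
) -> dict[int, str]:
    """Choose a base per block position so every plant stays within budget.

    Positions demanded identically (or by one plant only) are fixed directly.
    At conflicting positions every demanded base is tried (exhaustively over
    the — in practice one or two — conflict positions, in deterministic
    order); an assignment wins if each plant's realized edit cost (block
    mismatches vs the canonical pattern plus its spacer-shift cost) respects
    that pattern's budget *and* the fixed bases do not force an occurrence
    beyond the planted set into existence (see :func:`_unavoidable_extras`).
    """
    demands: dict[int, dict[str, None]] = {}
    for pl in placements:
        for pos, base in pl.variant_demands.items():
            demands.setdefault(pos, {})[base] = None
    conflict_pos = sorted(p for p, bases in demands.items() if len(bases) > 1)
    fixed = {
        pos: next(iter(bases)) for pos, bases in demands.items() if len(bases) == 1
    }
    candidate_sets = [sorted(demands[p]) for p in conflict_pos]
    for choice in itertools.product(*candidate_sets):
        assignment = dict(fixed)
        assignment.update(zip(conflict_pos, choice))
        over_budget = False
        for pl in placements:
            mism = sum(
                1
                for pos, canon_base in pl.canonical_demands.items()
                if assignment[pos] != canon_base
            )
            if mism + pl.spacer_cost > pl.pattern.edit_budget:
                over_budget = True
                break
        if over_budget:
            continue
        if not _unavoidable_extras(assignment, patterns, window_len, placements):
            return assignment
    raise PlanError(
        "overlapping plants cannot coexist within the edit budgets without "
        f"forcing spurious occurrences (conflicting positions: {conflict_pos})"
    )


def _realized_cost(pl: _Placement, assignment: Mapping[int, str]) -> int:
    mism = sum(
        1
        for pos, canon_base in pl.canonical_demands.items()
        if assignment[pos] != canon_base
    )
    return mism + pl.spacer_cost


def build_promoter(
    plan: PromoterPlan,
    pattern_set: Sequence[MotifPattern] | None = None,
    seed: int | np.random.Generator | None = 0,
    *,
    max_attempts: int = 1000,
) -> tuple[str, SyntheticTruth]:
    """Synthesize a promoter whose scan yields exactly the planted hits.

    The background is drawn uniform i.i.d., plant block bases are overwritten
    onto it, and the finished sequence is exhaustively scanned. Any
    occurrence beyond the planted set — background chance hits, or partial
    matches seeded by a plant's own blocks extending into adjacent background
    or spacer fill — is destroyed by re-randomizing the free (non-block)
    positions under it, and the sequence is rescanned; this repair loop runs
    until the found set equals the planted set exactly (same offsets,
    patterns, spacer geometry and edit costs). Plant scores are determined
    entirely by fixed block bases, so repairs can never disturb them.
    """
    if pattern_set is None:
        pattern_set = default_patterns()
    patterns = {p.name: p for p in pattern_set}
    rng = _rng(seed)
    placements = [_place(pl, plan.window_len, patterns) for pl in plan.plants]
    assignment = _resolve_conflicts(placements, patterns, plan.window_len)
    expected = {
        (pl.offset, pl.pattern.name, pl.genomic_spacers, _realized_cost(pl, assignment))
        for pl in placements
    }
    if len(expected) != len(placements):
        raise PlanError("two plants resolve to the same occurrence")
    seq = rng.choice(_BASES, size=plan.window_len)
    for pos, base in assignment.items():
        seq[pos] = base
    for _ in range(max_attempts):
        sequence = "".join(seq)
        hits = scan_region(sequence, pattern_set)
        found = {
            (h.region_offset, h.pattern_name, h.genomic_spacers, h.edit_cost)
            for h in hits
        }
        if found != expected:
            # Re-randomize the free (non-block) positions under every
            # unexpected hit: background and spacer interiors are
            # unconstrained, so resampling them never disturbs a plant but
            # destroys accidental matches with high probability. The planted
            # keys themselves are determined entirely by fixed block bases,
            # so they can never go missing.
            free: set[int] = set()
            for h in hits:
                key = (h.region_offset, h.pattern_name, h.genomic_spacers, h.edit_cost)
                if key in expected:
                    continue
                free.update(
                    p
                    for p in range(h.region_offset, h.region_offset + h.span)
                    if p not in assignment
                )
            if not free:
                raise PlanError(
                    "plants deterministically imply an occurrence beyond the "
                    "planted set; plan is unrealizable"
                )
            for p in sorted(free):
                seq[p] = rng.choice(_BASES)
            continue
        if found == expected:
            truth = SyntheticTruth(
                kind="promoter",
                seed=None if isinstance(seed, np.random.Generator) else seed,
                params={
                    "cluster_name": plan.cluster_name,
                    "window_len": plan.window_len,
                },
                planted={
                    "hits": [
                        {
                            "offset": pl.offset,
                            "pattern": pl.pattern.name,
                            "genomic_spacers": list(pl.genomic_spacers),
                            "edit_cost": _realized_cost(pl, assignment),
                            "upstream_distance": pl.plant.upstream_distance,
                            "orientation": pl.plant.orientation,
                            "variant": pl.plant.variant,
                        }
                        for pl in placements
                    ]
                },
            )
            return sequence, truth
    raise PlanError(
        f"no hit-free background found in {max_attempts} repair rounds; "
        "try a longer window or fewer plants"
    )


#: The SurR site arrangement upstream of each T. barophilus energy-metabolism
#: cluster: (variant string, upstream distance bp, orientation on the coding
#: strand). Short = GTTn3AAC, long = GTTn3AACn5GTT.
SURR_SITE_PLANS: dict[str, PromoterPlan] = {
    "Mrp-Mbh 1": PromoterPlan(
        "Mrp-Mbh 1",
        (
            Plant("ATTn3AAC", 21, "forward"),
            Plant("GTAn3AACn5TTT", 119, "forward"),
            Plant("GTTn3AATn5GTT", 139, "reverse"),
            Plant("ATTn3AACn5GTT", 147, "forward"),
        ),
        300,
    ),
    "Mrp-Mbh 2": PromoterPlan(
        "Mrp-Mbh 2",
        (
            Plant("GTTn3AACn5GTT", 11, "reverse"),
            Plant("GTTn3AACn5GTT", 96, "reverse"),
        ),
        300,
    ),
    "Mrp-Mbh-Codh": PromoterPlan(
        "Mrp-Mbh-Codh", (Plant("GTTn3ACC", 2, "forward"),), 300
    ),
    "SHII": PromoterPlan("SHII", (Plant("GTTn3AACn5GTT", 67, "forward"),), 200),
    "SHI": PromoterPlan(
        "SHI",
        (
            Plant("GTTn3AAGn5GTT", 94, "reverse"),
            Plant("GTTn3ATGn5GTT", 116, "forward"),
            Plant("GTTn3AAAn5GTT", 257, "forward"),
        ),
        320,
    ),
    "Mrp-Mbs": PromoterPlan(
        "Mrp-Mbs",
        (
            Plant("GTTn2AACn6GTT", 17, "forward"),
            Plant("GTTn3AAT", 53, "forward"),
            Plant("GTTn3AACn5GTT", 87, "reverse"),
            Plant("GTTn3AACn5GTT", 95, "forward"),
        ),
        300,
    ),
    "SurR": PromoterPlan(
        "SurR",
        (
            Plant("GTTn3AACn5GTT", 52, "reverse"),
            Plant("GTTn3AAC", 108, "forward"),
        ),
        300,
    ),
    "Pdo/Glutaredoxin": PromoterPlan(
        "Pdo/Glutaredoxin",
        (
            Plant("GTTn3AAC", 31, "forward"),
            Plant("GTTn3AACn5GTT", 80, "reverse"),
        ),
        200,
    ),
}

#: (cluster name, first-CDS locus tag, read direction) for the same clusters.
SURR_SITE_GENE_LAYOUT: list[tuple[str, str, str]] = [
    ("Mrp-Mbh 1", "TERMP_RS07420", "reverse"),
    ("Mrp-Mbh 2", "TERMP_RS07350", "reverse"),
    ("Mrp-Mbh-Codh", "TERMP_RS05755", "reverse"),
    ("SHII", "TERMP_RS00325", "forward"),
    ("SHI", "TERMP_RS02675", "reverse"),
    ("Mrp-Mbs", "TERMP_RS04310", "reverse"),
    ("SurR", "TERMP_RS03270", "reverse"),
    ("Pdo/Glutaredoxin", "TERMP_RS03275", "forward"),
]


def build_genome(
    plans: Sequence[tuple[PromoterPlan, str, str]] | None = None,
    pattern_set: Sequence[MotifPattern] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    contig_id: str = "synthetic_contig",
    cds_len: int = 120,
    gap_len: int = 60,
) -> tuple[GenomeRecord, list[Feature], list[ClusterDef], SyntheticTruth]:
    """Assemble verified promoters and dummy CDSs into one synthetic contig.

    ``plans`` is a sequence of (plan, locus_tag, read_direction); the default
    is the full T. barophilus cluster layout. Each promoter is placed 5' of
    its CDS in the reading orientation, so extracting the upstream window of
    each CDS at that plan's window length returns exactly the verified
    promoter sequence.
    """
    if plans is None:
        plans = [
            (SURR_SITE_PLANS[name], locus, direction)
            for name, locus, direction in SURR_SITE_GENE_LAYOUT
        ]
    rng = _rng(seed)
    parts: list[str] = []
    pos = 0  # 0-based running length
    features: list[Feature] = []
    clusters: list[ClusterDef] = []
    planted: dict[str, dict] = {}
    for plan, locus, direction in plans:
        prom, truth = build_promoter(plan, pattern_set, rng)
        gap = "".join(rng.choice(_BASES, size=gap_len))
        cds = "ATG" + "".join(rng.choice(_BASES, size=cds_len - 6)) + "TAA"
        if direction == "forward":
            segment = gap + prom + cds
            start = pos + len(gap) + len(prom) + 1  # 1-based CDS start
            end = start + cds_len - 1
        elif direction == "reverse":
            segment = gap + reverse_complement(cds) + reverse_complement(prom)
            start = pos + len(gap) + 1
            end = start + cds_len - 1
        else:
            raise PlanError(f"invalid read direction {direction!r}")
        parts.append(segment)
        pos += len(segment)
        features.append(
            Feature(
                locus_tag=locus,
                contig_id=contig_id,
                start=start,
                end=end,
                strand=direction,
            )
        )
        clusters.append(
            ClusterDef(
                name=plan.cluster_name,
                first_cds_locus=locus,
                read_direction=direction,
            )
        )
        planted[plan.cluster_name] = {
            "locus_tag": locus,
            "window_len": plan.window_len,
            **truth.planted,
        }
    genome = GenomeRecord(id=contig_id, sequence="".join(parts))
    truth = SyntheticTruth(
        kind="genome",
        seed=None if isinstance(seed, np.random.Generator) else seed,
        params={"contig_id": contig_id, "cds_len": cds_len, "gap_len": gap_len},
        planted=planted,
    )
    return genome, features, clusters, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def simulate_growth(
    mu: float,
    times: Sequence[float],
    *,
    n0: float = 2e6,
    lag_h: float = 0.0,
    capacity: float | None = None,
    noise_cv: float = 0.1,
    seed: int | np.random.Generator = 0,
    strain: str = "sim",
    condition: Condition | None = None,
    replicate_id: str = "r1",
) -> GrowthCurve:
    """Exponential growth with lag, optional carrying capacity, and noise.

    counts(t) = min(capacity, n0 * exp(mu * max(0, t - lag_h))), perturbed by
    median-preserving lognormal noise of coefficient of variation
    ``noise_cv`` (counting by chamber microscopy has multiplicative error).
    The default n0 of 2e6 cells/mL is the standard inoculation density.
    """
    if mu < 0 or n0 <= 0:
        raise ValueError("mu must be >= 0 and n0 > 0")
    if capacity is not None and capacity <= n0:
        raise ValueError("capacity must exceed n0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    t = np.asarray(times, dtype=float)
    counts = n0 * np.exp(mu * np.clip(t - lag_h, 0, None))
    if capacity is not None:
        counts = np.minimum(counts, capacity)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1 + noise_cv**2))
        counts = counts * np.exp(rng.normal(0.0, sigma, size=len(t)))
    return GrowthCurve(
        strain=strain,
        condition=condition or Condition(0.1, False, 0),
        replicate_id=replicate_id,
        times=tuple(t),
        counts=tuple(float(c) for c in counts),
    )


def simulate_growth_table(
    truth_grid: Sequence[tuple[str, Condition, float]],
    times: Sequence[float],
    *,
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int | np.random.Generator = 0,
    **kwargs,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a strain x condition grid of replicate curves as a tidy table.

    ``truth_grid`` rows are (strain, condition, true mu). Returns the counts
    table in the canonical TSV column layout plus the truth record.
    """
    rng = _rng(seed)
    rows = []
    planted = []
    for strain, cond, mu in truth_grid:
        for rep in range(1, n_replicates + 1):
            curve = simulate_growth(
                mu,
                times,
                noise_cv=noise_cv,
                seed=rng,
                strain=strain,
                condition=cond,
                replicate_id=f"r{rep}",
                **kwargs,
            )
            for t, c in zip(curve.times, curve.counts):
                rows.append(
                    {
                        "strain": strain,
                        "pressure_MPa": cond.pressure_mpa,
                        "sulfur": "present" if cond.sulfur else "absent",
                        "sulfur_conc_g_per_L": cond.sulfur_conc_g_per_l,
                        "replicate": f"r{rep}",
                        "time_h": t,
                        "cells_per_mL": c,
                    }
                )
        planted.append(
            {
                "strain": strain,
                "pressure_MPa": cond.pressure_mpa,
                "sulfur": "present" if cond.sulfur else "absent",
                "true_mu": mu,
            }
        )
    truth = SyntheticTruth(
        kind="growth",
        seed=None if isinstance(seed, np.random.Generator) else seed,
        params={"noise_cv": noise_cv, "n_replicates": n_replicates, "times": list(times)},
        planted={"rates": planted},
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_ct(
    ratio_table: pd.DataFrame,
    *,
    reference_gene: str = "pcna",
    ref_ct: float = 20.0,
    sd_bio: float = 0.3,
    sd_tech: float = 0.15,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a Ct table with planted expression ratios.

    ``ratio_table`` needs columns gene, strain, pressure_MPa, sulfur,
    sulfur_conc_g_per_L, true_ratio (the gene's expression relative to the
    reference in that group). Per biological replicate the reference Ct is
    drawn Normal(ref_ct, sd_bio); each target gene's Ct is the reference Ct
    minus log2(true_ratio) plus its own Normal(0, sd_bio) biological
    deviation; every well (reference included) then receives Normal(0,
    sd_tech) technical noise per technical replicate. With both SDs zero the
    planted ratios are recovered exactly.
    """
    required = {"gene", "strain", "pressure_MPa", "sulfur", "sulfur_conc_g_per_L", "true_ratio"}
    missing = required - set(ratio_table.columns)
    if missing:
        raise ValueError(f"ratio_table missing columns {sorted(missing)}")
    if (ratio_table["true_ratio"] <= 0).any():
        raise ValueError("true ratios must be > 0")
    rng = _rng(seed)
    group_cols = ["strain", "pressure_MPa", "sulfur", "sulfur_conc_g_per_L"]
    rows = []
    for group_key, grp in ratio_table.groupby(group_cols, sort=True):
        group = dict(zip(group_cols, group_key))
        for b in range(1, n_bio + 1):
            ref_base = ref_ct + rng.normal(0.0, sd_bio) if sd_bio > 0 else ref_ct
            gene_bases = {reference_gene: ref_base}
            for _, row in grp.iterrows():
                dev = rng.normal(0.0, sd_bio) if sd_bio > 0 else 0.0
                gene_bases[row["gene"]] = (
                    ref_base - math.log2(row["true_ratio"]) + dev
                )
            for gene, base in gene_bases.items():
                for k in range(1, n_tech + 1):
                    noise = rng.normal(0.0, sd_tech) if sd_tech > 0 else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            **group,
                            "bio_replicate": f"b{b}",
                            "tech_replicate": f"t{k}",
                            "ct": base + noise,
                        }
                    )
    truth = SyntheticTruth(
        kind="qpcr",
        seed=None if isinstance(seed, np.random.Generator) else seed,
        params={
            "reference_gene": reference_gene,
            "ref_ct": ref_ct,
            "sd_bio": sd_bio,
            "sd_tech": sd_tech,
            "n_bio": n_bio,
            "n_tech": n_tech,
        },
        planted={"ratios": ratio_table.to_dict(orient="records")},
    )
    return pd.DataFrame(rows), truth
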
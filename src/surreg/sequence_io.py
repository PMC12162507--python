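"""Genomic sequence and annotation I/O plus strand-aware promoter extraction.

Coordinates are 1-based inclusive throughout (GFF3 convention); conversion to
0-based half-open happens only at BED output time (see :mod:`surreg.motif_scan`).
A "promoter" here is the upstream window on the gene's coding strand, oriented
5'->3' and ending at the base immediately before the start codon, which is the
substrate the motif scanner operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Feature",
    "ClusterDef",
    "PromoterRegion",
    "IngestError",
    "read_fasta",
    "write_fasta",
    "read_features",
    "read_alias_table",
    "read_clusters",
    "write_clusters",
    "feature_index",
    "resolve_cluster",
    "reverse_complement",
    "extract_upstream",
    "deleted_assembly_size",
]

_VALID_CHARS = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class IngestError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: an accession-like id and its uppercase DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise IngestError(
                f"record {self.id!r}: illegal sequence characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """An annotated interval, 1-based inclusive, with strand."""

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str  # "forward" | "reverse"
    feature_kind: str = "CDS"

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError("locus_tag must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"{self.locus_tag}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClusterDef:
    """A gene cluster named by its product, anchored at the first CDS.

    For reverse read-direction clusters the "first" CDS is the one with the
    highest genomic coordinate, so its upstream region lies at higher
    coordinates and is returned in the reading orientation.
    """

    name: str
    first_cds_locus: str
    read_direction: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.read_direction not in ("forward", "reverse"):
            raise ValueError(
                f"cluster {self.name!r}: invalid read_direction "
                f"{self.read_direction!r}"
            )


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream window on the coding strand, ending just before the start codon.

    ``sequence[-1]`` is the base at gene-relative position -1. ``truncated`` is
    True iff the contig edge shortened the window below ``window_len``.
    """

    sequence: str
    window_len: int
    truncated: bool
    cluster: ClusterDef | None = None
    feature: Feature | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) > self.window_len:
            raise ValueError("promoter longer than requested window")
        if self.truncated != (len(self.sequence) < self.window_len):
            raise ValueError("truncated flag inconsistent with sequence length")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and multi-line entries concatenated. Empty files,
    duplicate ids and non-ACGTN characters raise :class:`IngestError`.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IngestError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise IngestError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, val = item.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_features(
    path: str | Path,
    dialect: str = "gff3",
    alias: Mapping[str, str] | None = None,
) -> list[Feature]:
    """Parse a minimal GFF3 dialect into CDS :class:`Feature` objects.

    Only seqid/type/start/end/strand and an ``ID=`` or ``locus_tag=``
    attribute are consulted. Non-CDS rows are kept with
    ``feature_kind="other"``. An optional alias map (old <-> new locus tags,
    from :func:`read_alias_table`) lets either naming scheme resolve; the
    canonical tag stored on the Feature is the one present in the file.
    """
    if dialect != "gff3":
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise IngestError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand_s, _phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise IngestError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start > end:
                raise IngestError(f"{path}:{lineno}: start {start} > end {end}")
            if strand_s == "+":
                strand = "forward"
            elif strand_s == "-":
                strand = "reverse"
            else:
                raise IngestError(
                    f"{path}:{lineno}: unknown strand symbol {strand_s!r}"
                )
            attr_map = _parse_gff_attributes(attrs)
            tag = attr_map.get("locus_tag") or attr_map.get("ID")
            if not tag:
                raise IngestError(
                    f"{path}:{lineno}: no ID or locus_tag attribute"
                )
            if alias is not None and tag in alias:
                # Keep the file's own tag; aliasing is applied at lookup time.
                pass
            features.append(
                Feature(
                    locus_tag=tag,
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_kind="CDS" if ftype == "CDS" else "other",
                )
            )
    return features


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping alternate locus tags to each other.

    Both directions are stored, so either an old-style or a new-style tag
    queries the same feature through :func:`feature_index`.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise IngestError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            a, b = parts
            mapping[a] = b
            mapping[b] = a
    return mapping


def feature_index(
    features: Sequence[Feature],
    alias: Mapping[str, str] | None = None,
) -> dict[str, Feature]:
    """Index features by locus tag, admitting aliased names as well."""
    index: dict[str, Feature] = {}
    for feat in features:
        index[feat.locus_tag] = feat
    if alias:
        for name, other in alias.items():
            if name not in index and other in index:
                index[name] = index[other]
    return index


def read_clusters(path: str | Path) -> list[ClusterDef]:
    """Read a cluster-definition TSV (columns: name, first_cds_locus, read_direction)."""
    clusters: list[ClusterDef] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                required = {"name", "first_cds_locus", "read_direction"}
                if not required.issubset(header):
                    raise IngestError(
                        f"{path}:{lineno}: header must contain {sorted(required)}"
                    )
                continue
            row = dict(zip(header, cols))
            try:
                clusters.append(
                    ClusterDef(
                        name=row["name"],
                        first_cds_locus=row["first_cds_locus"],
                        read_direction=row["read_direction"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise IngestError(f"{path}:{lineno}: {exc}") from exc
    return clusters


def write_clusters(clusters: Iterable[ClusterDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tfirst_cds_locus\tread_direction\n")
        for c in clusters:
            fh.write(f"{c.name}\t{c.first_cds_locus}\t{c.read_direction}\n")


def resolve_cluster(
    cluster: ClusterDef,
    features: Sequence[Feature] | Mapping[str, Feature],
    alias: Mapping[str, str] | None = None,
) -> Feature:
    """Find the cluster's first CDS, checking that strands agree."""
    index = (
        features
        if isinstance(features, Mapping)
        else feature_index(features, alias)
    )
    feat = index.get(cluster.first_cds_locus)
    if feat is None and alias is not None:
        alt = alias.get(cluster.first_cds_locus)
        if alt is not None:
            feat = index.get(alt)
    if feat is None:
        raise LookupError(
            f"cluster {cluster.name!r}: first CDS "
            f"{cluster.first_cds_locus!r} not found in annotation"
        )
    if feat.strand != cluster.read_direction:
        raise ValueError(
            f"cluster {cluster.name!r}: read_direction "
            f"{cluster.read_direction!r} disagrees with annotated strand "
            f"{feat.strand!r} of {feat.locus_tag}"
        )
    return feat


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"illegal characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_upstream(
    genome: GenomeRecord,
    feature: Feature,
    window_len: int = 300,
    cluster: ClusterDef | None = None,
) -> PromoterRegion:
    """Extract the upstream window of a CDS on its coding strand.

    Forward genes: ``genome[start-window_len .. start-1]`` as-is.
    Reverse genes: ``reverse_complement(genome[end+1 .. end+window_len])``.
    The window is truncated (never padded) at contig edges; extraction does not
    stop at neighbouring genes.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if feature.contig_id != genome.id:
        raise LookupError(
            f"feature {feature.locus_tag} is on contig {feature.contig_id!r}, "
            f"not {genome.id!r}"
        )
    if feature.end > genome.length:
        raise LookupError(
            f"feature {feature.locus_tag} extends past contig end"
        )
    if feature.strand == "forward":
        lo = max(0, feature.start - 1 - window_len)
        seq = genome.sequence[lo : feature.start - 1]
    else:
        seq = reverse_complement(
            genome.sequence[feature.end : feature.end + window_len]
        )
    return PromoterRegion(
        sequence=seq,
        window_len=window_len,
        truncated=len(seq) < window_len,
        cluster=cluster,
        feature=feature,
    )


def deleted_assembly_size(genome: GenomeRecord | int, deleted_feature_len: int) -> int:
    """Assembly size after an in-place deletion of the given length (bp)."""
    total = genome if isinstance(genome, int) else genome.length
    if deleted_feature_len < 0:
        raise ValueError("deleted_feature_len must be >= 0")
    if deleted_feature_len > total:
        raise ValueError(
            f"cannot delete {deleted_feature_len} bp from a {total} bp assembly"
        )
    return total - deleted_feature_len
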
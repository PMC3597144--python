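"""Readers and writers for the package's tab-separated external formats.

Formats (all UTF-8, tab-separated, ``#``-prefixed comment lines ignored):

* segmentation TSV — columns ``sample chrom start end n_probes total_cn``;
  one sample per file; emulates the layout of HMM segmentation output.
* probe TSV — columns ``probe_id chrom pos intensity``; one sample per file.
* gene annotation — BED6 (0-based half-open, converted on read) or GTF
  ``gene`` records (1-based inclusive, kept as-is).
* fusion report TSV — one row per candidate (11 columns) or per group member
  (13 columns, adding ``group`` and ``subgroup``).

Coordinates are 1-based inclusive internally.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .model import (
    DISCARDED,
    FusionCandidate,
    FusionGroup,
    GeneModel,
    ProbePanel,
    ProbeRecord,
    Segment,
    SegmentationProfile,
    ValidationError,
)

SEGMENTATION_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "total_cn"]
PROBE_COLUMNS = ["probe_id", "chrom", "pos", "intensity"]
CANDIDATE_COLUMNS = [
    "sample",
    "five_gene",
    "three_gene",
    "five_start",
    "five_end",
    "three_start",
    "three_end",
    "cn_five",
    "cn_three",
    "correlation",
    "rms",
]
GROUP_COLUMNS = CANDIDATE_COLUMNS + ["group", "subgroup"]


class ParseError(ValueError):
    """A malformed input row; the message names file and line."""


def _data_lines(path: Union[str, Path]):
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _int_field(value: str, what: str, path, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: {what} is not an integer: {value!r}") from None


def _float_field(value: str, what: str, path, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: {what} is not numeric: {value!r}") from None


def merge_same_cn(segments: Sequence[Segment]) -> List[Segment]:
    """Merge adjacent segments of equal copy number (probe counts summed).

    Idempotent: the result has no adjacent equal-CN pair.
    """
    merged: List[Segment] = []
    for seg in segments:
        if merged and merged[-1].total_cn == seg.total_cn:
            prev = merged.pop()
            merged.append(
                Segment(
                    chrom=prev.chrom,
                    start=prev.start,
                    end=seg.end,
                    n_probes=prev.n_probes + seg.n_probes,
                    total_cn=prev.total_cn,
                )
            )
        else:
            merged.append(seg)
    return merged


def read_segmentation(path: Union[str, Path]) -> SegmentationProfile:
    """Read a one-sample segmentation TSV into a validated profile.

    Segments are sorted per chromosome, overlap-checked, and adjacent
    segments with equal copy number are merged.
    """
    path = Path(path)
    header_seen = False
    sample_ids = set()
    rows: Dict[str, List[Segment]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != SEGMENTATION_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected header {SEGMENTATION_COLUMNS}, got {fields}"
                )
            header_seen = True
            continue
        if len(fields) != len(SEGMENTATION_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(SEGMENTATION_COLUMNS)} fields, got {len(fields)}"
            )
        sample, chrom = fields[0], fields[1]
        start = _int_field(fields[2], "start", path, lineno)
        end = _int_field(fields[3], "end", path, lineno)
        n_probes = _int_field(fields[4], "n_probes", path, lineno)
        total_cn = _int_field(fields[5], "total_cn", path, lineno)
        if start > end:
            raise ParseError(f"{path}:{lineno}: segment start {start} > end {end}")
        sample_ids.add(sample)
        try:
            seg = Segment(chrom=chrom, start=start, end=end, n_probes=n_probes, total_cn=total_cn)
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        rows.setdefault(chrom, []).append(seg)
    if not header_seen:
        raise ParseError(f"{path}: empty segmentation file (missing header)")
    if len(sample_ids) != 1:
        raise ParseError(f"{path}: expected exactly one sample id, found {sorted(sample_ids)}")
    for chrom in rows:
        rows[chrom].sort(key=lambda s: s.start)
        for a, b in zip(rows[chrom], rows[chrom][1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{path}: overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        rows[chrom] = merge_same_cn(rows[chrom])
    return SegmentationProfile(sample_id=sample_ids.pop(), segments=rows).validate()


def write_segmentation(profile: SegmentationProfile, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(SEGMENTATION_COLUMNS) + "\n")
        for chrom in profile.chromosomes():
            for seg in profile.segments[chrom]:
                out.write(
                    f"{profile.sample_id}\t{seg.chrom}\t{seg.start}\t{seg.end}"
                    f"\t{seg.n_probes}\t{seg.total_cn}\n"
                )


def read_probes(path: Union[str, Path], sample_id: Optional[str] = None) -> ProbePanel:
    """Read a probe-intensity TSV into a position-sorted panel.

    Out-of-order probes are sorted; duplicated (chrom, pos) is rejected.
    """
    path = Path(path)
    header_seen = False
    records: List[ProbeRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != PROBE_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected header {PROBE_COLUMNS}, got {fields}")
            header_seen = True
            continue
        if len(fields) != len(PROBE_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(PROBE_COLUMNS)} fields, got {len(fields)}"
            )
        records.append(
            ProbeRecord(
                probe_id=fields[0],
                chrom=fields[1],
                pos=_int_field(fields[2], "pos", path, lineno),
                intensity=_float_field(fields[3], "intensity", path, lineno),
            )
        )
    if not header_seen:
        raise ParseError(f"{path}: empty probe file (missing header)")
    if sample_id is None:
        sample_id = path.stem
    return ProbePanel(sample_id=sample_id, records=records)


def write_probes(panel: ProbePanel, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(PROBE_COLUMNS) + "\n")
        for rec in panel.records():
            out.write(f"{rec.probe_id}\t{rec.chrom}\t{rec.pos}\t{rec.intensity:.6f}\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(path: Union[str, Path], format: Optional[str] = None) -> List[GeneModel]:
    """Read gene models from BED6 or GTF.

    BED is 0-based half-open and converted to 1-based inclusive; GTF ``gene``
    records are 1-based inclusive and kept. Duplicated gene ids are rejected.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            format = "BED"
        elif suffix in (".gtf", ".gff"):
            format = "GTF"
        else:
            raise ParseError(f"{path}: cannot infer annotation format from suffix {suffix!r}")
    format = format.upper()
    if format not in ("BED", "GTF"):
        raise ParseError(f"unknown annotation format {format!r}")

    genes: List[GeneModel] = []
    seen: set = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if format == "BED":
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 fields, got {len(fields)}")
            chrom, start0, end0, name, _score, strand = fields[:6]
            start = _int_field(start0, "start", path, lineno) + 1
            end = _int_field(end0, "end", path, lineno)
            gene_id = gene_name = name
        else:
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF requires 9 fields, got {len(fields)}")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature != "gene":
                continue
            start = _int_field(start1, "start", path, lineno)
            end = _int_field(end1, "end", path, lineno)
            attributes = dict(_GTF_ATTR.findall(attrs))
            gene_id = attributes.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene record without gene_id attribute")
            gene_name = attributes.get("gene_name", gene_id)
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand character {strand!r}")
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicated gene id {gene_id!r}")
        seen.add(gene_id)
        try:
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_models_bed(genes: Sequence[GeneModel], path: Union[str, Path]) -> None:
    """Write genes as BED6 (converting back to 0-based half-open)."""
    with open(path, "w", encoding="utf-8") as out:
        for g in genes:
            out.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def _candidate_row(c: FusionCandidate) -> List[str]:
    return [
        c.sample_id,
        c.five_gene_id,
        c.three_gene_id,
        str(c.coords[0]),
        str(c.coords[1]),
        str(c.coords[2]),
        str(c.coords[3]),
        str(c.cn_pair[0]),
        str(c.cn_pair[1]),
        f"{c.correlation:.6f}",
        f"{c.rms:.6f}",
    ]


def _sort_key(row: List[str]):
    return (row[0], row[1], row[2], tuple(int(x) for x in row[3:7]))


def write_fusion_report(
    items: Union[Sequence[FusionCandidate], Sequence[FusionGroup], pd.DataFrame],
    path: Union[str, Path],
) -> None:
    """Write a candidate report (11 columns) or grouped report (13 columns).

    Rows are ordered by (sample, gene pair, coordinates); serialization is
    deterministic, so writing a parsed report reproduces it byte-for-byte.
    """
    if isinstance(items, pd.DataFrame):
        if items.dtypes.get("correlation") != object:
            items = format_report_df(items)
        columns = list(items.columns)
        rows = [[str(v) for v in rec] for rec in items.itertuples(index=False)]
    else:
        items = list(items)
        if items and isinstance(items[0], FusionGroup):
            columns = GROUP_COLUMNS
            rows = []
            for gi, group in enumerate(
                sorted(items, key=lambda g: g.gene_pair), start=1
            ):
                labels = group.subgroup_labels or [""] * len(group.members)
                for member, label in zip(group.members, labels):
                    rows.append(_candidate_row(member) + [str(gi), str(label)])
        else:
            columns = CANDIDATE_COLUMNS
            rows = [_candidate_row(c) for c in items]
    rows.sort(key=_sort_key)
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(columns) + "\n")
        for row in rows:
            out.write("\t".join(row) + "\n")


def read_fusion_report(path: Union[str, Path]) -> pd.DataFrame:
    """Read a fusion report back into a typed DataFrame."""
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    if list(df.columns) not in (CANDIDATE_COLUMNS, GROUP_COLUMNS):
        raise ParseError(f"{path}: unexpected fusion-report columns {list(df.columns)}")
    for col in ["five_start", "five_end", "three_start", "three_end", "cn_five", "cn_three"]:
        df[col] = df[col].astype(int)
    for col in ["correlation", "rms"]:
        df[col] = df[col].astype(float)
    if "group" in df.columns:
        df["group"] = df["group"].astype(int)
        # subgroup stays textual: integers mixed with the DISCARDED marker
        df["subgroup"] = df["subgroup"].astype(str)
    return df


def candidates_from_report(df: pd.DataFrame) -> List[FusionCandidate]:
    """Rebuild flat candidates from a parsed candidate report (for grouping)."""
    out: List[FusionCandidate] = []
    for row in df.itertuples(index=False):
        coords = (row.five_start, row.five_end, row.three_start, row.three_end)
        out.append(
            FusionCandidate(
                sample_id=row.sample,
                five_gene_id=row.five_gene,
                three_gene_id=row.three_gene,
                coords=coords,
                cn_pair=(row.cn_five, row.cn_three),
                correlation=row.correlation,
                rms=row.rms,
                fusion_len_bp=(coords[1] - coords[0] + 1) + (coords[3] - coords[2] + 1),
            )
        )
    return out


def format_report_df(df: pd.DataFrame) -> pd.DataFrame:
    """Render a typed report DataFrame back to the canonical string form."""
    out = df.copy()
    for col in ["five_start", "five_end", "three_start", "three_end", "cn_five", "cn_three"]:
        out[col] = out[col].map(str)
    for col in ["correlation", "rms"]:
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    if "group" in out.columns:
        out["group"] = out["group"].map(str)
        out["subgroup"] = out["subgroup"].map(str)
    return out
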
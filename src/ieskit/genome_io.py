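"""Readers/writers, coordinate maps and alignment filters shared by all stages.

Two reference spaces are used throughout the package:

* **MAC** -- the somatic genome, from which every IES has been excised; an
  excised IES leaves a single junction TA dinucleotide behind.
* **MAC+IES** ("MIC" for brevity) -- the same scaffolds with the IESs
  re-inserted.  An IES occupies ``[start, start + length + 2)`` on a MAC+IES
  scaffold, where ``length`` follows the one-TA convention: the stored
  sequence includes both boundary TAs and is ``length + 2`` long, and
  deleting ``[start, start + length)`` reproduces the MAC scaffold, leaving
  the right-hand TA as the MAC junction.

All interval arithmetic is 0-based half-open internally; GFF3 output is
1-based inclusive.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


GFF_SOURCE = "ieskit"
GFF_TYPE = "internal_eliminated_sequence"


class FormatError(ValueError):
    """Malformed input file (FASTA/GFF3/SAM)."""


class ValidationError(ValueError):
    """Annotation inconsistent with the reference genomes."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: uppercase sequence}`` map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate scaffold name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty record {rec.id!r} in {path}")
        genome[rec.id] = seq
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return path


# ---------------------------------------------------------------------------
# IES annotations
# ---------------------------------------------------------------------------

@dataclass
class IesAnnotation:
    """A TA-bounded IES on a MAC+IES scaffold (one-TA length convention)."""

    ies_id: str
    scaffold: str            # MAC+IES scaffold
    start: int               # 0-based, first base of the left TA
    length: int              # one-TA length (bp)
    sequence: str            # full sequence incl. both TAs, len == length + 2
    mac_scaffold: str
    mac_junction: int        # 0-based position of the junction TA's T on MAC

    @property
    def end(self) -> int:
        """End (exclusive) of the full IES interval incl. both TAs."""
        return self.start + self.length + 2

    def validate(self) -> None:
        if self.length < 26:
            raise ValidationError(f"{self.ies_id}: IES length {self.length} < 26")
        if len(self.sequence) != self.length + 2:
            raise ValidationError(
                f"{self.ies_id}: sequence length {len(self.sequence)} != length+2"
            )
        if not (self.sequence.startswith("TA") and self.sequence.endswith("TA")):
            raise ValidationError(f"{self.ies_id}: sequence not TA-bounded")


def write_gff3(annotations: Sequence[IesAnnotation], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = (
                f"ID={a.ies_id};ies_length={a.length};"
                f"mac_scaffold={a.mac_scaffold};mac_junction={a.mac_junction}"
            )
            fh.write(
                f"{a.scaffold}\t{GFF_SOURCE}\t{GFF_TYPE}\t{a.start + 1}\t{a.end}\t"
                f".\t+\t.\t{attrs}\n"
            )
    return path


def write_bed(annotations: Sequence[IesAnnotation], path: str | Path) -> Path:
    """BED 6+2 alternative (extra columns: mac_scaffold, mac_junction)."""
    path = Path(path)
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.scaffold}\t{a.start}\t{a.end}\t{a.ies_id}\t{a.length}\t+\t"
                f"{a.mac_scaffold}\t{a.mac_junction}\n"
            )
    return path


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, mic_genome: dict[str, str] | None = None) -> list[IesAnnotation]:
    """Read IES annotations from GFF3.

    The IES sequence is not stored in the GFF3; it is recovered from
    ``mic_genome`` when given, otherwise left empty (and ``validate`` will
    fail until filled in).
    """
    anns: list[IesAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            scaffold, _src, ftype, start1, end1, _score, _strand, _phase, attr = fields
            if ftype != GFF_TYPE:
                continue
            attrs = _parse_gff3_attributes(attr)
            start = int(start1) - 1
            length = int(attrs.get("ies_length", int(end1) - start - 2))
            seq = ""
            if mic_genome is not None:
                if scaffold not in mic_genome:
                    raise ValidationError(
                        f"{attrs.get('ID', '?')}: scaffold {scaffold!r} missing from genome"
                    )
                seq = mic_genome[scaffold][start:start + length + 2]
            anns.append(
                IesAnnotation(
                    ies_id=attrs.get("ID", f"ies_{lineno}"),
                    scaffold=scaffold,
                    start=start,
                    length=length,
                    sequence=seq,
                    mac_scaffold=attrs.get("mac_scaffold", scaffold),
                    mac_junction=int(attrs.get("mac_junction", -1)),
                )
            )
    return anns


def load_annotations(
    path: str | Path,
    mic_genome: dict[str, str],
    mac_genome: dict[str, str],
    check_window: int = 20,
) -> list[IesAnnotation]:
    """Read annotations and validate each against both reference genomes.

    Checks per record: the scaffold exists, the MAC+IES slice is TA-bounded
    and matches the stored convention, and excising ``[start, start+length)``
    locally reproduces the MAC sequence around ``mac_junction``.
    """
    anns = read_gff3(path, mic_genome=mic_genome)
    errors: list[str] = []
    for a in anns:
        try:
            a.validate()
        except ValidationError as exc:
            errors.append(str(exc))
            continue
        if a.mac_scaffold not in mac_genome:
            errors.append(f"{a.ies_id}: MAC scaffold {a.mac_scaffold!r} missing")
            continue
        mic = mic_genome[a.scaffold]
        mac = mac_genome[a.mac_scaffold]
        if mic[a.start:a.end] != a.sequence:
            errors.append(f"{a.ies_id}: MAC+IES slice does not match sequence")
            continue
        j = a.mac_junction
        if mac[j:j + 2] != "TA":
            errors.append(f"{a.ies_id}: MAC junction at {j} is not TA")
            continue
        w = check_window
        excised = mic[max(0, a.start - w):a.start] + mic[a.start + a.length:a.start + a.length + 2 + w]
        local = mac[max(0, j - w):j + 2 + w]
        if excised != local:
            errors.append(f"{a.ies_id}: excision does not reproduce MAC around junction {j}")
    if errors:
        raise ValidationError("; ".join(errors))
    return anns


# ---------------------------------------------------------------------------
# Coordinate mapping between MAC and MAC+IES space
# ---------------------------------------------------------------------------

class CoordinateMap:
    """Lift coordinates between MAC and MAC+IES scaffolds.

    Built from the IES annotations of one scaffold pair; MAC position ``p``
    maps to MAC+IES position ``p + sum(length of IESs with mac_junction <= p)``.
    """

    def __init__(self, annotations: Iterable[IesAnnotation]):
        per_scaffold: dict[str, list[IesAnnotation]] = {}
        for a in annotations:
            per_scaffold.setdefault(a.scaffold, []).append(a)
        self._junctions: dict[str, list[int]] = {}
        self._starts: dict[str, list[int]] = {}
        self._cumlen: dict[str, list[int]] = {}
        for scaf, anns in per_scaffold.items():
            anns.sort(key=lambda a: a.start)
            self._junctions[scaf] = [a.mac_junction for a in anns]
            self._starts[scaf] = [a.start for a in anns]
            cum = [0]
            for a in anns:
                cum.append(cum[-1] + a.length)
            self._cumlen[scaf] = cum

    def mac_to_mic(self, scaffold: str, pos: int) -> int:
        js = self._junctions.get(scaffold, [])
        k = bisect.bisect_right(js, pos)
        return pos + self._cumlen.get(scaffold, [0])[k]

    def mic_to_mac(self, scaffold: str, pos: int) -> int | None:
        """MAC position of a MAC+IES coordinate; None for IES-internal bases.

        Bases of the shared right TA map to the MAC junction TA.
        """
        starts = self._starts.get(scaffold, [])
        js = self._junctions.get(scaffold, [])
        cum = self._cumlen.get(scaffold, [0])
        k = bisect.bisect_right(starts, pos) - 1
        if k >= 0:
            ies_excised_end = starts[k] + (cum[k + 1] - cum[k])  # start + length
            if pos < ies_excised_end:
                return None  # inside the deleted part of IES k
            return pos - cum[k + 1]
        return pos - cum[0] if k == -1 else pos


# ---------------------------------------------------------------------------
# SAM helpers and alignment filtering
# ---------------------------------------------------------------------------

def sam_header(genome: dict[str, str]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return [r for r in fh if not r.is_unmapped]


@dataclass
class FilterReport:
    kept_pairs: int = 0
    dropped_nonunique: int = 0
    dropped_orphans: int = 0
    counts: Counter = field(default_factory=Counter)


def filter_unique_pairs(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], FilterReport]:
    """Keep only read pairs in which both mates map uniquely.

    Uniqueness is the producer's flag: mapping quality > 0.  Orphan mates
    (a query name seen for only one of the two mates) are skipped and
    counted.  The operation is idempotent.
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        by_name.setdefault(rec.query_name, []).append(rec)
    kept: list[pysam.AlignedSegment] = []
    report = FilterReport()
    for _name, recs in by_name.items():
        mates = {r.is_read2 for r in recs}
        if len(recs) != 2 or mates != {False, True}:
            report.dropped_orphans += len(recs)
            continue
        if all(r.mapping_quality > 0 for r in recs):
            kept.extend(recs)
            report.kept_pairs += 1
        else:
            report.dropped_nonunique += 2
    return kept, report


# ---------------------------------------------------------------------------
# Two-stage sRNA assignment (MAC first, then MAC+IES)
# ---------------------------------------------------------------------------

def srna_two_stage_assign(
    mac_records: Iterable[pysam.AlignedSegment] | str | Path,
    mic_records: Iterable[pysam.AlignedSegment] | str | Path,
    size_range: tuple[int, int] = (15, 35),
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Assign sRNA reads to MAC space first, then to MAC+IES space.

    A read with an exact match in the MAC set is assigned to MAC space;
    otherwise, if present in the MAC+IES set, it is assigned there.  Reads
    matching multiple locations in their assigned reference (more than one
    record, or flagged non-unique with mapping quality 0) are dropped.

    Returns a DataFrame (read, space, scaffold, start, length) and the
    per-length totals of assigned reads inside ``size_range`` (inclusive),
    used downstream for density normalization.
    """
    if isinstance(mac_records, (str, Path)):
        mac_records = read_sam(mac_records)
    if isinstance(mic_records, (str, Path)):
        mic_records = read_sam(mic_records)

    def collect(records):
        hits: dict[str, list[pysam.AlignedSegment]] = {}
        for r in records:
            hits.setdefault(r.query_name, []).append(r)
        return hits

    mac_hits = collect(mac_records)
    mic_hits = collect(mic_records)

    rows = []
    lo, hi = size_range
    totals: dict[int, int] = {n: 0 for n in range(lo, hi + 1)}
    for name, recs in mac_hits.items():
        if len(recs) != 1 or recs[0].mapping_quality == 0:
            continue
        r = recs[0]
        rows.append((name, "mac", r.reference_name, r.reference_start, r.query_length))
    for name, recs in mic_hits.items():
        if name in mac_hits:
            continue
        if len(recs) != 1 or recs[0].mapping_quality == 0:
            continue
        r = recs[0]
        rows.append((name, "mic", r.reference_name, r.reference_start, r.query_length))
    df = pd.DataFrame(rows, columns=["read", "space", "scaffold", "start", "length"])
    for n in df["length"]:
        if lo <= n <= hi:
            totals[n] += 1
    return df, totals


def iter_sam_paths(paths: Sequence[str | Path]) -> Iterator[pysam.AlignedSegment]:
    for p in paths:
        yield from read_sam(p)
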
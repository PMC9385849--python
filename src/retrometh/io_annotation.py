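"""Probe-to-repeat annotation.

Reads BED-like repeat annotations and CpG-probe manifests, intersects the
two, and assigns each repeat-resident probe an element class, a named
subfamily, and an evolutionary-age class.

Coordinate conventions
----------------------
Repeat intervals are 0-based half-open (BED).  Manifest positions are
1-based cytosine positions; the CpG dinucleotide of a probe at position
``pos`` occupies the half-open interval ``[pos - 1, pos + 1)``.  A probe is
repeat-resident iff that 2-bp footprint overlaps a repeat by at least 1 bp;
strand is ignored for the overlap (CpG methylation is symmetric) but kept
as metadata.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RepeatInterval",
    "ProbeRecord",
    "RepeatTaxon",
    "AnnotatedProbe",
    "AnnotationParseError",
    "GENE_FEATURES",
    "NAMED_FAMILIES",
    "AGE_BY_FAMILY",
    "classify_repeat_name",
    "read_repeat_annotation",
    "read_probe_manifest",
    "annotate_probes",
    "annotation_frame",
    "write_annotated_probes",
    "read_annotated_probes",
]

#: Gene-region feature vocabulary used on the array manifest.
GENE_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")

#: Fixed family -> evolutionary-age mapping.
AGE_BY_FAMILY = {
    "L1M": "old",
    "AluJ": "old",
    "L1P": "intermediate",
    "L1PB": "intermediate",
    "AluS": "intermediate",
    "L1HS": "young",
    "L1PA": "young",
    "AluY": "young",
    "HAL1": "related",
    "FAM": "related",
    "FLAM": "related",
    "FRAM": "related",
}

NAMED_FAMILIES = tuple(AGE_BY_FAMILY)

# Prefix rules in precedence order: longest LINE-1 prefixes first so that
# e.g. "L1PA3" matches L1PA and not L1P, and "L1MB3" matches L1M.
_PREFIX_RULES = (
    ("L1HS", "LINE1", "L1HS"),
    ("L1PA", "LINE1", "L1PA"),
    ("L1PB", "LINE1", "L1PB"),
    ("L1P", "LINE1", "L1P"),
    ("L1M", "LINE1", "L1M"),
    ("HAL1", "related", "HAL1"),
    ("AluJ", "Alu", "AluJ"),
    ("AluS", "Alu", "AluS"),
    ("AluY", "Alu", "AluY"),
    ("FLAM", "related", "FLAM"),
    ("FRAM", "related", "FRAM"),
    ("FAM", "related", "FAM"),
)


class AnnotationParseError(ValueError):
    """Raised when an annotation or manifest file is malformed."""


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat element occurrence on the genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.name:
            raise ValueError("repeat name must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must be > start ({self.start}) for {self.name}"
            )


@dataclass(frozen=True)
class ProbeRecord:
    """A CpG probe from the array manifest (1-based cytosine position)."""

    probe_id: str
    chrom: str
    pos: int
    strand: str = "."
    gene_names: tuple = ()
    gene_features: tuple = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: pos must be >= 1")
        if len(self.gene_names) != len(self.gene_features):
            raise ValueError(
                f"probe {self.probe_id}: gene_names and gene_features differ in length"
            )


@dataclass(frozen=True)
class RepeatTaxon:
    """Element class / family / age class triple for a repeat name."""

    element_class: str
    family: str
    age_class: str


_UNCLASSIFIED = RepeatTaxon("unclassified", "unclassified", "unclassified")


@dataclass(frozen=True)
class AnnotatedProbe:
    """A probe joined to its (single) host repeat, if any."""

    probe: ProbeRecord
    repeat: Optional[RepeatInterval]
    taxon: RepeatTaxon
    overlap_bp: int = 0

    @property
    def is_repeat_resident(self) -> bool:
        return self.repeat is not None


def classify_repeat_name(repeat_name: str) -> RepeatTaxon:
    """Classify a RepeatMasker-style name into (element class, family, age).

    Longest-prefix matching with precedence L1HS > L1PA > L1PB > L1P > L1M
    for LINE-1 names; AluJ/AluS/AluY for Alu; HAL1/FLAM/FRAM/FAM for the
    related half-L1 and Alu-monomer families.  Unmatched names classify as
    unclassified; this never raises.
    """
    if not repeat_name:
        raise ValueError("repeat name must be non-empty")
    for prefix, element_class, family in _PREFIX_RULES:
        if repeat_name.startswith(prefix):
            return RepeatTaxon(element_class, family, AGE_BY_FAMILY[family])
    return _UNCLASSIFIED


def read_repeat_annotation(path) -> list:
    """Read a BED4/BED6 repeat annotation into ``RepeatInterval`` records.

    Coordinates are parsed as 0-based half-open; records are returned in
    file order.  Malformed lines raise :class:`AnnotationParseError` naming
    the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"line {lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            try:
                intervals.append(RepeatInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
    return intervals


_MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "strand", "gene_names", "gene_features")


def read_probe_manifest(path) -> list:
    """Read a probe-manifest CSV into ``ProbeRecord`` objects.

    The gene columns hold ";"-separated parallel lists; empty columns yield
    empty lists.  Unequal list lengths raise :class:`AnnotationParseError`
    naming the probe.
    """
    probes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise AnnotationParseError(f"manifest missing columns: {missing}")
        for row in reader:
            probe_id = row["probe_id"]
            genes = tuple(g for g in row["gene_names"].split(";") if g) if row["gene_names"] else ()
            feats = tuple(f for f in row["gene_features"].split(";") if f) if row["gene_features"] else ()
            if len(genes) != len(feats):
                raise AnnotationParseError(
                    f"probe {probe_id}: gene_names and gene_features have different lengths"
                )
            try:
                pos = int(row["pos"])
            except ValueError as exc:
                raise AnnotationParseError(f"probe {probe_id}: non-integer pos {row['pos']!r}") from exc
            try:
                probes.append(
                    ProbeRecord(probe_id, row["chrom"], pos, row["strand"] or ".", genes, feats)
                )
            except ValueError as exc:
                raise AnnotationParseError(f"probe {probe_id}: {exc}") from exc
    return probes


def annotate_probes(probes: Sequence, repeats: Sequence) -> list:
    """Assign each probe its host repeat (maximal overlap) and taxon.

    The CpG footprint is ``[pos - 1, pos + 1)``.  When several repeats
    overlap a probe, the one with maximal ``overlap_bp`` wins; ties break on
    (chrom, start, repeat name), so the result is independent of repeat
    input order.  Probe order is preserved in the output.
    """
    by_chrom: dict = {}
    for rep in sorted(repeats, key=lambda r: (r.chrom, r.start, r.name, r.end)):
        by_chrom.setdefault(rep.chrom, []).append(rep)
    arrays = {
        chrom: (
            np.array([r.start for r in reps], dtype=np.int64),
            np.array([r.end for r in reps], dtype=np.int64),
        )
        for chrom, reps in by_chrom.items()
    }

    out = []
    for probe in probes:
        s, e = probe.pos - 1, probe.pos + 1
        best = None
        best_ov = 0
        if probe.chrom in arrays:
            starts, ends = arrays[probe.chrom]
            hit = np.nonzero((starts < e) & (ends > s))[0]
            if hit.size:
                ov = np.minimum(ends[hit], e) - np.maximum(starts[hit], s)
                k = hit[int(np.argmax(ov))]  # first max == coordinate tie-break
                best = by_chrom[probe.chrom][k]
                best_ov = int(ov.max())
        if best is None:
            out.append(AnnotatedProbe(probe, None, _UNCLASSIFIED, 0))
        else:
            out.append(AnnotatedProbe(probe, best, classify_repeat_name(best.name), best_ov))
    return out


def annotation_frame(annotated: Iterable) -> pd.DataFrame:
    """Flatten annotated probes to a DataFrame (one row per probe)."""
    rows = []
    for ap in annotated:
        rows.append(
            {
                "probe_id": ap.probe.probe_id,
                "chrom": ap.probe.chrom,
                "pos": ap.probe.pos,
                "repeat_name": ap.repeat.name if ap.repeat else "",
                "element_class": ap.taxon.element_class,
                "family": ap.taxon.family,
                "age_class": ap.taxon.age_class,
                "overlap_bp": ap.overlap_bp,
                "gene_names": ";".join(ap.probe.gene_names),
                "gene_features": ";".join(ap.probe.gene_features),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "chrom", "pos", "repeat_name", "element_class",
            "family", "age_class", "overlap_bp", "gene_names", "gene_features",
        ],
    )


def write_annotated_probes(annotated: Iterable, path) -> None:
    annotation_frame(annotated).to_csv(path, sep="\t", index=False)


def read_annotated_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str})
    for col in ("repeat_name", "gene_names", "gene_features"):
        df[col] = df[col].fillna("")
    return df
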
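"""Filtering, classification and quantification of small-RNA tag libraries.

A library is a set of collapsed tags: unique sequences with read counts.
Tags are classified against an annotation catalog by exact, full-length,
sense-strand sequence identity; a tag matching several categories is
assigned by a precedence order (miRNA first by default).  Per-miRNA digital
expression is the sum of reads over all isoforms of a gene, reported both
as raw counts and counts per million (CPM).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CATEGORIES", "DEFAULT_PRECEDENCE", "Catalog", "TagLibrary",
    "ClassifiedLibrary", "MiRNAProfile", "filter_tags", "classify_tags",
    "composition", "quantify_mirnas", "detection_summary",
]

#: Annotation categories, in default precedence order (unannotated last).
CATEGORIES = ("known_miRNA", "tRNA", "other_ncRNA", "genic_mRNA", "unannotated")
DEFAULT_PRECEDENCE = ("known_miRNA", "tRNA", "other_ncRNA", "genic_mRNA")


@dataclass
class TagLibrary:
    """Collapsed small-RNA tags: unique sequence -> read count."""

    library_id: str
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return int(sum(self.tags.values()))

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str | None = None) -> "TagLibrary":
        """Read a ``sequence<TAB>count`` file (no header)."""
        path = Path(path)
        tags: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                seq, count = line.split("\t")
                tags[seq] = tags.get(seq, 0) + int(count)
        return cls(library_id or path.stem, tags)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for seq, count in self.tags.items():
                fh.write(f"{seq}\t{count}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, library_id: str | None = None) -> "TagLibrary":
        """Read tags from FASTA; a ``count=N`` token in the header sets the
        read count (default 1); identical sequences are collapsed."""
        path = Path(path)
        tags: dict[str, int] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            count = 1
            for token in rec.description.split():
                if token.startswith("count="):
                    count = int(token[len("count="):])
            seq = str(rec.seq).upper().replace("U", "T")
            tags[seq] = tags.get(seq, 0) + count
        return cls(library_id or path.stem, tags)

    @classmethod
    def from_fastq(
        cls,
        path: str | Path,
        library_id: str | None = None,
        min_mean_quality: float | None = None,
    ) -> "TagLibrary":
        """Collapse a FASTQ file into tags, optionally dropping reads whose
        mean Phred quality is below ``min_mean_quality``."""
        path = Path(path)
        tags: dict[str, int] = {}
        for rec in SeqIO.parse(str(path), "fastq"):
            if min_mean_quality is not None:
                quals = rec.letter_annotations["phred_quality"]
                if quals and sum(quals) / len(quals) < min_mean_quality:
                    continue
            seq = str(rec.seq).upper().replace("U", "T")
            tags[seq] = tags.get(seq, 0) + 1
        return cls(library_id or path.stem, tags)


class Catalog:
    """Annotation catalog: category -> {sequence -> feature ids}.

    miRNA isoforms share a gene-level feature id, so several catalog
    sequences may map to the same miRNA gene.  One sequence may in
    principle occur under a single category with several feature ids
    (ambiguous tags); classification keeps all of them.
    """

    def __init__(self) -> None:
        self._by_category: dict[str, dict[str, tuple[str, ...]]] = {
            c: {} for c in CATEGORIES if c != "unannotated"
        }

    def add(self, category: str, sequence: str, feature: str) -> None:
        if category not in self._by_category:
            raise ValueError(f"unknown category {category!r}")
        seq = sequence.upper().replace("U", "T")
        existing = self._by_category[category].get(seq, ())
        if feature not in existing:
            self._by_category[category][seq] = existing + (feature,)

    def lookup(self, category: str, sequence: str) -> tuple[str, ...]:
        return self._by_category[category].get(sequence, ())

    def sequences(self, category: str) -> dict[str, tuple[str, ...]]:
        return dict(self._by_category[category])

    def features(self, category: str) -> set[str]:
        out: set[str] = set()
        for feats in self._by_category[category].values():
            out.update(feats)
        return out

    def all_sequences(self) -> set[str]:
        out: set[str] = set()
        for d in self._by_category.values():
            out.update(d)
        return out

    def to_fasta(self, path: str | Path) -> None:
        """Write one record per catalog sequence, header ``gene|isoform|category``."""
        records = []
        for category, seqs in self._by_category.items():
            iso = defaultdict(int)
            for seq, feats in seqs.items():
                for feat in feats:
                    iso[feat] += 1
                    rid = f"{feat}|iso{iso[feat]}|{category}"
                    records.append(SeqRecord(Seq(seq), id=rid, description=""))
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Catalog":
        cat = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            feat, _iso, category = rec.id.split("|")
            cat.add(category, str(rec.seq), feat)
        return cat


@dataclass
class ClassifiedLibrary:
    """Per-tag category and feature assignment for one library.

    ``table`` columns: sequence, count, category, feature (``;``-joined for
    ambiguous multi-gene tags, empty string for unannotated).
    """

    library_id: str
    table: pd.DataFrame

    @property
    def total_reads(self) -> int:
        return int(self.table["count"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def filter_tags(lib: TagLibrary, min_len: int = 18, max_len: int = 30) -> TagLibrary:
    """Keep tags with ``min_len <= len(sequence) <= max_len``; counts preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) exceeds max_len ({max_len})")
    kept = {s: c for s, c in lib.tags.items() if min_len <= len(s) <= max_len}
    return TagLibrary(lib.library_id, kept)


def classify_tags(
    lib: TagLibrary,
    catalog: Catalog,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> ClassifiedLibrary:
    """Assign each tag to exactly one category by exact full-length match.

    A tag present in several catalog categories is assigned to the first
    matching category in ``precedence``; a tag matching nothing is
    ``unannotated``.  Assignment depends only on the tag sequence, never on
    input order.
    """
    rows = []
    for seq, count in lib.tags.items():
        category = "unannotated"
        feature = ""
        for cand in precedence:
            feats = catalog.lookup(cand, seq)
            if feats:
                category = cand
                feature = ";".join(sorted(feats))
                break
        rows.append((seq, count, category, feature))
    table = pd.DataFrame(rows, columns=["sequence", "count", "category", "feature"])
    return ClassifiedLibrary(lib.library_id, table)


def composition(classified: ClassifiedLibrary) -> dict[str, float]:
    """Read-level category fractions (counts, not unique tags); sums to 1."""
    total = classified.total_reads
    if total == 0:
        raise ValueError("cannot compute composition of an empty library")
    by_cat = classified.table.groupby("category")["count"].sum()
    return {c: float(by_cat.get(c, 0)) / total for c in CATEGORIES}


@dataclass
class MiRNAProfile:
    """Digital miRNA expression: per-gene read count summed over isoforms."""

    library_id: str
    counts: dict[str, int]
    library_size: int

    @property
    def cpm(self) -> dict[str, float]:
        if self.library_size == 0:
            return {g: 0.0 for g in self.counts}
        return {g: c * 1e6 / self.library_size for g, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        cpm = self.cpm
        return pd.DataFrame(
            {"gene": list(self.counts), "count": list(self.counts.values()),
             "cpm": [cpm[g] for g in self.counts]}
        ).set_index("gene")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", lineterminator="\n")


def quantify_mirnas(
    classified: ClassifiedLibrary, genes: Iterable[str] | None = None
) -> MiRNAProfile:
    """Per-gene miRNA counts: sum of reads over all isoforms of each gene.

    An ambiguous tag shared by two miRNA genes is credited once to each
    (documented double-counting).  ``genes`` optionally fixes the gene set
    so absent genes appear with count 0.
    """
    counts: dict[str, int] = {g: 0 for g in genes} if genes is not None else {}
    sub = classified.table[classified.table["category"] == "known_miRNA"]
    for feature, count in zip(sub["feature"], sub["count"]):
        for gene in feature.split(";"):
            counts[gene] = counts.get(gene, 0) + int(count)
    return MiRNAProfile(classified.library_id, counts, classified.total_reads)


def detection_summary(
    profiles: Sequence[MiRNAProfile],
    detection_min: int = 1,
    low_count_max: int = 10,
) -> dict:
    """Presence/absence bookkeeping across libraries.

    A gene is detected in a library when its count reaches ``detection_min``.
    Genes with fewer than ``low_count_max`` reads in every library form the
    low-count class for which fold differences are not meaningful.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    universe: set[str] = set()
    for p in profiles:
        universe.update(p.counts)
    detected = {
        p.library_id: {g for g, c in p.counts.items() if c >= detection_min}
        for p in profiles
    }
    sets = list(detected.values())
    inter = set.intersection(*sets) if sets else set()
    union = set.union(*sets) if sets else set()
    low = {
        g for g in universe
        if all(p.counts.get(g, 0) < low_count_max for p in profiles)
    }
    return {
        "detected": detected,
        "n_detected": {lid: len(s) for lid, s in detected.items()},
        "intersection": inter,
        "union": union,
        "low_count": low,
    }
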
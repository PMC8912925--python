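"""Readers/writers for FASTA, BED, newick and repeat annotation tables.

Coordinates are 0-based half-open everywhere (BED native).  Minus-strand
element sequences are reverse-complemented at load so every downstream
analysis runs in LTR orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq


class SeqIOError(ValueError):
    """Raised on malformed sequence/interval/tree input."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0:
            raise SeqIOError(f"negative start {self.start}")
        if self.end <= self.start:
            raise SeqIOError(f"end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: GenomicInterval
    family: str
    element_id: str

    def __post_init__(self):
        if not self.family:
            raise SeqIOError("empty family name")


# structural classes of an analyzable LTR element
SOLO_LTR = "solo_ltr"
FIVE_PRIME_LTR = "five_prime_ltr"


@dataclass
class Element:
    id: str
    interval: GenomicInterval
    structure: str
    sequence: str = ""

    def __post_init__(self):
        if self.structure not in (SOLO_LTR, FIVE_PRIME_LTR):
            raise SeqIOError(f"unknown structure {self.structure!r}")
        if self.sequence and len(self.sequence) != len(self.interval):
            raise SeqIOError(
                f"{self.id}: sequence length {len(self.sequence)} != interval "
                f"span {len(self.interval)}"
            )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased and U is mapped to T.  Duplicate IDs and
    empty records raise :class:`SeqIOError`.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise SeqIOError(f"empty record {rec.id!r}")
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intervals(path, format: str = "bed") -> list[GenomicInterval]:
    """Read BED3+ lines into 0-based half-open intervals, preserving order."""
    if format != "bed":
        raise SeqIOError(f"unsupported interval format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SeqIOError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise SeqIOError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            try:
                out.append(GenomicInterval(parts[0], start, end, strand))
            except SeqIOError as exc:
                raise SeqIOError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_tree(path) -> dendropy.Tree:
    """Read a newick tree; normalize supports to [0,1], missing lengths to 0.

    Internal node labels that parse as numbers are interpreted as clade
    support, on either a [0,100] (percent) or [0,1] scale.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise SeqIOError(f"unparseable newick in {path}: {exc}") from exc
    raw = []
    for node in tree.preorder_node_iter():
        if node.edge.length is None:
            node.edge.length = 0.0
        if node.edge.length < 0:
            node.edge.length = 0.0
        sup = None
        if not node.is_leaf() and node.label is not None:
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        node.support = sup
        if sup is not None:
            raw.append(sup)
    percent_scale = any(s > 1.0 for s in raw)
    for node in tree.preorder_node_iter():
        if getattr(node, "support", None) is not None and percent_scale:
            node.support = node.support / 100.0
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    """Write newick with supports (as proportions) as internal node labels."""
    for node in tree.preorder_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None and not node.is_leaf():
            node.label = f"{sup:.4g}"
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


@dataclass
class AssemblyConfig:
    full_len_min: int = 4000  # provirus span must exceed this (bp)
    min_ltr_len: int = 350  # LTRs longer than this are analyzable
    merge_gap: int = 500  # max gap between LTR and internal annotation


def read_annotation_table(path) -> list[RepeatAnnotation]:
    """RepeatMasker-style TSV: chrom, start, end, strand, family, element_id."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise SeqIOError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, strand, family, eid = parts[:6]
            out.append(
                RepeatAnnotation(
                    GenomicInterval(chrom, int(start), int(end), strand), family, eid
                )
            )
    return out


def assemble_elements(
    annotations: list[RepeatAnnotation],
    ltr_families: set,
    internal_family: str,
    config: AssemblyConfig | None = None,
    genome: dict[str, str] | None = None,
) -> list[Element]:
    """Classify LTR annotations into solo LTRs and 5' LTRs of proviruses.

    An LTR adjacent (within ``merge_gap``) to an internal-region annotation
    on the same strand and upstream of it is the 5' LTR of a full-length
    insertion iff the merged LTR-int-LTR span exceeds ``full_len_min``; the
    paired 3' LTR is dropped.  Unpaired LTRs are solo.  Only LTRs longer
    than ``min_ltr_len`` are kept.
    """
    cfg = config or AssemblyConfig()
    # deduplicate identical annotations
    seen, uniq = set(), []
    for ann in annotations:
        key = (ann.interval.chrom, ann.interval.start, ann.interval.end,
               ann.interval.strand, ann.family)
        if key in seen:
            warnings.warn(f"duplicate annotation at {key} deduplicated")
            continue
        seen.add(key)
        uniq.append(ann)

    by_chrom: dict[str, list[RepeatAnnotation]] = {}
    for ann in uniq:
        by_chrom.setdefault(ann.interval.chrom, []).append(ann)

    elements: list[Element] = []
    for chrom in sorted(by_chrom):
        anns = sorted(by_chrom[chrom], key=lambda a: a.interval.start)
        consumed: set[int] = set()
        for i, ann in enumerate(anns):
            if i in consumed or ann.family not in ltr_families:
                continue
            structure = SOLO_LTR
            # look for LTR - internal - LTR run on the same strand
            if (
                i + 2 < len(anns)
                and anns[i + 1].family == internal_family
                and anns[i + 2].family in ltr_families
                and ann.interval.strand
                == anns[i + 1].interval.strand
                == anns[i + 2].interval.strand
                and anns[i + 1].interval.start - ann.interval.end <= cfg.merge_gap
                and anns[i + 2].interval.start - anns[i + 1].interval.end
                <= cfg.merge_gap
            ):
                span = anns[i + 2].interval.end - ann.interval.start
                if span > cfg.full_len_min:
                    if ann.interval.strand == "+":
                        structure = FIVE_PRIME_LTR
                        consumed.update({i + 1, i + 2})
                    else:
                        # on minus strand the rightmost LTR is 5'
                        consumed.update({i + 1, i + 2})
                        ann = anns[i + 2]
                        structure = FIVE_PRIME_LTR
            if len(ann.interval) <= cfg.min_ltr_len:
                continue
            seq = ""
            if genome is not None:
                seq = genome[ann.interval.chrom][ann.interval.start : ann.interval.end]
                if ann.interval.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
            elements.append(Element(ann.element_id, ann.interval, structure, seq))
    return elements
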
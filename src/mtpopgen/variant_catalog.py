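"""SNV cataloguing from aligned mitochondrial genomes.

An alignment column qualifies as variant when it shows at least two
distinct unambiguous bases.  Columns containing any gap character are
treated as indel sites and excluded entirely; IUPAC ambiguity codes
(heteroplasmic positions) are treated as missing calls, so a column that is
variable only through ambiguity codes is not an SNV.  A column with *k*
distinct unambiguous bases contributes *k - 1* variant records (a
tri-allelic position counts as two SNVs), with the majority base taken as
the column's reference allele.

Two table views are supported: Dataset 1 (all SNVs) and Dataset 2 (all
SNVs except singletons, i.e. variant alleles carried by exactly one genome
in the full sample).  Positions are reported 1-based on the ungapped
designated coordinate reference sequence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from . import annotation as ann
from .errors import ClassificationError, FormatError, InputError

__all__ = [
    "AlignedSet",
    "SNVRecord",
    "SNVTable",
    "read_alignment",
    "identify_snvs",
    "filter_singletons",
    "classify_sites",
]

BASES = ("A", "C", "G", "T")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")
GAP = b"-"
IUPAC = set(b"ACGTRYSWKMBDHVN-")

#: Functional classes a record can be assigned to (protein-coding split
#: into synonymous / non-synonymous).
CLS_SYN = "syn"
CLS_NON = "non"
SNV_CLASSES = (ann.CONTROL, ann.NONCODING, ann.RNA, CLS_SYN, CLS_NON)


@dataclass
class AlignedSet:
    """Equal-length aligned haploid sequences with population labels."""

    ids: list[str]
    populations: list[str]
    matrix: np.ndarray  # (n_samples, n_columns) dtype S1, uppercase
    ref_index: int = 0

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or len(self.ids) != self.matrix.shape[0]:
            raise FormatError("matrix shape inconsistent with sample ids")
        if len(self.populations) != len(self.ids):
            raise InputError("every sample needs exactly one population label")
        observed = set(self.matrix.tobytes())
        bad = observed - IUPAC
        if bad:
            raise FormatError(
                f"non-IUPAC characters in alignment: {sorted(chr(b) for b in bad)}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.populations:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def pop_rows(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.populations) if p == population], dtype=int
        )

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode()

    def reference_ungapped(self) -> str:
        """The coordinate reference sequence with gap characters removed."""
        row = self.matrix[self.ref_index]
        return row[row != GAP].tobytes().decode()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlignedSet)
            and self.ids == other.ids
            and self.populations == other.populations
            and self.ref_index == other.ref_index
            and self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
        )


def read_alignment(fasta_path, labels_path, ref_id: str | None = None) -> AlignedSet:
    """Read a multi-FASTA alignment and a ``sample<TAB>population`` table.

    ``ref_id`` names the coordinate reference record; default is the first
    record in the FASTA.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"unequal row lengths in {fasta_path}: {sorted(lengths)}")
    labels = pd.read_csv(labels_path, sep="\t", header=None,
                         names=["sample_id", "population"], dtype=str)
    label_map = dict(zip(labels["sample_id"], labels["population"]))
    ids = [r.id for r in records]
    missing = [i for i in ids if i not in label_map]
    if missing:
        raise InputError(f"samples without population label: {missing}")
    matrix = np.array(
        [np.frombuffer(str(r.seq).upper().encode(), dtype="S1") for r in records]
    )
    ref_index = 0 if ref_id is None else ids.index(ref_id)
    return AlignedSet(ids=ids, populations=[label_map[i] for i in ids],
                      matrix=matrix, ref_index=ref_index)


def write_alignment(aligned: AlignedSet, fasta_path, labels_path) -> None:
    with open(fasta_path, "w") as fh:
        for i, sid in enumerate(aligned.ids):
            fh.write(f">{sid}\n{aligned.sequence(i)}\n")
    with open(labels_path, "w") as fh:
        for sid, pop in zip(aligned.ids, aligned.populations):
            fh.write(f"{sid}\t{pop}\n")


@dataclass
class SNVRecord:
    """One variant allele at one reference position."""

    position: int  # 1-based on the ungapped coordinate reference
    ref: str  # majority base at the column
    alt: str  # the variant allele this record describes
    counts: dict[str, tuple[int, int, int]]  # pop -> (ref_count, alt_count, n_called)
    multiallelic: bool
    singleton: bool
    cls: str | None = None

    @property
    def total_alt(self) -> int:
        return sum(c[1] for c in self.counts.values())

    def n_called(self, population: str) -> int:
        return self.counts[population][2]


@dataclass
class SNVTable:
    """A set of SNV records plus provenance for one dataset view."""

    records: list[SNVRecord]
    dataset: int  # 1 = all SNVs, 2 = singletons removed
    reference: str  # ungapped coordinate reference sequence
    pop_sizes: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positions(self) -> int:
        return len({r.position for r in self.records})

    @property
    def n_multiallelic_positions(self) -> int:
        return len({r.position for r in self.records if r.multiallelic})

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (record, population)."""
        rows = []
        for r in self.records:
            for pop, (rc, ac, nc) in r.counts.items():
                rows.append(
                    {"position": r.position, "ref": r.ref, "alt": r.alt,
                     "pop": pop, "ref_count": rc, "alt_count": ac,
                     "n_called": nc, "multiallelic": r.multiallelic,
                     "singleton": r.singleton, "cls": r.cls}
                )
        return pd.DataFrame(
            rows, columns=["position", "ref", "alt", "pop", "ref_count",
                           "alt_count", "n_called", "multiallelic",
                           "singleton", "cls"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _alignment_hash(aligned: AlignedSet) -> str:
    h = hashlib.sha256()
    h.update(aligned.matrix.tobytes())
    return h.hexdigest()[:16]


def identify_snvs(aligned: AlignedSet) -> SNVTable:
    """Call SNVs column by column, producing the Dataset-1 table."""
    M = aligned.matrix
    pops = aligned.pop_names
    pop_rows = {p: aligned.pop_rows(p) for p in pops}

    has_gap = (M == GAP).any(axis=0)
    base_counts = np.stack([(M == b).sum(axis=0) for b in _BASE_BYTES])  # (4, L)
    pop_counts = {
        p: np.stack([(M[pop_rows[p]] == b).sum(axis=0) for b in _BASE_BYTES])
        for p in pops
    }

    present = base_counts > 0
    k = present.sum(axis=0)
    qualifying = (~has_gap) & (k >= 2)

    ref_row = M[aligned.ref_index]
    positions = np.cumsum(ref_row != GAP)  # 1-based ungapped coordinate

    records: list[SNVRecord] = []
    excluded_indel = [int(positions[c]) for c in np.nonzero(has_gap)[0]]
    for c in np.nonzero(qualifying)[0]:
        col_counts = base_counts[:, c]
        order = np.lexsort((np.arange(4), -col_counts))  # count desc, base asc
        ref_i = order[0]
        multi = k[c] > 2
        for alt_i in order[1:]:
            if col_counts[alt_i] == 0:
                continue
            counts = {
                p: (int(pop_counts[p][ref_i, c]), int(pop_counts[p][alt_i, c]),
                    int(pop_counts[p][:, c].sum()))
                for p in pops
            }
            total_alt = int(col_counts[alt_i])
            records.append(
                SNVRecord(position=int(positions[c]), ref=BASES[ref_i],
                          alt=BASES[alt_i], counts=counts,
                          multiallelic=bool(multi),
                          singleton=total_alt == 1)
            )
    return SNVTable(
        records=records,
        dataset=1,
        reference=aligned.reference_ungapped(),
        pop_sizes=aligned.pop_sizes(),
        provenance={
            "source_hash": _alignment_hash(aligned),
            "filter_log": {"excluded_indel_positions": excluded_indel},
        },
    )


def filter_singletons(table: SNVTable) -> SNVTable:
    """Dataset-2 view: drop every record whose variant allele is a singleton.

    Judged per allele, so a tri-allelic position can lose one allele and
    keep the other.  The multiallelic flag is recomputed on the remaining
    records.
    """
    if table.dataset != 1:
        raise InputError("filter_singletons expects a Dataset-1 table")
    kept = [r for r in table.records if not r.singleton]
    per_pos: dict[int, int] = {}
    for r in kept:
        per_pos[r.position] = per_pos.get(r.position, 0) + 1
    records = [
        SNVRecord(position=r.position, ref=r.ref, alt=r.alt,
                  counts=dict(r.counts),
                  multiallelic=per_pos[r.position] > 1,
                  singleton=False, cls=r.cls)
        for r in kept
    ]
    prov = dict(table.provenance)
    prov["singletons_removed"] = len(table.records) - len(records)
    return SNVTable(records=records, dataset=2, reference=table.reference,
                    pop_sizes=dict(table.pop_sizes), provenance=prov)


# -- functional classification ----------------------------------------

#: Class assignment priority when intervals overlap.
_PRIORITY = (ann.CONTROL, ann.CDS, ann.RNA)


def _codon_change(record: SNVRecord, row: pd.Series, reference: str) -> tuple[str, str]:
    """Reference and variant amino acids for ``record`` inside CDS ``row``."""
    pos, start, end = record.position, int(row["start"]), int(row["end"])
    frame, strand = int(row["frame"]), row["strand"]
    if strand == "+":
        offset = pos - start - frame
        c0 = start + frame + 3 * (offset // 3)
        codon_pos = [c0, c0 + 1, c0 + 2]
    else:
        offset = (end - frame) - pos
        c2 = end - frame - 3 * (offset // 3)
        codon_pos = [c2 - 2, c2 - 1, c2]
    if offset < 0 or codon_pos[0] < start or codon_pos[-1] > end:
        raise ClassificationError(
            f"no complete codon for position {pos} in {row['name']}"
        )
    if codon_pos[-1] > len(reference):
        raise ClassificationError(f"codon at {pos} beyond reference end")

    def build(base: str) -> str:
        return "".join(
            base if p == pos else reference[p - 1] for p in codon_pos
        )

    ref_codon, alt_codon = build(record.ref), build(record.alt)
    if strand == "-":
        ref_codon = str(Seq(ref_codon).reverse_complement())
        alt_codon = str(Seq(alt_codon).reverse_complement())
    # vertebrate mitochondrial genetic code
    return (str(Seq(ref_codon).translate(table=2)),
            str(Seq(alt_codon).translate(table=2)))


def classify_sites(table: SNVTable, annotation: pd.DataFrame) -> dict[str, int]:
    """Assign each record one functional class and return per-class counts.

    Records are annotated in place (``record.cls``).  Overlapping intervals
    are resolved control region > protein-coding > RNA gene, within a class
    by table order; positions covered by no interval are non-coding.
    Synonymous / non-synonymous status is decided by translating the
    reference vs variant codon under the vertebrate mitochondrial code.
    """
    counts = {c: 0 for c in SNV_CLASSES}
    by_class = {c: annotation[annotation["cls"] == c] for c in _PRIORITY}
    for record in table.records:
        assigned = None
        for cls in _PRIORITY:
            sub = by_class[cls]
            hit = sub[(sub["start"] <= record.position) & (record.position <= sub["end"])]
            if hit.empty:
                continue
            if cls == ann.CDS:
                aa_ref, aa_alt = _codon_change(record, hit.iloc[0], table.reference)
                assigned = CLS_SYN if aa_ref == aa_alt else CLS_NON
            else:
                assigned = cls
            break
        record.cls = assigned if assigned is not None else ann.NONCODING
        counts[record.cls] += 1
    return counts
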
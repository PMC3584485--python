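"""Functional region annotation of the mitochondrial genome.

Regions are held in a pandas DataFrame with 1-based inclusive ``start``/
``end`` coordinates on the ungapped reference, a functional ``cls`` (one of
:data:`CLASSES`), a ``strand`` and, for protein-coding intervals, the codon
``frame`` at ``start``.  On disk the table is BED (0-based half-open,
columns chrom/start/end/name/class/strand/frame); coordinates are converted
on read and write.

:func:`rcrs_annotation` returns the standard human mtDNA (rCRS,
NC_012920.1) gene map: the control region (16,024–16,569 joined with
1–576, 1,122 bp in total), the two rRNAs, the 22 tRNAs and the 13
protein-coding genes, ND6 on the minus strand.
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError

__all__ = [
    "CONTROL",
    "RNA",
    "CDS",
    "NONCODING",
    "CLASSES",
    "rcrs_annotation",
    "default_annotation",
    "read_annotation_bed",
    "write_annotation_bed",
]

CONTROL = "control_region"
RNA = "rna_gene"
CDS = "protein_coding"
NONCODING = "non_coding"
CLASSES = (CONTROL, NONCODING, RNA, CDS)

COLUMNS = ["chrom", "start", "end", "name", "cls", "strand", "frame"]

# name, start, end (1-based inclusive, rCRS), class, strand.  Frame is 0 at
# every gene start.  tRNA/rRNA coordinates follow the standard NC_012920
# feature table; protein-coding genes include their (incomplete) stop codons.
_RCRS_FEATURES = [
    ("CR_hvs", 16024, 16569, CONTROL, "+"),
    ("CR_origin", 1, 576, CONTROL, "+"),
    ("TRNF", 577, 647, RNA, "+"),
    ("RNR1", 648, 1601, RNA, "+"),
    ("TRNV", 1602, 1670, RNA, "+"),
    ("RNR2", 1671, 3229, RNA, "+"),
    ("TRNL1", 3230, 3304, RNA, "+"),
    ("ND1", 3307, 4262, CDS, "+"),
    ("TRNI", 4263, 4331, RNA, "+"),
    ("TRNQ", 4329, 4400, RNA, "-"),
    ("TRNM", 4402, 4469, RNA, "+"),
    ("ND2", 4470, 5511, CDS, "+"),
    ("TRNW", 5512, 5579, RNA, "+"),
    ("TRNA", 5587, 5655, RNA, "-"),
    ("TRNN", 5657, 5729, RNA, "-"),
    ("TRNC", 5761, 5826, RNA, "-"),
    ("TRNY", 5826, 5891, RNA, "-"),
    ("CO1", 5904, 7445, CDS, "+"),
    ("TRNS1", 7446, 7514, RNA, "-"),
    ("TRND", 7518, 7585, RNA, "+"),
    ("CO2", 7586, 8269, CDS, "+"),
    ("TRNK", 8295, 8364, RNA, "+"),
    ("ATP8", 8366, 8572, CDS, "+"),
    ("ATP6", 8527, 9207, CDS, "+"),
    ("CO3", 9207, 9990, CDS, "+"),
    ("TRNG", 9991, 10058, RNA, "+"),
    ("ND3", 10059, 10404, CDS, "+"),
    ("TRNR", 10405, 10469, RNA, "+"),
    ("ND4L", 10470, 10766, CDS, "+"),
    ("ND4", 10760, 12137, CDS, "+"),
    ("TRNH", 12138, 12206, RNA, "+"),
    ("TRNS2", 12207, 12265, RNA, "+"),
    ("TRNL2", 12266, 12336, RNA, "+"),
    ("ND5", 12337, 14148, CDS, "+"),
    ("ND6", 14149, 14673, CDS, "-"),
    ("TRNE", 14674, 14742, RNA, "-"),
    ("CYB", 14747, 15887, CDS, "+"),
    ("TRNT", 15888, 15953, RNA, "+"),
    ("TRNP", 15956, 16023, RNA, "-"),
]

RCRS_LENGTH = 16_569


def rcrs_annotation(chrom: str = "MT") -> pd.DataFrame:
    """The standard rCRS region map as an annotation table."""
    rows = [
        {"chrom": chrom, "start": s, "end": e, "name": n, "cls": c,
         "strand": strand, "frame": 0}
        for (n, s, e, c, strand) in _RCRS_FEATURES
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def default_annotation(L: int, chrom: str = "MT") -> pd.DataFrame:
    """Annotation for a genome of length ``L``.

    The real rCRS map when ``L`` is the rCRS length; otherwise a minimal
    synthetic layout (control region at the ends, one RNA gene, one
    plus-strand protein-coding gene) so that short test genomes still
    exercise every functional class.
    """
    if L == RCRS_LENGTH:
        return rcrs_annotation(chrom)
    ctrl = max(L // 20, 1)
    rna_end = min(L // 3, L - ctrl - 1)
    cds_start = rna_end + 1
    cds_len = max(((L - ctrl - cds_start) // 2) // 3 * 3, 3)
    rows = [
        {"chrom": chrom, "start": L - ctrl + 1, "end": L, "name": "CR_synth",
         "cls": CONTROL, "strand": "+", "frame": 0},
        {"chrom": chrom, "start": 1, "end": ctrl, "name": "CR_synth",
         "cls": CONTROL, "strand": "+", "frame": 0},
        {"chrom": chrom, "start": ctrl + 1, "end": rna_end, "name": "RNA_synth",
         "cls": RNA, "strand": "+", "frame": 0},
        {"chrom": chrom, "start": cds_start, "end": cds_start + cds_len - 1,
         "name": "CDS_synth", "cls": CDS, "strand": "+", "frame": 0},
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """Write the table as 7-column BED (0-based half-open)."""
    out = annotation.copy()
    out["start"] = out["start"] - 1  # 1-based inclusive -> 0-based half-open
    out = out[["chrom", "start", "end", "name", "cls", "strand", "frame"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path) -> pd.DataFrame:
    """Read a 7-column annotation BED, converting to 1-based inclusive."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=COLUMNS,
                         dtype={"frame": int})
    except ValueError as exc:
        raise FormatError(f"malformed annotation BED {path}: {exc}") from exc
    if df["cls"].isna().any() or not set(df["cls"]).issubset(CLASSES):
        raise FormatError(f"unknown region class in {path}")
    df["start"] = df["start"] + 1
    return df[COLUMNS]
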
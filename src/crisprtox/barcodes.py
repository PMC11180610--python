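"""Barcode-based clonal tracking.

Lentiviral barcodes (BARs) mark transduced clones; reads carry an
anchor–barcode–anchor structure.  Extraction is anchored matching with a
mismatch budget; sequencing-error satellites are folded back into their
parent barcode on an edit-distance graph (edges at distance ≤2, communities
collapsed onto the highest-count member), followed by a minimum-count
filter.  Clonal statistics: clone counts normalized by vector copy number
(a clone carrying v integrations contributes v distinct barcodes, so unique
barcodes / VCN estimates clones), repopulating-cell frequency (transplanted
culture-initiating cells per engrafted clone), Jaccard barcode sharing
between lineages and the fraction of stem/progenitor barcodes shared with
0..k mature lineages.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import edlib
import networkx as nx
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorSpec",
    "BarcodeMatrix",
    "TransplantInput",
    "extract_barcodes",
    "correct_barcodes",
    "clone_metrics",
    "jaccard_index",
    "sharing_classes",
]


@dataclass(frozen=True)
class AnchorSpec:
    """Read structure: 5' anchor, fixed-length barcode, 3' anchor."""

    anchor5: str
    anchor3: str
    barcode_length: int = 18
    max_anchor_mismatch: int = 1
    min_read_length: int = 50


@dataclass
class TransplantInput:
    """Inputs of the repopulating-cell frequency estimate."""

    d0_equivalent: int
    engrafted_barcodes_bm: int

    def __post_init__(self):
        if self.d0_equivalent <= 0 or self.engrafted_barcodes_bm <= 0:
            raise ValueError("transplant inputs must be positive")


@dataclass
class BarcodeMatrix:
    """Corrected barcode × sample read counts plus per-sample metadata.

    ``metadata`` is indexed by sample with at least a ``vcn`` column where
    clone counts are requested; ``lineage`` and ``organ`` columns are free
    labels.
    """

    counts: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    def sample_set(self, sample: str) -> set[str]:
        col = self.counts[sample]
        return set(col.index[col > 0])


def _hamming_leq(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def extract_barcodes(reads, anchor_spec: AnchorSpec,
                     ) -> tuple[Counter, dict[str, int]]:
    """Extract barcodes as the fixed-length segment between both anchors.

    Each anchor may carry up to ``max_anchor_mismatch`` mismatches; reads
    shorter than ``min_read_length`` or lacking either anchor are discarded
    and counted.  ``reads`` is a FASTQ path or an iterable of sequences.
    Returns (barcode counts, stats).
    """
    a5, a3 = anchor_spec.anchor5.upper(), anchor_spec.anchor3.upper()
    bl = anchor_spec.barcode_length
    mm = anchor_spec.max_anchor_mismatch
    counts: Counter[str] = Counter()
    stats = {"extracted": 0, "too_short": 0, "no_anchor": 0}
    for seq in _iter_reads(reads):
        seq = seq.upper()
        if len(seq) < anchor_spec.min_read_length:
            stats["too_short"] += 1
            continue
        span = len(a5) + bl + len(a3)
        hit = None
        for i in range(len(seq) - span + 1):
            if (_hamming_leq(seq[i:i + len(a5)], a5, mm)
                    and _hamming_leq(seq[i + len(a5) + bl:i + span], a3, mm)):
                hit = seq[i + len(a5):i + len(a5) + bl]
                break
        if hit is None:
            stats["no_anchor"] += 1
            continue
        counts[hit] += 1
        stats["extracted"] += 1
    total = stats["extracted"] + stats["no_anchor"]
    if total >= 20 and stats["no_anchor"] / total > 0.95:
        warnings.warn("anchors not found in >95% of reads; "
                      "anchor_spec may be wrong", stacklevel=2)
    return counts, stats


def _iter_reads(reads):
    if isinstance(reads, (str, Path)):
        return (str(rec.seq) for rec in SeqIO.parse(str(reads), "fastq"))
    return (str(r) for r in reads)


def _edit_distance_leq(a: str, b: str, k: int, metric: str) -> bool:
    if metric == "hamming":
        return len(a) == len(b) and _hamming_leq(a, b, k)
    return edlib.align(a, b, task="distance", k=k)["editDistance"] != -1


def correct_barcodes(counts: Union[Mapping[str, int], pd.DataFrame],
                     max_edit: int = 2, min_count: int = 2,
                     method: str = "components",
                     metric: str = "levenshtein",
                     metadata: Optional[pd.DataFrame] = None) -> BarcodeMatrix:
    """Error-correct barcodes on an edit-distance graph.

    A graph is built with edges between barcodes at edit distance ≤
    ``max_edit``.  With ``method='components'`` (default) each connected
    component's reads are reassigned to its highest-count member (ties go to
    the lexicographically smallest); ``method='directional'`` only merges a
    satellite into a neighbor holding at least twice its count plus one,
    following count-ratio merging.  Barcodes whose total corrected count
    falls below ``min_count`` are then removed.  Read counts are conserved
    up to that final filter.

    ``counts`` is either a barcode → count mapping (one sample) or a
    barcode × sample count DataFrame.
    """
    if isinstance(counts, pd.DataFrame):
        df = counts.astype(int).copy()
    else:
        df = pd.DataFrame({"sample": pd.Series(dict(counts), dtype=int)})
    if not len(df):
        return BarcodeMatrix(df, metadata)
    lengths = {len(b) for b in df.index}
    if len(lengths) > 1:
        raise ValueError("barcodes must all have the same length")
    totals = df.sum(axis=1)
    barcodes = list(df.index)
    graph = nx.Graph()
    graph.add_nodes_from(barcodes)
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if _edit_distance_leq(a, b, max_edit, metric):
                graph.add_edge(a, b)
    representative: dict[str, str] = {}
    if method == "components":
        for comp in nx.connected_components(graph):
            rep = min(comp, key=lambda bc: (-totals[bc], bc))
            for bc in comp:
                representative[bc] = rep
    elif method == "directional":
        order = sorted(barcodes, key=lambda bc: (-totals[bc], bc))
        for bc in order:
            if bc in representative:
                continue
            representative[bc] = bc
            for nb in graph.neighbors(bc):
                if nb not in representative and totals[bc] >= 2 * totals[nb] - 1:
                    representative[nb] = bc
        # chase chains so every barcode maps to a terminal representative
        for bc in barcodes:
            rep = representative[bc]
            while representative[rep] != rep:
                rep = representative[rep]
            representative[bc] = rep
    else:
        raise ValueError(f"unknown method {method!r}")
    corrected = df.groupby(df.index.map(representative.__getitem__)).sum()
    corrected = corrected[corrected.sum(axis=1) >= min_count]
    corrected.index.name = "barcode"
    return BarcodeMatrix(corrected.sort_index(), metadata)


def clone_metrics(matrix: BarcodeMatrix,
                  transplant: Optional[TransplantInput] = None,
                  ) -> tuple[pd.DataFrame, Optional[float]]:
    """Clone counts per sample and, optionally, cells per repopulating clone.

    Clone count = unique barcodes with nonzero reads / sample VCN.  The
    second return value is ``d0_equivalent / engrafted_barcodes_bm`` when a
    transplant input is supplied (the '1 of x' repopulating-cell frequency).
    """
    if matrix.metadata is None or "vcn" not in matrix.metadata.columns:
        raise ValueError("sample metadata with a 'vcn' column is required")
    rows = []
    for sample in matrix.counts.columns:
        vcn = float(matrix.metadata.loc[sample, "vcn"])
        if vcn <= 0:
            raise ValueError(f"VCN must be positive for sample {sample!r}")
        unique = int((matrix.counts[sample] > 0).sum())
        rows.append(dict(sample=sample, unique_barcodes=unique, vcn=vcn,
                         clones=unique / vcn))
    cells_per_src = None
    if transplant is not None:
        cells_per_src = (transplant.d0_equivalent
                         / transplant.engrafted_barcodes_bm)
    return pd.DataFrame(rows).set_index("sample"), cells_per_src


def jaccard_index(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def sharing_classes(hspc_set: Iterable[str],
                    lineage_sets: Mapping[str, Iterable[str]],
                    ) -> dict[int, float]:
    """Fraction of stem/progenitor barcodes shared with 0..k lineages."""
    hspc = set(hspc_set)
    if not hspc:
        raise ValueError("empty HSPC barcode set")
    sets = {name: set(s) for name, s in lineage_sets.items()}
    k = len(sets)
    tally = Counter(sum(bc in s for s in sets.values()) for bc in hspc)
    return {i: tally.get(i, 0) / len(hspc) for i in range(k + 1)}
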
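"""Structural-lesion assays: ddPCR copy numbers, large-deletion calls and
translocation junction enumeration.

Copy number per genome is the plain droplet ratio
``(target-positive / normalizer-positive) × 2`` against a two-copy
normalizer.  Large deletions in single colonies are called against a
mock-derived mean ± k·s.d. interval; by Chebyshev's inequality the interval
covers at least 1 − 1/k² of any distribution (≈89% for k = 3), so colonies
below the lower limit are enriched for true allele loss.  Group enrichment
is assessed with two-tailed Fisher's exact tests and Benjamini–Hochberg FDR.
For two loci cut on different chromosomes, the four reciprocal fusion
junctions and the primer pairs of the 2×2 matrix that amplify them are
enumerated, with breakpoint windows per editor chemistry.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DropletAssay",
    "MockInterval",
    "Locus",
    "Junction",
    "JunctionSet",
    "copy_number",
    "mock_interval",
    "call_loss",
    "call_allele_loss",
    "loss_enrichment_test",
    "enumerate_junctions",
    "in_silico_pcr",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DropletAssay:
    """Droplet counts for one sample and one flanking assay side."""

    target_positive: int
    normalizer_positive: int
    side: str = "upstream"
    sample: str = ""

    def __post_init__(self):
        if self.target_positive < 0 or self.normalizer_positive < 0:
            raise ValueError("droplet counts must be ≥ 0")


def copy_number(assay: DropletAssay, poisson_correct: bool = False,
                n_droplets: Optional[int] = None) -> float:
    """Copies per genome: (target-positive / normalizer-positive) × 2.

    The plain ratio (no Poisson correction of droplet occupancy) is the
    default readout.  ``poisson_correct=True`` instead converts positives to
    expected molecule counts via −ln(1 − k/n) before taking the ratio
    (requires ``n_droplets``).
    """
    if assay.normalizer_positive == 0:
        raise ValueError("normalizer-positive droplet count is zero")
    if not poisson_correct:
        return (assay.target_positive / assay.normalizer_positive) * 2.0
    if n_droplets is None or n_droplets <= max(assay.target_positive,
                                               assay.normalizer_positive):
        raise ValueError("Poisson correction needs total droplet count")
    lam_t = -math.log1p(-assay.target_positive / n_droplets)
    lam_n = -math.log1p(-assay.normalizer_positive / n_droplets)
    return (lam_t / lam_n) * 2.0


@dataclass(frozen=True)
class MockInterval:
    """Mean ± k·s.d. interval from mock-treated colonies.

    ``guaranteed_coverage`` is the distribution-free Chebyshev bound
    1 − 1/k² on the fraction of mock observations inside the interval.
    """

    mean: float
    sd: float
    k: float = 3.0
    n: int = 0

    @property
    def lower_limit(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def upper_limit(self) -> float:
        return self.mean + self.k * self.sd

    @property
    def guaranteed_coverage(self) -> float:
        return 1.0 - 1.0 / (self.k ** 2)


def mock_interval(mock_copies: Sequence[float], k: float = 3.0) -> MockInterval:
    """Interval from mock copy numbers: sample mean ± k · sample s.d. (n−1)."""
    values = np.asarray(list(mock_copies), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 mock values")
    if k <= 1:
        raise ValueError("k must exceed 1 for a nontrivial Chebyshev bound")
    return MockInterval(mean=float(values.mean()),
                        sd=float(values.std(ddof=1)), k=float(k),
                        n=int(values.size))


def call_loss(copies: float, interval: MockInterval,
              biallelic_threshold: float = 0.5) -> str:
    """Allele-loss call for one copy-number value.

    ``none`` at or above the interval's lower limit; ``monoallelic`` below
    it; ``biallelic`` below ``biallelic_threshold`` copies (default 0.5,
    midway between one and zero retained copies).
    """
    if copies >= interval.lower_limit:
        return "none"
    if copies < biallelic_threshold:
        return "biallelic"
    return "monoallelic"


def call_allele_loss(assays: Iterable[DropletAssay], interval: MockInterval,
                     biallelic_threshold: float = 0.5) -> pd.DataFrame:
    """Per-colony, per-side loss calls from droplet assays."""
    rows = []
    for a in assays:
        c = copy_number(a)
        rows.append(dict(sample=a.sample, side=a.side, copies=c,
                         call=call_loss(c, interval, biallelic_threshold)))
    return pd.DataFrame(rows, columns=["sample", "side", "copies", "call"])


def loss_enrichment_test(group_calls: Mapping[str, tuple[int, int]],
                         reference_group: str) -> pd.DataFrame:
    """Fisher's exact tests of below-limit proportions vs a reference group.

    ``group_calls`` maps group → (n_below, n_total).  Each non-reference
    group is compared to the reference on the 2×2 table
    (below, not below) × (group, reference) with the two-tailed
    minimum-likelihood Fisher's exact test; p-values are adjusted across
    comparisons with Benjamini–Hochberg.
    """
    if reference_group not in group_calls:
        raise ValueError(f"reference group {reference_group!r} missing")
    rb, rt = group_calls[reference_group]
    if rt <= 0:
        raise ValueError("reference group is empty")
    rows = []
    for group, (nb, nt) in group_calls.items():
        if group == reference_group:
            continue
        if not (0 <= nb <= nt):
            raise ValueError(f"invalid counts for group {group!r}")
        table = [[nb, nt - nb], [rb, rt - rb]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(dict(group=group, n_below=nb, n_total=nt,
                         ref_below=rb, ref_total=rt, p=float(p)))
    df = pd.DataFrame(rows, columns=["group", "n_below", "n_total",
                                     "ref_below", "ref_total", "p"])
    if len(df):
        df["q"] = stats.false_discovery_control(df["p"], method="bh")
    else:
        df["q"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# Translocation junctions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """An editing target for junction enumeration.

    ``cut`` is the 0-based boundary coordinate of the nick/cut on ``chrom``.
    ``left_primer`` is a forward primer upstream of the cut (top-strand
    sequence); ``right_primer`` is a reverse primer downstream of the cut
    (already reverse-complemented, as ordered from a vendor).  For CBE-style
    loci, ``deaminase_window`` gives the reference interval of the deaminase
    target sites so the breakpoint window spans from there to the nick.
    """

    name: str
    chrom: str
    cut: int
    editor: str = "cas9"
    left_primer: str = ""
    right_primer: str = ""
    deaminase_window: Optional[tuple[int, int]] = None

    def breakpoint_window(self) -> tuple[int, int]:
        if self.editor == "cbe" and self.deaminase_window is not None:
            lo, hi = self.deaminase_window
            return min(lo, self.cut), max(hi, self.cut)
        return self.cut, self.cut


@dataclass(frozen=True)
class Junction:
    """One interchromosomal fusion junction and the primer pair expected to
    amplify across it."""

    name: str
    segments: tuple[str, str]
    primer_pair: tuple[str, str]
    breakpoint_window_a: tuple[int, int]
    breakpoint_window_b: tuple[int, int]
    inverted: bool


@dataclass(frozen=True)
class JunctionSet:
    locus_a: Locus
    locus_b: Locus
    junctions: tuple[Junction, ...]

    def __len__(self) -> int:
        return len(self.junctions)


def enumerate_junctions(locus_a: Locus, locus_b: Locus) -> JunctionSet:
    """The four reciprocal fusion junctions between two cut loci.

    Requires the loci to be on different chromosomes.  Junction types:
    the two balanced fusions (A-left + B-right, B-left + A-right) and the
    two inverted fusions joining same-side segments (A-left + B-left,
    A-right + B-right).  Each is assigned the primer pair from the 2×2
    primer matrix that can amplify across it, and a predicted breakpoint
    window per locus (a point at the cut for nucleases; the span between
    the deaminase target sites and the nick for CBEs).
    """
    if locus_a.chrom == locus_b.chrom:
        raise ValueError(
            "junction enumeration supports inter-chromosomal locus pairs only")
    a, b = locus_a.name, locus_b.name
    wa, wb = locus_a.breakpoint_window(), locus_b.breakpoint_window()
    junctions = (
        Junction(f"{a}L-{b}R", (f"{a}:left", f"{b}:right"),
                 (f"{a}_left", f"{b}_right"), wa, wb, inverted=False),
        Junction(f"{b}L-{a}R", (f"{b}:left", f"{a}:right"),
                 (f"{b}_left", f"{a}_right"), wa, wb, inverted=False),
        Junction(f"{a}L-{b}L", (f"{a}:left", f"{b}:left"),
                 (f"{a}_left", f"{b}_left"), wa, wb, inverted=True),
        Junction(f"{a}R-{b}R", (f"{a}:right", f"{b}:right"),
                 (f"{a}_right", f"{b}_right"), wa, wb, inverted=True),
    )
    return JunctionSet(locus_a, locus_b, junctions)


def in_silico_pcr(template: str, forward: str, reverse: str,
                  max_product: Optional[int] = None) -> bool:
    """Whether a forward/reverse primer pair amplifies the template.

    The forward primer must occur on the top strand and the reverse primer's
    reverse complement downstream of it; ``max_product`` optionally caps the
    product length.
    """
    template = template.upper()
    f = template.find(forward.upper())
    if f < 0:
        return False
    r = template.find(_revcomp(reverse.upper()), f + len(forward))
    if r < 0:
        return False
    product = r + len(reverse) - f
    return max_product is None or product <= max_product
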
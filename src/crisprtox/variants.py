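"""Treatment-associated variant-landscape analysis.

Implements the filtering and set logic used to enrich for variants induced
by an editing treatment: hard quality filters (quality-by-depth, site and
per-sample depth, genotype quality), subtraction of the mock/germline
variant set, multiallelic-record removal, strand-collapsed SNV spectra,
the colony-pool VAF window, RNA-variant consensus filtering across callers,
and intersection with a cancer-gene panel.

Variant tables are pandas DataFrames with at least the columns
``chrom, pos, ref, alt`` (1-based VCF positions); quality columns
``qd, site_dp, gq, dp`` and ``vaf``/``gene``/``impact`` where the operation
needs them.  Variant identity everywhere is the ``(chrom, pos, ref, alt)``
tuple — genotype phase is ignored.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "SpectrumSummary",
    "SNV_CLASSES",
    "snv_class",
    "variant_keys",
    "apply_quality_filters",
    "subtract_germline",
    "treatment_associated_set",
    "intersection_counts",
    "remove_multiallelic",
    "mutational_spectrum",
    "vaf_window_filter",
    "rna_consensus_filter",
    "panel_intersect",
    "read_vcf",
]

KEY = ["chrom", "pos", "ref", "alt"]

#: Strand-collapsed SNV classes: each of the 12 ordered substitutions maps
#: into exactly one of these 6 (the pyrimidine-context convention).
SNV_CLASSES = ("C>T/G>A", "C>A/G>T", "C>G/G>C",
               "A>G/T>C", "A>T/T>A", "A>C/T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def snv_class(ref: str, alt: str) -> Optional[str]:
    """Strand-collapsed class of an SNV; None for non-SNVs."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref not in _COMP or alt not in _COMP:
        return None
    r, a = ref, alt
    if r in "GT":  # collapse to the C/A-reference strand
        r, a = _COMP[r], _COMP[a]
    for cls in SNV_CLASSES:
        if cls.split("/")[0] == f"{r}>{a}":
            return cls
    raise AssertionError("unreachable")


def variant_keys(variants: Union[pd.DataFrame, Iterable[tuple]]) -> set[tuple]:
    """Set of (chrom, pos, ref, alt) identity keys."""
    if isinstance(variants, pd.DataFrame):
        if not len(variants):
            return set()
        return set(map(tuple, variants[KEY].itertuples(index=False)))
    return set(map(tuple, variants))


@dataclass(frozen=True)
class FilterConfig:
    """Hard-filter thresholds; removals are strict inequalities, so a value
    exactly at a threshold is retained."""

    min_QD: float = 2.0
    min_site_DP: int = 500
    min_GQ: int = 80
    min_sample_DP_bulk: int = 50
    min_sample_DP_sorted: int = 10
    vaf_window: tuple[float, float] = (0.05, 0.2)
    vaf_min_coverage: int = 10
    rna_min_coverage: int = 20
    rna_min_BQ: int = 30
    rna_untreated_ref_fraction: float = 0.99

    def __post_init__(self):
        lo, hi = self.vaf_window
        if lo > hi:
            raise ValueError("vaf_window must be ordered")
        for name in ("min_QD", "min_site_DP", "min_GQ",
                     "min_sample_DP_bulk", "min_sample_DP_sorted",
                     "rna_min_coverage", "rna_min_BQ"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


def apply_quality_filters(variants: pd.DataFrame,
                          config: FilterConfig = FilterConfig(),
                          tier: str = "bulk") -> pd.DataFrame:
    """Remove records failing QD, site DP, GQ or per-sample DP thresholds.

    ``tier`` selects the per-sample depth threshold: ``bulk`` (in-vitro
    samples, default 50) or ``sorted`` (shallow sorted in-vivo fractions,
    default 10).  Records with a missing required field fail closed and the
    count is logged.
    """
    if tier == "bulk":
        min_dp = config.min_sample_DP_bulk
    elif tier == "sorted":
        min_dp = config.min_sample_DP_sorted
    else:
        raise ValueError(f"unknown tier {tier!r}")
    if not len(variants):
        return variants.copy()
    required = ["qd", "site_dp", "gq", "dp"]
    missing = variants[required].isna().any(axis=1)
    if missing.any():
        logger.warning("%d records with missing quality fields fail closed",
                       int(missing.sum()))
    keep = (~missing
            & (variants["qd"] >= config.min_QD)
            & (variants["site_dp"] >= config.min_site_DP)
            & (variants["gq"] >= config.min_GQ)
            & (variants["dp"] >= min_dp))
    return variants.loc[keep].reset_index(drop=True)


def subtract_germline(sample_variants: pd.DataFrame,
                      reference_variants: Union[pd.DataFrame, set],
                      ) -> pd.DataFrame:
    """Drop variants present in the mock/germline reference sample."""
    ref_keys = variant_keys(reference_variants)
    if not len(sample_variants):
        return sample_variants.copy()
    keys = list(map(tuple, sample_variants[KEY].itertuples(index=False)))
    keep = [k not in ref_keys for k in keys]
    return sample_variants.loc[keep].reset_index(drop=True)


def treatment_associated_set(condition_samples: Mapping[str, Sequence],
                             mock_samples: Sequence,
                             mode: str = "reference") -> dict[str, set]:
    """Per-condition treatment-associated variant sets.

    ``condition_samples`` maps condition → per-sample variant sets (or
    DataFrames); ``mock_samples`` is the mock/germline references.  Mode
    ``reference`` (default) subtracts the union of mock variants from each
    condition's union.  Mode ``shared`` additionally subtracts variants seen
    in at least one sample of *every* condition — recurrence across all
    treatment arms marks a germline variant missed by the mock.
    """
    if not condition_samples:
        raise ValueError("empty condition map")
    if not mock_samples:
        raise ValueError("at least one mock sample is required")
    if mode not in ("reference", "shared"):
        raise ValueError(f"unknown mode {mode!r}")
    mock_union: set = set()
    for m in mock_samples:
        mock_union |= variant_keys(m)
    per_condition_union = {
        cond: set.union(*(variant_keys(s) for s in samples)) if samples else set()
        for cond, samples in condition_samples.items()}
    extra: set = set()
    if mode == "shared":
        extra = set.intersection(*per_condition_union.values())
    return {cond: union - mock_union - extra
            for cond, union in per_condition_union.items()}


def intersection_counts(sample_sets: Mapping[str, Union[pd.DataFrame, set]],
                        ) -> dict[tuple[str, ...], int]:
    """Venn-style counts: for every membership pattern across samples, the
    number of variants showing exactly that pattern."""
    keysets = {name: variant_keys(v) for name, v in sample_sets.items()}
    universe = set.union(*keysets.values()) if keysets else set()
    counter: Counter[tuple[str, ...]] = Counter()
    for key in universe:
        pattern = tuple(sorted(n for n, s in keysets.items() if key in s))
        counter[pattern] += 1
    return dict(sorted(counter.items()))


def remove_multiallelic(variants: pd.DataFrame,
                        across: Optional[Sequence[pd.DataFrame]] = None,
                        max_alts_across: int = 2) -> pd.DataFrame:
    """Drop multiallelic sites: >1 alt at a (chrom, pos, ref) within the
    table, or more than ``max_alts_across`` distinct alts at the same
    position across the provided companion tables."""
    if not len(variants):
        return variants.copy()
    site = ["chrom", "pos", "ref"]
    n_alts = variants.groupby(site)["alt"].transform("nunique")
    keep = n_alts <= 1
    if across:
        pooled = pd.concat([variants[KEY]] + [t[KEY] for t in across if len(t)])
        across_alts = pooled.drop_duplicates().groupby(site)["alt"].nunique()
        flagged = set(across_alts[across_alts > max_alts_across].index)
        keep &= [tuple(row) not in flagged
                 for row in variants[site].itertuples(index=False)]
    return variants.loc[keep].reset_index(drop=True)


@dataclass
class SpectrumSummary:
    """Counts of insertions, deletions and the 6 SNV classes, with SNV-class
    proportions (over SNVs only; empty when there are none)."""

    counts: dict[str, int]
    snv_proportions: dict[str, float]

    @property
    def n_snv(self) -> int:
        return sum(self.counts.get(c, 0) for c in SNV_CLASSES)


def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


def mutational_spectrum(variants: pd.DataFrame) -> SpectrumSummary:
    """Classify variants by type and collapse SNVs into the 6 strand classes.

    Callers are expected to have removed multiallelic records beforehand
    (see :func:`remove_multiallelic`).
    """
    counts: dict[str, int] = {"insertion": 0, "deletion": 0}
    counts.update({c: 0 for c in SNV_CLASSES})
    for row in variants.itertuples(index=False):
        vt = _variant_type(row.ref, row.alt)
        if vt == "SNV":
            cls = snv_class(row.ref, row.alt)
            if cls is not None:
                counts[cls] += 1
        else:
            counts[vt] += 1
    n_snv = sum(counts[c] for c in SNV_CLASSES)
    props = ({c: counts[c] / n_snv for c in SNV_CLASSES} if n_snv else {})
    return SpectrumSummary(counts, props)


def vaf_window_filter(variants: pd.DataFrame, n_colonies: int,
                      config: FilterConfig = FilterConfig(),
                      ) -> tuple[pd.DataFrame, float]:
    """Keep variants inside the colony-pool VAF window.

    Removes records with coverage below ``config.vaf_min_coverage`` first,
    then retains those with VAF inside ``config.vaf_window`` (inclusive).
    Returns the filtered table and the expected VAF of a variant private to
    one of ``n_colonies`` equally represented diploid colonies,
    1 / (2·n_colonies).
    """
    if n_colonies <= 0:
        raise ValueError("n_colonies must be positive")
    expected_vaf = 1.0 / (2 * n_colonies)
    if not len(variants):
        return variants.copy(), expected_vaf
    lo, hi = config.vaf_window
    keep = ((variants["dp"] >= config.vaf_min_coverage)
            & (variants["vaf"] >= lo) & (variants["vaf"] <= hi))
    return variants.loc[keep].reset_index(drop=True), expected_vaf


def _pileup_stats(pileup: pd.DataFrame) -> pd.DataFrame:
    """Coverage and reference-base fraction per position from
    quality-filtered base counts (columns chrom, pos, ref, A, C, G, T)."""
    bases = ["A", "C", "G", "T"]
    out = pileup.copy()
    out["coverage"] = out[bases].sum(axis=1)
    ref_counts = np.array([row[b] for row, b in
                           zip(out[bases].to_dict("records"), out["ref"])])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ref_fraction"] = np.where(out["coverage"] > 0,
                                       ref_counts / out["coverage"], 0.0)
    return out.set_index(["chrom", "pos"])


def rna_consensus_filter(treated_calls: Mapping[str, Union[pd.DataFrame, set]],
                         untreated_calls: Mapping[str, Union[pd.DataFrame, set]],
                         treated_pileup: pd.DataFrame,
                         untreated_pileup: pd.DataFrame,
                         config: FilterConfig = FilterConfig()) -> set[tuple]:
    """Consensus RNA variants private to the treated sample.

    Keeps variants called by *all* tools in the treated sample, after
    removing any variant called in the untreated control by any tool;
    retained positions must have quality-filtered coverage ≥
    ``rna_min_coverage`` in both samples and an untreated reference-base
    fraction ≥ ``rna_untreated_ref_fraction``.  Pileups are assumed to count
    only bases with quality ≥ ``rna_min_BQ``.
    """
    if len(treated_calls) < 2:
        raise ValueError("need ≥2 caller call sets for a consensus")
    consensus = set.intersection(*(variant_keys(v)
                                   for v in treated_calls.values()))
    untreated_any: set = set()
    for v in untreated_calls.values():
        untreated_any |= variant_keys(v)
    consensus -= untreated_any
    t_stats = _pileup_stats(treated_pileup)
    u_stats = _pileup_stats(untreated_pileup)
    kept = set()
    for key in consensus:
        loc = (key[0], key[1])
        if loc not in t_stats.index or loc not in u_stats.index:
            continue
        if t_stats.loc[loc, "coverage"] < config.rna_min_coverage:
            continue
        if u_stats.loc[loc, "coverage"] < config.rna_min_coverage:
            continue
        if u_stats.loc[loc, "ref_fraction"] < config.rna_untreated_ref_fraction:
            continue
        kept.add(key)
    return kept


def panel_intersect(variants: pd.DataFrame, panel: Iterable[str],
                    impact_whitelist: Iterable[str] = ("high", "moderate"),
                    group_col: Optional[str] = None,
                    ) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Variants hitting a gene panel at whitelisted impact.

    ``variants`` must carry ``gene`` and ``impact`` annotation columns
    (annotation itself is upstream).  When ``group_col`` names a column, a
    sharing table (variant × group presence) is also returned.
    """
    panel = set(panel)
    whitelist = {w.lower() for w in impact_whitelist}
    if not len(variants) or not panel:
        hits = variants.iloc[0:0].copy()
        return hits, None
    keep = (variants["gene"].isin(panel)
            & variants["impact"].str.lower().isin(whitelist))
    hits = variants.loc[keep].reset_index(drop=True)
    sharing = None
    if group_col is not None and len(hits):
        sharing = (hits.assign(present=1)
                   .pivot_table(index=KEY + ["gene", "impact"],
                                columns=group_col, values="present",
                                aggfunc="max", fill_value=0)
                   .reset_index())
    return hits, sharing


def read_vcf(path, sample: Optional[str] = None) -> pd.DataFrame:
    """Read a (single-sample) VCF into the variant-table DataFrame layout."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        if sample is None:
            sample = list(vf.header.samples)[0]
        for rec in vf:
            s = rec.samples[sample]
            for alt in rec.alts or ():
                rows.append(dict(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    type=_variant_type(rec.ref, alt),
                    qd=float(rec.info.get("QD", np.nan)),
                    site_dp=int(rec.info["DP"]) if "DP" in rec.info else np.nan,
                    gq=s.get("GQ", np.nan),
                    dp=s.get("DP", np.nan),
                    vaf=float(s["AF"]) if s.get("AF") is not None else np.nan,
                ))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "type",
                                       "qd", "site_dp", "gq", "dp", "vaf"])
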
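"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (a) amplicon reads drawn from a configured outcome mixture, with
positioned deletions, bystander substitutions and scaffold-prefix insertions
plus i.i.d. per-base sequencing errors; (b) barcode-library reads from
log-normally abundant clones split across hematopoietic lineages; (c) VCF
variant tables sharing a germline set, with treatment-private SNVs of a
chosen spectrum and optional colony-pool VAF structure; (d) droplet counts
from a known copy number under a binomial droplet-occupancy model.

All randomness flows from ``SimConfig.seed``: a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .amplicon import (AmpliconSpec, Deletion, Insertion, PegSpec,
                       Substitution, apply_events)
from .lesions import DropletAssay
from .variants import snv_class

__all__ = [
    "SimConfig",
    "SampleDesign",
    "gen_amplicon_reads",
    "gen_barcode_reads",
    "gen_variant_tables",
    "gen_droplet_counts",
    "write_fastq",
    "write_vcf",
]

_BASES = "ACGT"


def _check_probability_map(name: str, m: Optional[dict]) -> None:
    if m is None:
        return
    total = sum(m.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in m.values()):
        raise ValueError(f"{name} contains negative probabilities")


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generators.

    The probability maps (``outcome_mixture``, ``lineage_split``,
    ``spectrum``) must each sum to 1 within 1e-9.  Fields beyond the core
    study conditions (barcode/anchor lengths, deletion-length model, variant
    counts, quality-field behavior, droplet occupancy) are exposed so tests
    can exercise both sides of every downstream filter.
    """

    seed: int = 0
    n_reads: int = 10_000
    per_base_error_rate: float = 0.001
    outcome_mixture: Optional[dict[str, float]] = None
    clone_count: int = 50
    clone_abundance_sigma: float = 1.0
    lineage_split: Optional[dict[str, float]] = None
    n_colonies: int = 6
    spectrum: Optional[dict[str, float]] = None
    n_droplets: int = 20_000
    # read structure for barcode libraries: vector context flanks the
    # anchor–barcode–anchor cassette so reads clear the length filter
    barcode_length: int = 18
    anchor_length: int = 12
    read_pad_length: int = 15
    # simulated deletion lengths: geometric, truncated
    deletion_mean_length: float = 4.0
    deletion_max_length: int = 30
    # variant-table generation
    n_germline_variants: int = 200
    n_private_variants: int = 50
    depth: int = 600
    fail_fraction: float = 0.0
    contig: str = "chr1"
    contig_length: int = 1_000_000
    # droplet model: fraction of droplets positive for the 2-copy normalizer
    droplet_norm_fraction: float = 0.05

    def __post_init__(self):
        _check_probability_map("outcome_mixture", self.outcome_mixture)
        _check_probability_map("lineage_split", self.lineage_split)
        _check_probability_map("spectrum", self.spectrum)
        if not 0 <= self.per_base_error_rate < 1:
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(stream)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown SimConfig fields: {sorted(extra)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------------

_PE_ONLY = {"precise_PE", "imprecise_PE", "other"}
_BE_ONLY = {"expected_edit", "other_SNV", "indel"}


def _sample_deletion(spec: AmpliconSpec, rng: np.random.Generator,
                     config: SimConfig, center: float) -> Deletion:
    mean = config.deletion_mean_length
    length = int(min(rng.geometric(1.0 / mean), config.deletion_max_length))
    start = int(round(center - length / 2.0))
    start = max(1, min(start, len(spec.reference) - length - 1))
    return Deletion(start, start + length)


def _deletion_center(spec: AmpliconSpec, rng: np.random.Generator) -> float:
    """Cas9-style: Normal around the cut; CBE-style: Uniform between the
    deaminase target sites and the nick."""
    if spec.conversion is None:
        return rng.normal(spec.cut, 2.0)
    coords = spec.window_coords + [spec.cut]
    lo, hi = min(coords), max(coords)
    return rng.uniform(lo, hi)


def _simulate_class(label: str, spec, rng: np.random.Generator,
                    config: SimConfig) -> tuple:
    """Return the event tuple implementing one sampled outcome class."""
    base = spec.base if isinstance(spec, PegSpec) else spec
    if label == "WT":
        return ()
    if label == "expected_edit":
        editable = base.editable_coords
        if not editable:
            raise ValueError("spec has no editable base in the editing window")
        pick = [c for c in editable if rng.random() < 0.5]
        if not pick:
            pick = [editable[rng.integers(len(editable))]]
        return tuple(base.expected_substitution(c) for c in sorted(pick))
    if label == "other_SNV":
        lo, hi = base.editing_window
        window = set(range(lo, hi + 1))
        choices = [p for p in range(1, base.protospacer_length + 1)
                   if p not in window]
        pos = int(rng.choice(choices))
        coord = base.ref_coord(pos)
        ref_base = base.reference[coord]
        alt = rng.choice([b for b in _BASES if b != ref_base])
        return (Substitution(coord, ref_base, str(alt)),)
    if label == "indel":
        center = _deletion_center(base, rng)
        return (_sample_deletion(base, rng, config, center),)
    # prime-editing classes
    if not isinstance(spec, PegSpec):
        raise ValueError(f"outcome class {label!r} requires a PegSpec")
    if label == "precise_PE":
        return spec.intended_events()
    if label == "imprecise_PE":
        intended = spec.intended_events()
        if rng.random() < 0.5:
            k = int(rng.integers(3, len(spec.scaffold_prefix) + 1))
            extra = Insertion(spec.peg_nick, spec.scaffold_prefix[:k])
            if not _clashes(extra, intended):
                return intended + (extra,)
        nicks = [spec.peg_nick]
        if spec.nick_gRNA is not None:
            nicks.append(spec.nick_gRNA.cut)
        for _ in range(50):  # resample until the indel avoids the edit
            nick = int(rng.choice(nicks))
            d = _sample_deletion(base, rng, config, float(nick))
            if not _clashes(d, intended):
                return intended + (d,)
        raise RuntimeError("cannot place an imprecise indel clear of the edit")
    if label == "other":
        nicks = [spec.peg_nick]
        if spec.nick_gRNA is not None:
            nicks.append(spec.nick_gRNA.cut)
        nick = int(rng.choice(nicks))
        return (_sample_deletion(base, rng, config, float(nick)),)
    raise ValueError(f"unknown outcome class {label!r}")


def _span(e) -> tuple[int, int]:
    if isinstance(e, Deletion):
        return e.start, e.end
    return e.pos, e.pos + (1 if isinstance(e, Substitution) else 0)


def _clashes(event, others: tuple) -> bool:
    """Whether an extra event overlaps (or abuts, for indels) existing ones."""
    s, e = _span(event)
    for o in others:
        os_, oe = _span(o)
        if s <= oe and os_ <= e:  # touching counts as a clash
            return True
    return False


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


def gen_amplicon_reads(spec: AmpliconSpec | PegSpec, config: SimConfig,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate amplicon reads from an outcome mixture.

    Returns ``(reads, truth)``: ``reads`` has columns ``read_id, sequence``;
    ``truth`` has ``read_id, true_class``.  Each read is the reference with
    the sampled modification applied, plus i.i.d. per-base substitution
    errors.
    """
    mixture = config.outcome_mixture or {"WT": 1.0}
    _check_probability_map("outcome_mixture", mixture)
    is_pe = isinstance(spec, PegSpec)
    valid = set(("WT",) + (("precise_PE", "imprecise_PE", "other") if is_pe
                           else ("expected_edit", "other_SNV", "indel")))
    bad = set(mixture) - valid
    if bad:
        kind = "PegSpec" if is_pe else "AmpliconSpec"
        raise ValueError(
            f"outcome classes {sorted(bad)} are incompatible with a {kind}")
    base = spec.base if is_pe else spec
    rng = config.rng(stream=1)
    labels = list(mixture)
    probs = np.array([mixture[k] for k in labels], dtype=float)
    draws = rng.choice(len(labels), size=config.n_reads, p=probs)
    rows, truth = [], []
    for i, d in enumerate(draws):
        label = labels[d]
        events = _simulate_class(label, spec, rng, config)
        seq = apply_events(base.reference, events)
        seq = _apply_errors(seq, config.per_base_error_rate, rng)
        rid = f"read{i:06d}"
        rows.append((rid, seq))
        truth.append((rid, label))
    reads = pd.DataFrame(rows, columns=["read_id", "sequence"])
    truth = pd.DataFrame(truth, columns=["read_id", "true_class"])
    return reads, truth


# ---------------------------------------------------------------------------
# Barcode-library reads
# ---------------------------------------------------------------------------


@dataclass
class BarcodeSim:
    """Simulated barcode-library sequencing run with truth."""

    reads: pd.DataFrame          # read_id, lineage, sequence
    truth: pd.DataFrame          # barcode, lineage, reads (realized counts)
    barcodes: list[str]          # truth clone barcodes
    anchor5: str
    anchor3: str


def _random_separated_barcodes(n: int, length: int,
                               rng: np.random.Generator,
                               min_distance: int = 3) -> list[str]:
    """Random fixed-length barcodes with pairwise edit distance > 2."""
    import edlib

    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cannot place enough well-separated barcodes")
        cand = "".join(rng.choice(list(_BASES), size=length))
        ok = all(
            edlib.align(cand, b, task="distance",
                        k=min_distance - 1)["editDistance"] == -1
            for b in out)
        if ok:
            out.append(cand)
    return out


def gen_barcode_reads(library_size: int, config: SimConfig) -> BarcodeSim:
    """Simulate barcode reads: anchor–barcode–anchor with per-base errors.

    ``config.clone_count`` clones are sampled (without replacement) from a
    library of ``library_size`` barcodes whose pairwise edit distance
    exceeds 2; clone abundances are log-normal and reads are split across
    lineages per ``lineage_split``.
    """
    if config.clone_count > library_size:
        raise ValueError("clone_count exceeds library_size")
    rng = config.rng(stream=2)
    library = _random_separated_barcodes(library_size, config.barcode_length,
                                         rng)
    idx = rng.choice(library_size, size=config.clone_count, replace=False)
    barcodes = [library[i] for i in idx]
    anchor5 = "".join(rng.choice(list(_BASES), size=config.anchor_length))
    anchor3 = "".join(rng.choice(list(_BASES), size=config.anchor_length))
    pad5 = "".join(rng.choice(list(_BASES), size=config.read_pad_length))
    pad3 = "".join(rng.choice(list(_BASES), size=config.read_pad_length))
    abundance = rng.lognormal(mean=0.0, sigma=config.clone_abundance_sigma,
                              size=config.clone_count)
    abundance /= abundance.sum()
    split = config.lineage_split or {"B": 1 / 3, "M": 1 / 3, "T": 1 / 3}
    rows, truth_rows = [], []
    rid = 0
    for lineage, frac in split.items():
        n_lin = int(round(config.n_reads * frac))
        counts = rng.multinomial(n_lin, abundance)
        for bc, c in zip(barcodes, counts):
            truth_rows.append((bc, lineage, int(c)))
            for _ in range(c):
                seq = pad5 + anchor5 + bc + anchor3 + pad3
                seq = _apply_errors(seq, config.per_base_error_rate, rng)
                rows.append((f"bread{rid:06d}", lineage, seq))
                rid += 1
    reads = pd.DataFrame(rows, columns=["read_id", "lineage", "sequence"])
    truth = pd.DataFrame(truth_rows, columns=["barcode", "lineage", "reads"])
    return BarcodeSim(reads, truth, barcodes, anchor5, anchor3)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------


@dataclass
class SampleDesign:
    """Sample layout: one mock/germline sample, ≥1 treated per condition."""

    mock: str
    treated: dict[str, list[str]]
    colony_pool: bool = False

    def __post_init__(self):
        if not self.mock or not self.treated or not any(self.treated.values()):
            raise ValueError("design needs a mock sample and ≥1 treated sample")

    @property
    def samples(self) -> list[str]:
        return [self.mock] + [s for ss in self.treated.values() for s in ss]


_FILTER_FIELDS = ("qd", "site_dp", "gq", "dp")


def _quality_fields(rng: np.random.Generator, fail: Optional[str] = None) -> dict:
    """Passing values are drawn well inside thresholds; a failing variant is
    drawn just below the threshold of one chosen filter."""
    q = {
        "qd": float(rng.uniform(5, 35)),
        "site_dp": int(rng.integers(600, 1201)),
        "gq": int(rng.integers(90, 100)),
        "dp": int(rng.integers(400, 801)),
    }
    if fail == "qd":
        q["qd"] = float(rng.uniform(0.5, 1.99))
    elif fail == "site_dp":
        q["site_dp"] = int(rng.integers(300, 500))
    elif fail == "gq":
        q["gq"] = int(rng.integers(60, 80))
    elif fail == "dp":
        q["dp"] = int(rng.integers(20, 50))
    return q


def _draw_snv(rng: np.random.Generator,
              spectrum: Optional[dict[str, float]]) -> tuple[str, str]:
    if spectrum is None:
        ref = str(rng.choice(list(_BASES)))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        return ref, alt
    labels = list(spectrum)
    probs = np.array([spectrum[k] for k in labels])
    cls = labels[int(rng.choice(len(labels), p=probs))]
    pair = cls.split("/")[int(rng.integers(2))]
    ref, alt = pair.split(">")
    return ref, alt


def gen_variant_tables(config: SimConfig, design: SampleDesign,
                       ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample variant tables with a shared germline.

    All samples (including the mock) carry a common germline variant set;
    each treated sample additionally carries private SNVs drawn from
    ``config.spectrum``.  In colony-pool mode each treated sample instead
    carries one heterozygous private variant per colony, so the pooled VAF
    concentrates near 1/(2·n_colonies).  A ``config.fail_fraction`` of
    private variants is drawn just below one quality threshold each, cycling
    through the four filters.

    Returns ``(tables, truth)`` where ``tables`` maps sample name to a
    variant DataFrame (columns: chrom, pos, ref, alt, type, qd, site_dp,
    gq, dp, vaf) and ``truth`` lists every planted variant with its origin.
    """
    rng = config.rng(stream=3)
    n_private = (config.n_colonies if design.colony_pool
                 else config.n_private_variants)
    total_needed = config.n_germline_variants + n_private * sum(
        len(v) for v in design.treated.values())
    positions = rng.choice(np.arange(1, config.contig_length),
                           size=total_needed, replace=False)
    positions = iter(int(p) for p in positions)

    germline = []
    for _ in range(config.n_germline_variants):
        ref, alt = _draw_snv(rng, None)
        pos = next(positions)
        vaf = rng.binomial(config.depth, 0.5) / config.depth
        germline.append(dict(chrom=config.contig, pos=pos, ref=ref, alt=alt,
                             type="SNV", vaf=float(vaf)))

    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []

    def _rows_for(sample: str, records: list[dict], kind: str) -> list[dict]:
        out = []
        for rec in records:
            fail = rec.get("_fail")
            q = _quality_fields(rng, fail)
            row = {k: v for k, v in rec.items() if not k.startswith("_")}
            row.update(q)
            out.append(row)
            truth_rows.append(dict(sample=sample, chrom=rec["chrom"],
                                   pos=rec["pos"], ref=rec["ref"],
                                   alt=rec["alt"], kind=kind,
                                   snv_class=snv_class(rec["ref"], rec["alt"]),
                                   vaf=rec["vaf"],
                                   passes_filters=fail is None))
        return out

    tables[design.mock] = pd.DataFrame(_rows_for(design.mock, germline,
                                                 "germline"))
    fail_cycle = 0
    for condition, samples in design.treated.items():
        for sample in samples:
            private = []
            for j in range(n_private):
                ref, alt = _draw_snv(rng, config.spectrum)
                pos = next(positions)
                if design.colony_pool:
                    p_true = 1.0 / (2 * config.n_colonies)
                else:
                    p_true = 0.5
                vaf = rng.binomial(config.depth, p_true) / config.depth
                rec = dict(chrom=config.contig, pos=pos, ref=ref, alt=alt,
                           type="SNV", vaf=float(vaf))
                if rng.random() < config.fail_fraction:
                    rec["_fail"] = _FILTER_FIELDS[fail_cycle % 4]
                    fail_cycle += 1
                private.append(rec)
            rows = _rows_for(sample, germline, "germline") + \
                _rows_for(sample, private, f"private:{condition}")
            tables[sample] = pd.DataFrame(rows).sort_values("pos",
                                                            ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return tables, truth


# ---------------------------------------------------------------------------
# Droplet counts
# ---------------------------------------------------------------------------


def gen_droplet_counts(true_copies: float, config: SimConfig,
                       rng: Optional[np.random.Generator] = None,
                       side: str = "upstream",
                       sample: str = "sim") -> DropletAssay:
    """Simulate a ddPCR assay for a locus at ``true_copies`` per genome.

    Droplet occupancy is binomial: the 2-copy normalizer is positive with
    probability ``droplet_norm_fraction``; the target with probability
    scaled by ``true_copies / 2``.  In expectation the plain ratio formula
    (target/normalizer) × 2 recovers ``true_copies``.
    """
    if true_copies < 0:
        raise ValueError("true_copies must be ≥ 0")
    p_norm = config.droplet_norm_fraction
    if true_copies > 2.0 / p_norm:
        warnings.warn("true_copies beyond droplet saturation regime; "
                      "target-positive counts will clip", stacklevel=2)
    if rng is None:
        rng = config.rng(stream=4)
    n = config.n_droplets
    norm_pos = int(rng.binomial(n, p_norm))
    p_target = min(1.0, p_norm * true_copies / 2.0)
    target_pos = int(rng.binomial(n, p_target))
    return DropletAssay(target_positive=target_pos,
                        normalizer_positive=norm_pos, side=side,
                        sample=sample)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_fastq(reads: pd.DataFrame, path) -> None:
    """Write a reads DataFrame (read_id, sequence) as Sanger Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            seq = row.sequence
            fh.write(f"@{row.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_vcf(table: pd.DataFrame, path, sample: str,
              contig: str = "chr1", contig_length: int = 1_000_000) -> None:
    """Write one sample's variant table as an uncompressed VCF v4.2."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,'
                    'Description="Quality by depth">')
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,'
                    'Description="Site depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                    'Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                    'Description="Sample depth">')
    header.add_line('##FORMAT=<ID=AF,Number=1,Type=Float,'
                    'Description="Allele fraction">')
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in table.sort_values("pos").itertuples(index=False):
            rec = vf.new_record(contig=row.chrom, start=row.pos - 1,
                                stop=row.pos - 1 + len(row.ref),
                                alleles=(row.ref, row.alt))
            rec.info["QD"] = float(row.qd)
            rec.info["DP"] = int(row.site_dp)
            s = rec.samples[sample]
            s["GT"] = (0, 1)
            s["GQ"] = int(row.gq)
            s["DP"] = int(row.dp)
            s["AF"] = float(row.vaf)
            vf.write(rec)
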
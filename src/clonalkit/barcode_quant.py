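"""Barcode-amplicon quantification: FASTQ reads to per-sample clone fractions.

The processing mirrors the amplicon analysis of a barcoded clone mixture:
reads are demultiplexed by exact index match; a read's barcode region is
kept only if it matches the WS design, every base has Phred >= 10 and the
mean Phred is strictly > 30; surviving reads are counted against the
experiment's barcode whitelist by exact match.  Per-sample fractions
divide each barcode's count by the total whitelist-matched reads of that
sample; an optional normalization divides fractions by their mean in the
T = 0 reference samples.  Background is estimated from a barcode known to
be absent from the inoculum: a clone is called detected only if its
fraction strictly exceeds the absent barcode's fraction in that sample.

Every read is accounted for: matched + index-unmatched + design-fail +
quality-fail + whitelist-unmatched equals the input read count.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_design import BarcodeLibrary, matches_design
from .synthetic_data import ReadSet

__all__ = [
    "QCConfig",
    "BarcodeCountTable",
    "ClonalFractionTable",
    "demultiplex",
    "quality_pass",
    "count_barcodes",
    "fractions",
    "normalize_to_t0",
    "estimate_background",
    "read_fastq",
    "quantify",
]

DISCARD_REASONS = ("index_unmatched", "design_fail", "quality_fail", "whitelist_unmatched")

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class QCConfig:
    """Quality thresholds for the barcode region.

    Per-base threshold is inclusive (>= 10), mean threshold strict
    (> 30); both apply to the barcode region only, not the index.
    """

    min_per_base_phred: int = 10
    min_mean_phred: float = 30.0
    ws_repeats: int = 15

    def __post_init__(self) -> None:
        if self.min_per_base_phred < 0:
            raise ValueError("min_per_base_phred must be >= 0")


@dataclass
class BarcodeCountTable:
    """Whitelist counts (samples x barcodes) plus per-sample discard tallies."""

    counts: pd.DataFrame  # index: samples, columns: clone labels
    discarded: pd.DataFrame  # index: samples, columns: DISCARD_REASONS
    total_reads: pd.Series  # per-sample input reads

    def __post_init__(self) -> None:
        matched = self.counts.sum(axis=1)
        binned = self.discarded.sum(axis=1)
        if not ((matched + binned) == self.total_reads).all():
            raise ValueError("accounting violated: matched + discarded != total reads")


@dataclass
class ClonalFractionTable:
    """Per-sample barcode fractions, optional T0-normalized values.

    ``normalized`` is filled by :func:`normalize_to_t0`; ``background``
    by :func:`estimate_background`.  ``undefined_samples`` lists samples
    whose whitelist-matched total was zero (fractions are NaN there).
    """

    fractions: pd.DataFrame  # index: samples, columns: clone labels
    normalized: pd.DataFrame | None = None
    background: pd.Series | None = None
    undefined_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTQ ingestion


def read_fastq(path: str, index_length: int = 0, sample: str = "sample") -> ReadSet:
    """Load a (optionally gzipped) Phred+33 FASTQ into a ReadSet.

    Bases outside ACGT (e.g. N) are encoded as 255 so they fail both the
    design check and whitelist matching.
    """
    from Bio import SeqIO

    opener = gzip.open if path.endswith(".gz") else open
    seqs, quals = [], []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            seqs.append(str(rec.seq).upper())
            quals.append(rec.letter_annotations["phred_quality"])
    if not seqs:
        return ReadSet(
            seq=np.zeros((0, 0), dtype=np.uint8),
            qual=np.zeros((0, 0), dtype=np.uint8),
            index_length=index_length,
            sample=sample,
        )
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("amplicon FASTQ must have fixed-length reads")
    seq_arr = np.full((len(seqs), width), 255, dtype=np.uint8)
    for i, s in enumerate(seqs):
        for j, b in enumerate(s):
            seq_arr[i, j] = _BASE_TO_CODE.get(b, 255)
    qual_arr = np.array(quals, dtype=np.uint8)
    return ReadSet(seq=seq_arr, qual=qual_arr, index_length=index_length, sample=sample)


# ---------------------------------------------------------------------------
# Demultiplexing


def demultiplex(
    reads: ReadSet, index_map: dict[str, str]
) -> tuple[dict[str, ReadSet], int]:
    """Split a pooled ReadSet by exact index match.

    Returns (sample -> ReadSet with the index stripped, n_unmatched).
    One mismatch in the index sends the read to the unmatched bin; no
    error correction is attempted.

    Raises
    ------
    ValueError
        If index tags differ in length, collide, or do not fit the reads.
    """
    tags = list(index_map.keys())
    if len(set(tags)) != len(tags) or len(set(index_map.values())) != len(index_map):
        raise ValueError("index map has duplicate entries")
    lengths = {len(t) for t in tags}
    if len(lengths) != 1:
        raise ValueError("all index sequences must have the same length")
    (ilen,) = lengths
    if reads.seq.shape[1] < ilen:
        raise ValueError("reads shorter than the index length")

    idx_region = reads.seq[:, :ilen]
    out: dict[str, ReadSet] = {}
    assigned = np.zeros(len(reads), dtype=bool)
    for tag, sample in index_map.items():
        codes = np.array([_BASE_TO_CODE[b] for b in tag], dtype=np.uint8)
        hit = (idx_region == codes).all(axis=1)
        out[sample] = ReadSet(
            seq=reads.seq[hit, ilen:],
            qual=reads.qual[hit, ilen:],
            index_length=0,
            sample=sample,
        )
        assigned |= hit
    return out, int((~assigned).sum())


# ---------------------------------------------------------------------------
# Quality and design filtering


def quality_pass(sequence: str, phred: list[int] | np.ndarray, qc: QCConfig) -> bool:
    """Single-read filter: per-base Phred >= threshold, mean strictly above
    the mean threshold, and the WS design satisfied.

    Raises
    ------
    ValueError
        If the quality string length differs from the sequence length.
    """
    phred = np.asarray(phred)
    if len(phred) != len(sequence):
        raise ValueError("quality string length does not match the barcode region")
    if (phred < qc.min_per_base_phred).any():
        return False
    if not phred.mean() > qc.min_mean_phred:
        return False
    return matches_design(sequence, qc.ws_repeats)


def _design_mask(seq: np.ndarray, ws_repeats: int) -> np.ndarray:
    """Vectorized WS-design check on a (n, 2*ws_repeats) code matrix."""
    if seq.shape[1] != 2 * ws_repeats:
        return np.zeros(seq.shape[0], dtype=bool)
    weak = (seq[:, 0::2] == 0) | (seq[:, 0::2] == 3)  # A or T at odd (1-based) positions
    strong = (seq[:, 1::2] == 1) | (seq[:, 1::2] == 2)  # C or G at even positions
    return weak.all(axis=1) & strong.all(axis=1)


def count_barcodes(
    reads: ReadSet | dict[str, ReadSet],
    library: BarcodeLibrary,
    qc: QCConfig | None = None,
    index_unmatched: dict[str, int] | int | None = None,
) -> BarcodeCountTable:
    """Count whitelist barcodes in one or several demultiplexed ReadSets.

    Filtering order per read: WS design, then Phred thresholds, then
    exact whitelist match; the first failing step claims the read's
    discard bin.  *index_unmatched* carries the demultiplexer's unmatched
    tally into the accounting (attributed to a pseudo-sample row
    ``_unmatched`` when given as an int for a single ReadSet).
    """
    qc = qc or QCConfig(ws_repeats=library.ws_repeats)
    if isinstance(reads, ReadSet):
        reads = {reads.sample: reads}
    if index_unmatched is None:
        index_unmatched = {}
    elif isinstance(index_unmatched, int):
        index_unmatched = {s: index_unmatched for s in list(reads)[:1]}

    whitelist = {
        np.array([_BASE_TO_CODE[b] for b in bc], dtype=np.uint8).tobytes(): i
        for i, bc in enumerate(library.barcodes)
    }
    width = library.length

    count_rows, discard_rows, totals = {}, {}, {}
    for sample, rs in reads.items():
        region = rs.seq[:, rs.index_length:]
        qual = rs.qual[:, rs.index_length:]
        n = region.shape[0]
        counts = np.zeros(len(library), dtype=int)
        tallies = dict.fromkeys(DISCARD_REASONS, 0)
        tallies["index_unmatched"] = int(index_unmatched.get(sample, 0))
        if n and region.shape[1] == width:
            design_ok = _design_mask(region, library.ws_repeats)
            qual_ok = (qual >= qc.min_per_base_phred).all(axis=1) & (
                qual.mean(axis=1) > qc.min_mean_phred
            )
            tallies["design_fail"] = int((~design_ok).sum())
            tallies["quality_fail"] = int((design_ok & ~qual_ok).sum())
            keep = design_ok & qual_ok
            kept = region[keep]
            buf = kept.tobytes()
            n_unmatched = 0
            for i in range(kept.shape[0]):
                idx = whitelist.get(buf[i * width : (i + 1) * width])
                if idx is None:
                    n_unmatched += 1
                else:
                    counts[idx] += 1
            tallies["whitelist_unmatched"] = n_unmatched
        elif n:
            tallies["design_fail"] = n  # wrong length: nothing can match the design
        count_rows[sample] = counts
        discard_rows[sample] = [tallies[r] for r in DISCARD_REASONS]
        totals[sample] = n + tallies["index_unmatched"]

    samples = list(reads)
    return BarcodeCountTable(
        counts=pd.DataFrame(count_rows, index=library.clone_labels).T.loc[samples],
        discarded=pd.DataFrame(discard_rows, index=DISCARD_REASONS).T.loc[samples],
        total_reads=pd.Series(totals).loc[samples],
    )


# ---------------------------------------------------------------------------
# Fractions, normalization, background


def fractions(table: BarcodeCountTable) -> ClonalFractionTable:
    """Barcode count / total whitelist-matched reads, per sample.

    Samples with zero matched reads yield NaN fractions and are listed in
    ``undefined_samples``.
    """
    totals = table.counts.sum(axis=1)
    undefined = list(totals.index[totals == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = table.counts.div(totals, axis=0)
    frac.loc[undefined] = np.nan
    return ClonalFractionTable(fractions=frac, undefined_samples=undefined)


def normalize_to_t0(
    fracs: ClonalFractionTable, t0_sample_ids: list[str]
) -> ClonalFractionTable:
    """Divide each fraction by the barcode's mean fraction in the T0 samples.

    Barcodes absent from every T0 sample (mean fraction 0) cannot be
    normalized: they are dropped from the normalized output with a
    warning.  Returns a new table carrying both raw and normalized values.
    """
    missing = [s for s in t0_sample_ids if s not in fracs.fractions.index]
    if missing:
        raise ValueError(f"T0 samples not in table: {missing}")
    t0_mean = fracs.fractions.loc[t0_sample_ids].mean(axis=0)
    zero = list(t0_mean.index[t0_mean == 0])
    if zero:
        warnings.warn(
            f"barcodes absent from all T0 samples excluded from normalization: {zero}",
            stacklevel=2,
        )
    keep = t0_mean.index[t0_mean > 0]
    normalized = fracs.fractions[keep].div(t0_mean[keep], axis=1)
    return ClonalFractionTable(
        fractions=fracs.fractions,
        normalized=normalized,
        background=fracs.background,
        undefined_samples=fracs.undefined_samples,
    )


def estimate_background(
    fracs: ClonalFractionTable, absent_barcode: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample background level and detection flags.

    The background of a sample is the fraction observed for a barcode
    known to be absent from the inoculum; any other barcode is flagged
    detected only if its fraction is strictly greater than that level.
    The background series is also stored on the table.
    """
    if absent_barcode not in fracs.fractions.columns:
        raise ValueError(f"absent barcode {absent_barcode!r} not in the fraction table")
    background = fracs.fractions[absent_barcode].rename("background")
    others = fracs.fractions.drop(columns=[absent_barcode])
    detected = others.gt(background, axis=0)
    fracs.background = background
    return background, detected


# ---------------------------------------------------------------------------
# End-to-end convenience used by the CLI


def quantify(
    pooled: ReadSet,
    index_map: dict[str, str],
    library: BarcodeLibrary,
    qc: QCConfig | None = None,
    t0_samples: list[str] | None = None,
    absent_barcode: str | None = None,
) -> tuple[BarcodeCountTable, ClonalFractionTable, dict]:
    """Demultiplex, filter, count and summarize one pooled amplicon run."""
    per_sample, n_unmatched = demultiplex(pooled, index_map)
    table = count_barcodes(per_sample, library, qc)
    if n_unmatched:
        first = table.discarded.index[0]
        table.discarded.loc[first, "index_unmatched"] += n_unmatched
        table.total_reads.loc[first] += n_unmatched
    fracs = fractions(table)
    if t0_samples:
        fracs = normalize_to_t0(fracs, t0_samples)
    if absent_barcode:
        estimate_background(fracs, absent_barcode)
    report = {
        "total_reads": {k: int(v) for k, v in table.total_reads.items()},
        "matched": {k: int(v) for k, v in table.counts.sum(axis=1).items()},
        "discarded": {
            s: {r: int(table.discarded.loc[s, r]) for r in DISCARD_REASONS}
            for s in table.discarded.index
        },
        "undefined_samples": fracs.undefined_samples,
    }
    return table, fracs, report


def write_qc_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
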
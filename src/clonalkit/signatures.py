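"""96-channel trinucleotide mutation spectra and signature refitting.

A single-base substitution is classified by the pyrimidine-strand
substitution type (C>A, C>G, C>T, T>A, T>C, T>G) and its immediate 5' and
3' flanking bases, giving the conventional 6 x 16 = 96 channels of the
COSMIC SBS layout.  A sample's spectrum is refit against a catalog of
signature profiles by nonnegative least squares (NNLS); the cosine
similarity between the observed and reconstructed spectrum measures how
well the catalog explains the sample.  Signatures contributing fewer than
a minimum number of mutations across all samples can be dropped and the
refit repeated on the reduced catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SBS_CHANNELS",
    "SUBSTITUTION_TYPES",
    "channel_for",
    "spectrum",
    "SignatureCatalog",
    "ExposureTable",
    "refit",
    "filter_signatures",
    "read_catalog_tsv",
    "write_catalog_tsv",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Conventional lexicographic channel order: substitution type major,
#: then 5' flank, then 3' flank (A[C>A]A, A[C>A]C, ... T[T>G]T).
SBS_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {ch: i for i, ch in enumerate(SBS_CHANNELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_for(ref: str, alt: str, context: str) -> str:
    """Map an SNV (ref, alt, centered 3-mer context) to its 96-channel label.

    Purine-reference mutations are reverse-complemented to the pyrimidine
    strand first, per the COSMIC convention.

    Raises
    ------
    ValueError
        If the call is not a valid SNV or the context middle base does not
        equal the reference base.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if len(context) != 3 or context[1] != ref:
        raise ValueError(
            f"context {context!r} middle base does not match reference {ref!r}"
        )
    if any(b not in _BASES for b in context) or alt not in _BASES:
        raise ValueError(f"non-ACGT base in {context!r}>{alt!r}")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        context = _revcomp(context)
        alt = _COMPLEMENT[alt]
        ref = _COMPLEMENT[ref]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def spectrum(records: pd.DataFrame, sample_columns: list[str] | None = None) -> pd.DataFrame:
    """Count the 96-channel spectrum of a mutation table.

    Parameters
    ----------
    records
        Mutation table with at least ``ref``, ``alt`` and ``context``
        columns.  If *sample_columns* is given, one spectrum per listed
        sample is counted using the per-sample ``alt_<sample>`` columns as
        presence indicators (alt count > 0); otherwise a single pooled
        spectrum labelled ``all`` is returned.

    Returns
    -------
    DataFrame of shape (96, n_samples), integer counts, indexed by channel.
    Non-SNV rows (multi-base ref/alt) are skipped; rows whose context
    middle base contradicts the reference raise :class:`ValueError`.
    """
    samples = sample_columns if sample_columns is not None else ["all"]
    counts = np.zeros((96, len(samples)), dtype=int)
    skipped = 0
    for row in records.itertuples(index=False):
        ref = str(row.ref)
        alt = str(row.alt)
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            skipped += 1
            continue
        ch = _CHANNEL_INDEX[channel_for(ref, alt, str(row.context))]
        if sample_columns is None:
            counts[ch, 0] += 1
        else:
            for j, s in enumerate(samples):
                if getattr(row, f"alt_{s}") > 0:
                    counts[ch, j] += 1
    result = pd.DataFrame(counts, index=list(SBS_CHANNELS), columns=samples)
    result.attrs["n_skipped_non_snv"] = skipped
    return result


@dataclass
class SignatureCatalog:
    """A 96 x K matrix of signature profiles, each column summing to 1."""

    profiles: pd.DataFrame  # index: channels, columns: signature labels

    def __post_init__(self) -> None:
        if list(self.profiles.index) != list(SBS_CHANNELS):
            # accept any row order but require the full channel set
            missing = set(SBS_CHANNELS) - set(self.profiles.index)
            if missing:
                raise ValueError(f"catalog is missing channels, e.g. {sorted(missing)[:3]}")
            self.profiles = self.profiles.loc[list(SBS_CHANNELS)]
        arr = self.profiles.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature column must sum to 1 (within 1e-6)")

    @property
    def labels(self) -> list[str]:
        return list(self.profiles.columns)

    def subset(self, labels: list[str]) -> "SignatureCatalog":
        return SignatureCatalog(self.profiles[labels])


@dataclass
class ExposureTable:
    """Nonnegative per-sample signature exposures (attributed mutation counts).

    ``cosine`` holds the per-sample cosine similarity between the observed
    spectrum and its NNLS reconstruction; NaN for all-zero samples.
    """

    exposures: pd.DataFrame  # index: signature labels, columns: samples
    cosine: pd.Series  # per-sample cosine similarity

    def totals(self) -> pd.Series:
        """Total mutations attributed to each signature across all samples."""
        return self.exposures.sum(axis=1)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def refit(spectrum_df: pd.DataFrame, catalog: SignatureCatalog) -> ExposureTable:
    """Refit each sample's spectrum against the catalog by NNLS.

    Exposures solve ``min ||spectrum - catalog @ e||_2`` subject to
    ``e >= 0``, per sample.  The reconstruction's cosine similarity to the
    observed spectrum is reported alongside.
    """
    spec = spectrum_df.loc[list(SBS_CHANNELS)].to_numpy(dtype=float)
    cat = catalog.profiles.to_numpy(dtype=float)
    expo = np.zeros((cat.shape[1], spec.shape[1]))
    cosines = np.full(spec.shape[1], np.nan)
    for j in range(spec.shape[1]):
        y = spec[:, j]
        if y.sum() == 0:
            continue
        e, _ = nnls(cat, y)
        expo[:, j] = e
        cosines[j] = _cosine(y, cat @ e)
    return ExposureTable(
        exposures=pd.DataFrame(expo, index=catalog.labels, columns=spectrum_df.columns),
        cosine=pd.Series(cosines, index=spectrum_df.columns, name="cosine"),
    )


def filter_signatures(
    spectrum_df: pd.DataFrame,
    catalog: SignatureCatalog,
    exposures: ExposureTable | None = None,
    min_total: int = 200,
) -> tuple[SignatureCatalog, ExposureTable]:
    """Drop signatures contributing < *min_total* mutations and refit.

    Retention is inclusive: a signature whose total attributed count is
    exactly *min_total* is kept.

    Raises
    ------
    ValueError
        If no signature reaches the threshold.
    """
    if exposures is None:
        exposures = refit(spectrum_df, catalog)
    totals = exposures.totals()
    keep = [lab for lab in catalog.labels if totals[lab] >= min_total]
    if not keep:
        raise ValueError(
            f"no signature contributes >= {min_total} mutations across all samples"
        )
    reduced = catalog.subset(keep)
    return reduced, refit(spectrum_df, reduced)


def read_catalog_tsv(path: str) -> SignatureCatalog:
    """Read a catalog TSV: channel rows (first column) x signature columns.

    The first column holds 96-channel labels in any order; remaining
    columns are signature profiles.  Rows are reordered to the
    conventional lexicographic layout (:data:`SBS_CHANNELS`).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog(df)


def write_catalog_tsv(catalog: SignatureCatalog, path: str) -> None:
    catalog.profiles.to_csv(path, sep="\t", index_label="channel")
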
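"""Design and validation of semi-random WS-pattern DNA barcodes.

Clonal lineage-tracing barcodes follow an alternating weak/strong (WS)
pattern: odd positions (1-based) are drawn from {A, T} and even positions
from {C, G}.  A barcode of ``ws_repeats`` pattern repeats is therefore
``2 * ws_repeats`` nt long with exactly 50% GC, which equalizes PCR
amplification efficiency across clones.  The designer below additionally
enforces a minimum pairwise Hamming distance so that sequencing errors
cannot convert one whitelisted barcode into another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WEAK = frozenset("AT")
STRONG = frozenset("CG")

__all__ = [
    "BarcodeLibrary",
    "matches_design",
    "generate_barcodes",
    "hamming",
    "read_library_tsv",
    "write_library_tsv",
    "write_library_fasta",
    "read_library_fasta",
]


def matches_design(sequence: str, ws_repeats: int) -> bool:
    """True iff *sequence* is a valid WS barcode of ``ws_repeats`` repeats.

    The check is purely positional: length must equal ``2 * ws_repeats``,
    every odd position (1-based) must be A or T and every even position C
    or G.  Any other character (including N) fails; no exception is raised
    for malformed input.
    """
    if len(sequence) != 2 * ws_repeats:
        return False
    for i, base in enumerate(sequence):
        if base not in (WEAK if i % 2 == 0 else STRONG):
            return False
    return True


def hamming(a: str, b: str) -> int:
    """Positional Hamming distance between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeLibrary:
    """An ordered whitelist of WS-design barcodes with clone labels.

    Invariants (checked by :meth:`validate`): every barcode is
    ``2 * ws_repeats`` nt, obeys the WS alternation (hence exactly 50% GC),
    all barcodes are distinct and every pair is at Hamming distance
    >= ``min_hamming``.
    """

    ws_repeats: int
    barcodes: list[str]
    clone_labels: list[str] = field(default_factory=list)
    min_hamming: int = 0

    def __post_init__(self) -> None:
        if not self.clone_labels:
            self.clone_labels = [f"CL{i + 1:02d}" for i in range(len(self.barcodes))]
        if len(self.clone_labels) != len(self.barcodes):
            raise ValueError("clone_labels and barcodes must have equal length")
        self.validate()

    def validate(self) -> None:
        for bc in self.barcodes:
            if not matches_design(bc, self.ws_repeats):
                raise ValueError(f"barcode {bc!r} violates the {self.ws_repeats}xWS design")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not all distinct")
        if self.min_hamming <= 1:
            return  # distinctness already guarantees distance >= 1
        n = len(self.barcodes)
        for i in range(n):
            for j in range(i + 1, n):
                d = hamming(self.barcodes[i], self.barcodes[j])
                if d < self.min_hamming:
                    raise ValueError(
                        f"barcodes {self.clone_labels[i]} and {self.clone_labels[j]} "
                        f"at Hamming distance {d} < {self.min_hamming}"
                    )

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def length(self) -> int:
        """Barcode length in nucleotides."""
        return 2 * self.ws_repeats

    def gc_fraction(self, barcode: str) -> float:
        return sum(b in STRONG for b in barcode) / len(barcode)

    def label_for(self, barcode: str) -> str:
        return self.clone_labels[self.barcodes.index(barcode)]


def _random_ws_string(rng: np.random.Generator, ws_repeats: int) -> str:
    weak = rng.integers(0, 2, size=ws_repeats)
    strong = rng.integers(0, 2, size=ws_repeats)
    out = []
    for w, s in zip(weak, strong):
        out.append("AT"[w])
        out.append("CG"[s])
    return "".join(out)


def generate_barcodes(
    n: int,
    ws_repeats: int = 15,
    min_hamming: int = 8,
    seed: int = 0,
    max_attempts: int = 10**6,
) -> BarcodeLibrary:
    """Generate *n* WS barcodes with pairwise Hamming distance >= *min_hamming*.

    Rejection sampling: random WS strings are drawn and kept if they are
    distinct from, and sufficiently distant to, every barcode accepted so
    far.  Deterministic for a fixed *seed*.

    Raises
    ------
    RuntimeError
        If *n* barcodes cannot be found within *max_attempts* draws, e.g.
        because *min_hamming* is too demanding for the barcode length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_hamming > 2 * ws_repeats:
        raise ValueError("min_hamming cannot exceed the barcode length")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(accepted) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {n} barcodes of length {2 * ws_repeats} at "
                f"pairwise Hamming distance >= {min_hamming} within "
                f"{max_attempts} attempts; relax min_hamming or shorten the list"
            )
        attempts += 1
        cand = _random_ws_string(rng, ws_repeats)
        if cand in seen:
            continue
        if min_hamming > 1 and any(hamming(cand, b) < min_hamming for b in accepted):
            continue
        accepted.append(cand)
        seen.add(cand)
    return BarcodeLibrary(ws_repeats=ws_repeats, barcodes=accepted, min_hamming=min_hamming)


# ---------------------------------------------------------------------------
# I/O: two-column TSV (clone_label, barcode) and FASTA (label as header)


def write_library_tsv(library: BarcodeLibrary, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("clone_label\tbarcode\n")
        for label, bc in zip(library.clone_labels, library.barcodes):
            fh.write(f"{label}\t{bc}\n")


def read_library_tsv(path: str, min_hamming: int = 0) -> BarcodeLibrary:
    labels, barcodes = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("clone_label"):
            raise ValueError("library TSV must start with a 'clone_label\\tbarcode' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            label, bc = line.split("\t")
            labels.append(label)
            barcodes.append(bc)
    if not barcodes:
        raise ValueError("empty barcode library")
    ws_repeats, rem = divmod(len(barcodes[0]), 2)
    if rem:
        raise ValueError("barcode length must be even")
    return BarcodeLibrary(
        ws_repeats=ws_repeats, barcodes=barcodes, clone_labels=labels, min_hamming=min_hamming
    )


def write_library_fasta(library: BarcodeLibrary, path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(bc), id=label, description="")
        for label, bc in zip(library.clone_labels, library.barcodes)
    ]
    seqio_write(records, path, "fasta")


def read_library_fasta(path: str, min_hamming: int = 0) -> BarcodeLibrary:
    from Bio import SeqIO

    labels, barcodes = [], []
    for rec in SeqIO.parse(path, "fasta"):
        labels.append(rec.id)
        barcodes.append(str(rec.seq).upper())
    if not barcodes:
        raise ValueError("empty barcode FASTA")
    ws_repeats, rem = divmod(len(barcodes[0]), 2)
    if rem:
        raise ValueError("barcode length must be even")
    return BarcodeLibrary(
        ws_repeats=ws_repeats, barcodes=barcodes, clone_labels=labels, min_hamming=min_hamming
    )
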
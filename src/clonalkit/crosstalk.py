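"""Interclonal ligand-receptor crosstalk screen.

Given a raw gene x sample count matrix over clonal populations and a
table of ligand-receptor pairs, the screen looks for secreted ligands
that a target clone fails to express while still expressing a cognate
receptor — the configuration in which the target can receive a signal it
cannot supply itself.  A ligand is a hit when (i) its library-size-offset
exact binomial depletion test is significant after Benjamini-Hochberg
correction across all tested ligands, (ii) the target has the minimum
cpm for that ligand among all samples, and (iii) at least one of its
receptors is expressed in the target above a cpm threshold.

The depletion test conditions on the ligand's total count n across
samples: under the null of equal expression, the target's count is
Binomial(n, target library size / total library size); the one-sided
p value is P(X <= k).  This is the dispersion-free exact analog of a
count-based differential test for a design with one sample per clone,
where no within-group dispersion can be estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["CrosstalkHit", "cpm", "ligand_depletion_test", "screen"]


@dataclass
class CrosstalkHit:
    """One screened ligand passing all gates."""

    ligand: str
    p_value: float
    fdr: float
    receptors_expressed: list[str]
    max_receptor_cpm: float
    target_cpm: float


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size, per sample column.

    Library sizes default to column sums.

    Raises
    ------
    ValueError
        If any library size is zero.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return counts * 1e6 / library_sizes


def ligand_depletion_test(
    counts: pd.DataFrame,
    target_sample: str,
    gene: str,
    library_sizes: pd.Series | None = None,
) -> float:
    """One-sided exact binomial p for the gene being lower in the target.

    p = P(X <= k) with X ~ Binomial(n, L_target / L_total), where k is
    the target's count and n the gene's total count across samples.  A
    gene with zero total count returns p = 1 (nothing to test).
    """
    if gene not in counts.index:
        raise KeyError(f"gene {gene!r} not in the count matrix")
    if target_sample not in counts.columns:
        raise KeyError(f"sample {target_sample!r} not in the count matrix")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    row = counts.loc[gene]
    n = int(row.sum())
    if n == 0:
        return 1.0
    k = int(row[target_sample])
    p_null = float(library_sizes[target_sample] / library_sizes.sum())
    return float(sps.binom.cdf(k, n, p_null))


def screen(
    counts: pd.DataFrame,
    pairs: pd.DataFrame,
    target: str,
    fdr_cut: float = 0.05,
    receptor_cpm_min: float = 2.0,
) -> list[CrosstalkHit]:
    """Run the full ligand-receptor crosstalk screen.

    *pairs* is a two-column table (ligand, receptor); a ligand may appear
    on several rows (one-to-many receptors).  BH correction runs across
    the tested ligand genes only — receptors are a gate, not a test.
    Hits are returned sorted by FDR then ligand name.

    Raises
    ------
    ValueError
        If none of the listed ligands is present in the count matrix.
    """
    if not {"ligand", "receptor"} <= set(pairs.columns):
        raise ValueError("pairs table needs 'ligand' and 'receptor' columns")
    receptor_map: dict[str, list[str]] = {}
    for lig, rec in zip(pairs["ligand"], pairs["receptor"]):
        receptor_map.setdefault(str(lig), []).append(str(rec))
    ligands = [g for g in receptor_map if g in counts.index]
    if not ligands:
        raise ValueError("no ligand from the pair table is present in the count matrix")
    ligands = sorted(ligands)

    library_sizes = counts.sum(axis=0)
    cpm_mat = cpm(counts, library_sizes)
    pvals = np.array(
        [ligand_depletion_test(counts, target, g, library_sizes) for g in ligands]
    )
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")

    hits: list[CrosstalkHit] = []
    for g, p, q in zip(ligands, pvals, fdrs):
        if q >= fdr_cut:
            continue
        lig_cpm = cpm_mat.loc[g]
        # "lowest in target": the target must have the strict minimum cpm
        if lig_cpm[target] > lig_cpm.drop(target).min():
            continue
        receptors = [r for r in receptor_map[g] if r in cpm_mat.index]
        expressed = [r for r in receptors if cpm_mat.loc[r, target] > receptor_cpm_min]
        if not expressed:
            continue
        hits.append(
            CrosstalkHit(
                ligand=g,
                p_value=float(p),
                fdr=float(q),
                receptors_expressed=expressed,
                max_receptor_cpm=float(max(cpm_mat.loc[r, target] for r in expressed)),
                target_cpm=float(lig_cpm[target]),
            )
        )
    hits.sort(key=lambda h: (h.fdr, h.ligand))
    return hits


def hits_to_frame(hits: list[CrosstalkHit]) -> pd.DataFrame:
    """Tabular view of screen hits for TSV output."""
    return pd.DataFrame(
        [
            {
                "ligand": h.ligand,
                "p_value": h.p_value,
                "fdr": h.fdr,
                "receptors_expressed": ",".join(h.receptors_expressed),
                "max_receptor_cpm": h.max_receptor_cpm,
                "target_cpm": h.target_cpm,
            }
            for h in hits
        ],
        columns=[
            "ligand",
            "p_value",
            "fdr",
            "receptors_expressed",
            "max_receptor_cpm",
            "target_cpm",
        ],
    )
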
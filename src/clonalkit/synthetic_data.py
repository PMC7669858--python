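"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design the pipeline was built for: a
multiclonal mixture of barcoded tumor clones injected into mice, sampled
by barcode-amplicon sequencing over time; whole-exome VAF tables that are
consistent with a known clone tree (including a parental sample that is a
mixture of the clones); negative-binomial expression count matrices with
one planted ligand depleted in a target clone; and blood luciferase
(Gluc) time series proportional to tumor burden.

Clone trajectories follow the observed in vivo pattern: a strong die-off
in the first week after injection, then clone-class-specific exponential
growth (growers expand, persisters hold, decliners shrink toward a floor).

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .barcode_design import BarcodeLibrary
from .signatures import SBS_CHANNELS

__all__ = [
    "CloneSpec",
    "SimulationConfig",
    "GroundTruth",
    "ReadSet",
    "default_clones",
    "simulate_clonal_dynamics",
    "simulate_barcode_reads",
    "simulate_mutation_set",
    "simulate_expression",
    "simulate_gluc",
    "clades_of",
    "tree_tips",
]

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CloneSpec:
    """One clone's growth behavior after the first-week die-off.

    ``growth_rate`` is the per-week multiplicative factor applied from
    week 1 onward: >1 grower, =1 persister, <1 decliner.
    """

    label: str
    klass: str  # grower | persister | decliner
    growth_rate: float

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.klass not in ("grower", "persister", "decliner"):
            raise ValueError(f"unknown clone class {self.klass!r}")


def default_clones() -> list[CloneSpec]:
    """Ten-clone mixture mirroring the study's clone classes.

    One dominant grower (CL31), one weak grower (CL49), persisters, and
    decliners; the 11th library barcode (CL11) is reserved as the
    absent-barcode background control and carries no cells.
    """
    return [
        CloneSpec("CL31", "grower", 2.0),
        CloneSpec("CL49", "grower", 1.4),
        CloneSpec("CL09", "persister", 1.0),
        CloneSpec("CL44", "persister", 1.0),
        CloneSpec("CL03", "persister", 1.0),
        CloneSpec("CL22", "persister", 0.95),
        CloneSpec("CL17", "decliner", 0.5),
        CloneSpec("CL46", "decliner", 0.5),
        CloneSpec("CL25", "decliner", 0.6),
        CloneSpec("CL28", "decliner", 0.4),
    ]


def default_library(seed: int = 0, min_hamming: int = 8):
    """An 11-barcode library labelled to match :func:`default_clones`.

    The 11th barcode, CL11, is the background control: it is in the
    sequenced whitelist but absent from the inoculum.
    """
    from .barcode_design import generate_barcodes

    labels = [c.label for c in default_clones()] + ["CL11"]
    lib = generate_barcodes(len(labels), ws_repeats=15, min_hamming=min_hamming, seed=seed)
    lib.clone_labels = labels
    return lib


@dataclass
class SimulationConfig:
    """Parameters shared by the generators.

    week1_survival is the fraction of injected cells alive at week 1 (the
    initial die-off); read_depth the number of amplicon reads per sample;
    substitution_error_rate the per-base sequencing error probability;
    quality_mean/sd parametrize the per-base Phred score draw;
    nb_dispersion the shared negative-binomial dispersion of expression
    counts (variance = mu + dispersion * mu^2); het_vaf the expected VAF
    of a clonal heterozygous variant in a diploid genome.
    """

    seed: int = 0
    clones: list[CloneSpec] = field(default_factory=default_clones)
    week1_survival: float = 0.1
    initial_cells: float = 1e6
    decliner_floor: float = 0.0
    read_depth: int = 100_000
    substitution_error_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    index_length: int = 6
    index_sequences: dict[str, str] | None = None
    nb_dispersion: float = 0.002
    het_vaf: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.week1_survival <= 1:
            raise ValueError("week1_survival must be in (0, 1]")
        if not 0 <= self.substitution_error_rate <= 1:
            raise ValueError("substitution_error_rate must be a probability")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.het_vaf <= 1:
            raise ValueError("het_vaf must be in [0, 1]")

    # -- YAML round trip (the one supported config dialect) ---------------
    def to_yaml(self, path: str) -> None:
        import yaml

        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        clones = [CloneSpec(**c) for c in data.pop("clones", [])]
        cfg = cls(**{**data, "clones": clones} if clones else data)
        return cfg


@dataclass
class GroundTruth:
    """The generating truth behind one synthetic dataset."""

    fractions: dict[str, dict[str, float]] | None = None  # sample -> clone -> fraction
    true_counts: dict[str, dict[str, int]] | None = None  # sample -> barcode label -> reads
    tree: object | None = None  # nested-tuple topology
    mutation_branches: dict[str, list[str]] | None = None  # mutation id -> carrying clones
    expected_vafs: dict[str, dict[str, float]] | None = None  # mutation id -> sample -> VAF
    exposures: dict[str, float] | None = None  # signature label -> true weight
    planted: dict[str, str] | None = None  # ligand/receptor/target_clone

    def to_json(self, path: str) -> None:
        data = {k: v for k, v in asdict(self).items() if v is not None}
        if "tree" in data:
            data["tree"] = _tree_to_json(self.tree)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _tree_to_json(tree):
    if isinstance(tree, str):
        return tree
    return [_tree_to_json(child) for child in tree]


# ---------------------------------------------------------------------------
# Clone trajectories


def simulate_clonal_dynamics(config: SimulationConfig, weeks: int) -> pd.DataFrame:
    """Deterministic clone abundance trajectories (clones x weeks 0..weeks).

    Week 0 holds the injected cell number; week 1 applies the die-off
    (``initial * week1_survival`` for every clone); each later week
    multiplies by the clone's class growth rate.  Decliners never fall
    below ``decliner_floor``.
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    labels = [c.label for c in config.clones]
    table = np.empty((len(labels), weeks + 1))
    for i, clone in enumerate(config.clones):
        table[i, 0] = config.initial_cells
        table[i, 1] = config.initial_cells * config.week1_survival
        for w in range(2, weeks + 1):
            value = table[i, w - 1] * clone.growth_rate
            if clone.klass == "decliner":
                value = max(value, config.decliner_floor)
            table[i, w] = value
    return pd.DataFrame(table, index=labels, columns=range(weeks + 1))


def clone_fractions(abundances: pd.DataFrame, week: int) -> pd.Series:
    """Normalize one week's abundances to fractions summing to 1."""
    col = abundances[week]
    total = col.sum()
    if total <= 0:
        raise ValueError(f"no cells at week {week}")
    return col / total


# ---------------------------------------------------------------------------
# Barcode amplicon reads


@dataclass
class ReadSet:
    """Amplicon reads held as numpy code matrices (A=0,C=1,G=2,T=3).

    Rows are reads; ``seq`` spans index + barcode, ``qual`` the matching
    Phred scores.  Kept in array form so that simulation and counting of
    10^5-read samples stay vectorized; ``to_fastq`` materializes standard
    Phred+33 FASTQ on demand.
    """

    seq: np.ndarray  # (n_reads, index_length + barcode_length) uint8 codes
    qual: np.ndarray  # same shape, Phred scores
    index_length: int
    sample: str

    def __len__(self) -> int:
        return self.seq.shape[0]

    def sequences(self) -> list[str]:
        return [bytes(_CODE_TO_BASE[row]).decode() for row in self.seq]

    def quality_strings(self) -> list[str]:
        return [bytes(row + 33).decode() for row in self.qual]

    def to_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, (s, q) in enumerate(zip(self.sequences(), self.quality_strings())):
                fh.write(f"@{self.sample}:read{i}\n{s}\n+\n{q}\n")


def _default_indices(samples: Sequence[str], length: int, rng: np.random.Generator) -> dict[str, str]:
    """Distinct random index tags, one per sample."""
    seen: set[str] = set()
    out: dict[str, str] = {}
    for s in samples:
        while True:
            tag = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
            if tag not in seen:
                seen.add(tag)
                out[s] = tag
                break
    return out


def simulate_barcode_reads(
    fractions: pd.Series | dict[str, float],
    library: BarcodeLibrary,
    config: SimulationConfig,
    sample: str = "S1",
    seed: int | None = None,
) -> tuple[ReadSet, GroundTruth]:
    """Simulate one sample's barcode-amplicon reads.

    Each read's source barcode is drawn multinomially from *fractions*
    (keyed by clone label; clones absent from the mapping get fraction 0).
    Per-base substitution errors occur at ``substitution_error_rate`` and
    change the base to one of the three alternatives uniformly.  Phred
    scores are drawn from N(quality_mean, quality_sd), rounded, clipped to
    [2, 40].  The sample's index tag is prepended to every read.
    """
    if isinstance(fractions, dict):
        fractions = pd.Series(fractions)
    if abs(float(fractions.sum()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    frac_vec = np.array([float(fractions.get(lab, 0.0)) for lab in library.clone_labels])
    if abs(frac_vec.sum() - 1.0) > 1e-9:
        missing = sorted(set(fractions.index) - set(library.clone_labels))
        raise ValueError(
            f"clone labels with nonzero fractions are absent from the library: {missing}"
        )
    counts = rng.multinomial(config.read_depth, frac_vec)

    # Source matrix: each whitelist barcode repeated per its draw.
    bc_codes = np.array(
        [[_BASE_TO_CODE[b] for b in bc] for bc in library.barcodes], dtype=np.uint8
    )
    seq_bc = np.repeat(bc_codes, counts, axis=0)

    # Substitution errors: shift by 1-3 mod 4 wherever the error mask hits.
    if config.substitution_error_rate > 0:
        mask = rng.random(seq_bc.shape) < config.substitution_error_rate
        shifts = rng.integers(1, 4, size=seq_bc.shape, dtype=np.uint8)
        seq_bc = np.where(mask, (seq_bc + shifts) % 4, seq_bc).astype(np.uint8)

    indices = config.index_sequences or _default_indices([sample], config.index_length, rng)
    tag = indices[sample]
    idx_codes = np.array([_BASE_TO_CODE[b] for b in tag], dtype=np.uint8)
    seq = np.hstack([np.tile(idx_codes, (len(seq_bc), 1)), seq_bc])

    qual = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd, size=seq.shape)),
        2,
        40,
    ).astype(np.uint8)

    truth = GroundTruth(
        fractions={sample: {lab: float(f) for lab, f in zip(library.clone_labels, frac_vec)}},
        true_counts={sample: {lab: int(c) for lab, c in zip(library.clone_labels, counts)}},
    )
    return ReadSet(seq=seq, qual=qual, index_length=config.index_length, sample=sample), truth


# ---------------------------------------------------------------------------
# Clone-tree-consistent mutation tables


def tree_tips(tree) -> list[str]:
    """Tip labels of a nested-tuple topology, left to right."""
    if isinstance(tree, str):
        return [tree]
    out: list[str] = []
    for child in tree:
        out.extend(tree_tips(child))
    return out


def clades_of(tree) -> list[frozenset[str]]:
    """All clades below the root (every edge of the rooted topology).

    Each clade is the tip set of one subtree, i.e. the set of clones that
    carry mutations arising on the branch above that subtree.  The root
    clade itself is excluded (truncal mutations shared by everything are
    uninformative for topology).
    """
    clades: list[frozenset[str]] = []

    def walk(node) -> frozenset[str]:
        if isinstance(node, str):
            clade = frozenset([node])
        else:
            clade = frozenset().union(*(walk(child) for child in node))
        clades.append(clade)
        return clade

    root = walk(tree)
    return [c for c in clades if c != root]


def _draw_contexts(
    rng: np.random.Generator, n: int, channel_probs: np.ndarray | None, purine_fraction: float
) -> tuple[list[str], list[str], list[str]]:
    """Draw (ref, alt, context) triples from a 96-channel distribution.

    With probability *purine_fraction* the mutation is reported on the
    purine strand (reverse-complemented), as real callers do, exercising
    the downstream strand normalization.
    """
    if channel_probs is None:
        channel_probs = np.full(96, 1 / 96)
    channels = rng.choice(96, size=n, p=channel_probs)
    flip = rng.random(n) < purine_fraction
    refs, alts, contexts = [], [], []
    for ch, fl in zip(channels, flip):
        label = SBS_CHANNELS[ch]
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        context = five + ref + three
        if fl:
            context = "".join(_COMPLEMENT[b] for b in reversed(context))
            ref = _COMPLEMENT[ref]
            alt = _COMPLEMENT[alt]
        refs.append(ref)
        alts.append(alt)
        contexts.append(context)
    return refs, alts, contexts


def simulate_mutation_set(
    tree,
    muts_per_branch: int,
    parent_mixture: dict[str, float],
    depth: int,
    config: SimulationConfig,
    channel_probs: np.ndarray | None = None,
    purine_fraction: float = 0.5,
    depth_jitter: float = 10.0,
    parental_sample: str = "parental",
    outgroup: str | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a per-sample VAF table consistent with a known clone tree.

    Every branch of *tree* (a nested tuple of clone labels) receives
    *muts_per_branch* heterozygous mutations.  A clone carries a mutation
    iff the branch lies on its root path, so its expected VAF is
    ``het_vaf`` when carried and 0 otherwise.  The parental sample is a
    cell mixture: its expected VAF is ``het_vaf`` times the summed
    mixture proportions of carrying clones.  Observed alt counts are
    binomial draws at the per-sample depth (``depth`` plus Poisson jitter,
    so depth >= the configured floor).

    When *outgroup* is given (e.g. a germline blood sample) an extra
    sample carrying none of the somatic mutations is emitted.  Including
    it as a taxon roots the inferred topology, which keeps the two
    root-adjacent clade stems on distinct unrooted edges — without it
    their mutations merge onto the central edge.

    Returns the mutation table (one row per mutation with per-sample
    ``depth_<s>`` / ``alt_<s>`` columns) and the generating ground truth.
    """
    if sum(parent_mixture.values()) > 1 + 1e-9:
        raise ValueError("parent_mixture proportions must sum to <= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tips = tree_tips(tree)
    clades = clades_of(tree)
    samples = tips + ([outgroup] if outgroup else []) + [parental_sample]

    n_mut = muts_per_branch * len(clades)
    refs, alts, contexts = _draw_contexts(rng, n_mut, channel_probs, purine_fraction)

    rows = []
    mutation_branches: dict[str, list[str]] = {}
    expected: dict[str, dict[str, float]] = {}
    positions = rng.choice(10**8, size=n_mut, replace=False)
    k = 0
    for clade in clades:
        parental_vaf = config.het_vaf * sum(parent_mixture.get(c, 0.0) for c in clade)
        for _ in range(muts_per_branch):
            mut_id = f"chr1:{int(positions[k]) + 1}"
            row = {
                "chrom": "chr1",
                "pos": int(positions[k]) + 1,
                "ref": refs[k],
                "alt": alts[k],
                "context": contexts[k],
            }
            exp_vafs = {}
            for s in samples:
                if s == parental_sample:
                    vaf = parental_vaf
                else:
                    vaf = config.het_vaf if s in clade else 0.0
                d = depth + (int(rng.poisson(depth_jitter)) if depth_jitter > 0 else 0)
                a = int(rng.binomial(d, vaf))
                row[f"depth_{s}"] = d
                row[f"alt_{s}"] = a
                exp_vafs[s] = vaf
            rows.append(row)
            mutation_branches[mut_id] = sorted(clade)
            expected[mut_id] = exp_vafs
            k += 1

    table = pd.DataFrame(rows)
    truth = GroundTruth(
        tree=tree,
        mutation_branches=mutation_branches,
        expected_vafs=expected,
        fractions={parental_sample: dict(parent_mixture)},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Expression counts with a planted depleted ligand


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + dispersion * mu^2.

    dispersion == 0 degenerates to Poisson.
    """
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    n_genes: int,
    samples: Sequence[str],
    planted: tuple[str, str, str] = ("AREG", "EGFR", "CL31"),
    config: SimulationConfig | None = None,
    n_decoy_pairs: int = 49,
    ligand_mean: float = 20.0,
    receptor_mean: float = 200.0,
    depletion_fold: float = 100.0,
    receptor_silent_prob: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a gene x sample count matrix with one planted depleted ligand.

    The planted ligand's mean is divided by *depletion_fold* in the target
    clone only; its receptor is expressed everywhere (including the
    target).  *n_decoy_pairs* additional ligand-receptor pairs have equal
    ligand means across samples (no depletion); each decoy receptor is
    silent (near-zero mean) with probability *receptor_silent_prob*,
    mirroring that most receptor genes are off in any one clone — the
    configuration the screen's receptor-expression gate exists to filter.
    Remaining genes are background with log-normal means.  Counts are
    negative binomial with the shared ``nb_dispersion`` of *config*.

    Returns (counts, pairs, truth): counts indexed by gene, pairs a
    two-column DataFrame (ligand, receptor).
    """
    config = config or SimulationConfig()
    ligand, receptor, target = planted
    if target not in samples:
        raise ValueError(f"target clone {target!r} not among samples")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    decoy_ligands = [f"LIG{i + 1:03d}" for i in range(n_decoy_pairs)]
    decoy_receptors = [f"REC{i + 1:03d}" for i in range(n_decoy_pairs)]
    special = [ligand, receptor] + decoy_ligands + decoy_receptors
    n_background = n_genes - len(special)
    if n_background < 0:
        raise ValueError("n_genes too small for the requested pair table")
    background = [f"G{i + 1:05d}" for i in range(n_background)]
    genes = special + background

    n_samples = len(samples)
    means = np.empty((len(genes), n_samples))
    means[0, :] = ligand_mean
    means[0, list(samples).index(target)] = ligand_mean / depletion_fold
    means[1, :] = receptor_mean
    silent = rng.random(n_decoy_pairs) < receptor_silent_prob
    for i in range(n_decoy_pairs):
        means[2 + i, :] = ligand_mean
        means[2 + n_decoy_pairs + i, :] = 0.1 if silent[i] else receptor_mean
    if n_background:
        bg = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_background)
        means[len(special):, :] = bg[:, None]

    counts = _nb_draw(rng, means, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=list(samples))
    pairs = pd.DataFrame(
        {
            "ligand": [ligand] + decoy_ligands,
            "receptor": [receptor] + decoy_receptors,
        }
    )
    truth = GroundTruth(planted={"ligand": ligand, "receptor": receptor, "target_clone": target})
    return counts_df, pairs, truth


# ---------------------------------------------------------------------------
# Gluc (blood luciferase) time series


def simulate_gluc(
    abundances: pd.Series,
    noise_sd: float,
    seed: int,
    n_mice: int = 1,
    scale: float = 1e-3,
    background: float = 0.0,
):
    """Simulate per-mouse blood luciferase series from a burden trajectory.

    *abundances* is a per-timepoint total tumor burden (index = weeks; the
    first point is the 24 h baseline).  Each mouse's reading is
    ``scale * abundance * exp(N(0, noise_sd))`` — multiplicative
    log-normal assay noise; ``noise_sd = 0`` makes the series exactly
    proportional to burden.
    """
    from .growth_dynamics import GlucSeries

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = abundances.to_numpy(dtype=float)
    series = []
    for m in range(n_mice):
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(values))) if noise_sd > 0 else 1.0
        readings = scale * values * noise
        series.append(
            GlucSeries(
                mouse_id=f"mouse{m + 1}",
                times=list(abundances.index),
                readings=list(readings),
                background=background,
            )
        )
    return series
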
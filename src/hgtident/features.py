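"""Compositional-atypicality features of a gene against its genome.

Each gene is scored against the genome-wide background with 15 scalar
signatures, every one a gene-vs-genome divergence that is zero when the
gene's composition matches the background:

* ``Karlin-DN`` — dinucleotide relative-abundance difference
  delta* = (1/16) * sum_XY | rho*_XY(gene) - rho*_XY(genome) | with
  rho*_XY = f*_XY / (f*_X f*_Y), frequencies symmetrized over the strand
  (sequence plus reverse complement), Karlin's convention.
* ``Karlin-CB`` — codon bias B(f|g) = sum_a p_a(f) * sum_{c in a}
  | f(c|a) - g(c|a) |: the amino-acid-frequency-weighted L1 distance
  between synonymous-codon usages, conditional on the amino acid.
* ``GC1-GC3`` — mean absolute deviation of the gene's positional G+C
  fractions from the genome's, averaged over the three codon positions.
  The raw (gc1, gc2, gc3) triple is available via :func:`gc_by_position`.
* ``Chi2-DN`` / ``Chi2-CB`` — Pearson goodness-of-fit statistic of the
  gene's dinucleotide / codon counts against background expectations,
  divided by the gene's unit count so genes of different length are
  comparable (set ``chi2_normalize=False`` for the raw statistic).
* ``JS-N`` / ``JS-DN`` / ``JS-CB`` — Jensen-Shannon divergence (bits,
  equal weights) between the gene's and the genome's nucleotide,
  dinucleotide and codon distributions.
* ``1-mer`` … ``7-mer`` — mean absolute word-frequency deviation
  (1/4^k) * sum_w | f_w(gene) - f_w(genome) |, strand-symmetrized.

Strand handling: the Karlin delta* and the k-mer deviations use
strand-symmetrized frequencies; the chi-square and Jensen-Shannon features
compare the coding strand directly (so a gene is exactly self-identical
to a background built from it alone); codon features are strand-specific
by definition.  Stop codons are excluded everywhere codons are counted:
the 61 sense codons are the support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import entropy

from .dataset import FEATURE_NAMES, HGT, NATIVE, LabeledDataset
from .seqio import GeneRecord, GenomeBundle, reverse_complement

logger = logging.getLogger(__name__)

MAX_K = 7

_LUT = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TABLE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_STOPS = set(_STANDARD_TABLE.stop_codons)
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]

SENSE_CODONS: tuple[str, ...] = tuple(c for c in _ALL_CODONS if c not in _STOPS)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS: tuple[str, ...] = tuple(sorted({_CODON_TABLE[c] for c in SENSE_CODONS}))
#: codon indices (into the 61-codon vector) grouped by amino acid
CODONS_OF_AA: dict[str, np.ndarray] = {
    aa: np.array([_CODON_INDEX[c] for c in SENSE_CODONS if _CODON_TABLE[c] == aa])
    for aa in AMINO_ACIDS
}


@dataclass
class FeatureConfig:
    """Numerical policy knobs for the feature computations."""

    pseudocount: float = 0.5
    js_weights: str = "equal"  # "equal" or "length"
    chi2_normalize: bool = True


DEFAULT_CONFIG = FeatureConfig()


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _count_kmers(arr: np.ndarray, k: int) -> np.ndarray:
    """Count k-mer words in one encoded sequence; windows touching N drop out."""
    n = arr.size
    out_size = 4**k
    if n < k:
        return np.zeros(out_size)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for i in range(k):
        window = arr[i : i + m]
        valid = window >= 0
        codes = codes * 4 + np.where(valid, window, 0)
        ok &= valid
    return np.bincount(codes[ok], minlength=out_size).astype(float)


def gene_kmer_counts(seq: str, k: int, symmetrize: bool) -> np.ndarray:
    arr = _encode(seq)
    counts = _count_kmers(arr, k)
    if symmetrize:
        counts = counts + _count_kmers(_encode(reverse_complement(seq)), k)
    return counts


def gene_codon_counts(seq: str) -> np.ndarray:
    """Counts over the 61 sense codons; stop and N-containing codons excluded."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    counts = np.zeros(len(SENSE_CODONS))
    for i in range(0, len(seq), 3):
        cod = seq[i : i + 3]
        idx = _CODON_INDEX.get(cod)
        if idx is not None:
            counts[idx] += 1
    return counts


def _codon_valid(seq: str) -> bool:
    return len(seq) % 3 == 0 and gene_codon_counts(seq).sum() >= 1


@dataclass
class CompositionModel:
    """Genome-wide background composition.

    ``kmer_counts[k]`` are strand-symmetrized word counts (every gene's
    sequence plus its reverse complement, counted separately so no
    junction words appear); ``kmer_counts_raw[k]`` are coding-strand-only
    counts used by the strand-specific chi-square and Jensen-Shannon
    features.  Codon counts cover the 61 sense codons, accumulated only
    over genes whose length is a multiple of 3.
    """

    kmer_counts: dict[int, np.ndarray]
    kmer_counts_raw: dict[int, np.ndarray]
    codon_counts: np.ndarray
    pos_gc: tuple[float, float, float]
    total_len: int
    n_codon_genes: int

    aa_codon_freq: dict[str, np.ndarray | None] = field(init=False)

    def __post_init__(self) -> None:
        self.aa_codon_freq = {}
        for aa, idx in CODONS_OF_AA.items():
            tot = self.codon_counts[idx].sum()
            self.aa_codon_freq[aa] = self.codon_counts[idx] / tot if tot > 0 else None

    def kmer_freq(self, k: int, symmetrized: bool = True) -> np.ndarray:
        counts = self.kmer_counts[k] if symmetrized else self.kmer_counts_raw[k]
        tot = counts.sum()
        if tot == 0:
            raise ValueError(f"background has no counted {k}-mers")
        return counts / tot

    def codon_freq(self) -> np.ndarray:
        tot = self.codon_counts.sum()
        if tot == 0:
            raise ValueError(
                "background has no codon counts: no gene with length divisible by 3"
            )
        return self.codon_counts / tot


def _gc_by_position_seq(seq: str) -> tuple[float, float, float]:
    out = []
    for pos in range(3):
        sub = seq[pos::3]
        denom = sum(1 for c in sub if c != "N")
        gc = sum(1 for c in sub if c in "GC")
        out.append(gc / denom if denom else 0.0)
    return tuple(out)  # type: ignore[return-value]


def build_composition(bundle: GenomeBundle) -> CompositionModel:
    """Accumulate the genome background over every gene in the bundle."""
    kmer_counts = {k: np.zeros(4**k) for k in range(1, MAX_K + 1)}
    kmer_raw = {k: np.zeros(4**k) for k in range(1, MAX_K + 1)}
    codon_counts = np.zeros(len(SENSE_CODONS))
    pos_gc_num = np.zeros(3)
    pos_gc_den = np.zeros(3)
    total_len = 0
    n_codon_genes = 0
    for gene in bundle:
        arr = _encode(gene.seq)
        rc = _encode(reverse_complement(gene.seq))
        total_len += len(gene.seq)
        for k in range(1, MAX_K + 1):
            fwd = _count_kmers(arr, k)
            kmer_raw[k] += fwd
            kmer_counts[k] += fwd + _count_kmers(rc, k)
        if len(gene.seq) % 3 == 0:
            counts = gene_codon_counts(gene.seq)
            if counts.sum() >= 1:
                codon_counts += counts
                n_codon_genes += 1
                for pos in range(3):
                    sub = gene.seq[pos::3]
                    pos_gc_den[pos] += sum(1 for c in sub if c != "N")
                    pos_gc_num[pos] += sum(1 for c in sub if c in "GC")
    pos_gc = tuple(
        float(pos_gc_num[i] / pos_gc_den[i]) if pos_gc_den[i] else 0.0 for i in range(3)
    )
    if n_codon_genes == 0:
        logger.warning(
            "no codon-eligible gene in bundle %s; codon features will fail",
            bundle.genome_id,
        )
    return CompositionModel(
        kmer_counts=kmer_counts,
        kmer_counts_raw=kmer_raw,
        codon_counts=codon_counts,
        pos_gc=pos_gc,  # type: ignore[arg-type]
        total_len=total_len,
        n_codon_genes=n_codon_genes,
    )


def _freq_with_pseudo(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Normalize counts; if any cell is zero, add the pseudocount to every cell."""
    if (counts == 0).any():
        counts = counts + pseudocount
    tot = counts.sum()
    if tot == 0:
        raise ValueError("empty count vector")
    return counts / tot


def _rho_star(mono_counts: np.ndarray, di_counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Dinucleotide odds ratios rho*_XY on symmetrized counts, as a 4x4 array."""
    mono = _freq_with_pseudo(mono_counts, pseudocount)
    tot = di_counts.sum()
    if tot == 0:
        raise ValueError("no dinucleotides counted")
    di = (di_counts / tot).reshape(4, 4)
    return di / np.outer(mono, mono)


def delta_star(
    gene: GeneRecord | str, bg: CompositionModel, config: FeatureConfig = DEFAULT_CONFIG
) -> float:
    """Karlin's dinucleotide relative-abundance difference delta*(gene, genome)."""
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    if len(seq) < 2:
        raise ValueError("delta* needs a gene of length >= 2")
    rho_f = _rho_star(
        gene_kmer_counts(seq, 1, symmetrize=True),
        gene_kmer_counts(seq, 2, symmetrize=True),
        config.pseudocount,
    )
    rho_g = _rho_star(bg.kmer_counts[1], bg.kmer_counts[2], config.pseudocount)
    return float(np.abs(rho_f - rho_g).sum() / 16.0)


def karlin_codon_bias(
    gene: GeneRecord | str, bg: CompositionModel, config: FeatureConfig = DEFAULT_CONFIG
) -> float:
    """Codon bias B(gene|genome): amino-acid-weighted L1 synonymous-usage distance."""
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    counts = gene_codon_counts(seq)
    n = counts.sum()
    if n < 1:
        raise ValueError("no sense codons in gene")
    total = 0.0
    for aa, idx in CODONS_OF_AA.items():
        aa_count = counts[idx].sum()
        if aa_count == 0:
            continue
        p_a = aa_count / n
        f_ca = counts[idx] / aa_count
        g_ca = bg.aa_codon_freq[aa]
        if g_ca is None:
            logger.warning(
                "amino acid %s absent from genome background; using uniform codon usage", aa
            )
            g_ca = np.full(len(idx), 1.0 / len(idx))
        total += p_a * float(np.abs(f_ca - g_ca).sum())
    return total


def gc_by_position(gene: GeneRecord | str) -> tuple[float, float, float]:
    """G+C fraction at codon positions 1..3; N positions excluded."""
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    if len(seq) % 3 != 0:
        raise ValueError(f"gene length {len(seq)} is not a multiple of 3")
    return _gc_by_position_seq(seq)


def gc_deviation(
    gene: GeneRecord | str, bg: CompositionModel
) -> float:
    """Mean |gc_i(gene) - gc_i(genome)| over the three codon positions."""
    g = gc_by_position(gene)
    return float(np.mean([abs(g[i] - bg.pos_gc[i]) for i in range(3)]))


def chi2_bias(
    gene: GeneRecord | str,
    bg: CompositionModel,
    unit: str,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float:
    """Pearson chi-square of gene unit counts against background expectation.

    ``unit`` is ``"dinucleotide"`` or ``"codon"``.  Divided by the gene's
    unit count when ``config.chi2_normalize`` (the default).
    """
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    if unit == "dinucleotide":
        observed = gene_kmer_counts(seq, 2, symmetrize=False)
        bg_counts = bg.kmer_counts_raw[2]
    elif unit == "codon":
        observed = gene_codon_counts(seq)
        bg_counts = bg.codon_counts
    else:
        raise ValueError(f"unit must be 'dinucleotide' or 'codon', got {unit!r}")
    n = observed.sum()
    if n < 1:
        raise ValueError(f"gene has no counted {unit}s")
    if (bg_counts[observed > 0] == 0).any():
        bg_counts = bg_counts + config.pseudocount
    g_freq = bg_counts / bg_counts.sum()
    support = g_freq > 0
    expected = n * g_freq[support]
    stat = float(((observed[support] - expected) ** 2 / expected).sum())
    # units observed where expectation is exactly zero cannot occur here
    # (pseudocount policy above), but guard the normalization regardless
    return stat / n if config.chi2_normalize else stat


def js_divergence(
    gene: GeneRecord | str,
    bg: CompositionModel,
    unit: str,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float:
    """Jensen-Shannon divergence (bits) between gene and genome distributions.

    ``unit`` is ``"nucleotide"``, ``"dinucleotide"`` or ``"codon"``.
    With equal weights (default) the value lies in [0, 1] bits and reaches
    1 only on disjoint supports.
    """
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    if unit == "nucleotide":
        p_counts = gene_kmer_counts(seq, 1, symmetrize=False)
        q = bg.kmer_freq(1, symmetrized=False)
    elif unit == "dinucleotide":
        p_counts = gene_kmer_counts(seq, 2, symmetrize=False)
        q = bg.kmer_freq(2, symmetrized=False)
    elif unit == "codon":
        p_counts = gene_codon_counts(seq)
        q = bg.codon_freq()
    else:
        raise ValueError(f"unknown unit {unit!r}")
    n = p_counts.sum()
    if n < 1:
        raise ValueError(f"gene has no counted {unit}s")
    p = p_counts / n
    if config.js_weights == "length":
        w1 = n / (n + bg.total_len)
        w2 = 1.0 - w1
    else:
        w1 = w2 = 0.5
    m = w1 * p + w2 * q
    js = entropy(m, base=2) - w1 * entropy(p, base=2) - w2 * entropy(q, base=2)
    return float(max(js, 0.0))


def kmer_deviation(gene: GeneRecord | str, bg: CompositionModel, k: int) -> float:
    """Mean absolute strand-symmetrized word-frequency deviation at order k."""
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    if len(seq) < k:
        raise ValueError(f"gene of length {len(seq)} is shorter than k={k}")
    counts = gene_kmer_counts(seq, k, symmetrize=True)
    n = counts.sum()
    if n < 1:
        raise ValueError(f"gene has no counted {k}-mers")
    f = counts / n
    g = bg.kmer_freq(k, symmetrized=True)
    return float(np.abs(f - g).sum() / (4**k))


def feature_vector(
    gene: GeneRecord | str, bg: CompositionModel, config: FeatureConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """The 15 features in canonical order (see :data:`hgtident.dataset.FEATURE_NAMES`)."""
    values = [
        delta_star(gene, bg, config),
        karlin_codon_bias(gene, bg, config),
        gc_deviation(gene, bg),
        chi2_bias(gene, bg, "dinucleotide", config),
        chi2_bias(gene, bg, "codon", config),
        js_divergence(gene, bg, "nucleotide", config),
        js_divergence(gene, bg, "dinucleotide", config),
        js_divergence(gene, bg, "codon", config),
    ]
    values.extend(kmer_deviation(gene, bg, k) for k in range(1, MAX_K + 1))
    out = np.array(values, dtype=float)
    assert out.shape == (len(FEATURE_NAMES),)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value")
    return out


def extract_features(
    bundle: GenomeBundle,
    bg: CompositionModel | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> LabeledDataset:
    """Feature matrix for a whole bundle against its own background.

    Genes failing codon validity (length not a multiple of 3, or no sense
    codon) are dropped with a warning — codon-based features need in-frame
    sequences.
    """
    if bg is None:
        bg = build_composition(bundle)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    ys: list[int] = []
    for gene in bundle:
        if not _codon_valid(gene.seq) or len(gene.seq) < MAX_K:
            logger.warning("dropping gene %s: not codon-valid", gene.id)
            continue
        ids.append(gene.id)
        rows.append(feature_vector(gene, bg, config))
        ys.append(1 if gene.label == HGT else 0)
    X = np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    return LabeledDataset(ids=ids, X=X, y=np.array(ys, dtype=int))
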
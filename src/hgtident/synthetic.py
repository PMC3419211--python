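"""Synthetic genomes with planted horizontally transferred genes.

The generator emulates the structure of a real detection problem: a
recipient genome whose coding sequences share one compositional model,
with a small minority of genes drawn from a compositionally divergent
donor model, plus ground-truth labels.  Every stage of the tool can then
be exercised end-to-end with no external data.

A genome model couples an order-2 Markov nucleotide model (a 16 x 4
transition table, giving the background its dinucleotide structure) with
a per-amino-acid synonymous codon usage table.  Genes are built codon by
codon: the amino-acid sequence is sampled i.i.d. from a fixed
distribution (uniform over the 20 residues by default), and the codon
for each residue is drawn with probability proportional to
``usage(codon | aa) * markov_weight(codon | previous two nucleotides)``.
Every gene starts with ATG, ends with an appended TAA and contains no
internal stop.

The donor model diverges from the recipient in two independently
tunable ways: ``delta_gc`` shifts the donor's expected G+C content (the
codon usage is exponentially tilted toward G+C-rich codons, with the
tilt solved numerically against the exact stationary composition of the
generative chain), and ``codon_eps`` perturbs the synonymous codon
usage and the Markov transitions multiplicatively.  With both zero the
donor equals the recipient and the two classes are indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .dataset import HGT, NATIVE
from .features import AMINO_ACIDS, CODONS_OF_AA, SENSE_CODONS
from .seqio import GeneRecord, GenomeBundle

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}
_GC_COUNT = np.array([sum(1 for ch in c if ch in "GC") for c in SENSE_CODONS])
_LAST2 = np.array([_NT_INDEX[c[1]] * 4 + _NT_INDEX[c[2]] for c in SENSE_CODONS])


@dataclass
class GenomeModel:
    """Order-2 Markov nucleotide model + codon usage table + residue frequencies."""

    trans: np.ndarray  # (16, 4): P(next nt | previous two nt)
    codon_usage: dict[str, np.ndarray]  # per amino acid, over its codons
    aa_probs: np.ndarray  # (20,) amino-acid sampling distribution

    def codon_weights(self) -> list[list[np.ndarray]]:
        """Normalized codon probabilities per (previous-2-nt state, amino acid)."""
        table: list[list[np.ndarray]] = []
        for s in range(16):
            per_aa: list[np.ndarray] = []
            for aa in AMINO_ACIDS:
                idx = CODONS_OF_AA[aa]
                w = np.empty(idx.size)
                for j, ci in enumerate(idx):
                    c = SENSE_CODONS[ci]
                    n0, n1, n2 = (_NT_INDEX[ch] for ch in c)
                    s1 = (s % 4) * 4 + n0
                    s2 = n0 * 4 + n1
                    w[j] = (
                        self.codon_usage[aa][j]
                        * self.trans[s, n0]
                        * self.trans[s1, n1]
                        * self.trans[s2, n2]
                    )
                per_aa.append(w / w.sum())
            table.append(per_aa)
        return table

    def _codon_given_state(self) -> np.ndarray:
        """P(codon | state) marginal over amino acids, shape (16, 61)."""
        weights = self.codon_weights()
        P = np.zeros((16, len(SENSE_CODONS)))
        for s in range(16):
            for ai, aa in enumerate(AMINO_ACIDS):
                P[s, CODONS_OF_AA[aa]] += self.aa_probs[ai] * weights[s][ai]
        return P

    def expected_gc(self) -> float:
        """Exact asymptotic G+C fraction of genes generated from this model."""
        P = self._codon_given_state()
        K = np.zeros((16, 16))
        for ci in range(len(SENSE_CODONS)):
            K[:, _LAST2[ci]] += P[:, ci]
        evals, evecs = np.linalg.eig(K.T)
        pi = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        pi = np.abs(pi) / np.abs(pi).sum()
        return float(pi @ P @ (_GC_COUNT / 3.0))


def make_recipient_model(
    seed: int, gc: float = 0.5, context_sigma: float = 0.6, usage_conc: float = 2.0
) -> GenomeModel:
    """A random but reproducible recipient background.

    ``context_sigma`` controls how strongly transitions deviate from the
    i.i.d. base composition (dinucleotide structure); ``usage_conc`` is
    the Dirichlet concentration of the synonymous codon usage (smaller =
    more biased usage).
    """
    rng = np.random.default_rng(seed)
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    z = rng.normal(size=(16, 4))
    trans = base * np.exp(context_sigma * z)
    trans /= trans.sum(axis=1, keepdims=True)
    usage = {
        aa: rng.dirichlet(np.full(CODONS_OF_AA[aa].size, usage_conc)) for aa in AMINO_ACIDS
    }
    aa_probs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    model = GenomeModel(trans=trans, codon_usage=usage, aa_probs=aa_probs)
    return _calibrate_gc(model, gc, f"recipient gc={gc}")


def _tilt_usage(model: GenomeModel, t: float) -> GenomeModel:
    """Exponentially tilt codon usage toward G+C-rich codons by factor t."""
    usage = {}
    for aa in AMINO_ACIDS:
        gc_counts = _GC_COUNT[CODONS_OF_AA[aa]]
        w = model.codon_usage[aa] * t**gc_counts
        usage[aa] = w / w.sum()
    return replace(model, codon_usage=usage)


def _calibrate_gc(model: GenomeModel, target: float, what: str) -> GenomeModel:
    """Tilt codon usage so the model's exact expected GC equals ``target``."""
    lo_t, hi_t = 1e-4, 1e4
    gc_floor = _tilt_usage(model, lo_t).expected_gc()
    gc_ceil = _tilt_usage(model, hi_t).expected_gc()
    if not gc_floor < target < gc_ceil:
        raise ValueError(
            f"infeasible {what}: target GC {target:.3f} outside the reachable "
            f"range ({gc_floor:.3f}, {gc_ceil:.3f}) under a uniform amino-acid "
            "distribution"
        )
    t = brentq(lambda tt: _tilt_usage(model, tt).expected_gc() - target, lo_t, hi_t)
    return _tilt_usage(model, t)


def derive_donor(
    recipient: GenomeModel, delta_gc: float, codon_eps: float, seed: int
) -> GenomeModel:
    """Donor model: GC shifted by ``delta_gc``, usage/transitions perturbed by ``codon_eps``."""
    rng = np.random.default_rng(seed)
    usage = {}
    for aa in AMINO_ACIDS:
        w = recipient.codon_usage[aa] * np.exp(
            codon_eps * rng.normal(size=CODONS_OF_AA[aa].size)
        )
        usage[aa] = w / w.sum()
    trans = recipient.trans * np.exp(0.5 * codon_eps * rng.normal(size=(16, 4)))
    trans /= trans.sum(axis=1, keepdims=True)
    donor = GenomeModel(trans=trans, codon_usage=usage, aa_probs=recipient.aa_probs.copy())
    if delta_gc != 0.0:
        target = recipient.expected_gc() + delta_gc
        donor = _calibrate_gc(donor, target, f"delta_gc={delta_gc:+.3f}")
    return donor


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic genome.

    Defaults mirror a realistically imbalanced bacterial genome sample:
    10% planted HGT genes, gene lengths 100-400 codons, recipient GC 0.45,
    donor GC shifted by +0.10 with a moderate codon-usage perturbation.
    """

    n_genes: int = 200
    hgt_fraction: float = 0.10
    gene_len_range: tuple[int, int] = (100, 400)  # codons, incl. start + stop
    gc: float = 0.45
    delta_gc: float = 0.10
    codon_eps: float = 0.7
    context_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hgt_fraction < 0.5:
            raise ValueError("hgt_fraction must be in [0, 0.5)")
        lo, hi = self.gene_len_range
        if lo < 4 or hi < lo:
            raise ValueError("gene_len_range must satisfy 4 <= lo <= hi (codons)")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")


def _sample_gene(
    n_codons: int,
    weights: list[list[np.ndarray]],
    aa_probs: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """One CDS: ATG + (n_codons - 2) body codons + TAA."""
    parts = ["ATG"]
    state = _NT_INDEX["T"] * 4 + _NT_INDEX["G"]
    aas = rng.choice(len(AMINO_ACIDS), size=n_codons - 2, p=aa_probs)
    us = rng.uniform(size=n_codons - 2)
    for ai, u in zip(aas, us):
        w = weights[state][ai]
        j = int(np.searchsorted(np.cumsum(w), u * w.sum()))
        j = min(j, w.size - 1)
        ci = CODONS_OF_AA[AMINO_ACIDS[ai]][j]
        parts.append(SENSE_CODONS[ci])
        state = _LAST2[ci]
    parts.append("TAA")
    return "".join(parts)


def generate(spec: SyntheticSpec) -> GenomeBundle:
    """Generate a labeled genome: native genes from the recipient model,
    ``round(n_genes * hgt_fraction)`` planted HGT genes from the donor model.

    Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_model, s_donor, s_labels, s_genes = (s.generate_state(1)[0] % 2**31 for s in ss.spawn(4))
    recipient = make_recipient_model(int(s_model), gc=spec.gc, context_sigma=spec.context_sigma)
    donor = derive_donor(recipient, spec.delta_gc, spec.codon_eps, int(s_donor))

    n_hgt = round(spec.n_genes * spec.hgt_fraction)
    rng_labels = np.random.default_rng(int(s_labels))
    hgt_idx = set(rng_labels.choice(spec.n_genes, size=n_hgt, replace=False).tolist())

    rng = np.random.default_rng(int(s_genes))
    rec_weights = recipient.codon_weights()
    don_weights = donor.codon_weights()
    lo, hi = spec.gene_len_range
    genes: list[GeneRecord] = []
    for i in range(spec.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        is_hgt = i in hgt_idx
        model = donor if is_hgt else recipient
        weights = don_weights if is_hgt else rec_weights
        seq = _sample_gene(n_codons, weights, model.aa_probs, rng)
        genes.append(
            GeneRecord(id=f"gene_{i + 1:04d}", seq=seq, label=HGT if is_hgt else NATIVE)
        )
    return GenomeBundle(genome_id=f"synthetic_seed{spec.seed}", genes=genes)


#: Benchmark difficulty tiers: donor divergence strong / moderate / weak.
BENCHMARK_SPECS: dict[str, dict] = {
    "easy": dict(delta_gc=0.15, codon_eps=1.2),
    "medium": dict(delta_gc=0.04, codon_eps=0.3),
    "hard": dict(delta_gc=0.02, codon_eps=0.15),
}


def benchmark_spec(difficulty: str, seed: int = 0, **overrides) -> SyntheticSpec:
    if difficulty not in BENCHMARK_SPECS:
        raise ValueError(f"difficulty must be one of {sorted(BENCHMARK_SPECS)}")
    kwargs = dict(BENCHMARK_SPECS[difficulty])
    kwargs.update(overrides)
    return SyntheticSpec(seed=seed, **kwargs)


def benchmark_suite(seed: int = 0) -> list[tuple[GenomeBundle, str]]:
    """The fixed easy/medium/hard benchmark bundles for one seed."""
    return [(generate(benchmark_spec(d, seed=seed)), d) for d in ("easy", "medium", "hard")]


def write_fasta(bundle: GenomeBundle, path: str | Path) -> None:
    lines = []
    for g in bundle:
        lines.append(f">{g.id}")
        lines.extend(g.seq[i : i + 70] for i in range(0, len(g.seq), 70))
    Path(path).write_text("\n".join(lines) + "\n")
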
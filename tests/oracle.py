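"""Independent brute-force recomputation of the 15 features.

Deliberately naive: pure-Python dictionaries, explicit loops, the genetic
code obtained by translating each codon with Bio.Seq.  Used as the
cross-check for the vectorized implementations; shares nothing with them
beyond the documented numerical policies (Jeffreys 0.5 pseudocount on a
count vector containing a zero where a ratio needs it, stop codons
excluded, strand symmetrization for the Karlin and k-mer features only).
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def words(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def count_words(seqs: list[str], k: int) -> dict[str, int]:
    d: dict[str, int] = {w: 0 for w in words(k)}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" not in w:
                d[w] += 1
    return d


def _freqs(counts: dict[str, int], pseudo: float = 0.5) -> dict[str, float]:
    vals = counts
    if any(v == 0 for v in counts.values()):
        vals = {w: v + pseudo for w, v in counts.items()}
    tot = sum(vals.values())
    return {w: v / tot for w, v in vals.items()}


def _plain_freqs(counts: dict[str, int]) -> dict[str, float]:
    tot = sum(counts.values())
    return {w: v / tot for w, v in counts.items()}


STOPS = {"TAA", "TAG", "TGA"}
CODON_AA = {w: str(Seq(w).translate()) for w in words(3) if w not in STOPS}
AA_SET = sorted(set(CODON_AA.values()))


def codon_counts(seq: str) -> dict[str, int]:
    d = {c: 0 for c in CODON_AA}
    for i in range(0, len(seq), 3):
        c = seq[i : i + 3]
        if c in d:
            d[c] += 1
    return d


def oracle_delta_star(gene: str, bg: list[str]) -> float:
    def rho(seqs):
        both = seqs + [revcomp(s) for s in seqs]
        mono = _freqs(count_words(both, 1))
        di = _plain_freqs(count_words(both, 2))
        return {x + y: di[x + y] / (mono[x] * mono[y]) for x in "ACGT" for y in "ACGT"}

    rf, rg = rho([gene]), rho(bg)
    return sum(abs(rf[w] - rg[w]) for w in rf) / 16.0


def oracle_karlin_cb(gene: str, bg: list[str]) -> float:
    gene_cod = codon_counts(gene)
    bg_cod = {c: 0 for c in CODON_AA}
    for s in bg:
        if len(s) % 3 == 0:
            for c, v in codon_counts(s).items():
                bg_cod[c] += v
    n = sum(gene_cod.values())
    total = 0.0
    for aa in AA_SET:
        cods = [c for c in CODON_AA if CODON_AA[c] == aa]
        aa_n = sum(gene_cod[c] for c in cods)
        if aa_n == 0:
            continue
        bg_n = sum(bg_cod[c] for c in cods)
        for c in cods:
            f = gene_cod[c] / aa_n
            g = bg_cod[c] / bg_n if bg_n > 0 else 1.0 / len(cods)
            total += (aa_n / n) * abs(f - g)
    return total


def oracle_gc_dev(gene: str, bg: list[str]) -> float:
    def gc_pos(seqs):
        out = []
        for pos in range(3):
            num = den = 0
            for s in seqs:
                for c in s[pos::3]:
                    if c != "N":
                        den += 1
                        if c in "GC":
                            num += 1
            out.append(num / den if den else 0.0)
        return out

    gg = gc_pos([gene])
    bb = gc_pos([s for s in bg if len(s) % 3 == 0 and sum(codon_counts(s).values()) >= 1])
    return sum(abs(gg[i] - bb[i]) for i in range(3)) / 3.0


def oracle_chi2(gene: str, bg: list[str], unit: str) -> float:
    if unit == "dinucleotide":
        obs = count_words([gene], 2)
        bgc = count_words(bg, 2)
    else:
        obs = codon_counts(gene)
        bgc = {c: 0 for c in CODON_AA}
        for s in bg:
            if len(s) % 3 == 0:
                for c, v in codon_counts(s).items():
                    bgc[c] += v
    n = sum(obs.values())
    if any(bgc[w] == 0 for w in obs if obs[w] > 0):
        bgc = {w: v + 0.5 for w, v in bgc.items()}
    tot = sum(bgc.values())
    stat = 0.0
    for w in obs:
        g = bgc[w] / tot
        if g > 0:
            e = n * g
            stat += (obs[w] - e) ** 2 / e
    return stat / n


def _entropy(p: dict[str, float]) -> float:
    return -sum(v * math.log2(v) for v in p.values() if v > 0)


def oracle_js(gene: str, bg: list[str], unit: str) -> float:
    if unit == "nucleotide":
        p = _plain_freqs(count_words([gene], 1))
        q = _plain_freqs(count_words(bg, 1))
    elif unit == "dinucleotide":
        p = _plain_freqs(count_words([gene], 2))
        q = _plain_freqs(count_words(bg, 2))
    else:
        p = _plain_freqs(codon_counts(gene))
        qc = {c: 0 for c in CODON_AA}
        for s in bg:
            if len(s) % 3 == 0:
                for c, v in codon_counts(s).items():
                    qc[c] += v
        q = _plain_freqs(qc)
    m = {w: 0.5 * p.get(w, 0.0) + 0.5 * q.get(w, 0.0) for w in set(p) | set(q)}
    return _entropy(m) - 0.5 * _entropy(p) - 0.5 * _entropy(q)


def oracle_kmer_dev(gene: str, bg: list[str], k: int) -> float:
    f = _plain_freqs(count_words([gene, revcomp(gene)], k))
    g = _plain_freqs(count_words(bg + [revcomp(s) for s in bg], k))
    return sum(abs(f[w] - g[w]) for w in words(k)) / 4**k


def oracle_feature_vector(gene: str, bg: list[str]) -> list[float]:
    vals = [
        oracle_delta_star(gene, bg),
        oracle_karlin_cb(gene, bg),
        oracle_gc_dev(gene, bg),
        oracle_chi2(gene, bg, "dinucleotide"),
        oracle_chi2(gene, bg, "codon"),
        oracle_js(gene, bg, "nucleotide"),
        oracle_js(gene, bg, "dinucleotide"),
        oracle_js(gene, bg, "codon"),
    ]
    vals.extend(oracle_kmer_dev(gene, bg, k) for k in range(1, 8))
    return vals
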
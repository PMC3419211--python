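"""Sequence and table I/O: CDS reading, label attachment, feature tables.

Conventions enforced at load time, relied on by every downstream module:

* sequences are uppercase, on the coding strand, frame 0 (minus-strand
  GenBank CDS are reverse-complemented by ``feature.extract``);
* ``U`` is mapped to ``T``; ambiguity codes other than ``N`` are mapped to
  ``N`` (with a logged count) so that frequency denominators stay exact —
  k-mers and codons containing ``N`` are simply excluded from counts;
* GenBank coordinates are 1-based inclusive on input; no coordinates are
  retained internally (all features are per-gene and position-free).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .dataset import FEATURE_NAMES, HGT, NATIVE, UNKNOWN, LabeledDataset

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> tuple[str, int]:
    """Uppercase, U->T, non-ACGTN -> N. Returns (sequence, n_ambiguous)."""
    s = seq.upper().replace("U", "T")
    n_amb = sum(1 for c in s if c not in _VALID)
    if n_amb:
        s = "".join(c if c in _VALID else "N" for c in s)
    return s, n_amb


@dataclass
class GeneRecord:
    """One coding sequence: id, in-frame nucleotide string, label."""

    id: str
    seq: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")
        if self.label not in (HGT, NATIVE, UNKNOWN):
            raise ValueError(f"invalid label {self.label!r} for gene {self.id}")


@dataclass
class GenomeBundle:
    """An ordered collection of genes from one genome."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def label_counts(self) -> dict[str, int]:
        counts = {HGT: 0, NATIVE: 0, UNKNOWN: 0}
        for g in self.genes:
            counts[g.label] += 1
        return counts


def read_cds_fasta(path: str | Path, genome_id: str | None = None) -> GenomeBundle:
    """Read in-frame CDS from a multi-FASTA file.

    The first whitespace-delimited token of each header is the gene id.
    All records get label ``UNKNOWN``.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    total_amb = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValueError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        seq, n_amb = _normalize(str(rec.seq))
        total_amb += n_amb
        genes.append(GeneRecord(id=gid, seq=seq))
    if not genes:
        raise ValueError(f"no FASTA records found in {path}")
    if total_amb:
        logger.warning("%d ambiguous bases mapped to N while reading %s", total_amb, path)
    return GenomeBundle(genome_id=genome_id or path.stem, genes=genes)


def read_genbank_cds(path: str | Path, genome_id: str | None = None) -> GenomeBundle:
    """Extract CDS features from a GenBank flat file.

    Each CDS becomes one gene: the coding-strand, join-resolved sequence.
    Ids come from ``locus_tag``, then ``protein_id``, then a positional tag.
    CDS with unresolvable locations are skipped with a warning.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    n_cds = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            try:
                raw = str(feat.extract(rec.seq))
            except Exception as exc:  # unresolvable location
                logger.warning("skipping CDS with unresolvable location in %s: %s", path, exc)
                continue
            quals = feat.qualifiers
            gid = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or f"CDS_{n_cds:04d}"
            )
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid!r} in {path}")
            seen.add(gid)
            seq, _ = _normalize(raw)
            genes.append(GeneRecord(id=gid, seq=seq))
    if n_cds == 0:
        raise ValueError(f"no CDS features in {path}")
    return GenomeBundle(genome_id=genome_id or path.stem, genes=genes)


def attach_labels(bundle: GenomeBundle, labels) -> GenomeBundle:
    """Attach HGT/NATIVE labels to genes by id, in place.

    ``labels`` is a mapping ``id -> label`` or an iterable of ``(id, label)``
    pairs.  With pairs, a repeated id is resolved last-write-wins (warned).
    Unlisted genes keep ``UNKNOWN``.  An id absent from the bundle is a hard
    error.  Returns the bundle (use :meth:`GenomeBundle.label_counts` for
    the per-label tally).
    """
    if hasattr(labels, "items"):
        items = list(labels.items())
    else:
        items = list(labels)
        ids = [i for i, _ in items]
        for dup in sorted({i for i in ids if ids.count(i) > 1}):
            logger.warning("gene %s listed more than once in labels; last write wins", dup)
    by_id = {g.id: g for g in bundle.genes}
    for gid, lab in items:
        if gid not in by_id:
            raise KeyError(f"label references unknown gene id {gid!r}")
        if lab not in (HGT, NATIVE):
            raise ValueError(f"label for {gid!r} must be HGT or NATIVE, got {lab!r}")
        by_id[gid].label = lab
    return bundle


def read_labels(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV (gene id, HGT|NATIVE); '#' lines are comments."""
    pairs: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"label line must have 2 tab-separated fields: {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def write_labels(bundle: GenomeBundle, path: str | Path) -> None:
    lines = [f"{g.id}\t{g.label}" for g in bundle.genes if g.label != UNKNOWN]
    Path(path).write_text("\n".join(lines) + "\n")


_LABEL_TO_INT = {HGT: 1, NATIVE: 0, UNKNOWN: 0}
_INT_TO_LABEL = {1: HGT, 0: NATIVE}


def write_feature_table(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a TSV feature table: id, the 15 features, label.

    Floats are written at 10 significant digits, so a write/read round
    trip is element-wise identical to better than 1e-9 relative error.
    """
    lines = ["\t".join(("id", *FEATURE_NAMES, "label"))]
    for i in range(dataset.n_genes):
        vals = "\t".join(f"{v:.10g}" for v in dataset.X[i])
        lines.append(f"{dataset.ids[i]}\t{vals}\t{_INT_TO_LABEL[int(dataset.y[i])]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path) -> LabeledDataset:
    """Read a TSV feature table written by :func:`write_feature_table`."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise ValueError(f"empty feature table {path}")
    header = text[0].split("\t")
    expected = ["id", *FEATURE_NAMES, "label"]
    missing = [c for c in expected if c not in header]
    if missing:
        raise ValueError(f"feature table {path} missing columns: {', '.join(missing)}")
    col = {name: header.index(name) for name in expected}
    ids: list[str] = []
    rows: list[list[float]] = []
    ys: list[int] = []
    for line in text[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        ids.append(parts[col["id"]])
        rows.append([float(parts[col[name]]) for name in FEATURE_NAMES])
        lab = parts[col["label"]]
        if lab not in _LABEL_TO_INT:
            raise ValueError(f"invalid label {lab!r} in {path}")
        ys.append(_LABEL_TO_INT[lab])
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(FEATURE_NAMES)))
    return LabeledDataset(ids=ids, X=X, y=np.array(ys, dtype=int))
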